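# Methods

## Signal model and generator

The synthetic cohort emulates a two-block elicitation design: each producer
contributes one continuous 4-channel recording at 1000 samples/s holding a
spontaneous block followed by a posed block (default 90 s per block),
with a configurable number of labelled smile events per block separated by
at least 1 s.

**Smile dynamics.** Each event draws a parameter vector — onset duration,
offset duration, apex amplitude, peak count, inter-peak dip — from per-type
laws. Continuous parameters follow truncated normals centred on the type
means scaled by a log-normal per-producer multiplicative effect
(`producer_effect_sd`, default 0.3). Because the configured SDs are of the
same order as the means, naive truncation at the physical lower bounds
(durations ≥ 1 frame, apex ≥ 0.05 mV) would inflate the realised mean by up
to ~30%; the latent location is therefore solved (Brent's method on the
closed-form truncated mean) so the *truncated* mean equals the configured
mean. Default type means and SDs are the published spatio-temporal feature
table: spontaneous onset 37.05 (SD 33.10) frames, offset 44.40 (41.05),
apex 1.21 (1.21) mV; posed onset 33.72 (32.74), offset 42.91 (44.81),
apex 0.89 (0.85) mV. Peak count is a rounded normal (mean 1.5, SD 0.5,
clipped to [1, 5]) identical across types; the dip between consecutive
apexes is 30 ± 10% of the apex.

**Durations are envelope frames.** The published table labels durations
"ms", but ~37 ms smile onsets are physiologically implausible (the same
source reports onset-time confidence intervals on a visibly different
scale), and the envelope is computed at 10 frames/s. Durations are therefore
interpreted as 100 ms envelope frames (37.05 frames ≈ 3.7 s), a documented
reading rather than a claim about the source's units.

**Waveform synthesis.** The parameter vector becomes a piecewise-linear
activation profile at 10 frames/s (rise to apex, optional inter-peak dips
6 frames apart, fall to zero), linearly interpolated to the signal rate.
Surface EMG is modelled as amplitude-modulated band-limited noise — the
standard phenomenology: the smile source is zero-mean Gaussian noise
band-limited to 5–350 Hz and multiplied by the summed activation; three
background muscle sources run at a low activation (0.1 mV) with mild slow
(< 0.5 Hz) amplitude modulation around a constant level. Strictly constant
Gaussian backgrounds would be unidentifiable by ICA (no contrast separates
Gaussians), so the mild modulation keeps the decomposition well-posed while
staying "low and roughly constant". The carrier is normalised to
E|carrier| = 1 so the rectified-mean envelope reads directly in the
configured mV scale: the envelope apex inside a labelled event recovers the
sampled apex amplitude (within ~10% after smoothing). Channels are
`mixing_matrix @ sources` (default: a symmetric full-rank volume-conduction
matrix with off-diagonal decay) plus common-mode 50 Hz line noise with
harmonics at amplitude `line_noise_amp/k` up to 350 Hz (so the notch bank is
exercised at every centre), two slow drift sinusoids (≤ 0.2 Hz,
`drift_amp` = 0.5 mV), and white sensor noise (SD 0.05 mV).

**What the generator does not emulate:** motion and blink artifacts,
electrode impedance changes, non-stationary line noise, laughter acoustics
coupling, eye-region (Duchenne) activity as a separate source, and any
cross-ethnicity or gender structure. Passing tests on this cohort show that
the pipeline recovers what the model puts in — calibrated envelopes, correct
feature directions, separable intra-individual classes — not that real
facial EMG is this clean.

## Conditioning

Zero-phase (forward–backward) filtering throughout, preserving onset/offset
timing: 4th-order Butterworth band-pass 5–350 Hz, then 2nd-order IIR notches
(quality 30) at every 50 Hz harmonic up to and including 350 Hz, then linear
detrending. "Up to 350 Hz" is read as inclusive. The first and last 0.5 s of
each recording are excluded from feature extraction (filter edge effects).

## Source separation

FastICA with a log-cosh contrast and deflation, whitened to unit-variance
components, seeded deterministically per stage (see *Seeding*).
Rank-deficient channel covariance (condition number > 1e10) is rejected
before fitting; non-convergence raises with the iteration budget. Component
signs are fixed by a positive-skewness convention — EMG bursts are sparse
and rectification downstream makes the sign immaterial, but a fixed
convention keeps runs comparable. The smile component is selected by the
ratio of rectified mean inside labelled smile intervals to outside, ties to
the lowest index. For feature extraction the selected component is rescaled
by the largest absolute entry of its estimated mixing column, restoring the
mV amplitude it contributes to the channel it drives hardest (ICA components
are otherwise scale-free).

## Envelope and features

Rectified component → means over non-overlapping 100 ms windows
(10 frames/s) → Savitzky–Golay filter, polynomial order 5, frame length 41
(a 4.1 s span, applied at the envelope rate, i.e. after the windowed
averaging), negatives clamped to 0. Series shorter than 41 frames are
rejected. Maxima need a prominence of 5% of the envelope's global range
(suppresses smoothing ripple; no threshold is stated in the source).
Between-maxima minima alternate with the maxima; on flat minimal plateaus
the trough is taken adjacent to the flank (last tied frame before a rise,
first after a fall), which anchors onset/offset durations at the point where
the envelope actually leaves baseline.

For every maximum inside a labelled smile interval, one feature row: apex
magnitude; onset trough = nearest preceding minimum bounded by the event
onset (if the nearest minimum lies before the event, the lowest frame
between event onset and peak); offset trough mirrored at the event offset;
durations floored at 1 frame; magnitude changes signed (onset ≥ 0,
offset ≤ 0); speeds = magnitude change / duration, exactly consistent by
construction. Multi-peaked smiles yield one row per detected peak. Note that
the 4.1 s smoothing span flattens dips shorter than roughly half the frame,
so closely spaced peaks can merge into one; it also smears onset durations
upward by roughly 10%, symmetrically across smile types.

## Discrimination

Feature rows are shuffled and the majority class undersampled to the
minority size (seeded, no fabrication). Each of the six features is compared
with a pooled-variance two-sample t-test (df = n1 + n2 − 2), 95% CI of the
mean difference, Cohen's d with pooled SD, Bonferroni correction over the
six tests. The difference is posed − spontaneous, matching the sign pattern
of the published statistics. Balanced undersampling breaks any pairing, so a
paired test is not applicable; the pooled-variance df reproduces the
published df pattern.

The classifier is an RBF-kernel SVM (C = 1, gamma = 1/(n_features · feature
variance), i.e. scikit-learn's `scale`), trained per producer on features
standardized with training-split statistics only. Splits are stratified
70/15/15 train/validation/test, repeated 20 times (the repeat count and
hyperparameters are this package's choices; the source states only the 70/15
split). Accuracy is reported on the test split; validation accuracy is
recorded alongside (the source is ambiguous about which split its headline
accuracy used) and the validation split is reserved for optional grid
selection, off by default. Producers with fewer than two smiles of either
class are excluded with a reason.

## Perception agreement

Forced-choice judgment records yield overall, per-true-type and
per-perceiver accuracy; percentages round half away from zero. The published
confusion tables ship as fixtures with *correctness* columns; the
stimulus × judged-label table is reconstructed by mapping (true type,
correct) → judged label. The chi-square of independence applies the Yates
continuity correction by default — verified by direct computation to be the
variant that reproduces the published statistics (90.52 and 3.16; the
uncorrected values are ≈ 91.1 and 3.28). Cohen's kappa uses
marginal-product expected agreement (two constant, identical raters are
defined as κ = 1; constant disagreeing raters are a degenerate error);
Fleiss' kappa uses the standard category-proportion formulation via
statsmodels, with unanimous tables defined as κ = 1. The one-sample t-test
against chance reports Cohen's d = (mean − 0.5)/SD and flags zero-variance
input as an infinite-t path.

## Seeding and determinism

One global integer seed per run. Every stage draws from
`SeedSequence([seed, crc32(stage_name)])`, so streams are independent,
reproducible, and stable under the addition of new stages; derived seeds
stay below 2³¹. Identical configuration and inputs give bit-identical
outputs everywhere, including FastICA initialisation and split shuffling.

## Problem sizes

The end-to-end study configuration (`GeneratorConfig.well_separated`) is 20
producers × (10 posed + 10 spontaneous) smiles with the published type
means, producer effect SD 0.3, and within-producer SD set to 25% of the
between-type mean gap — a regime where each producer's two smile types are
cleanly separated, mirroring an intra-individual design. Blocks are 200 s so
ten smiles of mean length ≈ 8.5 s fit with ≥ 1 s gaps. Calibration
simulations use 2000 replicates (t-test error rates) and 10,000 draws
(sampling-law means).

## Known limitations

- The mV calibration survives ICA only approximately (mixing-column
  back-projection); magnitude features are accurate to ~10–20% of the
  generated amplitudes, with directions and ratios preserved.
- Onset/offset durations inherit an upward smoothing bias of ~10% from the
  Savitzky–Golay span; the between-type gap is preserved.
- Closely multi-peaked smiles merge under the 4.1 s smoothing span, so the
  per-event row count can undercount the generated peaks.
- The generator's producer effect is a single multiplicative factor; real
  producers vary in shape, not just scale.
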