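"""Ground-truth-labelled synthetic distal facial EMG.

The generator emulates the structure of the elicitation study the pipeline
targets: each producer contributes one recording holding a spontaneous block
followed by a posed block, with labelled smile events inside each block.
Smile dynamics (onset/offset duration, apex magnitude) are sampled per smile
type from the published feature table, scaled by a per-producer multiplicative
random effect, turned into a non-negative activation profile at the envelope
frame rate (10 frames/s), and used to amplitude-modulate a band-limited
Gaussian EMG carrier.  The smile source plus three low-activity background
muscle sources are mixed into four channels by a volume-conduction mixing
matrix, then corrupted with 50 Hz line noise and its harmonics, slow drift,
and white sensor noise.

Durations are expressed in envelope frames (1 frame = 100 ms): the published
table labels them "ms", but ~37 ms smile onsets are physiologically
implausible and the envelope is computed at 10 frames/s, so a frame reading
(37.05 frames ≈ 3.7 s) is adopted throughout.

The carrier is normalised so that E|carrier| = 1; the rectified-mean envelope
of a modulated stretch then reads directly in the configured mV scale, and
the envelope apex inside a labelled event recovers the sampled apex
amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .io_core import (
    EventLabel,
    RawRecording,
    child_rng,
    logger,
    write_events,
    write_recording,
)

PARAM_FIELDS = ("onset_duration", "offset_duration", "apex_amplitude", "n_peaks", "inter_peak_dip")

#: frames separating consecutive apexes of a multi-peaked smile (100 ms each)
INTER_PEAK_GAP_FRAMES = 6

# Published spatio-temporal feature table: mean/SD per smile type.
# Durations in envelope frames, magnitudes in mV.
TABLE1_MEANS = {
    "spontaneous": {
        "onset_duration": 37.05,
        "offset_duration": 44.40,
        "apex_amplitude": 1.21,
        "n_peaks": 1.5,
        "inter_peak_dip": 0.30,
    },
    "posed": {
        "onset_duration": 33.72,
        "offset_duration": 42.91,
        "apex_amplitude": 0.89,
        "n_peaks": 1.5,
        "inter_peak_dip": 0.30,
    },
}
TABLE1_SDS = {
    "spontaneous": {
        "onset_duration": 33.10,
        "offset_duration": 41.05,
        "apex_amplitude": 1.21,
        "n_peaks": 0.5,
        "inter_peak_dip": 0.10,
    },
    "posed": {
        "onset_duration": 32.74,
        "offset_duration": 44.81,
        "apex_amplitude": 0.85,
        "n_peaks": 0.5,
        "inter_peak_dip": 0.10,
    },
}

# physical lower bounds used when truncating the sampling laws
_PARAM_BOUNDS = {
    "onset_duration": (1.0, np.inf),
    "offset_duration": (1.0, np.inf),
    "apex_amplitude": (0.05, np.inf),
    "n_peaks": (1.0, 5.0),
    "inter_peak_dip": (0.0, 0.9),
}

#: default volume-conduction mixing (sources in columns -> channels in rows)
DEFAULT_MIXING = np.array(
    [
        [1.00, 0.40, 0.20, 0.10],
        [0.40, 1.00, 0.40, 0.20],
        [0.20, 0.40, 1.00, 0.40],
        [0.10, 0.20, 0.40, 1.00],
    ]
)


@dataclass(frozen=True)
class SmileParams:
    """Dynamics of one smile event (durations in envelope frames, apex in mV)."""

    onset_duration: float
    offset_duration: float
    apex_amplitude: float
    n_peaks: int
    inter_peak_dip: float
    smile_type: str = "spontaneous"

    def __post_init__(self) -> None:
        if self.onset_duration < 1 or self.offset_duration < 1:
            raise ValueError("durations must be at least 1 frame")
        if self.apex_amplitude <= 0:
            raise ValueError("apex_amplitude must be positive")
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")
        if not 0 <= self.inter_peak_dip < 1:
            raise ValueError("inter_peak_dip must lie in [0, 1)")

    @property
    def n_frames(self) -> int:
        """Total support of the activation profile, in envelope frames."""
        n_on = max(1, round(self.onset_duration))
        n_off = max(1, round(self.offset_duration))
        return n_on + n_off + (self.n_peaks - 1) * INTER_PEAK_GAP_FRAMES + 1

    @property
    def duration_s(self) -> float:
        return self.n_frames / 10.0


@dataclass
class GeneratorConfig:
    """Study-structure parameters of the synthetic cohort.

    ``type_means``/``type_sds`` default to the published feature table.
    ``producer_effect_sd`` is the SD of a log-normal multiplicative producer
    effect applied to all of a producer's smile-parameter means.  When
    ``within_producer_gap_fraction`` is set, the per-draw SD of every
    parameter becomes that fraction of the between-type mean gap (a
    well-separated regime for classifier studies); otherwise ``type_sds``
    are used directly.
    """

    n_producers: int = 32
    events_per_block: int = 4
    block_duration_s: float = 90.0
    type_means: dict = field(default_factory=lambda: {k: dict(v) for k, v in TABLE1_MEANS.items()})
    type_sds: dict = field(default_factory=lambda: {k: dict(v) for k, v in TABLE1_SDS.items()})
    producer_effect_sd: float = 0.3
    within_producer_gap_fraction: float | None = None
    mixing_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_MIXING.copy())
    line_noise_amp: float = 0.2
    drift_amp: float = 0.5
    drift_freq_hz: float = 0.2
    sensor_noise_sd: float = 0.05
    background_activation: float = 0.1
    sampling_rate_hz: float = 1000.0
    frame_rate: float = 10.0
    min_gap_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.mixing_matrix = np.asarray(self.mixing_matrix, dtype=float)
        if self.mixing_matrix.shape != (4, 4):
            raise ValueError("mixing_matrix must be 4x4")
        if np.linalg.matrix_rank(self.mixing_matrix) < 4:
            raise ValueError("mixing_matrix must be full rank")
        for amp in (self.line_noise_amp, self.drift_amp, self.sensor_noise_sd,
                    self.producer_effect_sd, self.background_activation):
            if amp < 0:
                raise ValueError("noise amplitudes and SDs must be >= 0")

    def param_sd(self, smile_type: str, name: str) -> float:
        if self.within_producer_gap_fraction is not None:
            gap = abs(self.type_means["spontaneous"][name] - self.type_means["posed"][name])
            return self.within_producer_gap_fraction * gap
        return self.type_sds[smile_type][name]

    @classmethod
    def well_separated(cls, seed: int = 0, n_producers: int = 20,
                       events_per_block: int = 10) -> "GeneratorConfig":
        """The well-separated cohort regime used for classifier studies.

        Published type means, a 0.3-SD producer effect, and within-producer
        spread equal to 25% of the between-type mean gap.  Blocks are 200 s
        so ten smiles of mean length ~8.5 s fit with >= 1 s gaps.
        """
        return cls(
            n_producers=n_producers,
            events_per_block=events_per_block,
            block_duration_s=200.0,
            producer_effect_sd=0.3,
            within_producer_gap_fraction=0.25,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------

def _truncnorm_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    """Closed-form mean of N(mu, sd) truncated to (lo, hi)."""
    a, b = (lo - mu) / sd, (hi - mu) / sd
    z = ndtr(b) - ndtr(a)
    phi_a = np.exp(-0.5 * a * a) / np.sqrt(2 * np.pi)
    phi_b = 0.0 if np.isinf(b) else np.exp(-0.5 * b * b) / np.sqrt(2 * np.pi)
    return mu + sd * (phi_a - phi_b) / z


@lru_cache(maxsize=4096)
def _matched_location(mean: float, sd: float, lo: float, hi: float) -> float:
    """Latent location mu whose truncated mean equals ``mean`` (cached)."""
    lo_mu = mean - sd
    while _truncnorm_mean(lo_mu, sd, lo, hi) > mean:
        lo_mu -= 5 * sd
    return brentq(lambda m: _truncnorm_mean(m, sd, lo, hi) - mean,
                  lo_mu, mean + sd, xtol=1e-10 * max(1.0, sd))


def _mean_matched_truncnorm(mean: float, sd: float, lo: float, hi: float,
                            rng: np.random.Generator, size=None):
    """Draw from a truncated normal whose *truncated* mean equals ``mean``.

    Naive truncation of N(mean, sd) at ``lo`` inflates the mean when sd is of
    the order of the mean (as the published SDs are), so the latent location
    is solved for such that the truncated distribution is centred where
    configured.  Sampling is by inverse CDF, u ~ U(Phi(a), Phi(b)).
    """
    if sd == 0:
        return float(np.clip(mean, lo, hi)) if size is None else np.full(size, np.clip(mean, lo, hi))
    if not lo < mean < hi:
        raise ValueError(f"target mean {mean} outside truncation bounds ({lo}, {hi})")
    mu = _matched_location(float(mean), float(sd), float(lo), float(hi))
    a, b = (lo - mu) / sd, (hi - mu) / sd
    u = rng.uniform(ndtr(a), ndtr(b), size=size)
    x = mu + sd * ndtri(u)
    return float(x) if size is None else x


def sample_smile_params(smile_type: str, producer_effect: float,
                        cfg: GeneratorConfig, rng: np.random.Generator) -> SmileParams:
    """Sample one smile's dynamics for a given type and producer effect.

    Continuous parameters follow mean-matched truncated normals centred on
    ``type_means[smile_type] * producer_effect``; the peak count is a rounded
    truncated normal and the inter-peak dip is clipped to [0, 0.9].
    """
    if smile_type not in cfg.type_means:
        raise ValueError(f"unknown smile type {smile_type!r}")
    means = cfg.type_means[smile_type]
    draws: dict[str, float] = {}
    for name in ("onset_duration", "offset_duration", "apex_amplitude"):
        lo, hi = _PARAM_BOUNDS[name]
        target = means[name] * producer_effect
        target = max(target, lo * 1.01)
        draws[name] = float(_mean_matched_truncnorm(target, cfg.param_sd(smile_type, name), lo, hi, rng))
    lo, hi = _PARAM_BOUNDS["n_peaks"]
    sd = cfg.param_sd(smile_type, "n_peaks")
    raw = means["n_peaks"] if sd == 0 else rng.normal(means["n_peaks"], sd)
    n_peaks = int(np.clip(round(raw), lo, hi))
    lo, hi = _PARAM_BOUNDS["inter_peak_dip"]
    sd = cfg.param_sd(smile_type, "inter_peak_dip")
    dip_mean = float(np.clip(means["inter_peak_dip"], lo, hi))
    dip = dip_mean if sd == 0 else float(np.clip(rng.normal(dip_mean, sd), lo, hi))
    return SmileParams(
        onset_duration=draws["onset_duration"],
        offset_duration=draws["offset_duration"],
        apex_amplitude=draws["apex_amplitude"],
        n_peaks=n_peaks,
        inter_peak_dip=dip,
        smile_type=smile_type,
    )


# ---------------------------------------------------------------------------
# activation profile
# ---------------------------------------------------------------------------

def activation_profile(params: SmileParams, frame_rate: float = 10.0) -> np.ndarray:
    """Non-negative source-activation envelope of one smile, at frame rate.

    Piecewise-linear: baseline 0, rise over ``onset_duration`` frames to the
    apex, ``n_peaks`` apexes separated by dips to
    ``(1 - inter_peak_dip) * apex``, fall over ``offset_duration`` frames back
    to 0.  The maximum equals ``apex_amplitude``.
    """
    if frame_rate != 10.0:
        raise ValueError("the activation profile is defined at 10 frames/s (100 ms frames)")
    n_on = max(1, round(params.onset_duration))
    n_off = max(1, round(params.offset_duration))
    apex = params.apex_amplitude
    pieces = [np.linspace(0.0, apex, n_on + 1)]
    half = INTER_PEAK_GAP_FRAMES // 2
    dip_val = (1.0 - params.inter_peak_dip) * apex
    for _ in range(params.n_peaks - 1):
        pieces.append(np.linspace(apex, dip_val, half + 1)[1:])
        pieces.append(np.linspace(dip_val, apex, half + 1)[1:])
    pieces.append(np.linspace(apex, 0.0, n_off + 1)[1:])
    return np.concatenate(pieces)


# ---------------------------------------------------------------------------
# recording synthesis
# ---------------------------------------------------------------------------

def _bandlimited_carrier(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian noise band-limited to 5-350 Hz with E|x| = 1."""
    x = rng.standard_normal(n)
    sos = signal.butter(4, [5.0, 350.0], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x)
    # for a centred Gaussian E|X| = sigma * sqrt(2/pi); rescale to E|X| = 1
    x *= np.sqrt(np.pi / 2.0) / np.std(x)
    return x


def _slow_modulation(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Positive slow (< 0.5 Hz) amplitude modulation around 1 for background sources."""
    x = rng.standard_normal(n)
    sos = signal.butter(2, 0.4, btype="lowpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x)
    sd = np.std(x)
    if sd > 0:
        x /= sd
    return np.clip(1.0 + 0.5 * x, 0.1, None)


def _place_events(params_list: Sequence[SmileParams], block_duration_s: float,
                  min_gap_s: float, rng: np.random.Generator) -> list[float]:
    """Start times (s, within the block) with >= min_gap_s between events."""
    durations = np.array([p.duration_s for p in params_list])
    n = len(durations)
    free = block_duration_s - durations.sum() - (n + 1) * min_gap_s
    if free < 0:
        raise ValueError(
            f"{n} events totalling {durations.sum():.1f}s do not fit in a "
            f"{block_duration_s:.0f}s block with {min_gap_s:.0f}s gaps"
        )
    gaps = min_gap_s + free * rng.dirichlet(np.ones(n + 1))
    starts, t = [], 0.0
    for g, d in zip(gaps, durations):
        t += g
        starts.append(t)
        t += d
    return starts


def generate_recording(cfg: GeneratorConfig, producer_id: str,
                       return_params: bool = False):
    """Synthesize one producer's recording plus ground-truth event labels.

    The recording holds a spontaneous block followed by a posed block, each
    ``block_duration_s`` long.  Returns ``(RawRecording, [EventLabel])``, or
    ``(RawRecording, [EventLabel], [SmileParams])`` when ``return_params``
    so recovery tests can compare against the exact sampled dynamics.
    """
    rng = child_rng(cfg.seed, f"generator/{producer_id}")
    fs = cfg.sampling_rate_hz
    producer_effect = float(np.exp(rng.normal(0.0, cfg.producer_effect_sd)))

    total_s = 2 * cfg.block_duration_s
    n_frames_total = int(round(total_s * cfg.frame_rate))
    n_samples = int(round(total_s * fs))

    activation = np.zeros(n_frames_total)
    events: list[EventLabel] = []
    manifest: list[SmileParams] = []
    max_retries = 50
    for b, smile_type in enumerate(("spontaneous", "posed")):
        block_t0 = b * cfg.block_duration_s
        if cfg.events_per_block == 0:
            continue
        for attempt in range(max_retries + 1):
            params_list = [
                sample_smile_params(smile_type, producer_effect, cfg, rng)
                for _ in range(cfg.events_per_block)
            ]
            try:
                starts = _place_events(params_list, cfg.block_duration_s, cfg.min_gap_s, rng)
                break
            except ValueError:
                if attempt == max_retries:
                    raise
        for start, params in zip(starts, params_list):
            profile = activation_profile(params, cfg.frame_rate)
            f0 = int(round((block_t0 + start) * cfg.frame_rate))
            activation[f0:f0 + len(profile)] += profile
            events.append(
                EventLabel(
                    producer_id=producer_id,
                    block=smile_type,
                    onset_s=f0 / cfg.frame_rate,
                    offset_s=(f0 + len(profile)) / cfg.frame_rate,
                    expression="smile",
                    smile_type=smile_type,
                )
            )
            manifest.append(params)

    # upsample the frame-rate activation to the signal rate (linear interp
    # between frame centres)
    frame_centres = (np.arange(n_frames_total) + 0.5) / cfg.frame_rate
    t = np.arange(n_samples) / fs
    activation_hi = np.interp(t, frame_centres, activation)

    sources = np.empty((n_samples, 4))
    sources[:, 0] = _bandlimited_carrier(n_samples, fs, rng) * activation_hi
    for k in range(1, 4):
        carrier = _bandlimited_carrier(n_samples, fs, rng)
        sources[:, k] = carrier * cfg.background_activation * _slow_modulation(n_samples, fs, rng)

    channels = sources @ cfg.mixing_matrix.T

    if cfg.line_noise_amp > 0:
        line = np.zeros(n_samples)
        k = 1
        while k * 50.0 <= 350.0:
            line += (cfg.line_noise_amp / k) * np.sin(2 * np.pi * 50.0 * k * t + rng.uniform(0, 2 * np.pi))
            k += 1
        channels += np.outer(line, rng.uniform(0.5, 1.5, size=4))
    if cfg.drift_amp > 0:
        for c in range(4):
            channels[:, c] += cfg.drift_amp * np.sin(
                2 * np.pi * cfg.drift_freq_hz * t + rng.uniform(0, 2 * np.pi)
            )
            channels[:, c] += 0.5 * cfg.drift_amp * np.sin(
                2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi)
            )
    if cfg.sensor_noise_sd > 0:
        channels += rng.normal(0.0, cfg.sensor_noise_sd, size=channels.shape)

    rec = RawRecording(producer_id=producer_id, sampling_rate_hz=fs, samples=channels)
    if return_params:
        return rec, events, manifest
    return rec, events


def generate_cohort(cfg: GeneratorConfig, return_params: bool = False) -> dict:
    """Generate all producers of a cohort; keyed by producer id."""
    cohort = {}
    for i in range(cfg.n_producers):
        pid = f"p{i + 1:02d}"
        cohort[pid] = generate_recording(cfg, pid, return_params=return_params)
    return cohort


def write_cohort(cfg: GeneratorConfig, out_dir: str | Path) -> None:
    """Write per-producer signal CSVs, one events CSV and a parameter manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_events: list[EventLabel] = []
    manifest_rows = []
    for pid, (rec, events, params) in generate_cohort(cfg, return_params=True).items():
        write_recording(rec, out / f"{pid}.csv")
        all_events.extend(events)
        for ev, p in zip(events, params):
            manifest_rows.append({"producer_id": pid, "onset_s": ev.onset_s,
                                  "smile_type": p.smile_type, **{f: getattr(p, f) for f in PARAM_FIELDS}})
        logger.info("simulated %s: %d samples, %d events", pid, rec.n_samples, len(events))
    write_events(all_events, out / "events.csv")
    import pandas as pd

    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
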