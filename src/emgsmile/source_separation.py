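"""ICA decomposition of the four distal channels into muscle sources.

Distal electrodes record volume-conducted mixtures of several facial
muscles; with four channels, four sources can be estimated.  Decomposition
uses FastICA (log-cosh contrast, deflation) and the smile-related component
is selected as the one whose rectified activity is most concentrated inside
the labelled smile intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import skew
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .io_core import (
    DegenerateInputError,
    EventLabel,
    RawRecording,
    child_seed,
    logger,
    smile_events,
)


class ConvergenceError(RuntimeError):
    """FastICA failed to converge within the iteration budget."""

    def __init__(self, max_iter: int):
        super().__init__(f"ICA did not converge within {max_iter} iterations")
        self.max_iter = max_iter


@dataclass
class ComponentSet:
    """Estimated sources plus the (un)mixing estimates.

    ``sources`` is ``[n_samples, 4]`` with unit-variance components;
    ``mixing_estimate @ unmixing ~= I``.  Component signs follow a
    positive-skewness convention (EMG bursts are sparse, so activity skews
    the rectifiable tail positive); downstream envelopes rectify, making the
    sign immaterial there.
    """

    sources: np.ndarray
    unmixing: np.ndarray
    mixing_estimate: np.ndarray
    mean: np.ndarray
    sampling_rate_hz: float
    start_time_s: float = 0.0
    sign_convention: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.sources.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Channels re-mixed from the sources (inverse of the unmixing)."""
        return self.sources @ self.mixing_estimate.T + self.mean

    def source_in_sensor_units(self, index: int) -> np.ndarray:
        """A component rescaled to its mV contribution on its strongest channel.

        ICA components are scale-free (unit variance); multiplying by the
        largest absolute entry of the estimated mixing column restores the
        amplitude that component contributes to the channel it drives
        hardest, so envelope features read in mV.
        """
        gain = float(np.max(np.abs(self.mixing_estimate[:, index])))
        return self.sources[:, index] * gain


def ica_decompose(rec: RawRecording, seed: int = 0, max_iter: int = 1000,
                  tol: float = 1e-5) -> ComponentSet:
    """Unmix a preprocessed 4-channel recording into 4 independent components."""
    if rec.n_channels != 4:
        raise ValueError("ICA stage expects exactly 4 channels")
    if rec.duration_s < 10.0:
        raise ValueError("need at least 10 s of signal for a stable decomposition")
    cov = np.cov(rec.samples.T)
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e10:
        raise DegenerateInputError(
            f"channel covariance is rank-deficient (condition number {cond:.2g})"
        )
    ica = FastICA(
        n_components=4,
        algorithm="deflation",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=child_seed(seed, "ica"),
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(rec.samples)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            raise ConvergenceError(max_iter)

    flips = np.where(skew(sources, axis=0) < 0, -1.0, 1.0)
    sources = sources * flips
    unmixing = ica.components_ * flips[:, None]
    mixing = ica.mixing_ * flips[None, :]
    logger.info("ICA on %s converged in %d iterations", rec.producer_id, int(np.max(ica.n_iter_)))
    return ComponentSet(
        sources=sources,
        unmixing=unmixing,
        mixing_estimate=mixing,
        mean=ica.mean_,
        sampling_rate_hz=rec.sampling_rate_hz,
        start_time_s=rec.start_time_s,
        sign_convention=flips,
    )


def select_smile_component(cs: ComponentSet, events: Sequence[EventLabel]) -> int:
    """Index of the component most active inside labelled smile intervals.

    Scores each component by the ratio of its rectified mean inside smile
    intervals to its rectified mean outside; ties break to the lowest index.
    """
    smiles = smile_events(events)
    if not smiles:
        raise ValueError(
            "no smile events given; pass labelled smiles or extract features from all components"
        )
    n = cs.sources.shape[0]
    fs = cs.sampling_rate_hz
    inside = np.zeros(n, dtype=bool)
    for ev in smiles:
        i0 = max(0, int(round((ev.onset_s - cs.start_time_s) * fs)))
        i1 = min(n, int(round((ev.offset_s - cs.start_time_s) * fs)))
        inside[i0:i1] = True
    if not inside.any():
        raise ValueError("smile events do not overlap the recording")
    rect = np.abs(cs.sources)
    mean_in = rect[inside].mean(axis=0)
    mean_out = rect[~inside].mean(axis=0) if (~inside).any() else np.full(cs.n_components, np.finfo(float).tiny)
    ratios = mean_in / np.maximum(mean_out, np.finfo(float).tiny)
    return int(np.argmax(ratios))
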