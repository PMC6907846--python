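"""Envelope extraction, extrema detection and spatio-temporal smile features.

The envelope is the rectified component averaged over non-overlapping 100 ms
windows (10 frames/s) and smoothed with a Savitzky–Golay filter (order 5,
frame length 41).  For every envelope maximum inside a labelled smile
interval one feature row is produced: apex magnitude, onset/offset duration
(frames), onset/offset magnitude change (mV, signed + / −) and onset/offset
speed (magnitude change per frame).  A labelled smile may contain several
peaks, so events can yield several rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .io_core import EventLabel, PipelineConfig, logger, smile_events


class TooShortError(ValueError):
    """Series too short to smooth at the configured Savitzky–Golay frame."""


@dataclass
class Envelope:
    """Smoothed non-negative amplitude series at the envelope frame rate."""

    values: np.ndarray
    frame_rate: float = 10.0
    t0_s: float = 0.0

    @property
    def n_frames(self) -> int:
        return len(self.values)

    def frame_of(self, time_s: float) -> int:
        """Frame index whose window contains ``time_s`` (clipped to range)."""
        f = int(np.floor((time_s - self.t0_s) * self.frame_rate + 0.5))
        return int(np.clip(f, 0, self.n_frames - 1))

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class SmileFeatureRow:
    """One envelope peak's spatio-temporal feature vector.

    Sign conventions match the published table: onset magnitude change and
    speed are >= 0 (rise to the apex), offset magnitude change and speed are
    <= 0 (fall from the apex).  Durations are envelope frames (100 ms each).
    """

    producer_id: str
    event_ref: str
    peak_index: int
    smile_type: str
    apex_magnitude: float
    onset_duration: float
    offset_duration: float
    onset_magnitude_change: float
    offset_magnitude_change: float
    onset_speed: float
    offset_speed: float

    @property
    def onset_duration_ms(self) -> float:
        return self.onset_duration * 100.0

    @property
    def offset_duration_ms(self) -> float:
        return self.offset_duration * 100.0


FEATURE_COLUMNS = [
    "onset_duration", "offset_duration",
    "onset_magnitude_change", "offset_magnitude_change",
    "onset_speed", "offset_speed",
]


def compute_envelope(series: np.ndarray, cfg: PipelineConfig | None = None,
                     sampling_rate_hz: float = 1000.0, t0_s: float = 0.0) -> Envelope:
    """Rectify -> 100 ms non-overlapping window means -> Savitzky–Golay.

    Negative excursions introduced by the polynomial smoothing are clamped
    to zero (an envelope is non-negative by construction).
    """
    cfg = cfg or PipelineConfig()
    series = np.asarray(series, dtype=float)
    window = int(round(cfg.envelope_window_ms * sampling_rate_hz / 1000.0))
    n_frames = len(series) // window
    if n_frames < cfg.savgol_frame:
        raise TooShortError(
            f"{len(series)} samples give {n_frames} envelope frames; "
            f"need >= {cfg.savgol_frame} for the Savitzky–Golay frame"
        )
    frames = np.abs(series[: n_frames * window]).reshape(n_frames, window).mean(axis=1)
    smoothed = savgol_filter(frames, cfg.savgol_frame, cfg.savgol_order)
    t0 = t0_s + (window / 2.0) / sampling_rate_hz
    return Envelope(values=np.clip(smoothed, 0.0, None),
                    frame_rate=1000.0 / cfg.envelope_window_ms, t0_s=t0)


def detect_extrema(env: Envelope, prominence_frac: float = 0.05):
    """Alternating local maxima and minima of the envelope.

    Maxima require a prominence of ``prominence_frac`` of the global range
    (suppresses smoothing ripple).  Minima are the lowest frames between
    consecutive maxima; the stretches before the first and after the last
    maximum contribute boundary minima, so the sequence always alternates
    min, max, min, ..., max, min.  Returns ``(maxima, minima)`` as lists of
    ``(frame_index, value)``.
    """
    v = env.values
    if len(v) < 3:
        return [], []
    rng = float(v.max() - v.min())
    if rng == 0.0:
        return [], []
    peaks, _ = find_peaks(v, prominence=prominence_frac * rng)
    if len(peaks) == 0:
        return [], []

    def _min_index(lo: int, hi: int, tie: str) -> int:
        seg = v[lo:hi]
        ties = np.flatnonzero(seg == seg.min())
        # on a flat plateau of minimal values, the physically meaningful
        # trough is the one adjacent to the flank: the last tied frame
        # before a rise, the first after a fall, the middle inside a valley
        pick = {"last": ties[-1], "first": ties[0], "mid": ties[len(ties) // 2]}[tie]
        return lo + int(pick)

    minima_idx = [_min_index(0, peaks[0] + 1, "last")]
    for a, b in zip(peaks[:-1], peaks[1:]):
        minima_idx.append(_min_index(a, b + 1, "mid"))
    minima_idx.append(_min_index(peaks[-1], len(v), "first"))
    maxima = [(int(p), float(v[p])) for p in peaks]
    minima = [(m, float(v[m])) for m in minima_idx]
    return maxima, minima


def extract_features(env: Envelope, extrema, events: Sequence[EventLabel],
                     producer_id: str | None = None,
                     edge_guard_frames: int = 0) -> list[SmileFeatureRow]:
    """One feature row per envelope maximum inside a labelled smile interval.

    The onset trough is the nearest preceding minimum, bounded by the event
    onset frame (if the nearest minimum lies before the event, the lowest
    frame between the event onset and the peak is used instead); the offset
    trough mirrors this at the event offset.  Durations are floored at one
    frame and speeds are magnitude change per frame, so speed, magnitude and
    duration stay exactly consistent on every row.
    """
    maxima, minima = extrema
    v = env.values
    rows: list[SmileFeatureRow] = []
    min_frames = np.array([m[0] for m in minima], dtype=int)
    for ev_i, ev in enumerate(smile_events(events)):
        f_on = env.frame_of(ev.onset_s)
        f_off = env.frame_of(ev.offset_s)
        pid = producer_id or ev.producer_id
        event_ref = f"{pid}:{ev.block}:{ev.onset_s:.1f}"
        peaks_inside = [p for p, _ in maxima if f_on <= p < f_off]
        if edge_guard_frames:
            lo, hi = edge_guard_frames, env.n_frames - edge_guard_frames
            peaks_inside = [p for p in peaks_inside if lo <= p < hi]
        if not peaks_inside:
            logger.info("event %s has no interior envelope maximum; no feature rows", event_ref)
            continue
        for k, p in enumerate(peaks_inside):
            preceding = min_frames[min_frames < p]
            t_on = int(preceding.max()) if preceding.size else f_on
            if t_on < f_on:
                t_on = f_on + int(np.argmin(v[f_on:p])) if p > f_on else f_on
            following = min_frames[min_frames > p]
            t_off = int(following.min()) if following.size else f_off
            if t_off > f_off:
                t_off = p + int(np.argmin(v[p : f_off + 1]))
            on_dur = max(1, p - t_on)
            off_dur = max(1, t_off - p)
            on_dmag = max(0.0, float(v[p] - v[t_on]))
            off_dmag = min(0.0, float(v[t_off] - v[p]))
            rows.append(
                SmileFeatureRow(
                    producer_id=pid,
                    event_ref=event_ref,
                    peak_index=k,
                    smile_type=ev.smile_type,
                    apex_magnitude=float(v[p]),
                    onset_duration=float(on_dur),
                    offset_duration=float(off_dur),
                    onset_magnitude_change=on_dmag,
                    offset_magnitude_change=off_dmag,
                    onset_speed=on_dmag / on_dur,
                    offset_speed=off_dmag / off_dur,
                )
            )
    return rows


def features_to_frame(rows: Sequence[SmileFeatureRow]) -> pd.DataFrame:
    """Feature rows as a DataFrame (the exchange format of later stages)."""
    return pd.DataFrame(
        [
            {
                "producer_id": r.producer_id,
                "event_ref": r.event_ref,
                "peak_index": r.peak_index,
                "smile_type": r.smile_type,
                "apex_mV": r.apex_magnitude,
                "onset_frames": r.onset_duration,
                "offset_frames": r.offset_duration,
                "onset_dmag_mV": r.onset_magnitude_change,
                "offset_dmag_mV": r.offset_magnitude_change,
                "onset_speed": r.onset_speed,
                "offset_speed": r.offset_speed,
            }
            for r in rows
        ]
    )


#: DataFrame column -> canonical feature name used in comparisons
FRAME_TO_FEATURE = {
    "onset_frames": "onset_duration",
    "offset_frames": "offset_duration",
    "onset_dmag_mV": "onset_magnitude_change",
    "offset_dmag_mV": "offset_magnitude_change",
    "onset_speed": "onset_speed",
    "offset_speed": "offset_speed",
}


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.9g")


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
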