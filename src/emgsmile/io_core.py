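"""Shared data containers, file formats, configuration, seeding and logging.

All signals travel as :class:`RawRecording` (a time-major sample matrix in
millivolts), labelled expression intervals as :class:`EventLabel`, and the
pipeline's tunables as :class:`PipelineConfig`.  Signal files are plain
delimited text so recordings can be inspected, versioned and diffed; the
native format of the recording hardware is out of scope.

Conventions: time is in seconds, sample indices are 0-based, and event
intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("emgsmile")

DEFAULT_CHANNELS = ("ch1", "ch2", "ch3", "ch4")

BLOCKS = ("spontaneous", "neutral", "practice", "posed")
EXPRESSIONS = ("smile", "other")
SMILE_TYPES = ("posed", "spontaneous", "none")


class MalformedInputError(ValueError):
    """Input file or table violates the format contract."""


class EmptyInputError(ValueError):
    """Input contains no usable rows."""


class DegenerateInputError(ValueError):
    """Numerically degenerate input (e.g. rank-deficient channels)."""


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def child_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from the global seed.

    The derivation is ``SeedSequence([seed, crc32(stage)])`` so that every
    pipeline stage draws from an independent, reproducible stream and adding
    a stage never perturbs the streams of existing stages.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed), tag])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """A ``numpy`` Generator seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(seed, stage))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """Multichannel surface-EMG time series.

    ``samples`` is ``[n_samples, n_channels]`` in mV.  Four distal facial
    channels at 1000 samples/s is the native layout; the band-pass upper
    edge of 350 Hz requires ``sampling_rate_hz > 700``.
    """

    producer_id: str
    sampling_rate_hz: float
    samples: np.ndarray
    channels: Sequence[str] = DEFAULT_CHANNELS
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise MalformedInputError("samples must be a 2-D [n_samples, n_channels] array")
        if self.samples.shape[1] != len(self.channels):
            raise MalformedInputError(
                f"{self.samples.shape[1]} sample columns but {len(self.channels)} channel labels"
            )
        if not np.all(np.isfinite(self.samples)):
            raise MalformedInputError("samples contain non-finite values")
        if self.sampling_rate_hz <= 0:
            raise MalformedInputError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.sampling_rate_hz

    def with_samples(self, samples: np.ndarray) -> "RawRecording":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class EventLabel:
    """A labelled facial-expression interval, half-open ``[onset_s, offset_s)``."""

    producer_id: str
    block: str
    onset_s: float
    offset_s: float
    expression: str = "smile"
    smile_type: str = "none"

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise ValueError(f"unknown block {self.block!r}; expected one of {BLOCKS}")
        if self.expression not in EXPRESSIONS:
            raise ValueError(f"unknown expression {self.expression!r}")
        if self.smile_type not in SMILE_TYPES:
            raise ValueError(f"unknown smile_type {self.smile_type!r}")
        if not self.offset_s > self.onset_s:
            raise ValueError(
                f"offset_s ({self.offset_s}) must exceed onset_s ({self.onset_s})"
            )
        if (self.smile_type == "none") != (self.expression == "other"):
            raise ValueError("smile_type must be 'none' iff expression is 'other'")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class PipelineConfig:
    """Tunable parameters of the EMG analysis chain.

    Defaults are the published processing choices: 5–350 Hz band-pass,
    notches at the 50 Hz harmonics up to 350 Hz, 100 ms non-overlapping
    envelope windows, and Savitzky–Golay smoothing with a 5th-order
    polynomial over 41 envelope frames.
    """

    band_low_hz: float = 5.0
    band_high_hz: float = 350.0
    notch_base_hz: float = 50.0
    notch_max_hz: float = 350.0
    notch_quality: float = 30.0
    envelope_window_ms: float = 100.0
    savgol_order: int = 5
    savgol_frame: int = 41
    peak_prominence_frac: float = 0.05
    edge_guard_s: float = 0.5
    svm_c: float = 1.0
    svm_gamma: float | str = "scale"
    n_split_repeats: int = 20
    train_frac: float = 0.70
    val_frac: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("band_low_hz", "band_high_hz", "notch_base_hz", "notch_max_hz",
                     "notch_quality", "envelope_window_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.band_low_hz >= self.band_high_hz:
            raise ValueError("band_low_hz must be below band_high_hz")
        if self.savgol_frame % 2 == 0 or self.savgol_frame <= self.savgol_order:
            raise ValueError("savgol_frame must be odd and exceed savgol_order")
        if not 0 < self.train_frac < 1 or not 0 <= self.val_frac < 1:
            raise ValueError("split fractions must lie in (0, 1)")
        if self.train_frac + self.val_frac >= 1:
            raise ValueError("train_frac + val_frac must leave a test share")

    @property
    def test_frac(self) -> float:
        return 1.0 - self.train_frac - self.val_frac

    @property
    def envelope_frame_rate(self) -> float:
        return 1000.0 / self.envelope_window_ms

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_RECORDING_COLUMNS = ["time_s", "ch1", "ch2", "ch3", "ch4"]


def read_recording(path: str | Path, producer_id: str | None = None) -> RawRecording:
    """Read a delimited-text recording (``time_s,ch1,ch2,ch3,ch4``).

    The sampling rate is inferred from the median time step; a non-monotone
    or irregular time column is rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in _RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{path}: missing columns {missing}")
    if len(df) < 2:
        raise EmptyInputError(f"{path}: need at least 2 rows to infer a sampling rate")
    t = df["time_s"].to_numpy(dtype=float)
    steps = np.diff(t)
    if np.any(steps <= 0):
        bad = int(np.argmax(steps <= 0)) + 1
        raise MalformedInputError(f"{path}: time column not strictly increasing at row {bad}")
    step = float(np.median(steps))
    if np.max(np.abs(steps - step)) > 1e-6 + 1e-4 * step:
        raise MalformedInputError(f"{path}: irregular time step (median {step:g} s)")
    return RawRecording(
        producer_id=producer_id or Path(path).stem,
        sampling_rate_hz=1.0 / step,
        samples=df[_RECORDING_COLUMNS[1:]].to_numpy(dtype=float),
        start_time_s=float(t[0]),
    )


def write_recording(rec: RawRecording, path: str | Path) -> None:
    if rec.n_channels != 4:
        raise MalformedInputError("recording files carry exactly 4 channels")
    df = pd.DataFrame(rec.samples, columns=_RECORDING_COLUMNS[1:])
    df.insert(0, "time_s", rec.times())
    df.to_csv(path, index=False, float_format="%.12g")


_EVENT_COLUMNS = ["producer_id", "block", "onset_s", "offset_s", "expression", "smile_type"]


def read_events(path: str | Path) -> list[EventLabel]:
    """Read labelled expression intervals; invalid rows are reported by number."""
    df = pd.read_csv(path)
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{path}: missing columns {missing}")
    events: list[EventLabel] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            events.append(
                EventLabel(
                    producer_id=str(row.producer_id),
                    block=str(row.block),
                    onset_s=float(row.onset_s),
                    offset_s=float(row.offset_s),
                    expression=str(row.expression),
                    smile_type=str(row.smile_type),
                )
            )
        except ValueError as exc:
            raise MalformedInputError(f"{path}: row {i + 1}: {exc}") from exc
    return events


def write_events(events: Iterable[EventLabel], path: str | Path) -> None:
    df = pd.DataFrame([e.__dict__ for e in events], columns=_EVENT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9g")


def smile_events(events: Iterable[EventLabel]) -> list[EventLabel]:
    """The subset of events that are smiles (posed or spontaneous)."""
    return [e for e in events if e.expression == "smile"]
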