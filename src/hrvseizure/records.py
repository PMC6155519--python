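"""Core data containers shared across the processing chain.

The pipeline moves through three representations of cardiac activity:
raw multi-channel ECG (:class:`ECGRecord`), detected beat fiducials
(:class:`BeatSequence`) and RR-interval series in the beat domain
(:class:`RRSeries`) or uniformly resampled (:class:`UniformRRSeries`).
Seizure timing is carried by :class:`SeizureAnnotation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ECGRecord",
    "BeatSequence",
    "RRSeries",
    "UniformRRSeries",
    "SeizureAnnotation",
    "GroundTruth",
]


@dataclass
class ECGRecord:
    """Multi-channel uniformly sampled ECG.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Amplitudes in millivolt.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One name per channel.
    start_time : float
        Recording start, seconds (an offset clock; 0 for synthetic data).
    meta : dict
        Free-form annotations (ground-truth beat times, processing log, ...).
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    start_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs

    def copy(self) -> "ECGRecord":
        return ECGRecord(
            self.samples.copy(), self.fs, list(self.channel_names),
            self.start_time, dict(self.meta),
        )


@dataclass
class BeatSequence:
    """Detected QRS fiducial times with per-beat polarity."""

    fiducial_times_s: np.ndarray
    polarities: np.ndarray | None = None
    detector_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fiducial_times_s = np.asarray(self.fiducial_times_s, dtype=float)
        if self.fiducial_times_s.size and np.any(np.diff(self.fiducial_times_s) <= 0):
            raise ValueError("fiducial times must be strictly increasing")
        if self.polarities is None:
            self.polarities = np.ones_like(self.fiducial_times_s)

    def __len__(self) -> int:
        return self.fiducial_times_s.size

    def rr_series(self) -> "RRSeries":
        """RR intervals between successive fiducials, in ms."""
        if len(self) < 2:
            raise ValueError("need at least two beats to form RR intervals")
        rr = np.diff(self.fiducial_times_s) * 1000.0
        return RRSeries(rr_ms=rr, t0_s=float(self.fiducial_times_s[0]),
                        source="detected")


# per-interval correction markers
FLAG_NONE = 0
FLAG_RULE = 1
FLAG_FILTER = 2


@dataclass
class RRSeries:
    """Beat-domain RR interval series.

    ``beat_times_s`` holds the time of each interval's *terminating* beat:
    ``beat_times_s[i] = t0_s + cumsum(rr_ms)[i] / 1000``.
    """

    rr_ms: np.ndarray
    t0_s: float = 0.0
    corrected_flags: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if np.any(self.rr_ms <= 0):
            raise ValueError("RR intervals must be positive")
        if self.corrected_flags is None:
            self.corrected_flags = np.zeros(self.rr_ms.size, dtype=int)
        else:
            self.corrected_flags = np.asarray(self.corrected_flags, dtype=int)
            if self.corrected_flags.size != self.rr_ms.size:
                raise ValueError("corrected_flags length mismatch")

    def __len__(self) -> int:
        return self.rr_ms.size

    @property
    def beat_times_s(self) -> np.ndarray:
        return self.t0_s + np.cumsum(self.rr_ms) / 1000.0

    def copy(self) -> "RRSeries":
        return RRSeries(self.rr_ms.copy(), self.t0_s,
                        self.corrected_flags.copy(), self.source)


@dataclass
class UniformRRSeries:
    """RR series resampled on a uniform grid (tachogram)."""

    values_ms: np.ndarray
    rate_hz: float = 4.0
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.values_ms = np.asarray(self.values_ms, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return self.values_ms.size

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.values_ms.size) / self.rate_hz


@dataclass(frozen=True)
class SeizureAnnotation:
    """One seizure: electro-clinical onset and offset, seconds from start."""

    onset_s: float
    offset_s: float
    label: str = "seizure"

    def __post_init__(self) -> None:
        if not 0 <= self.onset_s < self.offset_s:
            raise ValueError("need 0 <= onset < offset")


def check_annotations(annotations: Sequence[SeizureAnnotation],
                      duration_s: float | None = None) -> list[SeizureAnnotation]:
    """Validate that annotations are sorted, non-overlapping and in range."""
    anns = sorted(annotations, key=lambda a: a.onset_s)
    for a, b in zip(anns, anns[1:]):
        if b.onset_s < a.offset_s:
            raise ValueError(f"overlapping annotations: {a} / {b}")
    if duration_s is not None and anns and anns[-1].offset_s > duration_s:
        raise ValueError("annotation extends past recording end")
    return anns


@dataclass
class GroundTruth:
    """Known truth attached to synthetic recordings."""

    beat_times_s: np.ndarray
    corrupted_beat_indices: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int))
    artifact_spans: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if self.beat_times_s.size and np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("ground-truth beat times must be strictly increasing")
        self.corrupted_beat_indices = np.asarray(self.corrupted_beat_indices,
                                                 dtype=int)
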