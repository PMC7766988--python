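"""Core annotation data model: tracks, fiducials, partitions and epochs.

A :class:`Track` is one uniformly sampled signal.  Annotations come in three
kinds, mirroring how physiological recordings are labelled in practice:

* :class:`FiducialSeries` — zero-duration events (R-peaks, PPG feet, ...),
  ordered in time and subject to a minimum inter-event distance;
* :class:`PartitionSet` — named, non-overlapping time intervals (artifact
  segments, interventions);
* :class:`EpochGrid` — consecutive fixed-length windows, each carrying one
  categorical label (e.g. 10-s signal-quality scores).

All timestamps are real-valued seconds so sub-sample event locations are
representable; sample indexing is 0-based and the time of sample ``i`` of a
track is ``offset + i / fs``.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "Track",
    "FiducialSeries",
    "PartitionSet",
    "EpochGrid",
    "derive_track",
    "pin_to_extremum",
    "interbeat_intervals",
]


@dataclass
class Track:
    """One uniformly sampled signal.

    Parameters
    ----------
    name : str
        Identifier of the signal (e.g. ``"ecg"``).
    fs : float
        Sampling rate in Hz, strictly positive.
    values : numpy.ndarray
        Amplitude samples; coerced to a float64 array.
    offset : float, optional
        Start time of the first sample in seconds (default 0).
    units : str, optional
        Free-text amplitude unit label (default "").
    """

    name: str
    fs: float
    values: np.ndarray
    offset: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("track values must be one-dimensional")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Span of the track in seconds (n / fs)."""
        return len(self.values) / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample timestamps: offset + i / fs."""
        return self.offset + np.arange(len(self.values)) / self.fs

    def index_of(self, t: float) -> int:
        """Nearest sample index for time ``t``, clipped to the track span."""
        i = int(round((t - self.offset) * self.fs))
        return min(max(i, 0), len(self.values) - 1)

    def value_at(self, t: float) -> float:
        """Linearly interpolated amplitude at time ``t``."""
        x = (t - self.offset) * self.fs
        i = int(math.floor(x))
        if i < 0:
            return float(self.values[0])
        if i >= len(self.values) - 1:
            return float(self.values[-1])
        frac = x - i
        return float((1 - frac) * self.values[i] + frac * self.values[i + 1])


@dataclass
class FiducialSeries:
    """Ordered zero-duration events on one track.

    Timestamps are kept strictly increasing with consecutive gaps of at
    least ``min_distance`` seconds; insertions violating the rule are
    rejected rather than applied destructively.
    """

    name: str
    timestamps: list[float] = field(default_factory=list)
    amplitudes: list[float] = field(default_factory=list)
    sublabels: list[str | None] = field(default_factory=list)
    min_distance: float = 0.0

    def __post_init__(self) -> None:
        if self.min_distance < 0:
            raise ValueError("min_distance must be >= 0")
        if not self.amplitudes:
            self.amplitudes = [math.nan] * len(self.timestamps)
        if not self.sublabels:
            self.sublabels = [None] * len(self.timestamps)
        if not (len(self.timestamps) == len(self.amplitudes) == len(self.sublabels)):
            raise ValueError("timestamps, amplitudes and sublabels must align")
        diffs = np.diff(self.timestamps)
        if len(diffs) and (diffs <= 0).any():
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    def insert(self, t: float, amplitude: float = math.nan,
               sublabel: str | None = None) -> bool:
        """Insert an event at time ``t``, keeping sorted order.

        Returns ``True`` on success.  If an existing event lies within
        ``min_distance`` of ``t`` the series is left unchanged and
        ``False`` is returned.
        """
        if not math.isfinite(t):
            raise ValueError("timestamp must be finite")
        i = bisect.bisect_left(self.timestamps, t)
        if i > 0 and t - self.timestamps[i - 1] < self.min_distance:
            return False
        if i < len(self.timestamps) and self.timestamps[i] - t < self.min_distance:
            return False
        if i < len(self.timestamps) and self.timestamps[i] == t:
            return False
        self.timestamps.insert(i, float(t))
        self.amplitudes.insert(i, float(amplitude))
        self.sublabels.insert(i, sublabel)
        return True

    def remove_at(self, i: int) -> None:
        del self.timestamps[i], self.amplitudes[i], self.sublabels[i]

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.asarray(self.timestamps, dtype=np.float64),
                np.asarray(self.amplitudes, dtype=np.float64))


@dataclass
class Partition:
    name: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"partition start must precede end "
                             f"({self.start} >= {self.end})")


@dataclass
class PartitionSet:
    """Named duration events; intervals never overlap (touching is allowed)."""

    partitions: list[Partition] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.partitions)

    def add(self, name: str, start: float, end: float) -> bool:
        """Add a partition unless it overlaps an existing one.

        Raises ``ValueError`` for start >= end; returns ``False`` (set
        unchanged) on overlap, ``True`` on insertion.
        """
        cand = Partition(name, float(start), float(end))
        for p in self.partitions:
            if cand.start < p.end and p.start < cand.end:
                return False
        i = bisect.bisect_left([p.start for p in self.partitions], cand.start)
        self.partitions.insert(i, cand)
        return True


@dataclass
class EpochGrid:
    """Fixed-length consecutive windows with one categorical label each.

    Window ``k`` covers the half-open interval ``[k*L, (k+1)*L)`` relative
    to the track start; a trailing partial window is still labelable.
    Unset labels are ``None``.
    """

    epoch_length: float
    label_set: list[str]
    n_epochs: int
    labels: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if not self.labels:
            self.labels = [None] * self.n_epochs
        if len(self.labels) != self.n_epochs:
            raise ValueError("labels length must equal n_epochs")

    def set_label(self, k: int, label: str) -> None:
        if label not in self.label_set:
            raise ValueError(f"label {label!r} not in label set {self.label_set}")
        self.labels[k] = label


def derive_track(track: Track, kind: str, cutoff_hz: float | None = None,
                 order: int = 4) -> Track:
    """Produce a derived signal (derivative or low-pass filtered) of a track.

    ``kind="derivative"`` applies central differences (one-sided at the
    ends), scaled to units per second.  ``kind="lowpass"`` applies a
    zero-phase Butterworth low-pass at ``cutoff_hz``.
    """
    if len(track) == 0:
        raise ValueError("cannot derive from an empty track")
    if kind == "derivative":
        vals = np.gradient(track.values) * track.fs
        return replace(track, name=f"d[{track.name}]", values=vals,
                       units=f"{track.units}/s" if track.units else "1/s")
    if kind == "lowpass":
        if cutoff_hz is None:
            raise ValueError("lowpass derivation requires cutoff_hz")
        nyq = track.fs / 2.0
        if cutoff_hz >= nyq:
            raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
        sos = butter(order, cutoff_hz / nyq, btype="low", output="sos")
        vals = sosfiltfilt(sos, track.values)
        return replace(track, name=f"lpf[{track.name}]", values=vals)
    raise ValueError(f"unknown derivation kind {kind!r}")


def pin_to_extremum(track: Track, t: float, window: float,
                    mode: str = "nearest") -> float:
    """Snap a timestamp to the local extremum of a track near ``t``.

    Searches samples in ``[t - window/2, t + window/2]`` (clipped to the
    track span) and returns the timestamp of the largest sample
    (``mode="peak"``), the smallest (``"valley"``), or whichever of the
    two is closer in time to ``t`` (``"nearest"``).  No sub-sample
    refinement is applied here.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    lo = track.index_of(t - window / 2)
    hi = track.index_of(t + window / 2)
    if hi < lo:
        lo, hi = hi, lo
    seg = track.values[lo:hi + 1]
    i_max = lo + int(np.argmax(seg))
    i_min = lo + int(np.argmin(seg))
    t_max = track.offset + i_max / track.fs
    t_min = track.offset + i_min / track.fs
    if mode == "peak":
        return t_max
    if mode == "valley":
        return t_min
    if mode == "nearest":
        return t_max if abs(t_max - t) <= abs(t_min - t) else t_min
    raise ValueError(f"unknown pin mode {mode!r}")


def interbeat_intervals(series: FiducialSeries) -> list[tuple[float, float]]:
    """Consecutive inter-event intervals, reported at the later event.

    Returns ``[(t_{i+1}, t_{i+1} - t_i), ...]``; an empty list for fewer
    than two events.  Spikes in this sequence are the usual visual cue
    for missed or extra beats.
    """
    ts = series.timestamps
    return [(ts[i + 1], ts[i + 1] - ts[i]) for i in range(len(ts) - 1)]
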