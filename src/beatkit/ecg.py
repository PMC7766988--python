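"""Block-wise streaming R-peak detector.

The ECG is processed in fixed-length blocks (default 0.5 s).  Each block is
enhanced with a single-scale continuous wavelet transform (Mexican-hat /
Ricker kernel tuned to the QRS band) followed by a modulus operation; the
resulting non-negative signal Y is compared against an adaptive threshold
formed from a weighted sum of a running noise level (average per-block STD
of Y) and a quasi-peak-detector signal level.  A state object carries
wavelet context, envelope levels and unresolved candidates across block
boundaries, so heartbeats split between blocks are detected exactly as if
the record were processed in one pass.  Detected peaks are finally refined
to sub-sample precision by fitting a parabola through the raw-ECG maximum
and its two neighbours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._stream import PeakStream, ThresholdState, qpd_filter
from .model import FiducialSeries, Track

__all__ = [
    "EcgParams",
    "EcgDetectorState",
    "ricker_kernel",
    "enhance_peaks",
    "update_threshold",
    "detect_rpeaks_block",
    "refine_peak",
    "detect_rpeaks",
]

MIN_FS = 100.0  # Hz; below this QRS morphology is undersampled — caller resamples


@dataclass
class EcgParams:
    """Tunable parameters of the R-peak detector.

    ``wavelet_scale`` is the Gaussian width of the Ricker kernel in seconds
    (``None`` resolves to 0.013 s, placing the kernel's peak frequency
    response near 17 Hz, inside the 10–25 Hz QRS band).  ``qpd_attack`` and
    ``qpd_decay`` are envelope time constants in seconds, converted to
    per-sample IIR coefficients at the track's sampling rate so behaviour
    does not depend on fs.
    """

    block_len: float = 0.5          # s
    wavelet_scale: float | None = None  # s (Ricker sigma); None -> 0.013
    noise_weight: float = 1.0       # w_n
    signal_weight: float = 1.0      # w_s
    threshold_scale: float = 0.25   # c
    qpd_attack: float = 0.01        # s
    qpd_decay: float = 1.5          # s
    noise_avg_coeff: float = 0.2    # EMA coefficient for the noise level
    refractory: float = 0.25        # s (240 bpm ceiling)
    warmup: float = 2.0             # s used to prime threshold levels
    snap_window: float = 0.05       # s; raw-ECG argmax search around a candidate
    block_phase: float = 0.0        # s; length of a leading partial block

    def __post_init__(self) -> None:
        if self.block_len <= 0:
            raise ValueError("block_len must be positive")
        if not (0 < self.qpd_attack <= self.qpd_decay):
            raise ValueError("attack time constant must be positive and "
                             "not exceed the decay time constant")

    @property
    def scale(self) -> float:
        return 0.013 if self.wavelet_scale is None else self.wavelet_scale


def ricker_kernel(fs: float, scale_s: float) -> np.ndarray:
    """Mexican-hat (Ricker) wavelet sampled at ``fs`` with width ``scale_s``.

    Support is truncated at ±4 sigma; the kernel integrates to ~0, so the
    transform is insensitive to DC offset and baseline drift slower than
    the QRS band.
    """
    sigma = scale_s * fs  # in samples
    half = max(2, int(math.ceil(4 * sigma)))
    t = np.arange(-half, half + 1, dtype=np.float64)
    a = 2.0 / (math.sqrt(3 * sigma) * math.pi ** 0.25)
    x = (t / sigma) ** 2
    return a * (1 - x) * np.exp(-x / 2)


def enhance_peaks(block: np.ndarray, fs: float, params: EcgParams | None = None) -> np.ndarray:
    """Single-scale CWT of a block followed by the modulus operation.

    Returns ``Y = |CWT(block)|`` with the same length as the input; record
    edges are reflect-padded.  Y is non-negative and linear in the block up
    to the modulus, so scaling the ECG by k scales Y by |k|.
    """
    params = params or EcgParams()
    block = np.asarray(block, dtype=np.float64)
    if len(block) == 0:
        raise ValueError("block must be non-empty")
    kern = ricker_kernel(fs, params.scale)
    half = (len(kern) - 1) // 2
    ext = np.pad(block, half, mode="reflect") if len(block) > 1 else \
        np.repeat(block, 2 * half + 1)
    return np.abs(np.convolve(ext, kern, mode="valid"))


@dataclass
class EcgDetectorState:
    """Cross-block carry-over for the streaming detector.

    Holds the adaptive-threshold stream (noise level, QPD level, pending
    candidate), plus enough raw samples to continue the wavelet
    convolution seamlessly at the next block boundary.
    """

    fs: float
    params: EcgParams = field(default_factory=EcgParams)

    def __post_init__(self) -> None:
        p = self.params
        self.stream = PeakStream(
            self.fs, noise_weight=p.noise_weight, signal_weight=p.signal_weight,
            threshold_scale=p.threshold_scale, qpd_attack=p.qpd_attack,
            qpd_decay=p.qpd_decay, noise_avg_coeff=p.noise_avg_coeff,
            refractory=p.refractory, warmup=p.warmup)
        self._kern = ricker_kernel(self.fs, p.scale)
        self._half = (len(self._kern) - 1) // 2
        self._ext = np.empty(0)   # unconsumed raw samples (incl. lead pad)
        self._lead_done = False

    # convenience accessors used by tests and reporting
    @property
    def noise_level(self) -> float:
        return self.stream.state.noise_level or 0.0

    @property
    def qpd_level(self) -> float:
        return self.stream.state.qpd_level

    @property
    def last_peak_time(self) -> float | None:
        i = self.stream._last_emit
        return None if i is None else i / self.fs

    def _enhance_increment(self, block: np.ndarray) -> np.ndarray:
        """Convert newly arrived raw samples into Y samples, keeping 2*half
        raw samples of context so the convolution matches a full-record
        pass exactly."""
        half = self._half
        self._ext = np.concatenate([self._ext, block])
        if not self._lead_done:
            if len(self._ext) < half + 1:  # too short to reflect-pad yet
                return np.empty(0)
            self._ext = np.concatenate([self._ext[half:0:-1], self._ext])
            self._lead_done = True
        if len(self._ext) <= 2 * half:
            return np.empty(0)
        y = np.abs(np.convolve(self._ext, self._kern, mode="valid"))
        self._ext = self._ext[len(y):]
        return y

    def _flush_enhance(self) -> np.ndarray:
        half = self._half
        raw_tail = self._ext
        if not self._lead_done:
            # record shorter than the kernel half-width: pad both ends
            if len(raw_tail) < 2:
                return np.empty(0)
            y = np.abs(np.convolve(np.pad(raw_tail, half, mode="reflect"),
                                   self._kern, mode="valid"))
            self._ext = np.empty(0)
            return y
        if len(raw_tail) < 2:
            return np.empty(0)
        pad = min(half, len(raw_tail) - 1)
        ext = np.concatenate([raw_tail, raw_tail[-2:-(pad + 2):-1]])
        y = np.abs(np.convolve(ext, self._kern, mode="valid"))
        self._ext = np.empty(0)
        return y


def update_threshold(state: EcgDetectorState, y_block: np.ndarray,
                     params: EcgParams | None = None) -> tuple[float, EcgDetectorState]:
    """Per-block threshold update: noise EMA + quasi-peak signal level.

    The noise level is the running average of the block STD of Y; the
    signal level is tracked per sample by the quasi-peak detector.  The
    returned threshold is ``c * (w_n * noise + w_s * qpd)`` using the
    post-block levels.  ``state`` is updated in place and returned.
    """
    p = params or state.params
    y_block = np.asarray(y_block, dtype=np.float64)
    if len(y_block) == 0:
        raise ValueError("y_block must be non-empty")
    ts: ThresholdState = state.stream.state
    ts.update_noise(float(np.std(y_block)), p.noise_avg_coeff)
    _, ts.qpd_level = qpd_filter(y_block, ts.qpd_level,
                                 state.stream.attack, state.stream.decay)
    return ts.threshold(p.noise_weight, p.signal_weight, p.threshold_scale), state


def detect_rpeaks_block(block: np.ndarray, fs: float, state: EcgDetectorState | None,
                        params: EcgParams | None = None) -> tuple[list[int], EcgDetectorState]:
    """Process one raw-ECG block; return candidate R indices resolved so far.

    Candidate indices are global sample indices into the full record (i.e.
    cumulative across blocks).  An empty ``block`` flushes the stream,
    emitting pending candidates held near the end of the previous block.
    """
    params = params or EcgParams()
    if state is None:
        state = EcgDetectorState(fs, params)
    block = np.asarray(block, dtype=np.float64)
    if len(block) == 0:
        y = state._flush_enhance()
        cands = state.stream.feed(y) if len(y) else []
        cands += state.stream.flush()
        return cands, state
    y = state._enhance_increment(block)
    return (state.stream.feed(y) if len(y) else []), state


def refine_peak(ecg: np.ndarray, idx: int, fs: float, offset: float = 0.0) -> float:
    """Sub-sample peak location by parabolic interpolation.

    Fits a second-order polynomial through ``ecg[idx-1..idx+1]`` and
    returns the time of its vertex, ``(idx + delta) / fs`` with
    ``delta = (y- − y+) / (2 (y- − 2 y0 + y+))``, clipped to ±0.5 samples.
    A flat triple (zero curvature) and edge indices return the unrefined
    grid time.
    """
    ecg = np.asarray(ecg, dtype=np.float64)
    if idx < 1 or idx > len(ecg) - 2:
        return offset + idx / fs
    ym, y0, yp = ecg[idx - 1], ecg[idx], ecg[idx + 1]
    denom = ym - 2 * y0 + yp
    delta = 0.0 if denom == 0 else 0.5 * (ym - yp) / denom
    delta = min(0.5, max(-0.5, delta))
    return offset + (idx + delta) / fs


def detect_rpeaks(ecg: Track, params: EcgParams | None = None) -> FiducialSeries:
    """Full pipeline: enhance → adaptive threshold → detect → refine.

    Returns a :class:`FiducialSeries` named ``"R"`` with strictly
    increasing sub-sample timestamps and a minimum gap equal to the
    refractory period.  Raises for sampling rates below 100 Hz; an empty
    or flat record yields an empty series.
    """
    params = params or EcgParams()
    if ecg.fs < MIN_FS:
        raise ValueError(f"ECG sampling rate must be >= {MIN_FS:g} Hz, "
                         f"got {ecg.fs:g} (resample first)")
    series = FiducialSeries("R", min_distance=0.0)
    x = ecg.values
    if len(x) == 0:
        return series
    state = EcgDetectorState(ecg.fs, params)
    nblock = max(1, int(round(params.block_len * ecg.fs)))
    first = int(round(params.block_phase * ecg.fs))
    pos = first if 0 < first < len(x) else nblock
    boundaries = list(range(pos, len(x), nblock)) + [len(x)]
    candidates: list[int] = []
    start = 0
    for e in boundaries:
        if e > start:
            c, state = detect_rpeaks_block(x[start:e], ecg.fs, state, params)
            candidates.extend(c)
            start = e
    c, _ = detect_rpeaks_block(np.empty(0), ecg.fs, state, params)
    candidates.extend(c)

    snap = max(1, int(round(params.snap_window * ecg.fs)))
    for idx in candidates:
        lo, hi = max(0, idx - snap), min(len(x), idx + snap + 1)
        j = lo + int(np.argmax(x[lo:hi]))
        t = refine_peak(x, j, ecg.fs, ecg.offset)
        series.insert(t, amplitude=ecg.value_at(t))
    return series
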