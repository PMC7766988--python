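"""Derivative-based PPG fiducial detector.

The pulse wave is low-pass filtered (default 10 Hz, zero-phase) and
differentiated.  Upstrokes — the points of steepest systolic rise — are
local maxima of the derivative and are found with the same adaptive
noise/quasi-peak thresholding machinery as the ECG detector, applied to the
zero-clamped derivative.  From each upstroke the remaining fiducials follow
from derivative zero-crossings: the foot is the last upward crossing before
the upstroke, the systolic peak the first downward crossing after it.  A
beat is valid only when foot, upstroke and peak are all found.  Secondary
fiducials (shoulder, dicrotic notch, secondary peak) are searched within
time and amplitude windows expressed as fractions of the beat's
foot-to-peak rise time and amplitude; absent fiducials are NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._stream import PeakStream
from .ecg import refine_peak
from .model import FiducialSeries, Track, derive_track

__all__ = [
    "PpgParams",
    "BeatFiducials",
    "preprocess_ppg",
    "zero_clamp",
    "find_upstrokes",
    "locate_primary_fiducials",
    "locate_secondary_fiducials",
    "beat_features",
    "detect_ppg_fiducials",
]

MIN_FS = 25.0  # Hz

FIDUCIAL_NAMES = ("foot", "upstroke", "peak",
                  "shoulder", "secondary_peak", "dicrotic_notch")


@dataclass
class PpgParams:
    """Tunable parameters of the PPG fiducial detector.

    The secondary-fiducial search windows are proportional: the dicrotic
    notch / secondary peak must lie within ``*_time_window × rise_time``
    after the systolic peak and within ``*_amp_window × foot-to-peak
    amplitude`` below it.  Thresholding parameters mirror the ECG
    detector's.
    """

    lpf_cutoff: float = 10.0        # Hz
    lpf_order: int = 4
    sp_time_window: float = 2.0     # × rise_time
    dn_time_window: float = 2.0
    sp_amp_window: float = 1.0      # × foot-to-peak amplitude
    dn_amp_window: float = 1.0
    noise_weight: float = 1.0
    signal_weight: float = 1.0
    threshold_scale: float = 0.25
    qpd_attack: float = 0.01        # s
    qpd_decay: float = 1.5          # s
    noise_avg_coeff: float = 0.2
    refractory: float = 0.25        # s
    warmup: float = 2.0             # s
    block_len: float = 0.5          # s
    block_phase: float = 0.0        # s

    def __post_init__(self) -> None:
        if self.lpf_cutoff <= 0:
            raise ValueError("lpf_cutoff must be positive")
        for w in (self.sp_time_window, self.dn_time_window,
                  self.sp_amp_window, self.dn_amp_window):
            if not 0 < w <= 5:
                raise ValueError("window fractions must lie in (0, 5]")


@dataclass
class Fiducial:
    t: float
    a: float

    @property
    def isnan(self) -> bool:
        return math.isnan(self.t)


NAN_FIDUCIAL = Fiducial(math.nan, math.nan)


@dataclass
class BeatFiducials:
    """Fiducials of one PPG beat; foot/upstroke/peak are always present,
    the others may be NaN."""

    foot: Fiducial
    upstroke: Fiducial
    peak: Fiducial
    shoulder: Fiducial = field(default_factory=lambda: NAN_FIDUCIAL)
    secondary_peak: Fiducial = field(default_factory=lambda: NAN_FIDUCIAL)
    dicrotic_notch: Fiducial = field(default_factory=lambda: NAN_FIDUCIAL)

    @property
    def rise_time(self) -> float:
        return self.peak.t - self.foot.t

    @property
    def foot_peak_amplitude(self) -> float:
        return self.peak.a - self.foot.a


def preprocess_ppg(ppg: Track, params: PpgParams | None = None) -> tuple[Track, Track]:
    """Zero-phase low-pass filter and differentiate a PPG track.

    Returns ``(lpf, dlpf)``; the derivative is in input units per second.
    Zero-phase (forward–backward) filtering keeps fiducial timestamps free
    of group delay.
    """
    params = params or PpgParams()
    if ppg.fs < MIN_FS:
        raise ValueError(f"PPG sampling rate must be >= {MIN_FS:g} Hz")
    if params.lpf_cutoff >= ppg.fs / 2:
        raise ValueError(f"cutoff {params.lpf_cutoff} Hz >= Nyquist {ppg.fs / 2} Hz")
    lpf = derive_track(ppg, "lowpass", cutoff_hz=params.lpf_cutoff,
                       order=params.lpf_order)
    dlpf = derive_track(lpf, "derivative")
    return lpf, dlpf


def zero_clamp(x: np.ndarray) -> np.ndarray:
    """Force negative values to zero (the upstroke polarity is always
    positive, so only the rising part of the derivative matters)."""
    return np.maximum(np.asarray(x, dtype=np.float64), 0.0)


def find_upstrokes(abs_dlpfs: np.ndarray, fs: float,
                   params: PpgParams | None = None) -> list[int]:
    """Indices of adaptive-threshold local maxima of the clamped derivative.

    Streams the signal block-wise through the shared noise-STD +
    quasi-peak threshold machinery; candidates are separated by at least
    the refractory period.
    """
    params = params or PpgParams()
    abs_dlpfs = np.asarray(abs_dlpfs, dtype=np.float64)
    stream = PeakStream(
        fs, noise_weight=params.noise_weight, signal_weight=params.signal_weight,
        threshold_scale=params.threshold_scale, qpd_attack=params.qpd_attack,
        qpd_decay=params.qpd_decay, noise_avg_coeff=params.noise_avg_coeff,
        refractory=params.refractory, warmup=params.warmup)
    nblock = max(1, int(round(params.block_len * fs)))
    first = int(round(params.block_phase * fs))
    pos = first if 0 < first < len(abs_dlpfs) else nblock
    out: list[int] = []
    start = 0
    for e in list(range(pos, len(abs_dlpfs), nblock)) + [len(abs_dlpfs)]:
        if e > start:
            out.extend(stream.feed(abs_dlpfs[start:e]))
            start = e
    out.extend(stream.flush())
    return out


def _cross_time(d: np.ndarray, i: int, fs: float, offset: float) -> float:
    """Linearly interpolated zero-crossing time between samples i and i+1."""
    d0, d1 = d[i], d[i + 1]
    frac = 0.0 if d1 == d0 else -d0 / (d1 - d0)
    frac = min(1.0, max(0.0, frac))
    return offset + (i + frac) / fs


def locate_primary_fiducials(lpf: Track, dlpf: Track, upstroke_idx: int,
                             lo: int = 0, hi: int | None = None
                             ) -> tuple[Fiducial, Fiducial, Fiducial] | None:
    """Foot, upstroke and systolic peak for one detected upstroke.

    The foot is the last upward derivative zero-crossing (dlpf ≤ 0 → > 0)
    before the upstroke; the peak is the first downward crossing
    (> 0 → ≤ 0) after it.  Crossing times are linearly interpolated and
    amplitudes read from the filtered signal.  The search is confined to
    ``[lo, hi)`` (neighbouring upstrokes / record edges); if either
    crossing is missing the beat is invalid and ``None`` is returned.
    """
    d = dlpf.values
    n = len(d)
    hi = n if hi is None else min(hi, n)
    if not lo <= upstroke_idx < hi:
        return None
    foot_i = None
    for i in range(upstroke_idx - 1, lo - 1, -1):
        if d[i] <= 0 < d[i + 1]:
            foot_i = i
            break
    peak_i = None
    for i in range(upstroke_idx, hi - 1):
        if d[i] > 0 >= d[i + 1]:
            peak_i = i
            break
    if foot_i is None or peak_i is None:
        return None
    t_foot = _cross_time(d, foot_i, dlpf.fs, dlpf.offset)
    t_peak = _cross_time(d, peak_i, dlpf.fs, dlpf.offset)
    t_up = refine_peak(d, upstroke_idx, dlpf.fs, dlpf.offset)
    foot = Fiducial(t_foot, lpf.value_at(t_foot))
    up = Fiducial(t_up, lpf.value_at(t_up))
    peak = Fiducial(t_peak, lpf.value_at(t_peak))
    if not foot.t < up.t < peak.t:
        return None
    return foot, up, peak


def locate_secondary_fiducials(lpf: Track, dlpf: Track, abs_dlpfs: np.ndarray,
                               beat: tuple[Fiducial, Fiducial, Fiducial],
                               params: PpgParams | None = None,
                               hi: int | None = None
                               ) -> tuple[Fiducial, Fiducial, Fiducial]:
    """Shoulder, secondary peak and dicrotic notch (each possibly NaN).

    The shoulder is the first derivative trough strictly between upstroke
    and peak.  After the peak the derivative is negative; a dicrotic notch
    shows up as the next upward zero-crossing and the secondary peak as
    the following downward one.  Both must fall inside the configured
    time window after the peak and amplitude window below it, otherwise
    both are NaN.  ``hi`` bounds the search (next beat's foot index).
    """
    params = params or PpgParams()
    foot, up, peak = beat
    d = dlpf.values
    fs = dlpf.fs
    n = len(d)
    hi = n if hi is None else min(hi, n)
    up_i = int(round((up.t - dlpf.offset) * fs))
    peak_i = int(round((peak.t - dlpf.offset) * fs))

    shoulder = NAN_FIDUCIAL
    for j in range(up_i + 1, peak_i):
        if 0 < j < n - 1 and d[j - 1] > d[j] < d[j + 1]:
            t = refine_peak(-d, j, fs, dlpf.offset)
            shoulder = Fiducial(t, lpf.value_at(t))
            break

    rise = peak.t - foot.t
    fp_amp = peak.a - foot.a
    dn = sp = NAN_FIDUCIAL
    dn_i = None
    for i in range(max(peak_i, 1), hi - 1):
        if d[i] <= 0 < d[i + 1]:
            dn_i = i
            break
    if dn_i is not None:
        sp_i = None
        for i in range(dn_i + 1, hi - 1):
            if d[i] > 0 >= d[i + 1]:
                sp_i = i
                break
        if sp_i is not None:
            t_dn = _cross_time(d, dn_i, fs, dlpf.offset)
            t_sp = _cross_time(d, sp_i, fs, dlpf.offset)
            cand_dn = Fiducial(t_dn, lpf.value_at(t_dn))
            cand_sp = Fiducial(t_sp, lpf.value_at(t_sp))
            ok = (t_dn - peak.t <= params.dn_time_window * rise
                  and t_sp - peak.t <= params.sp_time_window * rise
                  and peak.a - cand_dn.a <= params.dn_amp_window * fp_amp
                  and peak.a - cand_sp.a <= params.sp_amp_window * fp_amp)
            if ok:
                dn, sp = cand_dn, cand_sp
    return shoulder, sp, dn


def beat_features(beat: BeatFiducials, next_foot_t: float = math.nan) -> dict[str, float]:
    """Per-beat timing and amplitude features.

    ``decay_time`` needs the next beat's foot and is NaN for the last
    beat; the notch amplitude ratio is NaN when no notch was found.
    """
    rise = beat.rise_time
    decay = next_foot_t - beat.peak.t
    amp = beat.foot_peak_amplitude
    dn = beat.dicrotic_notch
    return {
        "rise_time": rise,
        "decay_time": decay,
        "foot_peak_amplitude": amp,
        "rise_decay_ratio": rise / decay if decay and not math.isnan(decay) else math.nan,
        "notch_amplitude_ratio": ((dn.a - beat.foot.a) / amp
                                  if not dn.isnan and amp else math.nan),
    }


def detect_ppg_fiducials(ppg: Track, params: PpgParams | None = None
                         ) -> dict[str, FiducialSeries]:
    """Full PPG pipeline: preprocess → upstrokes → per-beat fiducials.

    Returns one :class:`FiducialSeries` per fiducial name; beats whose
    foot or peak cannot be bracketed (record edges, monotone tails) are
    dropped, so the foot, upstroke and peak series always have equal
    length.  NaN secondary fiducials are simply absent from their series.
    """
    params = params or PpgParams()
    series = {name: FiducialSeries(name) for name in FIDUCIAL_NAMES}
    if len(ppg) < 3 or np.ptp(ppg.values) == 0:
        return series
    lpf, dlpf = preprocess_ppg(ppg, params)
    abs_d = zero_clamp(dlpf.values)
    upstrokes = find_upstrokes(abs_d, ppg.fs, params)

    beats: list[BeatFiducials] = []
    bounds: list[int] = []
    for k, ui in enumerate(upstrokes):
        lo = upstrokes[k - 1] if k > 0 else 0
        hi = upstrokes[k + 1] if k + 1 < len(upstrokes) else len(dlpf.values)
        prim = locate_primary_fiducials(lpf, dlpf, ui, lo, hi)
        if prim is None:
            continue
        beats.append(BeatFiducials(*prim))
        bounds.append(hi)

    for k, beat in enumerate(beats):
        # bound the notch search by the next beat's foot so the following
        # beat's onset is never mistaken for a dicrotic notch
        if k + 1 < len(beats):
            hi = int((beats[k + 1].foot.t - dlpf.offset) * dlpf.fs) + 1
        else:
            hi = bounds[k]
        sh, sp, dn = locate_secondary_fiducials(
            lpf, dlpf, abs_d, (beat.foot, beat.upstroke, beat.peak), params, hi)
        beat.shoulder, beat.secondary_peak, beat.dicrotic_notch = sh, sp, dn

    for beat in beats:
        series["foot"].insert(beat.foot.t, beat.foot.a)
        series["upstroke"].insert(beat.upstroke.t, beat.upstroke.a)
        series["peak"].insert(beat.peak.t, beat.peak.a)
        for name, f in (("shoulder", beat.shoulder),
                        ("secondary_peak", beat.secondary_peak),
                        ("dicrotic_notch", beat.dicrotic_notch)):
            if not f.isnan:
                series[name].insert(f.t, f.a)
    return series
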