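"""Synthetic ECG and PPG generators with exact ground-truth fiducials.

The generators exist so every detector and the evaluation harness can be
exercised offline against known truth.  Beats are sums of Gaussian waves:

* ECG — one Gaussian per wave (P, Q, R, S, T) placed relative to the beat's
  R time, with the QRS width, wave amplitudes and heart rate as the
  controllable morphology axes.  The R apex time is the ground truth.
* PPG — a narrow primary Gaussian (systolic rise and peak) plus an
  optional broader, delayed secondary Gaussian that produces a dicrotic
  notch, a secondary peak and a realistic slow diastolic decay.  Ground
  truth (foot, upstroke, peak, notch, secondary peak) is computed from the
  analytic pulse train's derivative on a fine grid, independent of any
  detector.  A partial pulse decaying into the record start gives the
  first beat a genuine onset.

Gaussian tails are smooth and band-limited-ish, which keeps truth exact
while spanning the same morphology axes the detectors care about.  RR
variability is Gaussian jitter; noise (white, baseline wander, bursts) is
added separately by :func:`add_noise` so the clean truth is preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import Track

__all__ = ["EcgSimSpec", "PpgSimSpec", "SimOutput",
           "gen_ecg", "gen_ppg", "add_noise"]


@dataclass
class EcgSimSpec:
    fs: float = 250.0
    duration: float = 60.0
    hr: float | list[float] = 60.0       # bpm; a sequence is an HR profile
    qrs_width: float = 0.08              # s
    p_amp: float = 0.15                  # relative to R
    t_amp: float = 0.35
    r_amp: float = 1.0
    hrv_sd: float = 0.0                  # s of Gaussian RR jitter
    seed: int = 0

    def __post_init__(self) -> None:
        hrs = np.atleast_1d(np.asarray(self.hr, dtype=float))
        if not ((hrs > 20) & (hrs <= 240)).all():
            raise ValueError("hr must lie in (20, 240] bpm")
        if not 0.04 < self.qrs_width < 0.2:
            raise ValueError("qrs_width must lie in (0.04, 0.2) s")
        if self.fs < 100:
            raise ValueError("fs must be >= 100 Hz")
        if self.duration <= 0 or self.hrv_sd < 0:
            raise ValueError("invalid duration or hrv_sd")


@dataclass
class PpgSimSpec:
    fs: float = 125.0
    duration: float = 60.0
    hr: float | list[float] = 60.0
    hrv_sd: float = 0.0
    rise_fraction: float = 0.2           # of beat period, shapes systolic width
    notch_delay: float = 0.35            # s after systolic peak centre
    notch_depth: float = 0.2             # 0 disables the secondary component
    second_peak_amp: float = 0.45        # relative to primary
    seed: int = 0

    def __post_init__(self) -> None:
        hrs = np.atleast_1d(np.asarray(self.hr, dtype=float))
        if not ((hrs > 20) & (hrs <= 240)).all():
            raise ValueError("hr must lie in (20, 240] bpm")
        if not 0.1 < self.rise_fraction < 0.5:
            raise ValueError("rise_fraction must lie in (0.1, 0.5)")
        if not 0 <= self.notch_depth < 1:
            raise ValueError("notch_depth must lie in [0, 1)")
        if self.fs < 25 or self.duration <= 0 or self.hrv_sd < 0:
            raise ValueError("invalid fs, duration or hrv_sd")


@dataclass
class SimOutput:
    """A generated track plus its exact fiducial truth."""

    track: Track
    truth: dict[str, np.ndarray] = field(default_factory=dict)


def _beat_times(spec, start: float, margin: float, rng) -> np.ndarray:
    """Cumulative beat anchor times from the HR profile plus RR jitter."""
    hrs = np.atleast_1d(np.asarray(spec.hr, dtype=float))
    profile_t = np.linspace(0, spec.duration, len(hrs)) if len(hrs) > 1 else None
    times = []
    t = start
    while t < spec.duration - margin:
        times.append(t)
        hr = float(np.interp(t, profile_t, hrs)) if profile_t is not None else hrs[0]
        rr = 60.0 / hr + (rng.normal(0.0, spec.hrv_sd) if spec.hrv_sd > 0 else 0.0)
        t += max(rr, 0.3)
    return np.asarray(times)


def _add_gaussians(sig: np.ndarray, fs: float, centers, amps, sigmas) -> None:
    """Accumulate Gaussian bumps onto a sample grid (±6 sigma support)."""
    n = len(sig)
    for c, a, s in zip(centers, amps, sigmas):
        lo = max(0, int((c - 6 * s) * fs))
        hi = min(n, int((c + 6 * s) * fs) + 1)
        if hi <= lo:
            continue
        t = np.arange(lo, hi) / fs
        sig[lo:hi] += a * np.exp(-((t - c) / s) ** 2 / 2)


def gen_ecg(spec: EcgSimSpec) -> SimOutput:
    """Gaussian-template ECG; truth["R"] holds the exact R-apex times.

    Each beat is the sum of five Gaussians with fixed relative placement:
    P at −0.20 s, Q/S flanking the R wave at ±0.6·QRS width, T at
    +0.30 s.  The R sigma is QRS width / 4 so the wave's ±2-sigma support
    equals the nominal QRS duration.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    r_times = _beat_times(spec, start=0.4, margin=0.45, rng=rng)
    qw = spec.qrs_width
    waves = [  # (offset s, amplitude, sigma s)
        (-0.20, spec.p_amp, 0.025),
        (-0.6 * qw, -0.12 * spec.r_amp, qw / 8),
        (0.0, spec.r_amp, qw / 4),
        (+0.6 * qw, -0.18 * spec.r_amp, qw / 8),
        (+0.30, spec.t_amp, 0.05),
    ]
    n = int(round(spec.duration * spec.fs))
    sig = np.zeros(n)
    for off, amp, sg in waves:
        _add_gaussians(sig, spec.fs, r_times + off, [amp] * len(r_times),
                       [sg] * len(r_times))
    track = Track("ecg_sim", spec.fs, sig, units="mV")
    return SimOutput(track, {"R": r_times})


def _ppg_components(spec: PpgSimSpec, rng) -> tuple[np.ndarray, list[tuple]]:
    """Primary beat centres plus the full Gaussian component list
    (including the leading partial pulse)."""
    hrs = np.atleast_1d(np.asarray(spec.hr, dtype=float))
    t_nom = 60.0 / float(np.mean(hrs))
    s1 = 0.35 * spec.rise_fraction * t_nom
    s2 = 0.22 * t_nom * (1 - 0.6 * spec.notch_depth)
    a2 = spec.second_peak_amp if spec.notch_depth > 0 else 0.0
    tail = (spec.notch_delay + 4 * s2) if a2 > 0 else 4 * s1
    c1 = _beat_times(spec, start=0.6 * t_nom, margin=tail + 0.05, rng=rng)

    comps: list[tuple] = []   # (center, amp, sigma)
    # leading partial pulse: its peak (and any secondary rise) lies at or
    # before t = 0, so the record opens on a plain diastolic decay
    lead = min(c1[0] - t_nom, -(spec.notch_delay + s2) if a2 > 0 else -s1)
    comps.append((lead, 1.0, s1))
    if a2 > 0:
        comps.append((lead + spec.notch_delay, a2, s2))
    for c in c1:
        comps.append((c, 1.0, s1))
        if a2 > 0:
            comps.append((c + spec.notch_delay, a2, s2))
    return c1, comps


def _eval_components(t: np.ndarray, comps, deriv: int = 0) -> np.ndarray:
    out = np.zeros_like(t)
    for c, a, s in comps:
        z = (t - c) / s
        g = a * np.exp(-z * z / 2)
        if deriv == 0:
            out += g
        elif deriv == 1:
            out += -g * z / s
        else:
            out += g * (z * z - 1) / (s * s)
    return out


def _crossings(sign_src: np.ndarray, t: np.ndarray, upward: bool) -> np.ndarray:
    d0, d1 = sign_src[:-1], sign_src[1:]
    mask = (d0 <= 0) & (d1 > 0) if upward else (d0 > 0) & (d1 <= 0)
    idx = np.nonzero(mask)[0]
    frac = np.where(d1[idx] != d0[idx], -d0[idx] / (d1[idx] - d0[idx]), 0.0)
    return t[idx] + frac * (t[1] - t[0])


def gen_ppg(spec: PpgSimSpec) -> SimOutput:
    """Two-Gaussian pulse train; truth from the analytic derivative.

    Truth fiducials are located on a 2-kHz evaluation of the analytic
    pulse train: the upstroke is the derivative maximum on the systolic
    rise (zero of the analytic second derivative), the foot/peak are the
    bracketing derivative zero-crossings, and — when the secondary
    component is enabled — the dicrotic notch and secondary peak are the
    next upward/downward crossing pair after the peak.
    """
    rng = np.random.default_rng(spec.seed)
    c1, comps = _ppg_components(spec, rng)
    n = int(round(spec.duration * spec.fs))
    sig = np.zeros(n)
    _add_gaussians(sig, spec.fs, [c for c, _, _ in comps],
                   [a for _, a, _ in comps], [s for _, _, s in comps])
    track = Track("ppg_sim", spec.fs, sig, units="a.u.")

    fs_fine = 2000.0
    tf = np.arange(int(spec.duration * fs_fine)) / fs_fine
    d1 = _eval_components(tf, comps, deriv=1)
    ups = _crossings(d1, tf, upward=True)       # feet and notches
    downs = _crossings(d1, tf, upward=False)    # peaks and secondary peaks
    d2 = _eval_components(tf, comps, deriv=2)
    upstroke_all = _crossings(d2, tf, upward=False)  # maxima of d1

    t_nom = 60.0 / float(np.mean(np.atleast_1d(np.asarray(spec.hr, dtype=float))))
    s1 = 0.35 * spec.rise_fraction * t_nom
    feet, upstrokes, peaks, notches, speaks = [], [], [], [], []
    for k, c in enumerate(c1):
        # the upstroke is the d1 maximum on the rise, just before the centre
        cand = upstroke_all[(upstroke_all > c - 3.5 * s1) & (upstroke_all <= c)]
        cand = [u for u in cand if _eval_components(np.array([u]), comps, 1)[0] > 0]
        if not cand:
            continue
        u = max(cand, key=lambda x: _eval_components(np.array([x]), comps, 1)[0])
        f = ups[ups < u]
        p = downs[downs > u]
        if not len(f) or not len(p):
            continue
        feet.append(f[-1])
        upstrokes.append(u)
        peaks.append(p[0])
        if spec.notch_depth > 0:
            nxt_f = ups[ups > p[0]]
            bound = c1[k + 1] if k + 1 < len(c1) else spec.duration
            dn_c = [x for x in nxt_f if x < bound]
            if dn_c:
                dn = dn_c[0]
                sp_c = downs[downs > dn]
                if len(sp_c) and sp_c[0] < bound:
                    notches.append(dn)
                    speaks.append(sp_c[0])
    truth = {"foot": np.asarray(feet), "upstroke": np.asarray(upstrokes),
             "peak": np.asarray(peaks)}
    if spec.notch_depth > 0:
        truth["dicrotic_notch"] = np.asarray(notches)
        truth["secondary_peak"] = np.asarray(speaks)
    return SimOutput(track, truth)


def add_noise(track: Track, white_snr_db: float | None = None,
              wander_amp: float = 0.0, wander_hz: float = 0.3,
              burst_rate: float = 0.0, burst_amp: float = 1.0,
              seed: int = 0) -> Track:
    """Additive corruption: white noise at a target SNR, sinusoidal
    baseline wander, and square-windowed noise bursts (0.5–2 s) at a
    Poisson rate per minute, emulating motion artifacts.  The input track
    is not modified; output is deterministic given the seed.
    """
    if wander_hz >= 1.0:
        raise ValueError("baseline wander must be below 1 Hz")
    rng = np.random.default_rng(seed)
    x = track.values.copy()
    n = len(x)
    t = np.arange(n) / track.fs
    if white_snr_db is not None:
        p_sig = float(np.var(track.values))
        sd = math.sqrt(p_sig / 10 ** (white_snr_db / 10.0))
        x += rng.normal(0.0, sd, n)
    if wander_amp > 0:
        x += wander_amp * np.sin(2 * np.pi * wander_hz * t
                                 + rng.uniform(0, 2 * np.pi))
    if burst_rate > 0:
        k = rng.poisson(burst_rate * track.duration / 60.0)
        for _ in range(k):
            start = rng.uniform(0, track.duration)
            length = rng.uniform(0.5, 2.0)
            lo = int(start * track.fs)
            hi = min(n, int((start + length) * track.fs))
            x[lo:hi] += rng.normal(0.0, burst_amp, hi - lo)
    return Track(track.name + "+noise", track.fs, x, track.offset, track.units)
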