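"""Streaming adaptive-threshold peak detection shared by the ECG and PPG
detectors.

The detector consumes a non-negative "enhanced" signal Y chunk by chunk and
emits indices of local maxima that exceed an adaptive threshold

    T = c * (w_n * noise_level + w_s * qpd_level)

where ``noise_level`` is a running (exponential) average of the per-chunk
standard deviation of Y and ``qpd_level`` is the output of a quasi-peak
detector: a first-order IIR envelope follower with a fast attack and slow
decay.  Candidates separated by less than a refractory period are merged
(the larger survives), and a candidate is only emitted once a full
refractory period has elapsed without a larger sample — which lets beats
split across chunk boundaries resolve correctly.

Every operation is positively homogeneous in Y, so detections are invariant
to amplitude scaling of the input signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ThresholdState", "PeakStream", "qpd_filter", "coeff_from_tc"]


def coeff_from_tc(tc: float, fs: float) -> float:
    """Per-sample IIR coefficient for a time constant ``tc`` (s) at ``fs``."""
    if tc <= 0:
        return 1.0
    return 1.0 - math.exp(-1.0 / (fs * tc))


def qpd_filter(y: np.ndarray, level: float, attack: float, decay: float) -> tuple[np.ndarray, float]:
    """Run the quasi-peak envelope follower over a chunk.

    ``level`` tracks the input with coefficient ``attack`` while rising and
    ``decay`` while falling.  Returns the per-sample level trace (value
    *before* consuming each sample, so a peak does not raise its own
    threshold) and the final level.
    """
    out = np.empty(len(y))
    for i, v in enumerate(y):
        out[i] = level
        if v > level:
            level += attack * (v - level)
        else:
            level += decay * (v - level)
    return out, level


@dataclass
class ThresholdState:
    """Adaptive-threshold bookkeeping carried across blocks."""

    noise_level: float | None = None   # EMA of per-block STD of Y (None = fresh)
    qpd_level: float = 0.0

    def update_noise(self, block_std: float, coeff: float) -> None:
        if self.noise_level is None:
            self.noise_level = block_std
        else:
            self.noise_level += coeff * (block_std - self.noise_level)

    def threshold(self, w_n: float, w_s: float, c: float) -> float:
        noise = self.noise_level or 0.0
        return c * (w_n * noise + w_s * self.qpd_level)


class PeakStream:
    """Stateful threshold-crossing local-maximum detector.

    Parameters are passed individually so the ECG and PPG front ends can
    map their own parameter objects onto the shared machinery.
    """

    def __init__(self, fs: float, *, noise_weight: float = 1.0,
                 signal_weight: float = 1.0, threshold_scale: float = 0.25,
                 qpd_attack: float = 0.01, qpd_decay: float = 1.5,
                 noise_avg_coeff: float = 0.2, refractory: float = 0.25,
                 warmup: float = 2.0):
        if not 0 < qpd_attack and 0 < qpd_decay:
            raise ValueError("QPD time constants must be positive")
        self.fs = fs
        self.w_n = noise_weight
        self.w_s = signal_weight
        self.c = threshold_scale
        self.attack = coeff_from_tc(qpd_attack, fs)
        self.decay = coeff_from_tc(qpd_decay, fs)
        if not 0 < self.decay <= self.attack <= 1:
            raise ValueError("require 0 < decay coeff <= attack coeff <= 1 "
                             "(attack time constant must not exceed decay)")
        self.noise_coeff = noise_avg_coeff
        self.refr = max(1, int(round(refractory * fs)))
        self.warmup_n = int(round(warmup * fs))
        self.state = ThresholdState()
        self._warm: list[np.ndarray] = []
        self._warm_count = 0
        self._primed = False
        self._i = 0                      # global index of next sample
        self._pending: tuple[int, float] | None = None
        self._last_emit: int | None = None

    # -- priming ---------------------------------------------------------
    def _prime(self, y: np.ndarray) -> None:
        """Initialise levels from an initial stretch of Y so detection does
        not start with a near-zero threshold."""
        if len(y):
            self.state.qpd_level = float(np.max(y))
            self.state.update_noise(float(np.std(y)), self.noise_coeff)
        self._primed = True

    # -- streaming -------------------------------------------------------
    def feed(self, y: np.ndarray) -> list[int]:
        """Consume a chunk of the enhanced signal; return indices (global,
        in samples) of peaks resolved during this call."""
        y = np.asarray(y, dtype=np.float64)
        if not self._primed:
            self._warm.append(y)
            self._warm_count += len(y)
            if self._warm_count < self.warmup_n:
                return []
            buf = np.concatenate(self._warm)
            self._warm = []
            self._prime(buf)
            return self._process(buf)
        return self._process(y)

    def flush(self) -> list[int]:
        """Signal end of data; emits any pending candidate."""
        out: list[int] = []
        if not self._primed and self._warm:
            buf = np.concatenate(self._warm)
            self._warm = []
            self._prime(buf)
            out.extend(self._process(buf))
        if self._pending is not None:
            out.append(self._pending[0])
            self._pending = None
        return out

    def _process(self, y: np.ndarray) -> list[int]:
        if len(y) == 0:
            return []
        self.state.update_noise(float(np.std(y)), self.noise_coeff)
        noise = self.state.noise_level or 0.0
        base = self.c * self.w_n * noise
        cs = self.c * self.w_s
        level = self.state.qpd_level
        attack, decay = self.attack, self.decay
        refr = self.refr
        pending = self._pending
        last = self._last_emit
        i = self._i
        out: list[int] = []
        for v in y:
            thr = base + cs * level
            if v > level:
                level += attack * (v - level)
            else:
                level += decay * (v - level)
            if v > thr and v > 0 and (last is None or i - last >= refr):
                if pending is None or v > pending[1]:
                    pending = (i, float(v))
            if pending is not None and i - pending[0] >= refr:
                out.append(pending[0])
                last = pending[0]
                pending = None
            i += 1
        self.state.qpd_level = level
        self._pending = pending
        self._last_emit = last
        self._i = i
        return out
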