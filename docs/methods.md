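# Methods

This note documents the models and numerical choices behind `beatkit`: what
each algorithm assumes, which parameters matter, what the synthetic
generators do and do not emulate, and where the design was genuinely open.

## ECG R-peak detector

### Model

The QRS complex is the highest-energy transient of the ECG, concentrated
roughly in the 10–25 Hz band. The detector enhances that band with a
single-scale continuous wavelet transform: convolution with a Mexican-hat
(Ricker) kernel of Gaussian width σ (default 13 ms, peak frequency response
≈ 17 Hz), followed by the modulus, yielding Y ≥ 0. The kernel has zero
mean, so DC offset and slow baseline wander do not reach Y. True
multiscale modulus-maxima line tracking is deliberately out of scope; a
single scale plus local-maximum search is sufficient for beat detection
and keeps the detector streaming-friendly.

Detection is block-wise (0.5 s) with an adaptive threshold

T = c · (w_n · N + w_s · S),  defaults c = 0.25, w_n = w_s = 1,

* N — noise level: exponential moving average (coefficient 0.2) of the
  per-block standard deviation of Y. Window-free, matching the streaming
  design.
* S — signal level: quasi-peak detector, a first-order IIR follower with
  separate attack and decay behaviour. Parameters are *time constants in
  seconds* (attack 10 ms, decay 1.5 s) converted to per-sample
  coefficients at the track's rate, so behaviour is sampling-rate
  invariant. With HR ≥ 40 bpm the decayed level at the next beat is
  ≥ exp(−1.5/1.5) ≈ 37 % of the last peak, so T stays in a useful band
  between noise floor and peak height.

The scale c was fixed from this decay analysis (threshold ≈ 5–15 % of the
QRS enhancement peak over the physiological HR range) before the
robustness suite was run, and not adjusted afterwards.

### Streaming semantics

A detector state carries across blocks: (i) enough raw samples to continue
the wavelet convolution exactly (so Y is bit-identical to a full-record
pass; record ends use reflect padding), (ii) envelope levels, (iii) the
pending candidate. A candidate is the running maximum of a suprathreshold
excursion and is only emitted once a full refractory period (0.25 s,
240 bpm ceiling) passes without a larger sample; an empty block flushes
the pipeline. This makes detections independent of block segmentation —
verified by phase-shifting the block grid.

The first 2 s of enhanced signal prime the levels (S ← max, N ← std)
before detection starts, so the first beats are not flagged against a
near-zero threshold. Priming is defined on the record, not the blocks,
preserving segmentation invariance. Every stage is positively homogeneous,
so detections are exactly invariant to amplitude scaling.

### Refinement

Candidate Y-maxima are snapped to the raw-ECG maximum within ±50 ms, then
refined by fitting a parabola through the maximum and its two neighbours:
δ = (y₋ − y₊) / (2(y₋ − 2y₀ + y₊)), clipped to ±½ sample; a flat triple
(zero curvature) or an edge sample is returned unrefined. On sampled
parabolas this recovers the vertex to machine precision; on band-limited
QRS shapes it reduces the mean timing error below the grid error.

Minimum sampling rate 100 Hz; the detector does not resample (caller's
responsibility). No P/Q/S/T delineation and no beat classification.

## PPG fiducial detector

### Model

Fiducials are defined through the first derivative of the low-pass
filtered pulse wave (Butterworth order 4, cutoff 10 Hz). Filtering is
zero-phase (forward–backward): an offline annotation tool wants
timestamps free of group delay, at the cost of being non-causal. The
derivative is zero-clamped — the systolic rise is always positive — and
upstrokes are found with the same noise/quasi-peak thresholding as the
ECG detector.

Per upstroke: foot = last upward derivative zero-crossing before it,
systolic peak = first downward crossing after it, both linearly
interpolated between the bracketing samples (sub-sample, consistent with
the ECG refinement). A beat missing either crossing (record edges,
monotone tails) is rejected, not extrapolated, so the foot/upstroke/peak
series always have equal length. The upstroke itself is refined
parabolically on the derivative.

Secondary fiducials: the shoulder is the first derivative trough strictly
between upstroke and peak (NaN if the derivative is unimodal there).
After the systolic peak the derivative is negative; the dicrotic notch
appears as the next *upward* crossing and the secondary peak as the
following *downward* one. (Stated the other way around in some
descriptions, but the notch is a local minimum of the signal, hence an
upward derivative crossing; the implemented order preserves
notch ≤ secondary peak.) Both must fall within 2.0 × rise-time after the
peak and within 1.0 × foot-to-peak amplitude below it — proportional
windows with no published reference values; these defaults are
calibration, not reproduction, and are fully configurable. The search is
additionally bounded by the next beat's foot so a following onset can
never masquerade as a notch.

## Evaluation harness

Events match when |Δt| ≤ τ, one-to-one. The matcher walks both sorted
sequences in order and pairs the earliest compatible events; for interval
compatibility on a line this greedy scheme attains maximum cardinality
(checked against a Hopcroft–Karp maximum-matching oracle on thousands of
random instances). Ties resolve toward the earlier detection. τ defaults:
50 ms (≈ half a normal QRS width) and 125 ms (half the beat period at
240 bpm). Error rate counts both error kinds, (FP+FN)/TP; an FP-only mode
exists as a flag because "false detections" is ambiguous.

## Synthetic generators

The generators define the test world; their defaults are fixed and the
acceptance thresholds were not tuned to them after the fact.

**ECG** — each beat is five Gaussians (P at −0.20 s, Q/S flanking R at
±0.6·QRS-width, T at +0.30 s; σ_R = QRS-width/4 so the ±2σ support equals
the nominal QRS duration; amplitudes 0.15, −0.12, 1.0, −0.18, 0.35
relative). RR intervals get Gaussian jitter (`hrv_sd`), and `hr` may be a
profile for variable rate. The R-apex truth is the analytic Gaussian
centre; neighbouring waves shift the true apex by < 0.1 ms, negligible at
every tolerance used. This is *not* a dynamical ECG model: no coupled
oscillator, no realistic HRV spectrum, no ectopy — morphology axes (HR,
QRS width, wave amplitudes) are what the detectors care about, and exact
truth is what the tests need.

**PPG** — each pulse is a narrow primary Gaussian (σ₁ = 0.35 ·
rise_fraction · beat period) plus, when `notch_depth > 0`, a broader
secondary Gaussian delayed by `notch_delay` (default 0.35 s, amplitude
0.45, σ₂ = 0.22 · period · (1 − 0.6 · notch_depth)). The secondary
component provides both the dicrotic notch/secondary peak and a realistic
slow diastolic decay, keeping the inter-beat minimum at ≈ 10 % of pulse
height — important numerically, because a train of narrow Gaussians alone
decays to ~1e−13 of peak between beats and derivative zero-crossings
there would be floating-point noise. A partial pulse decaying into the
record start gives the first beat a genuine onset. Truth is computed from
the *analytic* derivative (and second derivative for the upstroke) on a
2-kHz grid with interpolated zero-crossings — independent of the detector
path. With the default absolute notch delay, the proportional DN/SP
search windows accept the notch at ≤ ≈ 60 bpm and reject it at faster
rates; notch-recovery tests therefore run at 60 bpm.

**Noise** — white Gaussian at a target SNR (defined against the clean
signal's variance), sinusoidal baseline wander (< 1 Hz), and
square-windowed noise bursts of 0.5–2 s at a Poisson per-minute rate.
Crude relative to real motion artifacts, but sufficient to exercise
threshold adaptation.

A green test on this world establishes algorithmic correctness — closure,
invariances, graceful degradation — not clinical performance: real
recordings add morphology variability, ectopy and non-stationary
artifacts the generators do not model.

### Upstroke vs. peak precision

The claim that the steep upstroke is a more precise beat marker than the
rounded systolic peak rests on a physical argument: additive *drift*
shifts a flat extremum by (drift slope)/(signal curvature) but barely
moves a steep edge. Under pure white noise the opposite holds for these
smooth synthetic pulses (the 10-Hz LPF leaves the peak easier to localise
than the derivative maximum). The property test therefore uses white
noise *plus baseline wander* — the regime the claim is about, and the
dominant artifact in ambulatory PPG.

## Annotation model

Fiducial series keep timestamps strictly increasing with a configurable
minimum distance; a conflicting insertion is rejected (non-destructive
default) rather than replacing its neighbour. Timestamps are real-valued
seconds so sub-sample refinements are representable. Partitions within
one set may not overlap (touching endpoints allowed). Epochs are
half-open [kL, (k+1)L) windows; a trailing partial window is labelable.
The snap-to-extremum helper works on the sample grid by design (no
sub-sample refinement); its window size has no claimed default and must
be chosen by the caller.

Adjudication default is the strict reading: any non-unanimity among the
first three votes goes to the fourth reviewer, and a 3-to-1 majority
decides; otherwise the epoch escalates to the whole group. The looser
reading (2-of-3 majority is consensus) is available via a flag, because
"disagreement" is ambiguous between the two.

## Workspace persistence

HDF5 layout as documented in `workspace.py`; float64 throughout, so
save → load round-trips are exact. The schema carries a version and the
loader rejects future major versions. The layout is this package's own
contract; compatibility with any other tool's files is not claimed.
Configuration is a declarative YAML file (no executable hooks): source
directory (the one mandatory field), column-to-track mapping, detector
toggles with parameter overrides, annotation and epoch settings.

## Known limitations

* Single-scale wavelet enhancement assumes a dominant QRS deflection;
  very broad or low-amplitude QRS morphologies may need a different
  `wavelet_scale`.
* The ECG detector assumes a positive R apex when snapping to the raw
  signal.
* PPG beats at record edges are dropped, not extrapolated.
* No automatic signal-quality classification: epoch quality labels are a
  human-annotation scheme, merged by the adjudication logic.
* The streaming noise level updates per fed block, so block segmentation
  has a second-order effect on the threshold; detections are invariant in
  practice (tested), but the threshold trace itself is not bit-identical
  across segmentations.
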