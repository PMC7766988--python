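"""PPG fiducial detector: preprocessing, upstrokes, fiducial derivation."""

import math

import numpy as np
import pytest

from beatkit import PpgSimSpec, gen_ppg
from beatkit.evaluate import match_events
from beatkit.model import Track
from beatkit.ppg import (BeatFiducials, Fiducial, PpgParams, beat_features,
                         detect_ppg_fiducials, find_upstrokes,
                         locate_primary_fiducials, locate_secondary_fiducials,
                         preprocess_ppg, zero_clamp)
from beatkit.simulate import add_noise


class TestPreprocess:
    def test_constant_input(self):
        tr = Track("p", 100.0, np.full(500, 3.0))
        lpf, dlpf = preprocess_ppg(tr)
        np.testing.assert_allclose(lpf.values, 3.0, atol=1e-9)
        np.testing.assert_allclose(dlpf.values, 0.0, atol=1e-6)

    def test_sinusoid_derivative(self):
        fs = 100.0
        t = np.arange(int(10 * fs)) / fs
        tr = Track("p", fs, np.sin(2 * np.pi * t))
        _, dlpf = preprocess_ppg(tr)
        mid = slice(100, -100)
        # amplitude 2*pi, phase advanced by ~90 degrees (i.e. cosine)
        assert np.max(np.abs(dlpf.values[mid])) == pytest.approx(2 * np.pi, rel=0.02)
        np.testing.assert_allclose(dlpf.values[mid],
                                   2 * np.pi * np.cos(2 * np.pi * t[mid]),
                                   atol=0.05 * 2 * np.pi)

    def test_stopband_attenuation(self):
        fs = 100.0
        t = np.arange(int(10 * fs)) / fs
        tone = np.sin(2 * np.pi * 25 * t)
        lpf, _ = preprocess_ppg(Track("p", fs, np.sin(2 * np.pi * t) + tone))
        resid = lpf.values[100:-100] - np.sin(2 * np.pi * t[100:-100])
        # 25 Hz tone is > 10x attenuated (leaves < 0.1 amplitude residue)
        assert np.max(np.abs(resid)) < 0.1

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            preprocess_ppg(Track("p", 30.0, np.zeros(100)),
                           PpgParams(lpf_cutoff=20.0))


class TestZeroClamp:
    @pytest.mark.parametrize("x, expected", [
        ([-1, 2, -3], [0, 2, 0]),
        ([-5, -1], [0, 0]),
        ([0, 1, 2], [0, 1, 2]),
    ])
    def test_clamp(self, x, expected):
        np.testing.assert_array_equal(zero_clamp(np.array(x, float)), expected)


class TestFindUpstrokes:
    def test_zeros_give_none(self):
        assert find_upstrokes(np.zeros(1000), 125.0) == []

    def test_one_upstroke_per_beat(self, clean_ppg):
        lpf, dlpf = preprocess_ppg(clean_ppg.track)
        idx = find_upstrokes(zero_clamp(dlpf.values), clean_ppg.track.fs)
        truth = clean_ppg.truth["upstroke"]
        times = np.asarray(idx) / clean_ppg.track.fs
        m = match_events(times, truth, 0.020)
        assert m.fn == 0 and m.fp <= 1

    def test_scale_invariance(self, clean_ppg):
        _, dlpf = preprocess_ppg(clean_ppg.track)
        a = zero_clamp(dlpf.values)
        assert find_upstrokes(a, 125.0) == find_upstrokes(5.0 * a, 125.0)


class TestPrimaryFiducials:
    def _sinusoid_tracks(self, fs=1000.0):
        t = np.arange(int(1 * fs)) / fs
        lpf = Track("p", fs, -np.cos(2 * np.pi * t))
        dlpf = Track("dp", fs, 2 * np.pi * np.sin(2 * np.pi * t))
        return lpf, dlpf

    def test_sinusoid_analytic_positions(self):
        lpf, dlpf = self._sinusoid_tracks()
        out = locate_primary_fiducials(lpf, dlpf, 250)
        assert out is not None
        foot, up, peak = out
        assert foot.t == pytest.approx(0.0, abs=1e-3)
        assert up.t == pytest.approx(0.25, abs=1e-3)
        assert peak.t == pytest.approx(0.5, abs=1e-3)
        assert foot.a == pytest.approx(-1.0, abs=1e-3)
        assert peak.a == pytest.approx(1.0, abs=1e-3)

    def test_monotone_tail_rejects_beat(self):
        fs = 100.0
        d = np.linspace(0.1, 1.0, 200)  # derivative always positive: no peak
        lpf = Track("p", fs, np.cumsum(d) / fs)
        dlpf = Track("dp", fs, d)
        assert locate_primary_fiducials(lpf, dlpf, 100) is None

    def test_generator_truth_recovered(self, clean_ppg):
        det = detect_ppg_fiducials(clean_ppg.track)
        for name in ("foot", "peak"):
            m = match_events(det[name].timestamps, clean_ppg.truth[name], 0.010)
            assert m.fn == 0


class TestSecondaryFiducials:
    def test_single_gaussian_all_nan(self):
        sim = gen_ppg(PpgSimSpec(hr=60, duration=30, notch_depth=0.0, seed=2))
        det = detect_ppg_fiducials(sim.track)
        assert len(det["shoulder"]) == 0
        assert len(det["secondary_peak"]) == 0
        assert len(det["dicrotic_notch"]) == 0

    def test_notch_recovered_within_15ms(self, clean_ppg):
        det = detect_ppg_fiducials(clean_ppg.track)
        for name in ("dicrotic_notch", "secondary_peak"):
            truth = clean_ppg.truth[name]
            m = match_events(det[name].timestamps, truth, 0.015)
            assert m.tp >= len(truth) - 1

    def test_notch_outside_window_is_nan(self, clean_ppg):
        # shrink the proportional search windows so the notch falls outside
        params = PpgParams(dn_time_window=0.1, sp_time_window=0.1)
        det = detect_ppg_fiducials(clean_ppg.track, params)
        assert len(det["dicrotic_notch"]) == 0
        assert len(det["secondary_peak"]) == 0
        assert len(det["peak"]) > 0  # primaries unaffected


class TestBeatFeatures:
    def test_direct_subtraction(self):
        beat = BeatFiducials(Fiducial(1.0, 0.0), Fiducial(1.1, 1.0),
                             Fiducial(1.3, 2.0))
        feats = beat_features(beat, next_foot_t=2.0)
        assert feats["rise_time"] == pytest.approx(0.3)
        assert feats["foot_peak_amplitude"] == pytest.approx(2.0)
        assert feats["decay_time"] == pytest.approx(0.7)

    def test_last_beat_decay_nan(self):
        beat = BeatFiducials(Fiducial(1.0, 0.0), Fiducial(1.1, 1.0),
                             Fiducial(1.3, 2.0))
        assert math.isnan(beat_features(beat)["decay_time"])

    def test_fixed_morphology_rise_times_equal(self, clean_ppg):
        det = detect_ppg_fiducials(clean_ppg.track)
        rises = (np.asarray(det["peak"].timestamps)
                 - np.asarray(det["foot"].timestamps))
        # first beat's foot is shaped by the record's lead-in decay; the
        # steady-state beats share one morphology
        assert np.ptp(rises[1:]) <= 1.0 / clean_ppg.track.fs


class TestDetectPipeline:
    def test_equal_primary_counts_and_ordering(self, clean_ppg):
        det = detect_ppg_fiducials(clean_ppg.track)
        nf, nu, np_ = (len(det[k]) for k in ("foot", "upstroke", "peak"))
        assert nf == nu == np_ > 0
        for f, u, p in zip(det["foot"].timestamps, det["upstroke"].timestamps,
                           det["peak"].timestamps):
            assert f < u < p
        for k in ("shoulder", "secondary_peak", "dicrotic_notch"):
            assert len(det[k]) <= nf

    def test_derivative_near_zero_at_foot_and_peak(self, clean_ppg):
        _, dlpf = preprocess_ppg(clean_ppg.track)
        det = detect_ppg_fiducials(clean_ppg.track)
        scale = np.max(np.abs(dlpf.values))
        for name in ("foot", "peak"):
            for t in det[name].timestamps:
                assert abs(dlpf.value_at(t)) < 0.02 * scale

    def test_flat_signal_empty(self):
        det = detect_ppg_fiducials(Track("p", 125.0, np.zeros(1000)))
        assert all(len(s) == 0 for s in det.values())

    def test_dc_and_scale_invariance(self, clean_ppg):
        tr = clean_ppg.track
        shifted = Track("p", tr.fs, 3.7 * tr.values + 11.0)
        d1 = detect_ppg_fiducials(tr)
        d2 = detect_ppg_fiducials(shifted)
        for name in ("foot", "upstroke", "peak"):
            np.testing.assert_allclose(d1[name].timestamps, d2[name].timestamps,
                                       atol=1e-9)

    def test_upstroke_beats_peak_precision_under_drift(self):
        # steep-edge fiducials resist baseline wander better than the flat
        # systolic maximum; white noise alone would favour the peak
        ue, pe = [], []
        for seed in range(50):
            sim = gen_ppg(PpgSimSpec(hr=70, duration=30, seed=seed, hrv_sd=0.02))
            noisy = add_noise(sim.track, white_snr_db=25, wander_amp=0.3,
                              wander_hz=0.4, seed=seed + 500)
            det = detect_ppg_fiducials(noisy)
            for name, acc in (("upstroke", ue), ("peak", pe)):
                m = match_events(det[name].timestamps, sim.truth[name], 0.05)
                acc.extend(abs(r - d) for r, d in m.pairs)
        assert np.mean(ue) <= np.mean(pe)
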