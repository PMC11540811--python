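"""Per-pulse amplitudes and areas: analytic cases, integration oracle, identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulseflux import (
    DataError,
    DegeneratePulseError,
    ParameterError,
    PulseBoundary,
    PulsePair,
    Recording,
    detect_pulses,
    extract_features,
    ldf_total,
    pair_pulses,
    pulsatile_flux,
    pulse_amplitude,
)


def _riemann_10x(samples, fs):
    """Left Riemann sum on a 10x-oversampled linear interpolation (oracle)."""
    n = len(samples)
    fine = np.interp(np.linspace(0, n - 1, 10 * (n - 1) + 1), np.arange(n), samples)
    dx = 1.0 / (10.0 * fs)
    return float(np.sum(fine[:-1]) * dx)


class TestAmplitude:
    def test_constant_pulse_has_zero_amplitude(self):
        assert pulse_amplitude(np.full(50, 3.0)) == 0.0

    def test_half_sine_peak_one(self):
        u = np.linspace(0, 1, 1001)
        assert pulse_amplitude(np.sin(np.pi * u)) == pytest.approx(1.0, rel=1e-6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(DegeneratePulseError):
            pulse_amplitude(np.array([1.0, 2.0]))


class TestAreas:
    def test_rectangle(self):
        # constant 2.0 units over exactly 1.0 s
        fs = 100.0
        assert ldf_total(np.full(101, 2.0), fs) == pytest.approx(2.0)
        assert pulsatile_flux(np.full(101, 2.0), fs) == pytest.approx(0.0)

    def test_triangle_0_1_0(self):
        fs = 100.0
        tri = np.concatenate([np.linspace(0, 1, 51), np.linspace(1, 0, 51)[1:]])
        assert ldf_total(tri, fs) == pytest.approx(0.5, rel=1e-9)

    def test_triangle_1_3_1(self):
        fs = 100.0
        tri = 1.0 + 2.0 * np.concatenate(
            [np.linspace(0, 1, 51), np.linspace(1, 0, 51)[1:]]
        )
        assert ldf_total(tri, fs) == pytest.approx(2.0, rel=1e-9)
        assert pulsatile_flux(tri, fs) == pytest.approx(1.0, rel=1e-9)

    def test_all_negative_window_rejected(self):
        with pytest.raises(DataError):
            ldf_total(-np.ones(50), 100.0)

    def test_negative_samples_clipped(self):
        x = np.full(101, 1.0)
        x[50] = -5.0  # clipped to 0: two triangles notch out 1/100 units*s
        assert ldf_total(x, 100.0) == pytest.approx(1.0 - 0.01, rel=1e-9)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_trapezoid_matches_riemann_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 300))
        fs = float(rng.uniform(50, 500))
        x = rng.uniform(0.0, 3.0, size=n)
        assert ldf_total(x, fs) == pytest.approx(_riemann_10x(x, fs), rel=0.005)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pf_identity_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.0, 5.0, size=int(rng.integers(3, 300)))
        fs = 100.0
        tot = ldf_total(x, fs)
        pf = pulsatile_flux(x, fs)
        duration = (len(x) - 1) / fs
        assert 0.0 <= pf <= tot + 1e-12
        assert pf + x.min() * duration == pytest.approx(tot, abs=1e-12)


def _segment_pairs(rec):
    ppg_b = detect_pulses(rec.ppg, rec.fs, channel="PPG")
    ldf_b = detect_pulses(rec.ldf, rec.fs, channel="LDF")
    return pair_pulses(ppg_b, ldf_b, rec.fs)


class TestExtract:
    def test_matches_ground_truth_without_noise(self, clean_recording):
        cfg, rec, truth = clean_recording
        ext = extract_features(_segment_pairs(rec), rec)
        assert ext.n_skipped == 0
        det_on = np.array([r.onset_s for r in ext.rows])
        checked = 0
        for k in range(1, len(truth) - 1):
            j = int(np.argmin(np.abs(det_on - truth.onset_s[k])))
            if abs(det_on[j] - truth.onset_s[k]) > 0.02:
                continue
            row = ext.rows[j]
            assert row.PA_PPG == pytest.approx(truth.pa_ppg[k], rel=0.01)
            assert row.PA_LDF == pytest.approx(truth.pa_ldf[k], rel=0.01)
            assert row.LDF_TOT == pytest.approx(truth.ldf_tot[k], rel=0.01)
            assert row.PF == pytest.approx(truth.pf[k], rel=0.01)
            assert row.T_LDF == pytest.approx(truth.t_ldf[k], rel=0.01)
            checked += 1
        assert checked >= len(truth) - 4

    def test_ppg_offset_invariance_and_ldf_offset_equivariance(self, clean_recording):
        cfg, rec, _ = clean_recording
        pairs = _segment_pairs(rec)
        base = extract_features(pairs, rec)
        shifted = rec.copy(ppg=rec.ppg + 7.0, ldf=rec.ldf + 3.0)
        # same boundaries apply: adding constants moves no extremum
        moved = extract_features(pairs, shifted)
        for a, b in zip(base.rows, moved.rows):
            assert b.PA_PPG == pytest.approx(a.PA_PPG, abs=1e-9)
            assert b.PA_LDF == pytest.approx(a.PA_LDF, abs=1e-9)
            assert b.PF == pytest.approx(a.PF, abs=1e-9)
            assert b.LDF_TOT == pytest.approx(a.LDF_TOT + 3.0 * a.T_LDF, rel=1e-9)

    def test_degenerate_pulse_skipped_with_diagnostic(self, clean_recording):
        cfg, rec, _ = clean_recording
        pairs = list(_segment_pairs(rec))[:30]
        o = pairs[-1].ppg.end_idx
        tiny = PulsePair(
            ppg=PulseBoundary("PPG", o, o + 1, o + 2),
            ldf=PulseBoundary("LDF", o, o + 1, o + 2),
            lag_s=0.0,
        )
        ext = extract_features(pairs + [tiny], rec)
        assert len(ext.rows) == 30
        assert ext.n_skipped == 1

    def test_empty_pairs_rejected(self, clean_recording):
        _, rec, _ = clean_recording
        with pytest.raises(ParameterError):
            extract_features([], rec)

    def test_row_invariants_under_noise(self, noisy_recording):
        cfg, rec, _ = noisy_recording
        ext = extract_features(_segment_pairs(rec), rec)
        assert len(ext.rows) > 30
        for row in ext.rows:
            assert row.PA_PPG >= 0 and row.PA_LDF >= 0
            assert 0.0 <= row.PF <= row.LDF_TOT + 1e-12
            assert row.T_LDF > 0
            assert row.ldf_mean_in_pulse == pytest.approx(
                row.LDF_TOT / row.T_LDF, rel=1e-12
            )
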