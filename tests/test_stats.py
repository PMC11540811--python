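"""Regression inference, pulsatility index, summaries, demographics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulseflux import (
    DataError,
    DegenerateRegressorError,
    ValidationError,
    load_demographics,
    pooled_regress,
    pulsatility_index,
    regress,
    subject_summary,
    summarize_demographics,
)
from pulseflux.stats import _ols


def frame(x, y, feature="PA_LDF"):
    n = len(x)
    return pd.DataFrame(
        {
            "onset_s": np.arange(n, dtype=float),
            "PA_PPG": np.asarray(x, dtype=float),
            "PA_LDF": np.asarray(y, dtype=float),
            "LDF_TOT": np.asarray(y, dtype=float),
            "PF": np.asarray(y, dtype=float),
            "T_LDF": np.ones(n),
            "ldf_mean_in_pulse": np.ones(n),
        }
    )


def ols_oracle(x, y):
    """Explicit summation OLS + Pearson + t-based 95% CIs (independent route)."""
    import scipy.stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    r = sxy / math.sqrt(sxx * syy)
    resid = y - intercept - slope * x
    s2 = np.sum(resid**2) / (n - 2)
    se_slope = math.sqrt(s2 / sxx)
    se_intercept = math.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
    t = r * math.sqrt((n - 2) / (1 - r**2)) if abs(r) < 1 else math.inf
    p = 2 * scipy.stats.t.sf(abs(t), n - 2)
    tc = scipy.stats.t.ppf(0.975, n - 2)
    return dict(
        slope=slope, intercept=intercept, r=r, p=p,
        slope_ci=(slope - tc * se_slope, slope + tc * se_slope),
        intercept_ci=(intercept - tc * se_intercept, intercept + tc * se_intercept),
    )


class TestRegress:
    def test_perfect_line(self):
        x = np.arange(1.0, 11.0)
        res = regress(frame(x, 2 * x), "PA_LDF")
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p < 1e-12

    def test_four_point_pearson_hand_value(self):
        res = regress(frame([1, 2, 3, 4], [1, 3, 2, 4]), "PA_LDF")
        assert res.r == pytest.approx(0.8, abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        x = rng.normal(1.0, 0.3, n)
        y = 0.2 + 0.5 * x + rng.normal(0, 0.2, n)
        res = regress(frame(x, y), "PA_LDF")
        ref = ols_oracle(x, y)
        assert res.slope == pytest.approx(ref["slope"], abs=1e-10)
        assert res.intercept == pytest.approx(ref["intercept"], abs=1e-10)
        assert res.r == pytest.approx(ref["r"], abs=1e-10)
        assert res.p == pytest.approx(ref["p"], abs=1e-10)
        assert res.slope_ci_low == pytest.approx(ref["slope_ci"][0], abs=1e-10)
        assert res.slope_ci_high == pytest.approx(ref["slope_ci"][1], abs=1e-10)
        assert res.intercept_ci_low == pytest.approx(ref["intercept_ci"][0], abs=1e-10)
        assert res.intercept_ci_high == pytest.approx(
            ref["intercept_ci"][1], abs=1e-10
        )
        assert -1 <= res.r <= 1 and 0 <= res.p <= 1
        assert res.slope_ci_low <= res.slope <= res.slope_ci_high

    def test_type_i_error_rate_near_nominal(self):
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(size=30)
            y = rng.normal(size=30)  # independent of x
            if regress(frame(x, y), "PA_LDF").p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_duplication_keeps_estimates_shrinks_ci(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=15)
        y = 1 + 0.5 * x + rng.normal(0, 0.3, 15)
        one = regress(frame(x, y), "PA_LDF")
        two = regress(frame(np.tile(x, 2), np.tile(y, 2)), "PA_LDF")
        assert two.slope == pytest.approx(one.slope, abs=1e-12)
        assert two.r == pytest.approx(one.r, abs=1e-12)
        assert (two.slope_ci_high - two.slope_ci_low) < (
            one.slope_ci_high - one.slope_ci_low
        )

    def test_zero_variance_regressor_rejected(self):
        with pytest.raises(DegenerateRegressorError):
            regress(frame(np.ones(10), np.arange(10.0)), "PA_LDF")


class TestPooled:
    def test_identical_subjects_match_single_subject(self):
        rng = np.random.default_rng(3)
        x = rng.normal(1, 0.2, 30)
        y = 0.2 + 0.1 * x + rng.normal(0, 0.02, 30)
        single = regress(frame(x, y), "PA_LDF")
        double = pooled_regress([frame(x, y), frame(x, y)], "PA_LDF")
        assert double.n == 60
        assert double.slope == pytest.approx(single.slope, abs=1e-12)
        assert double.r == pytest.approx(single.r, abs=1e-12)

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(4)
        frames = [
            frame(rng.normal(1, 0.2, 20), rng.normal(0.3, 0.05, 20)) for _ in range(3)
        ]
        a = pooled_regress(frames, "PA_LDF")
        b = pooled_regress(frames[::-1], "PA_LDF")
        assert a.slope == pytest.approx(b.slope, abs=1e-12)
        assert a.r == pytest.approx(b.r, abs=1e-12)


class TestPLI:
    def test_square_wave_analytic(self):
        ldf = np.tile([1.0, 3.0], 500)  # equal dwell: mean 2
        res = pulsatility_index(frame([1, 2, 3], [2.0, 2.0, 2.0]), ldf)
        assert res.mean_ldf == pytest.approx(2.0)
        assert res.mean == pytest.approx(1.0)

    def test_constant_ldf_gives_zero_pli(self):
        res = pulsatility_index(frame([1, 2, 3], [0.0, 0.0, 0.0]), np.full(100, 2.0))
        assert res.mean == 0.0

    def test_scale_invariance(self):
        rows = frame([1, 2, 3], [0.5, 0.6, 0.7])
        ldf = np.linspace(1, 3, 200)
        k = 7.3
        a = pulsatility_index(rows, ldf)
        scaled_rows = frame([1, 2, 3], [0.5 * k, 0.6 * k, 0.7 * k])
        b = pulsatility_index(scaled_rows, ldf * k)
        assert b.mean == pytest.approx(a.mean, rel=1e-12)

    def test_pf_variant(self):
        rows = frame([1, 2, 3], [2.0, 2.0, 2.0])
        res = pulsatility_index(rows, np.full(10, 2.0), numerator="PF")
        assert res.numerator == "PF"
        assert res.mean == pytest.approx(1.0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(DataError):
            pulsatility_index(frame([1, 2, 3], [1, 1, 1]), np.zeros(10))


class TestSubjectSummary:
    def _analyzed(self, recording_fixture):
        from pulseflux import (
            detect_pulses,
            extract_features,
            find_qualifying_window,
            pair_pulses,
        )

        cfg, rec, _ = recording_fixture
        ppg_b = detect_pulses(rec.ppg, rec.fs, channel="PPG")
        ldf_b = detect_pulses(rec.ldf, rec.fs, channel="LDF")
        ext = extract_features(pair_pulses(ppg_b, ldf_b, rec.fs), rec)
        return rec, ext.rows

    def test_window_covering_whole_recording_equalizes_means(self, noisy_recording):
        rec, rows = self._analyzed(noisy_recording)
        window = __import__("pulseflux").find_qualifying_window(
            rows, window_len=len(rows), min_count=1
        )
        assert window.qualified
        s = subject_summary(rec, window)
        assert s.LDF_30_PULSE == pytest.approx(s.LDF_30_MINUTE, rel=0.01)

    def test_stationary_recording_window_mean_tracks_overall(self, noisy_recording):
        rec, rows = self._analyzed(noisy_recording)
        window = __import__("pulseflux").find_qualifying_window(rows)
        assert window.qualified
        s = subject_summary(rec, window)
        assert s.LDF_30_PULSE == pytest.approx(s.LDF_30_MINUTE, rel=0.02)
        assert s.mean_PLI > 0
        assert set(s.regressions) == {"PA_LDF", "LDF_TOT", "PF"}


class TestDemographics:
    def test_packaged_cohort_summary(self):
        summary = summarize_demographics(load_demographics())
        assert summary.n == 10
        assert round(summary.mean["age"], 1) == 26.0
        assert round(summary.sd["age"], 1) == 1.3
        assert round(summary.mean["bmi"], 1) == 23.2
        assert round(summary.sd["bmi"], 1) == 2.7
        assert summary.n_bmi_over_25 == 4
        assert summary.n_systolic_ge_120 == 4

    def test_single_row_has_undefined_sd(self):
        rows = load_demographics()[:1]
        summary = summarize_demographics(rows)
        assert summary.sd["age"] is None
        assert summary.mean["age"] == 28.0

    def test_missing_field_names_subject_and_field(self, tmp_path):
        path = tmp_path / "demo.csv"
        path.write_text(
            "subject_id,sex,age,height,weight,bmi,systolic_bp,diastolic_bp,heart_rate\n"
            "3,M,26,,64.7,24.9,104,60,69\n"
        )
        with pytest.raises(ValidationError, match=r"subject 3.*height"):
            load_demographics(path)

    def test_inconsistent_bmi_rejected_when_strict(self, tmp_path):
        df = pd.DataFrame(
            [
                {
                    "subject_id": 1, "sex": "M", "age": 30, "height": 1.80,
                    "weight": 80.0, "bmi": 30.0, "systolic_bp": 120,
                    "diastolic_bp": 70, "heart_rate": 60,
                }
            ]
        )
        path = tmp_path / "demo.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="bmi"):
            load_demographics(path)  # 80/1.8^2 = 24.7, far from 30
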