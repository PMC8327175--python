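"""Repeated-measures correlation, Bland-Altman and regression agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ventdp import (
    CohortSpec,
    agreement_report,
    bland_altman,
    linreg_r2,
    make_cohort,
    rmcorr,
    simulate_repeated_measures,
)
from ventdp.model import DrivingPressureRegressor, FEATURES


class TestRmcorr:
    def test_common_slope_with_subject_offsets_gives_unity(self):
        rows = []
        for s, offset in enumerate([0.0, 5.0, -3.0]):
            for x in (1.0, 2.0, 3.0):
                rows.append((f"s{s}", x, 2.0 * x + offset))
        df = pd.DataFrame(rows, columns=["s", "x", "y"])
        res = rmcorr(df.s, df.x, df.y)
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0
        assert res.df == 9 - 3 - 1

    def test_matches_independent_reference_implementation(self, rng):
        df = simulate_repeated_measures(30, 4, -0.4, seed=99)
        ours = rmcorr(df.subject, df.x, df.y)
        pg = pytest.importorskip("pingouin")
        ref = pg.rm_corr(data=df, x="x", y="y", subject="subject")
        assert ours.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert ours.df == int(ref["dof"].iloc[0])
        assert ours.p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-8)

    def test_recovers_generating_within_subject_correlation(self):
        df = simulate_repeated_measures(200, 3, -0.68, seed=0)
        res = rmcorr(df.subject, df.x, df.y)
        assert res.r == pytest.approx(-0.68, abs=0.05)
        assert res.p < 0.001

    def test_sign_follows_slope_under_axis_flip(self):
        df = simulate_repeated_measures(50, 3, 0.6, seed=2)
        r_pos = rmcorr(df.subject, df.x, df.y).r
        r_neg = rmcorr(df.subject, -df.x, df.y).r
        assert r_neg == pytest.approx(-r_pos, abs=1e-12)

    def test_affine_rescaling_invariance(self):
        df = simulate_repeated_measures(50, 3, 0.6, seed=3)
        a = rmcorr(df.subject, df.x, df.y).r
        b = rmcorr(df.subject, 3.5 * df.x + 100.0, 0.2 * df.y - 7.0).r
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_pair_subjects_excluded_with_warning(self):
        df = simulate_repeated_measures(5, 3, 0.5, seed=4)
        df.loc[df.subject == "S0001", "y"] = [np.nan, np.nan, df.y.iloc[2]]
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = rmcorr(df.subject, df.x, df.y)
        assert res.n_subjects == 4

    def test_fewer_than_two_subjects_is_error(self):
        df = simulate_repeated_measures(2, 3, 0.5, seed=5)
        df = df[df.subject == "S0001"]
        with pytest.raises(ValueError, match="2 subjects"):
            rmcorr(df.subject, df.x, df.y)


class TestBlandAltman:
    def test_identical_methods_have_zero_bias_and_loa(self):
        a = np.arange(10.0)
        res = bland_altman(a, a)
        assert res.bias == 0.0 and res.loa_low == 0.0 and res.loa_high == 0.0

    def test_symmetric_differences_give_cohort_scale_loa(self):
        # d alternating +-1.2 over 60 pairs: bias 0, sd = 1.2*sqrt(60/59)
        b = np.zeros(60)
        a = np.tile([-1.2, 1.2], 30)
        res = bland_altman(a, b)
        sd = 1.2 * np.sqrt(60 / 59)
        assert res.bias == pytest.approx(0.0, abs=1e-12)
        assert res.sd_diff == pytest.approx(sd, abs=1e-12)
        assert res.loa_high == pytest.approx(2.4, abs=0.05)
        assert res.loa_low == pytest.approx(-2.4, abs=0.05)

    def test_loa_multiplier_configurable(self):
        a, b = np.array([0.0, 2.0, 4.0]), np.zeros(3)
        assert bland_altman(a, b, multiplier=1.96).loa_high == pytest.approx(2.0 + 1.96 * 2.0)

    @given(
        d=st.lists(st.floats(-10, 10), min_size=2, max_size=40),
        c=st.floats(-5, 5),
    )
    @settings(max_examples=60, deadline=None)
    def test_translation_and_antisymmetry(self, d, c):
        """Shifting one method shifts the bias only; swapping flips its sign."""
        a = np.asarray(d)
        b = np.zeros_like(a)
        base = bland_altman(a, b)
        shifted = bland_altman(a + c, b)
        assert shifted.bias == pytest.approx(base.bias + c, abs=1e-9)
        assert shifted.sd_diff == pytest.approx(base.sd_diff, abs=1e-9)
        swapped = bland_altman(b, a)
        assert swapped.bias == pytest.approx(-base.bias, abs=1e-9)
        assert swapped.sd_diff == pytest.approx(base.sd_diff, abs=1e-9)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="2"):
            bland_altman([1.0], [2.0])


class TestLinreg:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept, r2, p = linreg_r2(x, 2 * x + 1)
        assert slope == pytest.approx(2.0) and intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_independent_noise_has_negligible_r2(self, rng):
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        _, _, r2, p = linreg_r2(x, y)
        assert r2 < 0.02

    def test_r2_symmetric_in_x_and_y(self, rng):
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        assert linreg_r2(x, y)[2] == pytest.approx(linreg_r2(y, x)[2], abs=1e-12)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            linreg_r2(np.ones(5), np.arange(5.0))


class TestAgreementReport:
    def _analyzed_cohort(self, noise, seed, n_patients=20):
        cohort = make_cohort(
            CohortSpec(n_patients=n_patients, dpl_noise_sd=noise, seed=seed)
        )
        model = DrivingPressureRegressor.published()
        cohort["dpl_eit"] = model.predict(cohort[list(FEATURES)])
        cohort["el_eit"] = cohort["dpl_eit"] / (cohort["tv_ml"] / 1000.0)
        cohort["pi_eit"] = cohort["pplat"] * cohort["el_eit"] / cohort["ers"]
        return cohort

    def test_perfect_prediction_gives_unit_r2_zero_bias(self):
        cohort = self._analyzed_cohort(noise=0.0, seed=6)
        report = agreement_report(cohort)
        for key in ("dpl", "el", "pi"):
            assert report[key]["regression"]["r2"] == pytest.approx(1.0, abs=1e-9)
            assert report[key]["bland_altman"]["bias"] == pytest.approx(0.0, abs=1e-9)

    def test_loa_half_width_tracks_injected_noise(self):
        # measured = equation + N(0, 1.2); prediction = equation
        # -> LoA half-width ~ 2 * 1.2 = 2.4 cmH2O
        cohort = self._analyzed_cohort(noise=1.2, seed=7, n_patients=100)
        report = agreement_report(cohort)
        half = (report["dpl"]["bland_altman"]["loa_high"] - report["dpl"]["bland_altman"]["loa_low"]) / 2
        assert half == pytest.approx(2.4, rel=0.10)

    def test_report_schema_complete_and_finite(self):
        report = agreement_report(self._analyzed_cohort(noise=1.0, seed=8))
        assert report["n_rows"] == 60 and report["n_subjects"] == 20
        for key in ("dpl", "el", "pi"):
            for block in ("regression", "bland_altman", "rmcorr"):
                assert all(np.isfinite(v) for v in report[key][block].values())

    def test_quality_flag_excludes_rows(self):
        cohort = self._analyzed_cohort(noise=1.0, seed=9)
        cohort.loc[cohort.index[0], "quality_ok"] = False
        report = agreement_report(cohort)
        assert report["n_rows"] == 59
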