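"""Nested random-intercept LMM: oracles, back-transforms, LRT, ICC."""
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cd8pet.mixedmodel import (LmmFit, LmmSpec, compute_icc, fit_lmm, lrt,
                               percent_effect, treatment_change_model)
from cd8pet.petquant import summarize_uptake


def balanced_oneway(g=12, m=5, sd_u=0.7, sd_e=0.4, seed=0):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sd_u, g)
    y = (u[:, None] + rng.normal(0, sd_e, (g, m))).ravel()
    return pd.DataFrame({"patient_id": np.repeat(np.arange(g), m), "y": y})


def nested_cohort(n_pat=20, n_les=5, n_scan=2, s2p=0.19, s2l=0.22, s2e=0.01,
                  seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_pat):
        up = rng.normal(0, math.sqrt(s2p))
        for l in range(n_les):
            vl = rng.normal(0, math.sqrt(s2l))
            for _ in range(n_scan):
                rows.append({"patient_id": p, "lesion_id": f"{p}-{l}",
                             "y": 1.7 + up + vl + rng.normal(0, math.sqrt(s2e))})
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_balanced_reml_equals_anova_method_of_moments(self):
        df = balanced_oneway()
        g, m = 12, 5
        fit = fit_lmm(df, LmmSpec(response="y", fixed="1", random="patient"))
        y = df["y"].to_numpy().reshape(g, m)
        ybar = y.mean(axis=1)
        msb = m * np.sum((ybar - y.mean()) ** 2) / (g - 1)
        msw = np.sum((y - ybar[:, None]) ** 2) / (g * (m - 1))
        assert fit.sigma2_resid == pytest.approx(msw, abs=1e-8)
        assert fit.sigma2_patient == pytest.approx((msb - msw) / m, abs=1e-8)

    def test_matches_statsmodels_mixedlm_on_nested_data(self):
        sm = pytest.importorskip("statsmodels.api")
        df = nested_cohort(n_pat=15, n_les=4, seed=3)
        fit = fit_lmm(df, LmmSpec(response="y", fixed="1",
                                  random="patient+lesion"))
        md = sm.MixedLM.from_formula(
            "y ~ 1", groups="patient_id", re_formula="1",
            vc_formula={"lesion": "0 + C(lesion_id)"}, data=df)
        mf = md.fit(reml=True)
        assert fit.sigma2_patient == pytest.approx(mf.cov_re.iloc[0, 0], rel=1e-3, abs=1e-6)
        assert fit.sigma2_lesion == pytest.approx(float(mf.vcomp[0]), rel=1e-3, abs=1e-6)
        assert fit.sigma2_resid == pytest.approx(mf.scale, rel=1e-3, abs=1e-6)
        assert fit.loglik == pytest.approx(mf.llf, abs=1e-5)

    def test_zero_noise_beta_equals_ols(self):
        df = pd.DataFrame({"patient_id": np.repeat(np.arange(6), 4),
                           "x": np.tile([0.0, 1, 2, 3], 6)})
        df["y"] = 2.0 + 0.5 * df["x"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lmm(df, LmmSpec(response="y", fixed="1 + x"))
        assert fit.beta == pytest.approx([2.0, 0.5], abs=1e-10)

    def test_component_recovery_on_nested_simulations(self):
        ests = np.array([
            [f.sigma2_patient, f.sigma2_lesion, f.sigma2_resid]
            for f in (fit_lmm(nested_cohort(n_pat=38, n_les=7, seed=s),
                              LmmSpec(response="y", fixed="1",
                                      random="patient+lesion"))
                      for s in range(60))
        ])
        mean = ests.mean(axis=0)
        assert mean == pytest.approx([0.19, 0.22, 0.01], rel=0.10)

    def test_intercept_backtransform_matches_geometric_mean(self):
        vals = np.array([2.0, 3.5, 5.0, 8.0, 1.5, 6.0])
        df = pd.DataFrame({"patient_id": np.repeat([0, 1], 3),
                           "y": np.log(vals)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lmm(df, LmmSpec(response="y", fixed="1", random="patient"))
        gm = summarize_uptake(vals).geometric_mean
        assert math.exp(fit.beta[0]) == pytest.approx(gm, rel=1e-9)

    def test_satterthwaite_df_on_balanced_design(self):
        # intercept-only, strong patient effect: df for the intercept ~ g - 1
        df = balanced_oneway(g=10, m=4, sd_u=1.0, sd_e=0.1, seed=2)
        fit = fit_lmm(df, LmmSpec(response="y", fixed="1", random="patient"))
        df_icpt = fit.satterthwaite_df(np.array([1.0]))
        assert df_icpt == pytest.approx(9.0, rel=0.15)

    def test_design_errors(self):
        df = balanced_oneway()
        df["x2"] = 1.0  # collinear with the intercept
        with pytest.raises(ValueError, match="rank deficient"):
            fit_lmm(df, LmmSpec(response="y", fixed="1 + x2"))
        solo = df[df.patient_id == 0]
        with pytest.raises(ValueError, match="2 patients"):
            fit_lmm(solo, LmmSpec(response="y", fixed="1"))
        df["lesion_id"] = np.arange(len(df))  # one scan per lesion
        with pytest.raises(ValueError, match="repeated scans"):
            fit_lmm(df, LmmSpec(response="y", fixed="1", random="patient+lesion"))


class TestPercentEffect:
    def _fit(self):
        return fit_lmm(balanced_oneway(seed=5),
                       LmmSpec(response="y", fixed="1", random="patient"))

    def test_backtransform_identities(self):
        fit = self._fit()
        fit.beta = np.array([math.log(1.62)])
        pct, _, _ = percent_effect(fit, [1.0])
        assert pct == pytest.approx(62.0, abs=1e-9)
        fit.beta = np.array([-0.04718])
        pct, _, _ = percent_effect(fit, [1.0])
        assert pct == pytest.approx(-4.61, abs=0.005)
        fit.beta = np.array([0.0])
        assert percent_effect(fit, [1.0])[0] == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(-0.9, 2.0))
    def test_reciprocal_symmetry(self, b):
        fit = self._fit()
        fit.beta = np.array([b])
        p_fwd, _, _ = percent_effect(fit, [1.0])
        p_rev, _, _ = percent_effect(fit, [-1.0])
        assert p_rev == pytest.approx(100.0 * (1.0 / (1.0 + p_fwd / 100.0) - 1.0),
                                      rel=1e-9, abs=1e-9)

    def test_nonconformable_contrast(self):
        with pytest.raises(ValueError):
            self._fit().contrast([1.0, 0.0])


class TestLrt:
    def test_identical_models_give_zero_statistic(self):
        df = balanced_oneway(seed=6)
        df["g"] = np.tile([0, 1], len(df) // 2)
        full = fit_lmm(df, LmmSpec(response="y", fixed="1 + g", method="ml"))
        stat, dof, p = lrt(full, full)
        assert stat == pytest.approx(0.0, abs=1e-10) and p == 1.0
        # strong factor
        df["y"] = df["y"] + 3.0 * df["g"]
        full2 = fit_lmm(df, LmmSpec(response="y", fixed="1 + g", method="ml"))
        red2 = fit_lmm(df, LmmSpec(response="y", fixed="1", method="ml"))
        assert lrt(full2, red2)[2] < 1e-6

    def test_reml_fits_rejected(self):
        df = balanced_oneway(seed=7)
        df["g"] = np.tile([0, 1], len(df) // 2)
        full = fit_lmm(df, LmmSpec(response="y", fixed="1 + g"))
        red = fit_lmm(df, LmmSpec(response="y", fixed="1"))
        with pytest.raises(ValueError, match="ML"):
            lrt(full, red)

    def test_null_factor_type_one_error_calibrated(self):
        rejections = 0
        n_sims = 200
        for s in range(n_sims):
            df = balanced_oneway(g=15, m=4, seed=100 + s)
            rng = np.random.default_rng(s)
            df["g"] = rng.integers(0, 2, len(df)).astype(float)
            full = fit_lmm(df, LmmSpec(response="y", fixed="1 + g", method="ml"))
            red = fit_lmm(df, LmmSpec(response="y", fixed="1", method="ml"))
            rejections += lrt(full, red)[2] < 0.05
        assert 0.02 <= rejections / n_sims <= 0.09


class TestIcc:
    def _fake_fit(self, s2p, s2l, s2e):
        return LmmFit(beta=np.array([0.0]), beta_names=("Intercept",),
                      vcov_beta=np.eye(1), sigma2_patient=s2p,
                      sigma2_lesion=s2l, sigma2_resid=s2e, loglik=0.0,
                      method="reml", n_obs=10, n_params=3,
                      spec=LmmSpec(response="y"), boundary=False)

    def test_equal_components_give_half(self):
        assert compute_icc(self._fake_fit(0.3, 0.0, 0.3)) == pytest.approx(0.5)

    def test_zero_patient_component_gives_zero(self):
        assert compute_icc(self._fake_fit(0.0, 0.1, 0.2)) == 0.0

    def test_all_zero_components_undefined(self):
        with pytest.raises(ValueError):
            compute_icc(self._fake_fit(0.0, 0.0, 0.0))


class TestTreatmentChange:
    def _table(self, slope, seed=0, n_pat=20):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_pat):
            bor = "PD" if p % 2 else "PR"
            up = rng.normal(0, 0.4)
            day = rng.uniform(28, 36)
            for l in range(4):
                vl = rng.normal(0, 0.4)
                base = 1.7 + up + vl
                for t in (0.0, day):
                    rows.append({"patient_id": p, "lesion_id": f"{p}-{l}",
                                 "timepoint": t, "bor": bor,
                                 "suv_max": math.exp(base + slope * t / 7
                                                     + rng.normal(0, 0.1))})
        return pd.DataFrame(rows)

    def test_projection_is_compounded_weekly_rate(self):
        rep = treatment_change_model(self._table(-0.05))
        rate = rep.percent_per_week / 100.0
        assert rep.projection_30d_percent == pytest.approx(
            100.0 * ((1.0 + rate) ** (30.0 / 7.0) - 1.0), rel=1e-12)

    def test_recovers_known_slope(self):
        rep = treatment_change_model(self._table(math.log(1 - 0.046), seed=3))
        assert rep.ci[0] <= -4.6 <= rep.ci[1]

    def test_requires_on_treatment_rows(self):
        df = self._table(-0.05)
        with pytest.raises(ValueError, match="on-treatment"):
            treatment_change_model(df[df.timepoint == 0])
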