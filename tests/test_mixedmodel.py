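import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pmexposure.design import (
    DesignError,
    build_design,
    emm_contrast,
    emm_table,
)
from pmexposure.mixedmodel import (
    RandomInterceptML,
    fit_model,
    indoor_slope,
    sensitivity_suite,
    variance_components_icc,
)
from pmexposure.reported import (
    reported_coefs,
    reported_emm_table,
)
from pmexposure.synthetic import simulate_design

warnings.filterwarnings("ignore")


@pytest.fixture(scope="module")
def cohort():
    df, truth = simulate_design(seed=100, n_participants=24, n_days=2, minute_step=10)
    return df, truth


class TestDesign:
    def test_column_count_and_names(self, cohort):
        df, _ = cohort
        d = build_design(df)
        assert d.names[0] == "intercept"
        assert "indoor" in d.names and "idw" in d.names and "indoor:idw" in d.names
        assert sum(n.startswith("landuse[") for n in d.names) == 7

    def test_rank_deficiency_names_aliased_columns(self, cohort):
        df, _ = cohort
        df = df.copy()
        df["season"] = np.where(df["sex"] == "male", "winter", "spring")
        with pytest.raises(DesignError, match="aliased"):
            build_design(df)

    def test_single_level_factor_rejected(self, cohort):
        df, _ = cohort
        df = df.copy()
        df["season"] = "spring"
        with pytest.raises(DesignError, match="season"):
            build_design(df)


class TestEngine:
    def test_matches_statsmodels_ml_likelihood_and_estimates(self, cohort):
        df, _ = cohort
        d = build_design(df)
        engine = RandomInterceptML(d.X, d.y, d.groups)
        efit = engine.fit()
        res = sm.MixedLM(d.y, d.X, groups=d.groups).fit(reml=False)
        assert efit["loglike"] == pytest.approx(res.llf, abs=0.1)
        assert np.abs(efit["beta"] - np.asarray(res.fe_params)).max() < 1e-3

    def test_profile_ci_brackets_the_estimate(self, cohort):
        df, _ = cohort
        d = build_design(df)
        engine = RandomInterceptML(d.X, d.y, d.groups)
        efit = engine.fit()
        j = d.names.index("indoor")
        lo, hi = engine.profile_ci(j, fit=efit)
        assert lo < efit["beta"][j] < hi
        assert np.isfinite(lo) and np.isfinite(hi)

    def test_profile_ci_close_to_wald_in_large_samples(self, cohort):
        df, _ = cohort
        d = build_design(df)
        engine = RandomInterceptML(d.X, d.y, d.groups)
        efit = engine.fit()
        j = d.names.index("idw")
        lo, hi = engine.profile_ci(j, fit=efit)
        wald = 1.959964 * efit["se"][j]
        assert (hi - lo) / 2 == pytest.approx(wald, rel=0.05)


class TestFitModel:
    def test_zero_noise_zero_re_recovers_truth_exactly(self):
        df, truth = simulate_design(seed=3, n_participants=12, n_days=1,
                                    minute_step=15, re_sd=0.0, resid_sd=0.0)
        # a perfectly deterministic response pins every coefficient
        # (demographics are all-null in truth and alias at this tiny n)
        d = build_design(df, demographics="none")
        beta, *_ = np.linalg.lstsq(d.X, d.y, rcond=None)
        expected = {n: truth.get(n, 0.0) for n in d.names}
        got = dict(zip(d.names, beta))
        for n in d.names:
            assert got[n] == pytest.approx(expected[n], abs=1e-8)

    def test_estimates_near_truth_at_default_noise(self, cohort):
        df, truth = cohort
        fit = fit_model(df, ci_coefs=None)
        assert fit.coefs["hour[16-19]"] == pytest.approx(truth["hour[16-19]"], abs=0.3)
        assert fit.coefs["idw"] == pytest.approx(truth["idw"], abs=0.06)

    def test_bh_family_excludes_intercept_and_orders(self, cohort):
        df, _ = cohort
        fit = fit_model(df, ci_coefs=None)
        assert "intercept" not in fit.p_bh
        for n, adj in fit.p_bh.items():
            assert adj >= fit.pvalues[n] - 1e-12


class TestIndoorSlope:
    def test_reported_coefficients_give_published_indoor_slope(self):
        assert indoor_slope(reported_coefs()) == pytest.approx(0.111, abs=1e-9)

    def test_zero_interaction_reduces_to_main_effect(self):
        assert indoor_slope({"idw": 0.3, "indoor:idw": 0.0}) == 0.3

    def test_missing_interaction_is_an_error(self):
        with pytest.raises(KeyError):
            indoor_slope({"idw": 0.3})

    def test_generator_round_trip_with_attenuated_indoor_slope(self):
        # outdoor slope 0.5, indoor slope 0.2 => interaction -0.3
        truth = {"intercept": 4.0, "idw": 0.5, "indoor:idw": -0.3}
        df, _ = simulate_design(seed=8, n_participants=30, n_days=2,
                                minute_step=10, true_coefs=truth, resid_sd=1.0)
        fit = fit_model(df, ci_coefs=None)
        assert indoor_slope(fit) == pytest.approx(0.2, abs=0.03)


class TestEMM:
    def test_balanced_one_factor_emms_equal_group_means(self):
        # balanced two-level factor, no other structure
        rng = np.random.default_rng(11)
        y = np.concatenate([rng.normal(5, 0.1, 500), rng.normal(9, 0.1, 500)])
        coefs = {"intercept": y[:500].mean(), "season[winter]": y[500:].mean() - y[:500].mean()}
        emms = emm_table(coefs, {"season": ("spring", "winter")}, idw_mean=0.0)
        by = emms.set_index("level")["emm"]
        assert by["spring"] == pytest.approx(y[:500].mean(), abs=1e-8)
        assert by["winter"] == pytest.approx(y[500:].mean(), abs=1e-8)

    def test_emm_differences_equal_coefficient_differences(self, cohort):
        df, _ = cohort
        fit = fit_model(df, ci_coefs=None)
        diff = emm_contrast(fit.emm, "landuse", "industrial", "office")
        expected = fit.coefs["landuse[industrial]"] - fit.coefs["landuse[office]"]
        assert diff == pytest.approx(expected, abs=1e-9)

    def test_reported_table_reproduces_published_contrasts(self):
        emms = reported_emm_table()
        assert emm_contrast(emms, "landuse", "industrial", "office") == pytest.approx(
            3.2, abs=0.05
        )
        assert emm_contrast(emms, "landuse", "residential", "office") == pytest.approx(
            3.0, abs=0.05
        )


class TestICC:
    def test_between_one_residual_four_gives_point_two(self):
        df, _ = simulate_design(seed=5, n_participants=40, n_days=1, minute_step=10,
                                true_coefs={"intercept": 5.0}, re_sd=1.0, resid_sd=2.0)
        icc, singular = variance_components_icc(df)
        assert not singular
        assert icc == pytest.approx(0.2, abs=0.07)

    def test_identical_participants_give_zero(self):
        df = pd.DataFrame({
            "studyid": np.repeat([f"P{i}" for i in range(10)], 50),
            "y": np.tile(np.random.default_rng(0).normal(5, 1, 50), 10),
        })
        icc, singular = variance_components_icc(df)
        assert icc == pytest.approx(0.0, abs=1e-6)

    def test_vanishing_residual_drives_icc_to_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "studyid": np.repeat([f"P{i}" for i in range(20)], 30),
            "y": np.repeat(rng.normal(5, 2, 20), 30)
            + rng.normal(0, 1e-3, 600),
        })
        icc, _ = variance_components_icc(df)
        assert icc > 0.999


@pytest.fixture(scope="module")
def suite():
    df, _ = simulate_design(seed=7, n_participants=30, n_days=1, minute_step=15)
    return sensitivity_suite(df, seed=42), df


class TestSensitivity:
    def test_spatiotemporal_coefficients_stable_under_true_demographic_null(
        self, suite
    ):
        out, _ = suite
        tab = out["nested"].set_index("coefficient")
        fit3 = out["nested_fits"]["model3"]
        for name in ("indoor", "idw", "indoor:idw", "hour[16-19]"):
            se = fit3.se[name]
            assert abs(tab.loc[name, "model1"] - tab.loc[name, "model3"]) < 2 * se

    def test_partition_is_seed_deterministic(self, suite):
        out, df = suite
        again = sensitivity_suite(df, seed=42)
        assert again["assignment"] == out["assignment"]

    def test_logo_ranges_are_finite_and_reported_per_coefficient(self, suite):
        out, _ = suite
        summary = out["logo_summary"]
        assert (summary["n_refits"] >= 8).all()
        assert np.isfinite(summary["range"]).all()
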