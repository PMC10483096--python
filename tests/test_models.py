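"""Design construction, parameter counting, and Gaussian GLM fitting."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from hoiscan import (
    GrowthRateModel,
    SimParams,
    build_design,
    count_parameters,
    fit_all_models,
    growth_table,
    simulate_community,
)
from hoiscan.models import RankDeficiencyError, UnderdeterminedError
from hoiscan.validation import pooled_growth_table, two_species_scenario

# (model, K in a 2-species community, K in a 3-species community)
K_TABLE = [
    ("additive_LV", 4, 5),
    ("interactive_LV_intra", 6, 8),
    ("interactive_LV_inter", 5, 8),
    ("interactive_LV_full", 7, 11),
    ("additive_Ricker", 4, 5),
    ("interactive_Ricker", 5, 8),
]


class TestCountParameters:
    @pytest.mark.parametrize("name,k2,k3", K_TABLE)
    def test_published_counts(self, name, k2, k3):
        assert count_parameters(name, 2) == k2
        assert count_parameters(name, 3) == k3

    def test_single_species_inter_has_no_pairs(self):
        assert count_parameters("interactive_LV_inter", 1) == 3
        assert count_parameters("interactive_Ricker", 1) == 3

    def test_invalid_species_count(self):
        with pytest.raises(ValueError):
            count_parameters("additive_LV", 0)


def _reg_table(n_species, n_obs=40, seed=0):
    rng = np.random.default_rng(seed)
    codes = ["C", "D", "S"][:n_species]
    data = {"r": rng.uniform(0.2, 2.0, n_obs)}
    for c in codes:
        data[f"N_{c}"] = rng.uniform(10, 1000, n_obs)
    return pd.DataFrame(data)


class TestBuildDesign:
    def test_full_three_species_columns(self):
        design = build_design(_reg_table(3), "interactive_LV_full")
        assert design.columns == [
            "N_C", "N_D", "N_S",
            "N_C:N_C", "N_D:N_D", "N_S:N_S",
            "N_C:N_D", "N_C:N_S", "N_D:N_S",
        ]
        assert 2 + len(design.columns) == 11

    def test_inter_two_species(self):
        design = build_design(_reg_table(2), "interactive_LV_inter")
        assert design.columns == ["N_C", "N_D", "N_C:N_D"]

    def test_single_species_interactive_ricker(self):
        design = build_design(_reg_table(1), "interactive_Ricker")
        assert design.columns == ["N_C"]

    def test_exclude_focal_k_drops_pairs(self):
        all_pairs = build_design(_reg_table(3), "interactive_LV_inter")
        literal = build_design(_reg_table(3), "interactive_LV_inter",
                               inter_pairs="exclude_focal_k", focal="D")
        assert "N_C:N_D" in all_pairs.columns
        assert "N_C:N_D" not in literal.columns
        assert len(literal.columns) == len(all_pairs.columns) - 1

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_design(_reg_table(2, n_obs=0), "additive_LV")


class TestFitting:
    def test_noiseless_lv_recovery(self):
        """Exact least squares on exactly linear noiseless data."""
        params = two_species_scenario("none", process_noise_sd=0.0)
        reg = pooled_growth_table(params, replicates=1, seed=0)
        res = GrowthRateModel.from_regression_table(
            reg.drop(columns=["microcosm_id", "t"]), "additive_LV",
            focal="C", community="CD").fit()
        assert res.converged
        assert res.lambda_hat == pytest.approx(params.lambda_["C"], abs=1e-8)
        assert res.alpha_hat["C"] == pytest.approx(params.alpha[("C", "C")], abs=1e-8)
        assert res.alpha_hat["D"] == pytest.approx(params.alpha[("C", "D")], abs=1e-8)
        # zero residuals: the variance floor keeps the log-likelihood finite
        assert np.isfinite(res.llf)

    def test_noiseless_ricker_recovery_vs_direct_optimizer(self):
        """Log-link IRLS fit agrees with truth and with a generic optimizer
        maximizing the identical Gaussian likelihood."""
        lam, a_cc, a_cd = 1.2, 4e-4, 1e-4
        params = SimParams(
            species=["C", "D"], lambda_={"C": lam, "D": 1.0},
            alpha={("C", "C"): a_cc, ("C", "D"): a_cd, ("D", "D"): 3e-4},
            family="Ricker", carrying_capacity={"C": 1000.0, "D": 1200.0},
            process_noise_sd=0.0,
        )
        table = simulate_community(params)
        reg = growth_table(table, "C", "CD").drop(columns=["microcosm_id", "t"])
        res = GrowthRateModel.from_regression_table(
            reg, "additive_Ricker", focal="C", community="CD").fit()
        assert res.lambda_hat == pytest.approx(lam, abs=1e-6)
        assert res.alpha_hat["C"] == pytest.approx(a_cc, abs=1e-6)
        assert res.alpha_hat["D"] == pytest.approx(a_cd, abs=1e-6)

        y = reg["r"].to_numpy()
        X = np.column_stack([np.ones(len(reg)), reg["N_C"], reg["N_D"]])

        def nss(theta):  # residual sum of squares of the log-link mean
            return np.sum((y - np.exp(X @ (theta / [1, 1e3, 1e3]))) ** 2)

        opt = minimize(nss, x0=[0.0, 0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 5000})
        theta = opt.x / [1, 1e3, 1e3]
        assert res.lambda_hat == pytest.approx(np.exp(theta[0]), abs=1e-5)
        assert res.alpha_hat["C"] == pytest.approx(-theta[1], abs=1e-6)

    def test_nested_models_never_lose_likelihood(self):
        params = two_species_scenario("full")
        reg = pooled_growth_table(params, replicates=2, seed=42)
        fits = {f.spec.name: f for f in fit_all_models(reg, focal="C",
                                                       community="CD")}
        base = fits["additive_LV"].llf
        for name in ("interactive_LV_intra", "interactive_LV_inter",
                     "interactive_LV_full"):
            assert fits[name].llf >= base - 1e-9
        assert fits["interactive_LV_full"].llf >= \
            fits["interactive_LV_intra"].llf - 1e-9
        if fits["interactive_Ricker"].converged:
            assert fits["interactive_Ricker"].llf >= \
                fits["additive_Ricker"].llf - 1e-6

    def test_k_matches_closed_form_for_all_fits(self, study_table):
        for community, n_sp in [("CD", 2), ("CDS", 3)]:
            reg = growth_table(study_table, "D", community)
            for fit in fit_all_models(reg, focal="D", community=community):
                assert fit.K == count_parameters(fit.spec, n_sp)

    def test_three_species_k_multiset(self, study_table):
        reg = growth_table(study_table, "C", "CDP")
        ks = sorted(f.K for f in fit_all_models(reg, focal="C", community="CDP"))
        assert ks == [5, 5, 8, 8, 8, 11]

    def test_sign_convention_round_trip(self):
        """Simulated suppression coefficients come back positive (and the
        boosting cross-term negative) when strongly identified."""
        params = two_species_scenario("full", process_noise_sd=0.02)
        reg = pooled_growth_table(params, replicates=4, seed=9)
        res = GrowthRateModel.from_regression_table(
            reg.drop(columns=["microcosm_id", "t"]), "interactive_LV_full",
            focal="C", community="CD").fit()
        for name, value in [("N_C", -res.params["N_C"]),
                            ("N_C:N_C", -res.params["N_C:N_C"])]:
            se = res.bse[name]
            if abs(value) > 5 * se:
                assert value > 0  # suppression terms were simulated positive

    def test_underdetermined_full_model_flagged_not_fatal(self):
        reg = _reg_table(3, n_obs=4)
        fits = fit_all_models(reg, focal="C", community="CDS")
        by_name = {f.spec.name: f for f in fits}
        assert not by_name["interactive_LV_full"].converged
        assert by_name["additive_LV"].converged

    def test_collinear_design_names_columns(self):
        reg = _reg_table(2, n_obs=30)
        reg["N_D"] = 2.0 * reg["N_C"]
        with pytest.raises(RankDeficiencyError, match="N_D"):
            GrowthRateModel.from_regression_table(reg, "additive_LV")

    def test_underdetermined_direct_error(self):
        with pytest.raises(UnderdeterminedError):
            GrowthRateModel.from_regression_table(_reg_table(3, n_obs=3),
                                                  "interactive_LV_full")

    def test_summary_mentions_key_quantities(self):
        reg = _reg_table(2)
        res = GrowthRateModel.from_regression_table(
            reg, "additive_LV", focal="C", community="CD").fit()
        text = res.summary()
        assert "Additive LV" in text and "K=4" in text and "lambda" in text


class TestRecoveryScaling:
    def test_rmse_decreases_with_sample_size_smoke(self):
        """Estimator error shrinks as pooled transitions double (20 reps)."""
        from hoiscan.validation import parameter_recovery_rmse

        rmse = parameter_recovery_rmse(n_reps=20, seed=5)
        assert rmse[4] < rmse[2]
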