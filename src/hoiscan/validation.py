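"""Simulation-based validation experiments for the model-fitting stack.

Self-contained generate-and-recover experiments on a two-species
community: exact coefficient recovery from noiseless data, estimator
RMSE as a function of the number of growth transitions, and how often
AICc parsimony selection recovers the generating model class under
process noise. The scenario parameters are fixed here so the same
conditions are exercised by the test suite, the acceptance script and
any user re-running the experiments.

Scenario: two unequal competitors (intrinsic responses 1.0 and 1.2 per
day, carrying capacities 1000 and 1600/mL — the asymmetry keeps their
trajectories linearly independent), cross-competition 30% resp. 20% of
self-limitation, lognormal process noise sigma = 0.05 on each step,
sampled every 2 days for 53 days starting from 10% of carrying
capacity. The HOI variant adds quadratic and cross-product terms scaled
so the HOI load is about half the self-limitation load at typical
densities (~700/mL), i.e. clearly present but not dominant.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .growth import growth_table
from .io import TimeSeriesTable
from .models import GrowthRateModel, fit_all_models
from .selection import select_model
from .simulate import SimParams, simulate_community

#: Model names without HOI terms (linear or log-linear pairwise only).
NO_HOI_MODELS = frozenset({"additive_LV", "additive_Ricker"})

_LAMBDA = {"C": 1.0, "D": 1.2}
_KCC = {"C": 1000.0, "D": 1600.0}
# self-limitation placing each monoculture equilibrium at carrying capacity
_ALPHA = {
    ("C", "C"): (_LAMBDA["C"] - 0.5) / _KCC["C"],
    ("D", "D"): (_LAMBDA["D"] - 0.5) / _KCC["D"],
}
_ALPHA[("C", "D")] = 0.3 * _ALPHA[("C", "C")]
_ALPHA[("D", "C")] = 0.2 * _ALPHA[("D", "D")]
_BETA = 0.5 * _ALPHA[("C", "C")] / 700.0  # half the self-limitation load at ~700/mL


def two_species_scenario(hoi_structure: str = "none",
                         process_noise_sd: float = 0.05,
                         seed: int = 0) -> SimParams:
    """The fixed validation community (see module docstring)."""
    beta_intra: dict = {}
    beta_inter: dict = {}
    if hoi_structure == "full":
        beta_intra = {(i, j): _BETA for i in "CD" for j in "CD"}
        beta_inter = {("C", "C", "D"): _BETA, ("D", "C", "D"): _BETA}
    elif hoi_structure != "none":
        raise ValueError("scenario supports hoi_structure 'none' or 'full'")
    return SimParams(
        species=["C", "D"],
        lambda_=dict(_LAMBDA),
        alpha=dict(_ALPHA),
        beta_intra=beta_intra,
        beta_inter=beta_inter,
        family="LV",
        hoi_structure=hoi_structure,
        carrying_capacity=dict(_KCC),
        process_noise_sd=process_noise_sd,
        seed=seed,
    )


def pooled_growth_table(params: SimParams, replicates: int,
                        seed: int, focal: str = "C") -> pd.DataFrame:
    """Simulate ``replicates`` microcosms and pool their growth rows."""
    frames = []
    for rep in range(1, replicates + 1):
        p = dataclasses.replace(params, seed=(seed * 1009 + rep) % (2**31))
        frames.append(
            simulate_community(p, microcosm_id=f"CD_r{rep}", replicate=rep).df
        )
    table = TimeSeriesTable(pd.concat(frames, ignore_index=True), validate=False)
    return growth_table(table, focal, "CD")


def noiseless_recovery_error(hoi_structure: str = "none") -> float:
    """Max |estimate - truth| fitting the generating model to noiseless data.

    Exact least squares on exactly linear data: the error is numerical
    round-off only.
    """
    params = two_species_scenario(hoi_structure, process_noise_sd=0.0)
    reg = pooled_growth_table(params, replicates=1, seed=0)
    spec = "additive_LV" if hoi_structure == "none" else "interactive_LV_full"
    res = GrowthRateModel.from_regression_table(
        reg.drop(columns=["microcosm_id", "t"]), spec, focal="C", community="CD"
    ).fit()
    errors = [abs(res.lambda_hat - _LAMBDA["C"]),
              abs(res.alpha_hat["C"] - _ALPHA[("C", "C")]),
              abs(res.alpha_hat["D"] - _ALPHA[("C", "D")])]
    if hoi_structure == "full":
        errors += [abs(res.beta_intra_hat[j] - _BETA) for j in "CD"]
        errors.append(abs(res.beta_inter_hat[("C", "D")] - _BETA))
    return float(max(errors))


def parameter_recovery_rmse(replicates_grid: tuple[int, ...] = (2, 4),
                            n_reps: int = 200, seed: int = 0) -> dict[int, float]:
    """RMSE of additive-LV coefficient estimates vs pooled sample size.

    For each entry of ``replicates_grid`` (2 pooled microcosms ~ 52
    transitions, 4 ~ 104), fits the generating additive LV model on
    ``n_reps`` independent noisy studies and returns the aggregate RMSE
    over (lambda, alpha_CC, alpha_CD), each scaled by its true value so
    the coefficients contribute comparably.
    """
    truth = np.array([_LAMBDA["C"], _ALPHA[("C", "C")], _ALPHA[("C", "D")]])
    out: dict[int, float] = {}
    for n_replicates in replicates_grid:
        sq = []
        for r in range(n_reps):
            params = two_species_scenario("none", seed=0)
            reg = pooled_growth_table(params, n_replicates,
                                      seed=seed * 7919 + r * 13 + n_replicates)
            res = GrowthRateModel.from_regression_table(
                reg.drop(columns=["microcosm_id", "t"]), "additive_LV",
                focal="C", community="CD",
            ).fit()
            est = np.array([res.lambda_hat, res.alpha_hat["C"], res.alpha_hat["D"]])
            sq.append(((est - truth) / truth) ** 2)
        out[n_replicates] = float(np.sqrt(np.mean(sq)))
    return out


def selection_recovery_rate(hoi_structure: str, n_reps: int = 200,
                            seed: int = 0, replicates: int = 4) -> float:
    """Fraction of synthetic studies whose most parsimonious model matches
    the generating model class (no-HOI vs HOI-containing)."""
    params = two_species_scenario(hoi_structure)
    hits = 0
    for r in range(n_reps):
        reg = pooled_growth_table(params, replicates, seed=seed * 104729 + r)
        fits = fit_all_models(reg, focal="C", community="CD")
        winner = select_model(fits).most_parsimonious_model
        is_no_hoi = winner in NO_HOI_MODELS
        hits += is_no_hoi if hoi_structure == "none" else (not is_no_hoi)
    return hits / n_reps
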