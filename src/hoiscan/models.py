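"""The six-model competition suite and its Gaussian maximum-likelihood fits.

Per focal species and community, six candidate models describe the
per-capita growth-rate response r as a function of consumer densities:

    additive LV            r = lambda - sum_j a_j N_j
    interactive LV intra   ... - sum_j b_jj N_j^2
    interactive LV inter   ... - sum_{j<k} b_jk N_j N_k
    interactive LV full    ... - both HOI sums
    additive Ricker        r = lambda * exp(-sum_j a_j N_j)
    interactive Ricker     r = lambda * exp(-sum_j a_j N_j - sum_{j<k} b_jk N_j N_k)

LV models are fitted as Gaussian GLMs with identity link (ordinary least
squares); Ricker models as Gaussian GLMs with log link. Reported
coefficients follow the sign convention above: positive alpha/beta means
suppression of growth. The parameter count K includes the intercept and
the Gaussian dispersion, so K = 2 + (number of slope columns); this is
the counting under which the candidate models have K = {4, 6, 5, 7, 4, 5}
in a two-species community and {5, 8, 8, 11, 5, 8} with three species.

By default the interspecific-HOI sum runs over ALL unordered pairs of
distinct community members, including pairs containing the focal species
(that is what makes both focal species' inter-HOI models the same size);
``inter_pairs="exclude_focal_k"`` restricts to pairs whose second member
is not the focal species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .species import Species, Treatment

#: Minimum residual variance; keeps the log-likelihood finite when a
#: model interpolates the data exactly.
SIGMA2_FLOOR = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """One of the six candidate model structures."""

    name: str
    family: str  # "LV" | "Ricker"
    hoi_structure: str  # "none" | "intra" | "inter" | "full"

    @property
    def link(self) -> str:
        return "identity" if self.family == "LV" else "log"

    @property
    def label(self) -> str:
        return MODEL_LABELS[self.name]


MODEL_SPECS: dict[str, ModelSpec] = {
    "additive_LV": ModelSpec("additive_LV", "LV", "none"),
    "interactive_LV_intra": ModelSpec("interactive_LV_intra", "LV", "intra"),
    "interactive_LV_inter": ModelSpec("interactive_LV_inter", "LV", "inter"),
    "interactive_LV_full": ModelSpec("interactive_LV_full", "LV", "full"),
    "additive_Ricker": ModelSpec("additive_Ricker", "Ricker", "none"),
    "interactive_Ricker": ModelSpec("interactive_Ricker", "Ricker", "inter"),
}

#: Fixed model order, also the final tie-break in selection.
MODEL_ORDER = list(MODEL_SPECS)

MODEL_LABELS = {
    "additive_LV": "Additive LV",
    "interactive_LV_intra": "Interactive LV (intra HOI)",
    "interactive_LV_inter": "Interactive LV (inter HOI)",
    "interactive_LV_full": "Interactive LV (full HOI)",
    "additive_Ricker": "Additive Ricker",
    "interactive_Ricker": "Interactive Ricker",
}


class UnderdeterminedError(ValueError):
    """Fewer observations than coefficients."""


class RankDeficiencyError(ValueError):
    """Perfectly collinear design columns."""


def count_parameters(spec: ModelSpec | str, n_species: int) -> int:
    """Closed-form K (intercept + dispersion + slope columns)."""
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    spec = MODEL_SPECS[spec] if isinstance(spec, str) else spec
    n_pairs = math.comb(n_species, 2)
    k = 2 + n_species  # intercept + dispersion + linear terms
    if spec.hoi_structure in ("intra", "full"):
        k += n_species
    if spec.hoi_structure in ("inter", "full"):
        k += n_pairs
    return k


@dataclass
class DesignMatrix:
    """Response vector plus named predictor columns for one model."""

    response: np.ndarray
    X: pd.DataFrame  # slope columns only (no intercept)
    species: list[str]  # community consumer codes in canonical order

    @property
    def n_obs(self) -> int:
        return len(self.response)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)


def build_design(
    table: pd.DataFrame,
    spec: ModelSpec | str,
    *,
    inter_pairs: str = "all",
    focal: Species | str | None = None,
) -> DesignMatrix:
    """Build the design matrix for one model from a regression table.

    ``table`` must hold the response column ``r`` and density columns
    ``N_<code>``. Column naming is deterministic: linear terms ``N_j``,
    quadratic terms ``N_j:N_j``, cross terms ``N_j:N_k`` with j before k
    in canonical species order.
    """
    spec = MODEL_SPECS[spec] if isinstance(spec, str) else spec
    if len(table) == 0:
        raise ValueError("empty regression table")
    density_cols = [c for c in table.columns if c.startswith("N_")]
    if not density_cols or "r" not in table.columns:
        raise ValueError("regression table needs an 'r' column and N_* columns")
    codes = [c[2:] for c in density_cols]

    X = table[density_cols].copy()
    if spec.hoi_structure in ("intra", "full"):
        for code in codes:
            X[f"N_{code}:N_{code}"] = table[f"N_{code}"] ** 2
    if spec.hoi_structure in ("inter", "full"):
        focal_code = Species(focal).value if focal is not None else None
        for cj, ck in combinations(codes, 2):
            if inter_pairs == "exclude_focal_k" and ck == focal_code:
                continue
            X[f"N_{cj}:N_{ck}"] = table[f"N_{cj}"] * table[f"N_{ck}"]
    return DesignMatrix(
        response=table["r"].to_numpy(dtype=float),
        X=X.astype(float),
        species=codes,
    )


def _check_design(design: DesignMatrix) -> np.ndarray:
    n, p = design.n_obs, design.X.shape[1] + 1
    if n <= p - 1:
        raise UnderdeterminedError(
            f"{n} observations cannot identify {p} mean parameters"
        )
    exog = sm.add_constant(design.X.to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        # locate offending columns by incremental rank growth
        bad, cols = [], exog[:, :1]
        for name, col in zip(design.columns, exog[:, 1:].T):
            cand = np.column_stack([cols, col])
            if np.linalg.matrix_rank(cand) == cols.shape[1]:
                bad.append(name)
            else:
                cols = cand
        raise RankDeficiencyError(f"collinear design column(s): {bad}")
    return exog


@dataclass
class GrowthRateResults:
    """Fitted coefficients and fit statistics for one candidate model.

    Coefficients are reported in the suppression sign convention:
    ``lambda_hat`` is the intrinsic growth-rate response and positive
    ``alpha_hat`` / ``beta_*_hat`` values depress growth.
    """

    spec: ModelSpec
    focal: Species | None
    community: Treatment | None
    lambda_hat: float
    alpha_hat: dict[str, float]
    beta_intra_hat: dict[str, float]
    beta_inter_hat: dict[tuple[str, str], float]
    sigma2_hat: float
    n_obs: int
    K: int
    llf: float
    converged: bool
    params: pd.Series  # raw regression coefficients (intercept + slopes)
    bse: pd.Series

    @property
    def aicc(self) -> float:
        from .selection import aicc

        return aicc(self.llf, self.K, self.n_obs)

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "focal": self.focal.value if self.focal else None,
            "community": self.community.code if self.community else None,
            "lambda": self.lambda_hat,
            "alpha": dict(self.alpha_hat),
            "beta_intra": dict(self.beta_intra_hat),
            "beta_inter": {f"{j}:{k}": v for (j, k), v in self.beta_inter_hat.items()},
            "sigma2": self.sigma2_hat,
            "n_obs": self.n_obs,
            "K": self.K,
            "loglik": self.llf,
            "AICc": self.aicc if self.n_obs > self.K + 1 else None,
            "converged": self.converged,
        }

    def summary(self) -> str:
        lines = [
            f"{self.spec.label}"
            + (f" | focal {self.focal.value}" if self.focal else "")
            + (f" | community {self.community.code}" if self.community else ""),
            f"  link={self.spec.link}  n={self.n_obs}  K={self.K}  "
            f"loglik={self.llf:.3f}  AICc={self.aicc:.3f}  "
            f"converged={self.converged}",
            f"  lambda = {self.lambda_hat:.6g}",
        ]
        for code, a in self.alpha_hat.items():
            lines.append(f"  alpha[{code}] = {a:.6g}")
        for code, b in self.beta_intra_hat.items():
            lines.append(f"  beta_intra[{code}] = {b:.6g}")
        for (j, k), b in self.beta_inter_hat.items():
            lines.append(f"  beta_inter[{j},{k}] = {b:.6g}")
        return "\n".join(lines)


class GrowthRateModel:
    """Gaussian GLM for the per-capita growth-rate response of one species.

    Statsmodels-style usage::

        model = GrowthRateModel.from_timeseries(table, focal="C",
                                                community="CDS",
                                                spec="interactive_Ricker")
        res = model.fit()
        print(res.summary())

    Parameters
    ----------
    design : DesignMatrix
        Response and named slope columns (see :func:`build_design`).
    spec : ModelSpec
        Chooses the link: identity for LV, log for Ricker.
    """

    def __init__(
        self,
        design: DesignMatrix,
        spec: ModelSpec | str,
        *,
        focal: Species | str | None = None,
        community: Treatment | str | None = None,
    ) -> None:
        self.spec = MODEL_SPECS[spec] if isinstance(spec, str) else spec
        self.design = design
        self.focal = Species(focal) if focal is not None else None
        self.community = (
            Treatment(community) if isinstance(community, str) else community
        )
        self.exog = _check_design(design)

    @classmethod
    def from_regression_table(
        cls,
        table: pd.DataFrame,
        spec: ModelSpec | str,
        *,
        focal: Species | str | None = None,
        community: Treatment | str | None = None,
        inter_pairs: str = "all",
    ) -> "GrowthRateModel":
        spec = MODEL_SPECS[spec] if isinstance(spec, str) else spec
        design = build_design(table, spec, inter_pairs=inter_pairs, focal=focal)
        return cls(design, spec, focal=focal, community=community)

    @classmethod
    def from_timeseries(
        cls,
        table,
        focal: Species | str,
        community: Treatment | str,
        spec: ModelSpec | str,
        *,
        method: str = "ratio_per_day",
        inter_pairs: str = "all",
    ) -> "GrowthRateModel":
        from .growth import growth_table

        reg = growth_table(table, Species(focal), community, method=method)
        reg = reg.drop(columns=["microcosm_id", "t"])
        return cls.from_regression_table(
            reg, spec, focal=focal, community=community, inter_pairs=inter_pairs
        )

    def fit(self, *, tol: float = 1e-10, maxiter: int = 200) -> GrowthRateResults:
        y = self.design.response
        exog = self.exog
        n = len(y)
        if self.spec.link == "identity":
            res = sm.OLS(y, exog).fit()
            coefs, bse, mu, converged = res.params, res.bse, res.fittedvalues, True
        else:
            # start from least squares on the log of the clipped response
            positive = y[y > 0]
            eps = (positive.min() * 1e-3) if len(positive) else 1e-9
            start = sm.OLS(np.log(np.maximum(y, eps)), exog).fit().params
            glm = sm.GLM(y, exog, family=sm.families.Gaussian(sm.families.links.Log()))
            try:
                res = glm.fit(start_params=start, maxiter=maxiter, tol=tol)
                converged = bool(res.converged)
            except Exception:
                return self._failed_result(n)
            coefs, bse, mu = res.params, res.bse, res.fittedvalues
        rss = float(np.sum((y - mu) ** 2))
        sigma2 = max(rss / n, SIGMA2_FLOOR)
        llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + rss / (n * sigma2))
        names = ["intercept"] + self.design.columns
        params = pd.Series(np.asarray(coefs), index=names)
        return self._package(params, pd.Series(np.asarray(bse), index=names),
                             sigma2, llf, converged)

    def _package(self, params, bse, sigma2, llf, converged) -> GrowthRateResults:
        lam = params["intercept"]
        if self.spec.link == "log":
            lam = float(np.exp(lam))
        alpha, beta_intra, beta_inter = {}, {}, {}
        for name, value in params.items():
            if name == "intercept":
                continue
            coef = -float(value)  # suppression sign convention
            if ":" in name:
                left, right = name.split(":")
                j, k = left[2:], right[2:]
                if j == k:
                    beta_intra[j] = coef
                else:
                    beta_inter[(j, k)] = coef
            else:
                alpha[name[2:]] = coef
        return GrowthRateResults(
            spec=self.spec,
            focal=self.focal,
            community=self.community,
            lambda_hat=float(lam),
            alpha_hat=alpha,
            beta_intra_hat=beta_intra,
            beta_inter_hat=beta_inter,
            sigma2_hat=float(sigma2),
            n_obs=self.design.n_obs,
            K=2 + len(self.design.columns),
            llf=float(llf),
            converged=converged,
            params=params,
            bse=bse,
        )

    def _failed_result(self, n: int) -> GrowthRateResults:
        names = ["intercept"] + self.design.columns
        nan = pd.Series(np.full(len(names), np.nan), index=names)
        return GrowthRateResults(
            spec=self.spec, focal=self.focal, community=self.community,
            lambda_hat=float("nan"), alpha_hat={}, beta_intra_hat={},
            beta_inter_hat={}, sigma2_hat=float("nan"), n_obs=n,
            K=2 + len(self.design.columns), llf=float("nan"),
            converged=False, params=nan, bse=nan,
        )


def fit_model(
    design: DesignMatrix,
    spec: ModelSpec | str,
    *,
    focal: Species | str | None = None,
    community: Treatment | str | None = None,
) -> GrowthRateResults:
    """Functional wrapper over :class:`GrowthRateModel`."""
    return GrowthRateModel(design, spec, focal=focal, community=community).fit()


def fit_all_models(
    table: pd.DataFrame,
    focal: Species | str | None = None,
    community: Treatment | str | None = None,
    *,
    inter_pairs: str = "all",
) -> list[GrowthRateResults]:
    """Fit all six candidate models on the identical observation set.

    Per-model fitting errors (e.g. an underdetermined full-HOI design)
    are converted into non-converged results so the remaining models can
    still be compared.
    """
    results = []
    for name in MODEL_ORDER:
        spec = MODEL_SPECS[name]
        try:
            model = GrowthRateModel.from_regression_table(
                table.drop(columns=[c for c in ("microcosm_id", "t") if c in table]),
                spec, focal=focal, community=community, inter_pairs=inter_pairs,
            )
            results.append(model.fit())
        except (UnderdeterminedError, RankDeficiencyError):
            design = build_design(
                table.drop(columns=[c for c in ("microcosm_id", "t") if c in table]),
                spec, inter_pairs=inter_pairs, focal=focal,
            )
            dummy = GrowthRateModel.__new__(GrowthRateModel)
            dummy.spec = spec
            dummy.design = design
            dummy.focal = Species(focal) if focal is not None else None
            dummy.community = (
                Treatment(community) if isinstance(community, str) else community
            )
            results.append(dummy._failed_result(design.n_obs))
    return results
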