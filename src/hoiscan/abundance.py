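"""Mean-abundance summaries and the two-factor community-effect analysis.

Each microcosm contributes one mean density per species (averaged over
every sampling day, zeros included). Effects of community composition on
those means are estimated with a two-way linear model with interaction:
identity of the third competitor (none / Paramecium / Spirostomum,
baseline none) crossed with predator presence, on log10(mean + 1)
densities by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io import TimeSeriesTable
from .species import Species, Treatment

TRANSFORMS = ("log10p1", "identity")


@dataclass(frozen=True)
class AbundanceSummary:
    species: Species
    treatment: str
    replicate: int
    microcosm_id: str
    mean_density: float
    sem: float  # standard error over sampling days


@dataclass(frozen=True)
class EffectEstimate:
    """One linear-model coefficient on the transformed mean-density scale."""

    species: Species
    factor: str
    b: float
    ci95: tuple[float, float]
    n: int  # replicates per cell
    p_value: float


def summarize_abundance(table: TimeSeriesTable) -> list[AbundanceSummary]:
    """One summary per (species, microcosm): mean and SEM over sampling days."""
    out: list[AbundanceSummary] = []
    df = table.df
    grouped = df.groupby(["microcosm_id", "species"], sort=False)
    for (mc, sp), sub in grouped:
        dens = sub["density"].to_numpy()
        sem = float(np.std(dens, ddof=1) / np.sqrt(len(dens))) if len(dens) > 1 else 0.0
        out.append(AbundanceSummary(
            species=Species(sp),
            treatment=sub["treatment"].iloc[0],
            replicate=int(sub["replicate"].iloc[0]),
            microcosm_id=mc,
            mean_density=float(dens.mean()),
            sem=sem,
        ))
    return out


def summaries_frame(summaries: list[AbundanceSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        treatment = Treatment(s.treatment)
        third = [sp.value for sp in treatment.consumers if sp.value not in ("C", "D")]
        rows.append({
            "species": s.species.value,
            "treatment": s.treatment,
            "replicate": s.replicate,
            "microcosm_id": s.microcosm_id,
            "mean_density": s.mean_density,
            "sem": s.sem,
            "third_species": third[0] if third else "none",
            "predator": treatment.predator_present,
        })
    return pd.DataFrame(rows)


def abundance_effects(
    summaries: list[AbundanceSummary],
    species: Species | str,
    transform: str = "log10p1",
) -> tuple[list[EffectEstimate], pd.DataFrame]:
    """Two-way linear model (third species x predator) for one species.

    Returns the coefficient estimates with normal-theory 95% CIs and the
    two-way ANOVA table (type-II F tests).
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"transform must be one of {TRANSFORMS}")
    species = Species(species)
    df = summaries_frame(summaries)
    df = df[df["species"] == species.value].copy()
    if df.empty:
        raise ValueError(f"no summaries for species {species.value}")
    if transform == "log10p1":
        df["y"] = np.log10(df["mean_density"] + 1.0)
    else:
        df["y"] = df["mean_density"]
    for factor in ("third_species", "predator"):
        if df[factor].nunique() < 2:
            raise ValueError(
                f"factor {factor!r} has a single level "
                f"({df[factor].unique().tolist()}); two-way model is degenerate"
            )
    levels = [lv for lv in ("none", "P", "S") if lv in set(df["third_species"])]
    df["third_species"] = pd.Categorical(df["third_species"], categories=levels)
    model = smf.ols("y ~ C(third_species) * C(predator)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    n_per_cell = int(df.groupby(["third_species", "predator"], observed=True)
                       .size().median())
    ci = model.conf_int()
    effects = [
        EffectEstimate(
            species=species,
            factor=name,
            b=float(model.params[name]),
            ci95=(float(ci.loc[name, 0]), float(ci.loc[name, 1])),
            n=n_per_cell,
            p_value=float(model.pvalues[name]),
        )
        for name in model.params.index
    ]
    return effects, anova
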