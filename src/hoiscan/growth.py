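"""Per-capita growth-rate observations from abundance time series.

For a focal species i with consecutive samples N_t and N_{t+dt}, the
regression response is

    ratio_per_day      r = (N_{t+dt} / N_t) / dt      (default)
    log_ratio_per_day  r = ln(N_{t+dt} / N_t) / dt

with the covariates — densities of every consumer in the community —
taken at the interval start t. Transitions with N_t = 0 are dropped (the
per-capita rate is undefined); under the log-ratio convention transitions
with N_{t+dt} = 0 are dropped as well. Replicate microcosms of the same
community are pooled, each contributing its own observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import TimeSeriesTable
from .species import Species, Treatment, species_sort_key

logger = logging.getLogger(__name__)

GROWTH_METHODS = ("ratio_per_day", "log_ratio_per_day")


@dataclass(frozen=True)
class GrowthObservation:
    """One regression row: response plus densities at the interval start."""

    microcosm_id: str
    focal: Species
    t: float
    dt: float
    r: float
    covariates: dict[str, float]  # species code -> density at time t


def compute_growth_rates(
    table: TimeSeriesTable,
    focal: Species,
    method: str = "ratio_per_day",
    include_predator_treatments: bool = False,
) -> list[GrowthObservation]:
    """Growth-rate observations for ``focal`` across all microcosms.

    Predator treatments are excluded by default: predators drive early
    extinctions, so interaction strengths are estimated in predator-free
    communities only.
    """
    if method not in GROWTH_METHODS:
        raise ValueError(f"method must be one of {GROWTH_METHODS}")
    focal = Species(focal)
    import numpy as np

    observations: list[GrowthObservation] = []
    df = table.df
    for mc, sub in df.groupby("microcosm_id", sort=False):
        treatment = Treatment(sub["treatment"].iloc[0])
        if treatment.predator_present and not include_predator_treatments:
            continue
        if focal not in treatment.species_set:
            logger.warning("focal species %s absent from microcosm %s; skipped",
                           focal.value, mc)
            continue
        consumers = [sp.value for sp in treatment.consumers]
        wide = sub.pivot(index="day", columns="species", values="density").sort_index()
        days = wide.index.to_numpy()
        focal_dens = wide[focal.value].to_numpy()
        for a in range(len(days) - 1):
            n_t, n_next = focal_dens[a], focal_dens[a + 1]
            if n_t <= 0:
                continue
            dt = days[a + 1] - days[a]
            if method == "ratio_per_day":
                r = (n_next / n_t) / dt
            else:
                if n_next <= 0:
                    continue
                r = float(np.log(n_next / n_t) / dt)
            observations.append(GrowthObservation(
                microcosm_id=mc,
                focal=focal,
                t=float(days[a]),
                dt=float(dt),
                r=float(r),
                covariates={c: float(wide[c].to_numpy()[a]) for c in consumers},
            ))
    return observations


def assemble_regression_table(
    observations: list[GrowthObservation],
    community: Treatment,
) -> pd.DataFrame:
    """Rectangular table: response column ``r`` plus one density column per
    consumer species, named ``N_<code>`` in canonical order, rows sorted by
    (microcosm, t)."""
    if not observations:
        raise ValueError("no observations to assemble")
    community = community if isinstance(community, Treatment) else Treatment(community)
    consumers = [sp.value for sp in community.consumers]
    for obs in observations:
        if set(obs.covariates) != set(consumers):
            raise ValueError(
                f"observation from microcosm {obs.microcosm_id} has covariates "
                f"{sorted(obs.covariates)}, expected {sorted(consumers)}: "
                "mixed communities cannot be pooled"
            )
    rows = sorted(observations, key=lambda o: (o.microcosm_id, o.t))
    data = {
        "microcosm_id": [o.microcosm_id for o in rows],
        "t": [o.t for o in rows],
        "r": [o.r for o in rows],
    }
    for code in sorted(consumers, key=lambda c: species_sort_key(Species(c))):
        data[f"N_{code}"] = [o.covariates[code] for o in rows]
    return pd.DataFrame(data)


def growth_table(
    table: TimeSeriesTable,
    focal: Species,
    community: Treatment | str,
    method: str = "ratio_per_day",
) -> pd.DataFrame:
    """Convenience: restrict to one community, compute and assemble."""
    community = community if isinstance(community, Treatment) else Treatment(community)
    sub = table.subset(treatments=[community.code])
    obs = compute_growth_rates(sub, focal, method=method)
    return assemble_regression_table(obs, community)
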