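"""Persistence analysis: extinction times, Kaplan-Meier, log-rank tests.

A species' persistence in a microcosm is its time to extinction. Because
single zero counts can be detection failures (a 250 uL subsample of a
sparse culture), extinction is scored only when zeros persist to the end
of the series: the event time is the first sampled day of the terminal
all-zero run. A species still present at the last sample (or one that
rebounds after a zero) is right-censored at the study end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank_test
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import TimeSeriesTable
from .species import Species

logger = logging.getLogger(__name__)

STUDY_END_DEFAULT = 53.0


@dataclass(frozen=True)
class SurvivalDatum:
    """One microcosm's time-to-extinction record for one species."""

    unit_id: str
    group: str  # treatment code
    species: Species
    time: float
    event: bool  # True = extinction observed, False = right-censored


@dataclass
class KMCurve:
    """Product-limit survival estimate with 95% bands.

    Bands use the Greenwood variance on the log-survival scale,
    S * exp(+/- 1.96 * sqrt(var(log S))).
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def extract_survival(
    table: TimeSeriesTable,
    species: Species | str,
    study_end: float = STUDY_END_DEFAULT,
) -> list[SurvivalDatum]:
    """Time-to-extinction data for ``species`` in every microcosm holding it."""
    species = Species(species)
    data: list[SurvivalDatum] = []
    df = table.df
    for mc, sub in df.groupby("microcosm_id", sort=False):
        series = sub[sub["species"] == species.value]
        if series.empty:
            continue
        days = series["day"].to_numpy()
        dens = series["density"].to_numpy()
        group = sub["treatment"].iloc[0]
        if dens[-1] > 0:
            data.append(SurvivalDatum(mc, group, species, float(study_end), False))
            continue
        # first day of the terminal all-zero run
        idx = len(dens) - 1
        while idx > 0 and dens[idx - 1] == 0:
            idx -= 1
        time = float(days[idx])
        if time <= 0:
            # never detected at all: earliest resolvable extinction time
            time = float(days[1]) if len(days) > 1 else float(study_end)
        data.append(SurvivalDatum(mc, group, species, time, True))
    if not data:
        logger.warning("species %s absent from every microcosm", species.value)
    return data


def _unpack(data: list[SurvivalDatum]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([d.time for d in data], dtype=float)
    events = np.array([d.event for d in data], dtype=bool)
    return times, events


def km_estimate(data: list[SurvivalDatum]) -> KMCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod (1 - d_i/n_i)."""
    if not data:
        raise ValueError("no survival data")
    times, events = _unpack(data)
    kmf = KaplanMeierFitter().fit(times, event_observed=events)
    tab = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    grid = tab.index.to_numpy(dtype=float)
    d = tab["observed"].to_numpy(dtype=float)
    n = tab["at_risk"].to_numpy(dtype=float)
    surv = np.cumprod(1.0 - d / n)
    # Greenwood variance on the log scale
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = np.where(n > d, d / (n * (n - d)), np.inf)
        var_log = np.cumsum(incr)
        half = 1.959963984540054 * np.sqrt(var_log)
        lower = np.where(surv > 0, surv * np.exp(-half), 0.0)
        upper = np.where(surv > 0, np.minimum(surv * np.exp(half), 1.0), 0.0)
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk=n.astype(int),
        n_events=d.astype(int),
        ci_lower=lower,
        ci_upper=upper,
    )


def logrank_test(groups: dict[str, list[SurvivalDatum]]) -> LogRankResult:
    """k-group log-rank chi-square test (df = k - 1)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, data in groups.items():
        if not data:
            raise ValueError(f"group {name!r} has no data")
    frames = []
    for name, data in groups.items():
        times, events = _unpack(data)
        frames.append(pd.DataFrame({"time": times, "event": events, "group": name}))
    df = pd.concat(frames, ignore_index=True)
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    k = len(groups)
    stat = float(res.test_statistic)
    return LogRankResult(
        statistic=stat,
        df=k - 1,
        p_value=float(stats.chi2.sf(stat, k - 1)),
    )


def pairwise_logrank(
    groups: dict[str, list[SurvivalDatum]],
    adjust: str = "BH",
) -> pd.DataFrame:
    """All unordered pairwise log-rank tests, BH-adjusted by default.

    Returns a long table with columns group1, group2, statistic, p_raw,
    p_adjusted.
    """
    if adjust not in ("BH", "none"):
        raise ValueError("adjust must be 'BH' or 'none'")
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            ta, ea = _unpack(groups[a])
            tb, eb = _unpack(groups[b])
            res = _ll_logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
            rows.append({
                "group1": a, "group2": b,
                "statistic": float(res.test_statistic),
                "p_raw": float(res.p_value),
            })
    out = pd.DataFrame(rows)
    if adjust == "BH":
        out["p_adjusted"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    else:
        out["p_adjusted"] = out["p_raw"]
    return out


def survival_by_treatment(
    table: TimeSeriesTable,
    species: Species | str,
    treatments: list[str],
    study_end: float = STUDY_END_DEFAULT,
) -> dict[str, list[SurvivalDatum]]:
    """Extract per-treatment survival data for one species."""
    data = extract_survival(table.subset(treatments=treatments), species, study_end)
    return {
        code: [d for d in data if d.group == code]
        for code in treatments
        if any(d.group == code for d in data)
    }
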