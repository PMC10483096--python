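"""Small-sample AICc ranking and the parsimony selection rule.

Models within 2 AICc units of the best are treated as equivalently
supported; among those, the model with the fewest estimated parameters K
is deemed the most parsimonious. Ties on K fall back to lower AICc, then
to a fixed model-name order, so selection is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .models import MODEL_ORDER, GrowthRateResults


def aicc(loglik: float, K: int, n: int) -> float:
    """AICc = -2*loglik + 2K + 2K(K+1)/(n - K - 1); requires n > K + 1."""
    if n <= K + 1:
        raise ValueError(
            f"AICc undefined for n={n}, K={K}: correction term needs n > K + 1"
        )
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


class SelectionError(ValueError):
    pass


@dataclass
class SelectionTable:
    """AICc ranking of the candidate models for one (focal, community)."""

    rows: pd.DataFrame  # model, K, loglik, AICc, dAICc — sorted by AICc
    best_aicc_model: str
    most_parsimonious_model: str
    focal: str | None
    community: str | None
    excluded: list[str]  # non-converged models left out of the ranking

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        head = f"SelectionTable(focal={self.focal}, community={self.community})"
        return head + "\n" + self.rows.to_string(index=False)


def select_model(fits: list[GrowthRateResults]) -> SelectionTable:
    """Rank converged fits by AICc and apply the parsimony rule.

    All fits must share the same observation set (identical ``n_obs``).
    Non-converged fits are excluded from the ranking and listed in the
    result's ``excluded`` field.
    """
    converged = [f for f in fits if f.converged]
    excluded = [f.spec.name for f in fits if not f.converged]
    if not converged:
        raise SelectionError("no converged fits to select among")
    n_set = {f.n_obs for f in converged}
    if len(n_set) > 1:
        raise SelectionError(f"fits disagree on n_obs: {sorted(n_set)}")

    order_index = {name: i for i, name in enumerate(MODEL_ORDER)}
    rows = pd.DataFrame({
        "model": [f.spec.name for f in converged],
        "K": [f.K for f in converged],
        "n_obs": [f.n_obs for f in converged],
        "loglik": [f.llf for f in converged],
        "AICc": [f.aicc for f in converged],
    })
    rows["dAICc"] = rows["AICc"] - rows["AICc"].min()
    rows = rows.sort_values(
        by=["AICc", "model"],
        key=lambda c: c.map(order_index) if c.name == "model" else c,
        kind="mergesort",
    ).reset_index(drop=True)

    candidates = rows[rows["dAICc"] < 2.0]
    winner = candidates.sort_values(
        by=["K", "AICc", "model"],
        key=lambda c: c.map(order_index) if c.name == "model" else c,
        kind="mergesort",
    ).iloc[0]["model"]

    focal = converged[0].focal
    community = converged[0].community
    return SelectionTable(
        rows=rows,
        best_aicc_model=rows.iloc[0]["model"],
        most_parsimonious_model=winner,
        focal=focal.value if focal is not None else None,
        community=community.code if community is not None else None,
        excluded=excluded,
    )


def selection_report(tables: list[SelectionTable]) -> pd.DataFrame:
    """Stack selection tables into one long report.

    One row per (focal, community, model) with K, AICc, dAICc and a flag
    on the most parsimonious model, mirroring the layout of a published
    model-selection table.
    """
    from .models import MODEL_LABELS

    frames = []
    for tab in tables:
        df = tab.rows.copy()
        df.insert(0, "focal", tab.focal)
        df.insert(1, "community", tab.community)
        df["label"] = df["model"].map(MODEL_LABELS)
        df["most_parsimonious"] = df["model"] == tab.most_parsimonious_model
        frames.append(df)
    columns = ["focal", "community", "model", "label", "K", "n_obs",
               "loglik", "AICc", "dAICc", "most_parsimonious"]
    if not frames:
        return pd.DataFrame(columns=columns)
    return pd.concat(frames, ignore_index=True)[columns]
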