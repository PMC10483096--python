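"""Long-format abundance time-series tables: container, validation, CSV I/O.

The central exchange format of the pipeline is a long table with one row
per (microcosm, day, species) holding a density in individuals/mL.
Densities are explicit: a species that was looked for and not seen is
recorded as 0, never as a missing cell.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .species import Species, Treatment

#: Canonical column order of the on-disk CSV.
CANONICAL_COLUMNS = ["microcosm_id", "treatment", "replicate", "day", "species", "density"]


class SchemaError(ValueError):
    """A required column cannot be resolved in an input file."""


class ValidationError(ValueError):
    """A table violates a structural invariant."""


@dataclass
class TimeSeriesTable:
    """Validated long-format abundance records.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain the canonical columns. Rows are sorted into
        (microcosm_id, day, species-order) order on construction.
    validate : bool
        Run the full invariant check (default). Construction from
        already-validated internals may skip it.
    """

    df: pd.DataFrame
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df["day"] = pd.to_numeric(df["day"], errors="raise").astype(float)
        df["density"] = pd.to_numeric(df["density"], errors="raise").astype(float)
        df["replicate"] = df["replicate"].astype(int)
        df["species"] = df["species"].astype(str)
        df["microcosm_id"] = df["microcosm_id"].astype(str)
        df["treatment"] = df["treatment"].astype(str)
        order = {sp.value: i for i, sp in enumerate(Species)}
        df = df.sort_values(
            by=["microcosm_id", "day", "species"],
            key=lambda col: col.map(order) if col.name == "species" else col,
            kind="mergesort",
        ).reset_index(drop=True)
        object.__setattr__(self, "df", df[CANONICAL_COLUMNS])
        if self.validate:
            self._check_invariants()

    def _check_invariants(self) -> None:
        df = self.df
        known = {sp.value for sp in Species}
        bad_sp = sorted(set(df["species"]) - known)
        if bad_sp:
            raise ValidationError(f"unknown species code(s): {', '.join(bad_sp)}")
        if not np.isfinite(df["density"]).all():
            idx = df.index[~np.isfinite(df["density"])].tolist()
            raise ValidationError(f"non-finite density at row(s) {idx}")
        neg = df.index[df["density"] < 0].tolist()
        if neg:
            raise ValidationError(f"negative density at row(s) {neg}")
        dup = df.duplicated(subset=["microcosm_id", "day", "species"])
        if dup.any():
            rows = df.loc[dup, ["microcosm_id", "day", "species"]].iloc[0]
            raise ValidationError(
                "duplicate (microcosm, day, species) record: "
                f"({rows['microcosm_id']}, {rows['day']}, {rows['species']})"
            )
        for treatment_code in df["treatment"].unique():
            treatment = Treatment(treatment_code)  # raises on unknown code
            allowed = {sp.value for sp in treatment.species_set}
            present = set(df.loc[df["treatment"] == treatment_code, "species"])
            extra = sorted(present - allowed)
            if extra:
                raise ValidationError(
                    f"species {extra} recorded in treatment {treatment_code} "
                    f"whose composition is {sorted(allowed)}"
                )
        # Within a microcosm every species must be sampled on the same days.
        for mc, sub in df.groupby("microcosm_id", sort=False):
            grids = {sp: tuple(s["day"]) for sp, s in sub.groupby("species", sort=False)}
            ref = next(iter(grids.values()))
            for sp, grid in grids.items():
                if grid != ref:
                    raise ValidationError(
                        f"microcosm {mc}: sampling days of species {sp} "
                        "differ from the other species"
                    )
            if any(b <= a for a, b in zip(ref, ref[1:])):
                raise ValidationError(f"microcosm {mc}: days not strictly increasing")

    # -- convenience accessors -------------------------------------------------
    @property
    def microcosms(self) -> list[str]:
        return list(dict.fromkeys(self.df["microcosm_id"]))

    def subset(self, *, treatments: list[str] | None = None,
               microcosms: list[str] | None = None) -> "TimeSeriesTable":
        df = self.df
        if treatments is not None:
            df = df[df["treatment"].isin(treatments)]
        if microcosms is not None:
            df = df[df["microcosm_id"].isin(microcosms)]
        return TimeSeriesTable(df.reset_index(drop=True), validate=False)

    def species_series(self, microcosm_id: str, species: Species) -> pd.DataFrame:
        """(day, density) frame for one species in one microcosm."""
        df = self.df
        sub = df[(df["microcosm_id"] == microcosm_id) & (df["species"] == species.value)]
        return sub[["day", "density"]].reset_index(drop=True)

    def equals(self, other: "TimeSeriesTable", rtol: float = 1e-12) -> bool:
        a, b = self.df, other.df
        if len(a) != len(b):
            return False
        meta = ["microcosm_id", "treatment", "replicate", "species"]
        if not a[meta].equals(b[meta]):
            return False
        return bool(
            np.allclose(a["day"], b["day"], rtol=rtol, atol=0.0)
            and np.allclose(a["density"], b["density"], rtol=rtol, atol=0.0)
        )

    def __len__(self) -> int:
        return len(self.df)


def read_timeseries(path: str | os.PathLike, schema: dict[str, str] | None = None) -> TimeSeriesTable:
    """Read a long-format abundance CSV into a validated table.

    ``schema`` maps canonical column names to the names used in the file,
    e.g. ``{"microcosm_id": "jar", "density": "indiv_per_ml"}``; columns
    not mentioned are expected under their canonical names.
    """
    raw = pd.read_csv(path)
    schema = schema or {}
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = schema.get(canonical, canonical)
        if source not in raw.columns:
            raise SchemaError(
                f"column {source!r} (for {canonical!r}) not found in {path}; "
                f"available: {list(raw.columns)}"
            )
        rename[source] = canonical
    return TimeSeriesTable(raw.rename(columns=rename)[CANONICAL_COLUMNS])


def write_timeseries(table: TimeSeriesTable, path: str | os.PathLike) -> str:
    """Write the canonical long CSV (header always present). Returns path."""
    table.df.to_csv(path, index=False, float_format="%.12g")
    return os.fspath(path)


def validate_design(table: TimeSeriesTable) -> dict:
    """Report how the table matches the 6-treatment x 4-replicate design.

    Returns a report dict (never raises): per-treatment replicate counts,
    the sampling-day grid(s) observed, and species missing from each
    treatment's expected composition.
    """
    df = table.df
    replicate_counts: dict[str, int] = {}
    missing_species: dict[str, list[str]] = {}
    from .species import TREATMENT_ORDER

    for code in TREATMENT_ORDER:
        sub = df[df["treatment"] == code]
        replicate_counts[code] = sub["microcosm_id"].nunique()
        expected = {sp.value for sp in Treatment(code).species_set}
        missing = sorted(expected - set(sub["species"])) if len(sub) else sorted(expected)
        if missing and len(sub):
            missing_species[code] = missing
    grids = {
        mc: tuple(sorted(sub["day"].unique()))
        for mc, sub in df.groupby("microcosm_id", sort=False)
    }
    distinct_grids = sorted(set(grids.values()))
    # Microcosms where one species' sampled days differ from another's.
    grid_mismatches = []
    for mc, sub in df.groupby("microcosm_id", sort=False):
        per_species = {tuple(s["day"]) for _, s in sub.groupby("species", sort=False)}
        if len(per_species) > 1:
            grid_mismatches.append(mc)
    return {
        "n_microcosms": df["microcosm_id"].nunique(),
        "replicate_counts": replicate_counts,
        "complete_design": all(v == 4 for v in replicate_counts.values()),
        "missing_species": missing_species,
        "sampling_grids": distinct_grids,
        "uniform_grid": len(distinct_grids) <= 1,
        "grid_mismatches": grid_mismatches,
    }
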