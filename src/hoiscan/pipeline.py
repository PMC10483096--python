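"""End-to-end run: simulate (or load) -> growth rates -> fits -> selection
-> survival -> abundance, with a manifest for reproducibility.

Every stochastic stage draws from one root seed, so two runs with the
same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .abundance import abundance_effects, summaries_frame, summarize_abundance
from .growth import growth_table
from .io import TimeSeriesTable, read_timeseries, validate_design, write_timeseries
from .models import fit_all_models
from .selection import SelectionTable, select_model, selection_report
from .simulate import ObservationParams, SimParams, default_study_params, generate_study
from .species import FOCAL_PAIR, Species, Treatment
from .survival import km_estimate, logrank_test, pairwise_logrank, survival_by_treatment

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    outdir: str = "hoiscan_run"
    data_path: str | None = None  # read real data instead of simulating
    replicates: int = 4
    focal_species: list[str] = field(default_factory=lambda: ["C", "D"])
    communities: list[str] = field(default_factory=lambda: ["CD", "CDP", "CDS"])
    growth_method: str = "ratio_per_day"
    survival_species: list[str] = field(default_factory=lambda: ["C", "D", "Pd"])
    study_end: float = 53.0
    pairwise_adjust: str = "BH"
    abundance_transform: str = "log10p1"
    observation: dict = field(default_factory=lambda: ObservationParams().to_dict())
    simulation: dict | None = None  # treatment code -> SimParams dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def sim_params(self) -> dict[str, SimParams]:
        if self.simulation is None:
            return default_study_params()
        return {code: SimParams.from_dict(d) for code, d in self.simulation.items()}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _km_record(curve) -> dict:
    return {
        "times": curve.times.tolist(),
        "survival": curve.survival.tolist(),
        "at_risk": curve.at_risk.tolist(),
        "n_events": curve.n_events.tolist(),
        "ci_lower": curve.ci_lower.tolist(),
        "ci_upper": curve.ci_upper.tolist(),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write artifacts under ``config.outdir``.

    Returns a dict of in-memory results (table, selection tables,
    survival results, abundance effects, manifest).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "hoiscan",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": [],
    }
    results: dict = {"manifest": manifest}

    # -- stage 1: data -------------------------------------------------------
    stage = "data"
    try:
        if config.data_path is not None:
            table = read_timeseries(config.data_path)
        else:
            table = generate_study(
                config.sim_params(),
                obs=ObservationParams(**config.observation),
                replicates=config.replicates,
                seed=config.seed,
            )
        write_timeseries(table, outdir / "data.csv")
        report = validate_design(table)
        manifest["stages"].append({
            "name": stage,
            "n_records": len(table),
            "n_microcosms": report["n_microcosms"],
        })
        results["table"] = table
        results["design_report"] = report
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _persist_manifest(manifest, outdir)
        raise PipelineError(stage, exc) from exc

    # -- stage 2: growth rates + model fits + selection ----------------------
    stage = "selection"
    try:
        selections: list[SelectionTable] = []
        fits_json = []
        n_dropped = 0
        for community in config.communities:
            if Treatment(community).predator_present:
                # interaction strengths are estimated without predators only
                logger.warning("skipping predator treatment %s in fitting", community)
                continue
            for focal in config.focal_species:
                reg = growth_table(results["table"], Species(focal), community,
                                   method=config.growth_method)
                fits = fit_all_models(reg, focal=focal, community=community)
                fits_json.extend(f.to_dict() for f in fits)
                n_dropped += sum(not f.converged for f in fits)
                selections.append(select_model(fits))
        report_df = selection_report(selections)
        report_df.to_csv(outdir / "selection.csv", index=False, float_format="%.6f")
        with open(outdir / "fits.json", "w") as fh:
            json.dump(fits_json, fh, indent=1, sort_keys=True)
        manifest["stages"].append({
            "name": stage,
            "n_tables": len(selections),
            "n_nonconverged": n_dropped,
        })
        results["selections"] = selections
        results["selection_report"] = report_df
    except Exception as exc:  # noqa: BLE001
        _persist_manifest(manifest, outdir)
        raise PipelineError(stage, exc) from exc

    # -- stage 3: survival ---------------------------------------------------
    stage = "survival"
    try:
        survival_out: dict = {}
        strata = {
            "no_predator": ["CD", "CDP", "CDS"],
            "with_predator": ["CDPd", "CDPPd", "CDSPd"],
        }
        for sp_code in config.survival_species:
            sp = Species(sp_code)
            sp_out: dict = {}
            for stratum, codes in strata.items():
                if sp.is_predator and stratum == "no_predator":
                    continue
                groups = survival_by_treatment(results["table"], sp, codes,
                                               study_end=config.study_end)
                groups = {k: v for k, v in groups.items() if v}
                if not groups:
                    continue
                entry: dict = {
                    "km": {code: _km_record(km_estimate(data))
                           for code, data in groups.items()},
                }
                if len(groups) >= 2:
                    lr = logrank_test(groups)
                    entry["logrank"] = {
                        "statistic": lr.statistic, "df": lr.df, "p_value": lr.p_value,
                    }
                    pw = pairwise_logrank(groups, adjust=config.pairwise_adjust)
                    entry["pairwise"] = pw.to_dict(orient="records")
                sp_out[stratum] = entry
            survival_out[sp_code] = sp_out
        with open(outdir / "survival.json", "w") as fh:
            json.dump(survival_out, fh, indent=1, sort_keys=True)
        manifest["stages"].append({"name": stage, "species": config.survival_species})
        results["survival"] = survival_out
    except Exception as exc:  # noqa: BLE001
        _persist_manifest(manifest, outdir)
        raise PipelineError(stage, exc) from exc

    # -- stage 4: abundance --------------------------------------------------
    stage = "abundance"
    try:
        summaries = summarize_abundance(results["table"])
        summaries_frame(summaries).to_csv(outdir / "abundance_summaries.csv",
                                          index=False, float_format="%.6f")
        effect_rows = []
        for sp in FOCAL_PAIR:
            effects, anova = abundance_effects(summaries, sp,
                                               transform=config.abundance_transform)
            for e in effects:
                effect_rows.append({
                    "species": e.species.value, "factor": e.factor, "b": e.b,
                    "ci_low": e.ci95[0], "ci_high": e.ci95[1],
                    "n": e.n, "p_value": e.p_value,
                })
        import pandas as pd

        pd.DataFrame(effect_rows).to_csv(outdir / "abundance_effects.csv",
                                         index=False, float_format="%.6f")
        manifest["stages"].append({"name": stage, "n_effects": len(effect_rows)})
        results["abundance_effects"] = effect_rows
    except Exception as exc:  # noqa: BLE001
        _persist_manifest(manifest, outdir)
        raise PipelineError(stage, exc) from exc

    _persist_manifest(manifest, outdir)
    return results


def _persist_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
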