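"""End-to-end orchestration: data -> exposure -> rates -> smoothing -> DiD.

The pipeline consumes either user-supplied CSVs (villages, events,
covariates, adjacency) or a synthetic-data configuration, runs the
stages in order, and writes every artefact with provenance metadata
(stage, configuration hash, seed).  All interchange is plain CSV/JSON;
the posterior-draw bank is a compressed numpy container.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bym, exposure, propagate, rates, simulate
from .periods import ANALYSIS_PERIODS

logger = logging.getLogger(__name__)

#: Covariates entering the adjusted DiD by default.
DEFAULT_DID_COVARIATES = [
    "agri_pct",
    "unemployment_pct",
    "secondary_ed_pct",
    "smoking_pct",
    "obesity_pct",
    "temp_var_annual",
    "hospital_beds_per_1000",
    "retired_plant",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    outdir: str = "chpdid_run"
    seed: int = 0
    input_dir: str | None = None          # CSV directory; None -> simulate
    simulation: dict = field(default_factory=dict)
    exposure_threshold: float = 0.50
    sensitivity_70_30: bool = False
    pooling: str = "calendar"             # calendar | november
    age_bands: str = "main"               # main | fine
    subgroups: list = field(default_factory=lambda: ["all"])
    smoothing: str = "bypass"             # bym | bypass | none
    n_draws: int = 6000
    bym_spec: dict = field(default_factory=dict)
    adjusted: bool = True
    control_group: str = "never"
    covariates: list = field(default_factory=lambda: list(DEFAULT_DID_COVARIATES))
    exclude: list = field(default_factory=list)
    exclude_reason: str = ""
    sensitivity_battery: bool = False
    outlier_ids: list = field(default_factory=list)  # battery-only exclusions

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        """Hash of the analysis-relevant configuration (output path aside)."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def exclude_townships(
    frame: pd.DataFrame, ids: list, reason: str = ""
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop listed townships from any township-keyed table, logging each."""
    if not ids:
        return frame, []
    known = set(frame["township_id"].unique())
    unknown = [t for t in ids if t not in known]
    if unknown:
        raise ValueError(f"unknown township ids: {unknown}")
    log = [{"township_id": t, "reason": reason} for t in ids]
    for entry in log:
        logger.info("excluding %s (%s)", entry["township_id"], reason)
    return frame[~frame["township_id"].isin(ids)].reset_index(drop=True), log


def _provenance(config: RunConfig, stage: str) -> dict:
    return {
        "stage": stage,
        "config_hash": config.hash(),
        "seed": config.seed,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the result bundle (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runlog = []
    bundle: dict = {"provenance": _provenance(config, "pipeline")}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            runlog.append({"stage": name, "status": "failed", "error": str(exc)})
            (outdir / "runlog.json").write_text(json.dumps(runlog, indent=1))
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        runlog.append(
            {"stage": name, "status": "ok",
             "seconds": round(time.perf_counter() - t0, 3)}
        )
        return result

    # ------------------------------------------------------------ data
    def load_data():
        if config.input_dir is None:
            sim = simulate.SimulationConfig(
                **{**config.simulation, "seed": config.seed}
            )
            data = simulate.generate_dataset(sim)
            data.write(outdir / "data")
            return data.villages, data.events, data.covariates, data.adjacency
        d = Path(config.input_dir)
        read = lambda name: pd.read_csv(d / name)
        villages = read("villages.csv")
        events = read("events.csv")
        covariates = read("covariates.csv")
        adjacency = read("adjacency.csv")
        return villages, events, covariates, adjacency

    villages, events, covariates, adjacency = stage("data", load_data)

    # -------------------------------------------------------- exposure
    def exposure_stage():
        fractions = exposure.compute_enrolled_fraction(villages)
        if config.sensitivity_70_30:
            sens = exposure.assign_exposure_sensitivity(fractions)
            bundle["excluded_30_70"] = sens.excluded
            panel = sens.panel
        else:
            panel = exposure.assign_exposure(
                fractions, threshold=config.exposure_threshold
            )
        panel.to_csv(outdir / "exposure.csv", index=False)
        return panel

    exposure_panel = stage("exposure", exposure_stage)

    # ----------------------------------------------------------- rates
    def rates_stage():
        pooled = rates.pool_events(events, window_start=config.pooling)
        if config.exclude:
            pooled_f, log = exclude_townships(
                pooled, config.exclude, config.exclude_reason
            )
            bundle["exclusions"] = log
        else:
            pooled_f = pooled
        keep = exposure_panel["township_id"].unique()
        pooled_f = pooled_f[pooled_f["township_id"].isin(keep)]
        tables = {}
        for sub in config.subgroups:
            tab = rates.direct_standardize(
                pooled_f, subgroup=sub, age_bands=config.age_bands
            )
            tables[sub] = rates.log_rates(tab)
        all_rates = pd.concat(tables.values(), ignore_index=True)
        all_rates.to_csv(outdir / "rates.csv", index=False)
        return pooled_f, tables

    pooled, rate_tables = stage("rates", rates_stage)

    # ------------------------------------------------------- smoothing
    def smoothing_stage():
        banks = {}
        for si, sub in enumerate(config.subgroups):
            sub_seed = (config.seed + 1000003 * si) % 2**31
            if config.smoothing == "bym":
                spec = bym.BYMSpec(**config.bym_spec)
                banks[sub] = bym.fit_bym(
                    pooled, adjacency, spec=spec, seed=sub_seed,
                    subgroup=sub, age_bands=config.age_bands,
                    periods=ANALYSIS_PERIODS,
                )
            elif config.smoothing == "bypass":
                banks[sub] = bym.bypass_draws(
                    pooled, n_draws=config.n_draws, seed=sub_seed,
                    subgroup=sub, age_bands=config.age_bands,
                    periods=ANALYSIS_PERIODS,
                )
            else:  # none: a single zero-variance draw of the direct rates
                banks[sub] = bym.bypass_draws(
                    pooled, n_draws=1, seed=sub_seed, subgroup=sub,
                    age_bands=config.age_bands, periods=ANALYSIS_PERIODS,
                    resample=False,
                )
        np.savez_compressed(
            outdir / "draws.npz",
            **{sub: b.log_rate for sub, b in banks.items()},
        )
        meta = {sub: b.meta for sub, b in banks.items()}
        (outdir / "draws_meta.json").write_text(
            json.dumps({**_provenance(config, "smoothing"), "banks": meta},
                       indent=1, default=str)
        )
        return banks

    banks = stage("smoothing", smoothing_stage)

    # ------------------------------------------------- DiD over draws
    def did_stage():
        cov_names = config.covariates if config.adjusted else None
        summaries = {}
        for sub, bank in banks.items():
            summaries[sub] = propagate.run_over_draws(
                bank,
                exposure_panel,
                covariates,
                adjusted=config.adjusted,
                control_group=config.control_group,
                covariate_names=cov_names,
            )
        result = {
            **_provenance(config, "did"),
            "subgroups": {s: v.to_dict() for s, v in summaries.items()},
        }
        (outdir / "did_result.json").write_text(
            json.dumps(result, indent=1, default=str)
        )
        return summaries

    summaries = stage("did", did_stage)

    # ------------------------------------------- impact and diagnostics
    def impact_stage():
        out: dict = {}
        final = ANALYSIS_PERIODS[-1]
        exp_ids = exposure_panel[
            (exposure_panel["period"] == final) & exposure_panel["exposed"]
        ]["township_id"].unique()
        obs = pooled[pooled["period"] == final]
        e_exposed = float(obs[obs["township_id"].isin(exp_ids)]["events"].sum())
        e_unexposed = float(obs[~obs["township_id"].isin(exp_ids)]["events"].sum())
        main_sub = config.subgroups[0]
        overall = summaries[main_sub].summary("overall", as_percent=True)
        avoided = propagate.events_avoided_exposed(
            e_exposed, overall["estimate"], overall["ci"]
        )
        additional = propagate.events_avoided_if_all_exposed(
            e_unexposed, overall["estimate"], overall["ci"]
        )
        out["events_avoided_exposed"] = asdict(avoided)
        out["events_avoided_if_all_exposed"] = asdict(additional)

        pre_rates = rates.log_rates(
            rates.direct_standardize(
                rates.pool_events(events, window_start=config.pooling),
                subgroup=main_sub, age_bands=config.age_bands,
            )
        )
        try:
            out["pretrend"] = propagate.pretrend_diagnostic(
                pre_rates, exposure_panel
            )
        except ValueError as exc:
            out["pretrend"] = {"error": str(exc)}
        (outdir / "propagated_results.json").write_text(
            json.dumps({**_provenance(config, "impact"), **out},
                       indent=1, default=str)
        )
        return out

    impact = stage("impact", impact_stage)

    # ---------------------------------------------------------- report
    lines = [f"CHP DiD analysis (config {config.hash()}, seed {config.seed})"]
    for sub, summ in summaries.items():
        lines.append(f"\nSubgroup: {sub}")
        for target, label in (
            ("overall", "overall ATT"),
            ("e0", "ATT <2 years"),
            ("e1", "ATT 2-4 years"),
        ):
            if target in summ.points:
                s = summ.summary(target)
                lines.append(
                    f"  {label}: {s['estimate']:+.1f}% "
                    f"(95% CI {s['ci'][0]:+.1f} to {s['ci'][1]:+.1f})"
                )
    av = impact["events_avoided_exposed"]
    lines.append(
        f"\nEvents avoided in exposed townships ({ANALYSIS_PERIODS[-1]}): "
        f"{av['avoided']} (95% CI {av['ci'][0]}-{av['ci'][1]})"
    )
    av2 = impact["events_avoided_if_all_exposed"]
    lines.append(
        "Additional events avoided if all townships exposed: "
        f"{av2['avoided']} (95% CI {av2['ci'][0]}-{av2['ci'][1]})"
    )
    report = "\n".join(lines)
    (outdir / "report.txt").write_text(report + "\n")
    (outdir / "runlog.json").write_text(json.dumps(runlog, indent=1))

    bundle.update(
        {
            "summaries": {s: v.to_dict() for s, v in summaries.items()},
            "impact": impact,
            "report": report,
            "runlog": runlog,
        }
    )

    if config.sensitivity_battery:
        bundle["sensitivity"] = run_sensitivity_battery(config, events)
        (outdir / "sensitivity_results.json").write_text(
            json.dumps(
                {**_provenance(config, "sensitivity"), **bundle["sensitivity"]},
                indent=1, default=str,
            )
        )
    return bundle


def sensitivity_variants(config: RunConfig) -> dict[str, dict]:
    """One-at-a-time alternate specifications mirroring the study's
    robustness checks, relative to the main configuration."""
    return {
        "threshold_70_30": {"sensitivity_70_30": True},
        "fine_age_bands": {"age_bands": "fine"},
        "november_pooling": {"pooling": "november"},
        "plus_hypercholesterolaemia": {
            "covariates": list(config.covariates)
            + ["hypercholesterolaemia_pct"]
        },
        "heating_season_temperature": {
            "covariates": [
                c if c != "temp_var_annual" else "temp_var_heating"
                for c in config.covariates
            ]
        },
        "outlier_exclusion": {},  # applies the configured outlier id list
    }


def run_sensitivity_battery(config: RunConfig, events: pd.DataFrame) -> dict:
    """Re-run the pipeline once per alternate specification.

    Each variant changes exactly one analysis choice relative to the main
    configuration; results land under ``<outdir>/sensitivity/<name>``.
    Variants whose inputs are unavailable (november pooling without
    monthly events; outlier exclusion without an id list) are recorded as
    skipped rather than failing the battery.
    """
    results: dict = {}
    base = asdict(config)
    base["sensitivity_battery"] = False
    for name, overrides in sensitivity_variants(config).items():
        if name == "november_pooling" and "month" not in events.columns:
            results[name] = {"status": "skipped", "reason": "no monthly events"}
            continue
        if name == "outlier_exclusion":
            if not config.outlier_ids:
                results[name] = {
                    "status": "skipped", "reason": "no outlier id list"
                }
                continue
            overrides = {
                "exclude": list(config.outlier_ids),
                "exclude_reason": "high-incidence outlier",
            }
        variant = dict(base)
        variant.update(overrides)
        variant["outdir"] = str(Path(config.outdir) / "sensitivity" / name)
        try:
            sub = run_pipeline(RunConfig(**variant))
        except PipelineError as exc:
            results[name] = {"status": "failed", "error": str(exc)}
            continue
        main_sub = config.subgroups[0]
        results[name] = {
            "status": "ok",
            "overall": sub["summaries"][main_sub]["overall"]["percent"],
        }
    return results
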