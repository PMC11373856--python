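"""End-to-end orchestration: data in, per-unit measures, area statistics out.

A pipeline run (simulate or load) measures tau_C, tau_R and R_tot for every
unit, computes per-area medians with bootstrap confidence intervals, runs
group comparisons and hierarchy-score correlations, optionally fits the
hierarchical Bayesian area models with an ELPD comparison and LOO-PIT
check, and writes CSV/JSON reports plus a run manifest.  Every random stage
is seeded from the master seed, so a fixed seed yields byte-identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import branching, io, stats
from .bayes import ModelSpec, build_design, compare_elpd, fit_model, loo_pit
from .timescales import FitMode

logger = logging.getLogger(__name__)

MEASURES = ("tau_C", "tau_R", "R_tot")


@dataclass
class PipelineConfig:
    # data source: CSV paths ...
    spikes_path: str | None = None
    meta_path: str | None = None
    # ... or simulation configs (dicts of BNConfig fields)
    simulate: list = field(default_factory=list)
    # measurement
    dt: float = 5.0
    fit_mode: FitMode = "two_timescale"
    T_min_fit: float = 30.0
    T_max_fit: float = 10_000.0
    T_min_R: float = 30.0
    T_max_R: float = 5_000.0
    n_grid: int = 25
    d: int = 5
    # statistics
    n_boot: int = 10_000
    level: float = 0.95
    # Bayesian stage (heavy; off by default)
    bayes_measures: list = field(default_factory=list)
    bayes_spec: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "pipeline_out"

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig(**yaml.safe_load(fh))


def _acquire(config: PipelineConfig):
    """Trains + records, either loaded from CSV or freshly simulated."""
    if config.spikes_path:
        return io.read_spike_table(config.spikes_path, config.meta_path)
    trains, records = [], []
    bn_fields = {f.name for f in dataclasses.fields(branching.BNConfig)}
    for i, simcfg in enumerate(config.simulate):
        kw = {k: v for k, v in simcfg.items() if k in bn_fields}
        kw["seed"] = simcfg.get("seed", config.seed + i)
        cfg = branching.BNConfig(**kw)
        rec = branching.simulate(cfg)
        trains.extend(rec.trains)
        for tr in rec.trains:
            records.append(
                io.UnitRecord(
                    unit_id=tr.unit_id,
                    mouse_id=f"net{i}",
                    area=simcfg.get("area", f"sim{i}"),
                    group=simcfg.get("group", "V1"),
                    hierarchy_score=float(simcfg.get("hierarchy_score", 0.0)),
                    firing_rate=max(tr.rate, 1e-6),
                    rf_flag=int(simcfg.get("rf_flag", 0)),
                )
            )
    return trains, records


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns {"tables": ..., "paths": ..., "manifest": ...}.

    Per-unit failures (e.g. too few spikes for an estimate) are recorded in
    the manifest and the pipeline continues with the remaining units.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trains, records = _acquire(config)
    rec_by_id = {r.unit_id: r for r in records}
    ss = np.random.SeedSequence([config.seed, 1234])
    unit_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(trains))]

    failures = []
    rows = []
    for tr, u_seed in zip(trains, unit_seeds):
        rec = rec_by_id.get(tr.unit_id)
        flagged = io.flag_low_count(tr, rec)
        try:
            row = branching.measure_unit(
                tr,
                dt=config.dt,
                fit_mode=config.fit_mode,
                T_min_fit=config.T_min_fit,
                T_max_fit=config.T_max_fit,
                T_min_R=config.T_min_R,
                T_max_R=config.T_max_R,
                seed=u_seed,
            )
        except Exception as err:  # keep going; record the failure
            failures.append({"unit_id": tr.unit_id, "error": str(err)})
            row = {"unit_id": tr.unit_id, "n_spikes": tr.n_spikes}
        row["flagged"] = flagged
        if rec is not None:
            row.update(area=rec.area, group=rec.group,
                       hierarchy_score=rec.hierarchy_score,
                       mouse_id=rec.mouse_id,
                       firing_rate_hz=rec.firing_rate, rf_flag=rec.rf_flag)
        rows.append(row)
    units = pd.DataFrame(rows)
    units_renamed = units.rename(
        columns={"tau_C": "tau_C_ms", "tau_sec": "tau_sec_ms", "tau_R": "tau_R_ms",
                 "fit_converged": "fit_converged", "fit_residual": "fit_residual"}
    )
    results_path = out_dir / "unit_measures.csv"
    cols = [c for c in io.RESULT_COLUMNS if c in units_renamed.columns]
    extra = [c for c in units_renamed.columns if c not in cols]
    units_renamed[cols + extra].to_csv(results_path, index=False, float_format="%.12g")

    tables = {"units": units}
    # per-area medians with bootstrap CIs
    if "area" in units.columns:
        med_rows = []
        for bi, (area, grp) in enumerate(units.groupby("area")):
            for measure in MEASURES:
                if measure not in grp:
                    continue
                vals = grp[measure].dropna().to_numpy()
                if not len(vals):
                    continue
                med, lo, hi = stats.median_ci_bootstrap(
                    vals, config.n_boot, config.level, seed=config.seed + bi
                )
                med_rows.append(
                    {"area": area, "measure": measure, "n": len(vals),
                     "median": med, "ci_lo": lo, "ci_hi": hi,
                     "hierarchy_score": grp["hierarchy_score"].iloc[0]}
                )
        medians = pd.DataFrame(med_rows)
        medians.to_csv(out_dir / "area_medians.csv", index=False, float_format="%.12g")
        tables["medians"] = medians

        # V1 vs higher-cortical group comparisons
        cmp_rows = []
        if "group" in units.columns and {"V1", "higher_cortical"} <= set(units["group"]):
            for measure in MEASURES:
                if measure not in units:
                    continue
                a = units.loc[units["group"] == "V1", measure].dropna()
                b = units.loc[units["group"] == "higher_cortical", measure].dropna()
                if len(a) and len(b):
                    rec_cmp = stats.group_compare(a, b, family_size=len(MEASURES))
                    rec_cmp["measure"] = measure
                    cmp_rows.append(rec_cmp)
        if cmp_rows:
            pd.DataFrame(cmp_rows).to_csv(out_dir / "group_tests.csv", index=False,
                                          float_format="%.12g")
            tables["group_tests"] = pd.DataFrame(cmp_rows)

        # hierarchy correlations over area medians
        corr_rows = []
        if len(medians) and medians["area"].nunique() >= 3:
            for measure in MEASURES:
                sub = medians[medians["measure"] == measure]
                if len(sub) >= 3:
                    c = stats.hierarchy_correlation(sub["median"], sub["hierarchy_score"])
                    c["measure"] = measure
                    corr_rows.append(c)
        if corr_rows:
            pd.DataFrame(corr_rows).to_csv(out_dir / "hierarchy_correlations.csv",
                                           index=False, float_format="%.12g")
            tables["hierarchy_correlations"] = pd.DataFrame(corr_rows)

    # optional hierarchical Bayesian stage
    bayes_report = {}
    for measure in config.bayes_measures:
        sub = units.dropna(subset=[measure])
        design = build_design(sub)
        y = sub.loc[design.index, measure]
        fits = {}
        for term in ("groups", "hierarchy"):
            spec = ModelSpec.for_measure(measure, area_term=term,
                                         seed=config.seed, **config.bayes_spec)
            fits[term] = fit_model(spec, design, y)
        comp = compare_elpd(fits["groups"], fits["hierarchy"])
        pit = loo_pit(fits["hierarchy"], seed=config.seed)
        bayes_report[measure] = {
            "elpd": comp,
            "loo_pit_ks": pit["ks"],
            "loo_pit_inside": pit["inside"],
            "diagnostics": {t: f.diagnostics for t, f in fits.items()},
        }
    if bayes_report:
        with open(out_dir / "bayes_report.json", "w") as fh:
            json.dump(bayes_report, fh, indent=2, default=float)

    manifest = {
        "config": dataclasses.asdict(config),
        "n_units": len(trains),
        "n_failures": len(failures),
        "failures": failures,
        "n_flagged": int(units["flagged"].sum()) if "flagged" in units else 0,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {"tables": tables, "out_dir": str(out_dir),
            "manifest": manifest, "bayes": bayes_report}
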