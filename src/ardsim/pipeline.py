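"""End-to-end pipeline: generate -> calibrate -> sweep -> report.

Every stage writes its outputs to disk and can be re-run from the previous
stage's files; a run manifest records the global seed, a configuration
hash and per-stage wall times.  A single global seed fans out to per-stage
and per-patient sub-seeds through ``numpy.random.SeedSequence([seed, ...])``
so that changing the cohort size never reshuffles earlier patients.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import (CohortCalibration, ga_profile)
from .cohort import (CohortSpec, ConfigurationError, RiskTable,
                     generate_cohort, generate_risk_table, read_cohort,
                     write_cohort)
from .simulator import SimConfig, VirtualPatient
from .sweep import InterventionGrid, InterventionStudy, default_grids

#: Published column schemas of every CSV the pipeline writes.
SCHEMAS = {
    "cohort_baseline": ["patient_id", "severity", "hb", "bsa", "vr", "vt_pbw",
                        "ideal_body_weight", "pf_ratio", "paco2", "svo2",
                        "cstat", "ph"],
    "cohort_rm_series": ["patient_id", "peep", "variable", "value"],
    "risk_table": ["intervention_id", "delta_p", "peep", "relative_risk"],
    "index_table": ["patient_id", "intervention_id", "delta_p", "peep",
                    "index_name", "value"],
    "condition_table": ["intervention_id", "delta_p", "peep", "index",
                        "mean", "sd", "n"],
    "correlation_table": ["intervention_id", "index", "r", "p", "strong"],
    "calibration_log": ["patient_id", "stage", "generation", "best_fitness",
                        "mean_fitness"],
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the offending file/stage."""


def validate_schema(frame: pd.DataFrame, name: str, path="") -> None:
    missing = set(SCHEMAS[name]) - set(frame.columns)
    if missing:
        raise StageError(f"{name} table {path} is missing columns {sorted(missing)}")


@dataclass
class RunConfig:
    """Reproducible configuration of one pipeline run."""

    out_dir: str = "ardsim_run"
    seed: int = 0
    n_patients: int = 26
    n_severe: int = 13
    n_moderate: int = 7
    n_mild: int = 6
    ga_profile: str = "full"
    risk_table_path: str | None = None     # external CSV; None -> synthetic
    risk_slope: float = 0.08
    record_dt: float = 1e-2                # s, recording resolution
    grids: dict = field(default_factory=dict)   # {id: [(dp, peep), ...]}
    cohort_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
            else json.loads(text)
        cfg = cls(**data)
        if cfg.risk_table_path and not Path(cfg.risk_table_path).exists():
            raise ConfigurationError(
                f"risk table path {cfg.risk_table_path} not resolvable")
        return cfg

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(n_patients=self.n_patients, n_severe=self.n_severe,
                          n_moderate=self.n_moderate, n_mild=self.n_mild,
                          seed=_sub_seed(self.seed, 0),
                          **self.cohort_overrides)

    def intervention_grids(self) -> dict[int, InterventionGrid]:
        if not self.grids:
            return default_grids()
        return {int(k): InterventionGrid(int(k), [tuple(c) for c in v])
                for k, v in self.grids.items()}

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sub_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def stage_generate(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    spec = config.cohort_spec()
    cohort = generate_cohort(spec)
    write_cohort(cohort, out, spec)
    grids = config.intervention_grids()
    if config.risk_table_path:
        frame = pd.read_csv(config.risk_table_path)
        validate_schema(frame, "risk_table", config.risk_table_path)
        risk = RiskTable(frame)
    else:
        risk = generate_risk_table(
            {i: g.conditions for i, g in grids.items()},
            monotone_slope=config.risk_slope, seed=_sub_seed(config.seed, 1))
    risk.frame.to_csv(out / "risk_table.csv", index=False)
    return out


def stage_calibrate(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    cohort = read_cohort(out)
    ga1, ga2 = ga_profile(config.ga_profile)
    sim_config = SimConfig(record_dt=config.record_dt)
    model = CohortCalibration(cohort, ga_stage1=ga1, ga_stage2=ga2,
                              sim_config=sim_config)
    results = model.fit(seed=_sub_seed(config.seed, 2))
    pdir = out / "patients"
    pdir.mkdir(exist_ok=True)
    log_rows = []
    for res in results.results:
        (pdir / f"{res.patient.patient_id}.json").write_text(res.patient.to_json())
        for stage, hist in (("pulmonary", res.history_stage1),
                            ("cardiovascular", res.history_stage2)):
            for gen, best, mean in hist:
                log_rows.append({"patient_id": res.patient.patient_id,
                                 "stage": stage, "generation": gen,
                                 "best_fitness": best, "mean_fitness": mean})
    log = pd.DataFrame(log_rows)
    validate_schema(log, "calibration_log")
    log.to_csv(out / "calibration_log.csv", index=False)
    (out / "calibration_summary.json").write_text(json.dumps({
        "fit_r2": results.fit_r2, "fit_p": results.fit_p,
        "stage1_fitness": [r.stage1_fitness for r in results.results],
        "stage2_fitness": [r.stage2_fitness for r in results.results],
        "warnings": {r.patient.patient_id: r.warnings for r in results.results},
    }, indent=1))
    return out


def load_patients(out_dir) -> list[VirtualPatient]:
    pdir = Path(out_dir) / "patients"
    paths = sorted(pdir.glob("P*.json"))
    if not paths:
        raise StageError(f"no calibrated patients found under {pdir}")
    patients = []
    for path in paths:
        try:
            patients.append(VirtualPatient.from_json(path.read_text()))
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise StageError(f"corrupted patient file {path}: {exc}") from exc
    return patients


def stage_sweep(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    patients = load_patients(out)
    risk_path = out / "risk_table.csv"
    if not risk_path.exists():
        raise StageError(f"missing risk table {risk_path}")
    frame = pd.read_csv(risk_path)
    validate_schema(frame, "risk_table", risk_path)
    study = InterventionStudy(patients, config.intervention_grids(),
                              RiskTable(frame),
                              SimConfig(record_dt=config.record_dt))
    results = study.run()
    tidy = results.per_patient.melt(
        id_vars=["patient_id", "intervention_id", "delta_p", "peep"],
        var_name="index_name", value_name="value")
    validate_schema(tidy, "index_table")
    tidy.to_csv(out / "index_table.csv", index=False)
    validate_schema(results.condition_table, "condition_table")
    results.condition_table.to_csv(out / "condition_table.csv", index=False)
    validate_schema(results.correlation_table, "correlation_table")
    results.correlation_table.to_csv(out / "correlation_table.csv", index=False)
    return out


def stage_report(config: RunConfig, plots: bool = False) -> Path:
    out = Path(config.out_dir)
    for name in ("condition_table", "correlation_table"):
        path = out / f"{name}.csv"
        if not path.exists():
            raise StageError(f"missing sweep output {path}")
        validate_schema(pd.read_csv(path), name, path)
    corr = pd.read_csv(out / "correlation_table.csv")
    strong = corr[corr["strong"] == True]  # noqa: E712
    report = {
        "strong_indices": sorted(strong["index"].unique().tolist()),
        "n_conditions": int(pd.read_csv(out / "condition_table.csv")
                            .groupby(["intervention_id", "delta_p", "peep"])
                            .ngroups),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    if plots:
        from .plots import plot_sweep_panels
        plot_sweep_panels(pd.read_csv(out / "condition_table.csv"),
                          pd.read_csv(out / "risk_table.csv"),
                          out / "sweep_panels.png")
    return out


STAGES = {
    "generate": stage_generate,
    "calibrate": stage_calibrate,
    "sweep": stage_sweep,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stages=("generate", "calibrate",
                                            "sweep", "report")) -> dict:
    """Execute the stages in order; returns the run manifest (also on disk).

    A stage failure raises :class:`StageError` after writing a checkpoint
    manifest naming the completed stages, so the run can resume.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stages": {},
    }
    manifest_path = out / "manifest.json"
    for name in stages:
        t0 = time.perf_counter()
        try:
            STAGES[name](config)
        except Exception as exc:
            manifest["failed_stage"] = {"stage": name, "error": str(exc)}
            manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "wall_time_s": round(time.perf_counter() - t0, 3)}
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
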