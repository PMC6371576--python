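"""Synthetic virtual-patient observation sets and relative-risk tables.

The source cohort this package emulates is a 25-patient adult ARDS series
(13 severe / 7 moderate / 6 mild by Berlin PF-ratio cut-offs) that is not
publicly deposited.  The generator reproduces its *statistical structure*:
per-variable cohort means and SDs of the published baseline table, a
severity-stratified PF-ratio distribution, and a recruitment-maneuver (RM)
series of cardiac index, PaCO2, MAP and SvO2 across a PEEP ladder.  Draws
are truncated normals per variable (independent between variables, which
is a documented limitation); the RM responses follow smooth monotone
templates plus measurement-scale noise, kept mutually consistent through
reflex-free circulatory relations (MAP tied to CI through a Windkessel
relation, SvO2 tied to CI through the Fick principle).

Relative-risk tables are synthetic stand-ins for the external
epidemiological supplement the analysis pairs with; real values can be
supplied in the same CSV schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

SEVERITIES = ("severe", "moderate", "mild")

#: Cohort means (SD) of the baseline characteristics being emulated.
TABLE1 = {
    "paco2": (61.0, 5.2),        # mmHg
    "ph": (7.24, 0.03),
    "svo2": (0.74, 0.093),       # fraction
    "ci": (5.0, 0.3),            # L/min/m^2
    "map": (90.0, 2.6),          # mmHg
    "cstat": (22.0, 3.6),        # ml/cmH2O
    "vr": (12.5, 0.8),           # breaths/min
    "vt_pbw": (5.9, 0.08),       # ml/kg predicted body weight
    "pf_severe": (72.0, 9.6),    # mmHg
    "pf_moderate": (152.0, 37.0),
    "pf_mild": (244.0, 37.0),
}

#: Physiological truncation ranges per variable.
TRUNCATION = {
    "paco2": (35.0, 90.0),
    "ph": (7.05, 7.50),
    "svo2": (0.40, 0.95),
    "ci": (3.0, 7.5),
    "map": (60.0, 120.0),
    "cstat": (10.0, 45.0),
    "vr": (8.0, 20.0),
    "vt_pbw": (4.0, 8.0),
    "pf_severe": (35.0, 99.9),
    "pf_moderate": (100.1, 199.9),
    "pf_mild": (200.1, 450.0),
}


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort to generate.

    The default emulates the source cohort: 26 adult ARDS patients split
    13 severe / 7 moderate / 6 mild by Berlin PF-ratio cut-offs.
    """

    n_patients: int = 26
    n_severe: int = 13
    n_moderate: int = 7
    n_mild: int = 6
    seed: int = 0
    ideal_body_weight: float = 70.0            # kg
    hb: float = 10.5                            # g/dl
    bsa: float = 1.8                            # m^2
    distribution_params: dict = field(default_factory=lambda: dict(TABLE1))
    rm_peep_ladder: tuple = (10.0, 15.0, 20.0, 25.0)  # cmH2O
    rm_delta_p: float = 25.0                   # cmH2O held during the RM
    # RM response templates (see docs/methods.md)
    ci_slope: float = 0.012                    # fractional CI loss per cmH2O above PEEP 10
    # PaCO2 ratio to baseline at PEEP 10: the recruitment-driven CO2 washout
    # dip scales with the recruitable (shunted) lung, i.e. with severity.
    paco2_rm_floor: dict = field(default_factory=lambda: {
        "severe": 0.75, "moderate": 0.78, "mild": 0.82})
    paco2_rm_curvature: float = 0.0022         # quadratic hypercapnic rise per cmH2O^2
    venous_pressure: float = 8.0               # mmHg, Windkessel offset tying MAP to CI
    sao2_rm: float = 0.97                      # assumed SaO2 during the RM (FiO2 1.0)
    noise_sd: dict = field(default_factory=lambda: {
        "ci": 0.1, "paco2": 1.5, "map": 2.0, "svo2": 0.01})

    def validate(self) -> None:
        if self.n_severe + self.n_moderate + self.n_mild != self.n_patients:
            raise ConfigurationError("severity counts must sum to n_patients")
        if min(self.n_severe, self.n_moderate, self.n_mild) < 0 or self.n_patients <= 0:
            raise ConfigurationError("counts must be non-negative, n_patients > 0")
        for name, (_, sd) in self.distribution_params.items():
            if sd < 0:
                raise ConfigurationError(f"SD of {name} must be >= 0")
        ladder = np.asarray(self.rm_peep_ladder, dtype=float)
        if ladder.size and np.any(np.diff(ladder) <= 0):
            raise ConfigurationError("PEEP ladder must be strictly increasing")


@dataclass
class PatientDataset:
    """Clinical observations for one virtual patient (calibration targets).

    ``baseline`` holds the static targets: PF ratio and static compliance
    referenced to PEEP 10 cmH2O, PaCO2 / SvO2 / pH at the ventilation
    baseline (PEEP 5, plateau 30 cmH2O, FiO2 1.0).  ``rm_series`` holds the
    recruitment-maneuver responses across the PEEP ladder.
    """

    patient_id: str
    severity: str
    baseline: dict               # pf_ratio, paco2, svo2, cstat, ph
    rm_series: list              # [{peep, ci, paco2, map, svo2}, ...]
    hb: float = 10.5
    bsa: float = 1.8
    vr: float = 12.5
    vt_pbw: float = 5.9
    ideal_body_weight: float = 70.0

    def validate(self) -> None:
        pf = self.baseline["pf_ratio"]
        ok = {"severe": pf < 100.0,
              "moderate": 100.0 <= pf <= 200.0,
              "mild": pf > 200.0}[self.severity]
        if not ok:
            raise ValueError(f"{self.patient_id}: severity inconsistent with PF {pf}")
        if min(self.baseline["paco2"], self.baseline["cstat"], pf) <= 0:
            raise ValueError("pressures, tensions and compliances must be positive")
        if not 0.0 < self.baseline["svo2"] < 1.0:
            raise ValueError("SvO2 must lie in (0, 1)")
        for row in self.rm_series:
            if min(row["ci"], row["map"], row["paco2"]) <= 0:
                raise ValueError("RM series values must be positive")
            if not 0.0 < row["svo2"] < 1.0:
                raise ValueError("RM SvO2 must lie in (0, 1)")


@dataclass
class RiskTable:
    """Relative risk of death per (intervention, delta_p, peep) condition."""

    frame: pd.DataFrame   # columns: intervention_id, delta_p, peep, relative_risk

    def __post_init__(self):
        required = {"intervention_id", "delta_p", "peep", "relative_risk"}
        if not required.issubset(self.frame.columns):
            raise ConfigurationError(f"risk table must have columns {sorted(required)}")
        if (self.frame["relative_risk"] <= 0).any():
            raise ConfigurationError("relative risks must be positive")
        keys = self.frame[["intervention_id", "delta_p", "peep"]]
        if keys.duplicated().any():
            raise ConfigurationError("duplicate (intervention, delta_p, peep) rows")

    def risks_for(self, intervention_id: int, conditions) -> np.ndarray:
        sub = self.frame[self.frame["intervention_id"] == intervention_id]
        out = []
        for dp, peep in conditions:
            row = sub[(sub["delta_p"] == dp) & (sub["peep"] == peep)]
            if row.empty:
                raise KeyError(f"no risk entry for intervention {intervention_id}, "
                               f"dP={dp}, PEEP={peep}")
            out.append(float(row["relative_risk"].iloc[0]))
        return np.asarray(out)


def _draw(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float,
          size=None):
    """Truncated-normal draw; degenerates to the mean when sd == 0."""
    if sd == 0:
        return np.full(size, mean) if size else mean
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_patient(spec: CohortSpec, index: int, severity: str,
                     rng: np.random.Generator) -> PatientDataset:
    dp = spec.distribution_params
    tr = TRUNCATION

    def draw(name):
        return float(_draw(rng, *dp[name], *tr[name]))

    pf = float(_draw(rng, *dp[f"pf_{severity}"], *tr[f"pf_{severity}"]))
    paco2 = draw("paco2")
    ci0 = draw("ci")
    # SvO2 must be jointly feasible with the drawn PF and CI through the
    # Fick principle (SaO2 - VO2 / (1.34 Hb CO x 10)) for a physiological
    # VO2 range; truncate the draw to that interval.
    from .gas_exchange import severinghaus_sao2
    sao2_pf = float(severinghaus_sao2(pf))   # FiO2 1.0 -> PaO2 = PF ratio
    co0 = ci0 * spec.bsa
    denom = 1.34 * spec.hb * co0 * 10.0   # ml O2/min per unit of saturation
    sv_lo = max(TRUNCATION["svo2"][0], sao2_pf - 330.0 / denom)
    sv_hi = min(TRUNCATION["svo2"][1], sao2_pf - 130.0 / denom)
    if sv_lo >= sv_hi:
        sv_lo, sv_hi = TRUNCATION["svo2"]
    baseline = {
        "pf_ratio": pf,
        "paco2": paco2,
        "svo2": float(_draw(rng, *dp["svo2"], sv_lo, sv_hi)),
        "cstat": draw("cstat"),
        "ph": draw("ph"),
    }
    map0 = draw("map")
    svo2_0 = baseline["svo2"]
    pv = spec.venous_pressure
    nsd = spec.noise_sd
    rm = []
    for peep in spec.rm_peep_ladder:
        drop = max(0.0, peep - 10.0) * spec.ci_slope
        ci = ci0 * (1.0 - drop)
        # reflex-free Windkessel: MAP tracks CO around a fixed venous offset
        map_ = pv + (map0 - pv) * (ci / ci0)
        # Fick: the arteriovenous O2 difference scales inversely with CO
        svo2 = spec.sao2_rm - (spec.sao2_rm - svo2_0) * (ci0 / ci)
        # Fixed-dP PEEP stepping: effective alveolar ventilation first gains
        # from recruitment, then falls with overdistension -> convex
        # hypercapnic rise relative to baseline.
        d10 = peep - 10.0
        floor = spec.paco2_rm_floor[severity]
        paco2_rm = paco2 * (floor + spec.paco2_rm_curvature * d10 * d10)
        row = {
            "peep": float(peep),
            "ci": float(np.clip(ci + rng.normal(0, nsd["ci"]), 1.0, 9.0)),
            "paco2": float(np.clip(paco2_rm + rng.normal(0, nsd["paco2"]), 25, 130)),
            "map": float(np.clip(map_ + rng.normal(0, nsd["map"]), 40, 130)),
            "svo2": float(np.clip(svo2 + rng.normal(0, nsd["svo2"]), 0.30, 0.97)),
        }
        rm.append(row)
    ds = PatientDataset(
        patient_id=f"P{index + 1:02d}",
        severity=severity,
        baseline=baseline,
        rm_series=rm,
        hb=spec.hb,
        bsa=spec.bsa,
        vr=draw("vr"),
        vt_pbw=draw("vt_pbw"),
        ideal_body_weight=spec.ideal_body_weight,
    )
    ds.validate()
    return ds


def generate_cohort(spec: CohortSpec) -> list[PatientDataset]:
    """Generate the full cohort; deterministic for a given ``spec.seed``.

    Each patient is drawn from an independent child seed so that changing
    the cohort size does not reshuffle earlier patients.
    """
    spec.validate()
    severities = (["severe"] * spec.n_severe + ["moderate"] * spec.n_moderate
                  + ["mild"] * spec.n_mild)
    cohort = []
    for i, sev in enumerate(severities):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i]))
        cohort.append(generate_patient(spec, i, sev, rng))
    return cohort


def generate_risk_table(conditions_by_intervention: dict,
                        monotone_slope: float = 0.08,
                        noise: float = 0.0,
                        seed: int = 0) -> RiskTable:
    """Synthetic relative-risk table, affine in driving pressure.

    ``conditions_by_intervention`` maps intervention id to an ordered list of
    (delta_p, peep) pairs.  Risk = 1 + slope * (dP - mean dP) + noise, clipped
    to stay strictly positive.
    """
    if not conditions_by_intervention or not any(conditions_by_intervention.values()):
        raise ConfigurationError("condition list must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for iid, conditions in conditions_by_intervention.items():
        if not conditions:
            raise ConfigurationError(f"intervention {iid} has no conditions")
        dps = np.array([c[0] for c in conditions], dtype=float)
        base = 1.0 + monotone_slope * (dps - dps.mean())
        eps = rng.normal(0.0, noise, size=dps.size) if noise > 0 else np.zeros(dps.size)
        rr = np.maximum(base + eps, 0.05)
        for (dp, peep), r in zip(conditions, rr):
            rows.append({"intervention_id": iid, "delta_p": float(dp),
                         "peep": float(peep), "relative_risk": float(r)})
    return RiskTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# CSV round-trips
# ---------------------------------------------------------------------------

def cohort_to_frames(cohort: list[PatientDataset]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Baseline (wide) and RM-series (long) frames for a cohort."""
    base_rows, rm_rows = [], []
    for p in cohort:
        row = {"patient_id": p.patient_id, "severity": p.severity, "hb": p.hb,
               "bsa": p.bsa, "vr": p.vr, "vt_pbw": p.vt_pbw,
               "ideal_body_weight": p.ideal_body_weight}
        row.update(p.baseline)
        base_rows.append(row)
        for r in p.rm_series:
            for var in ("ci", "paco2", "map", "svo2"):
                rm_rows.append({"patient_id": p.patient_id, "peep": r["peep"],
                                "variable": var, "value": r[var]})
    return pd.DataFrame(base_rows), pd.DataFrame(rm_rows)


def frames_to_cohort(baseline: pd.DataFrame, rm: pd.DataFrame) -> list[PatientDataset]:
    cohort = []
    for _, row in baseline.iterrows():
        pid = row["patient_id"]
        sub = rm[rm["patient_id"] == pid]
        series = []
        for peep, grp in sub.groupby("peep", sort=True):
            entry = {"peep": float(peep)}
            entry.update({r["variable"]: float(r["value"]) for _, r in grp.iterrows()})
            series.append(entry)
        cohort.append(PatientDataset(
            patient_id=pid, severity=row["severity"],
            baseline={k: float(row[k]) for k in
                      ("pf_ratio", "paco2", "svo2", "cstat", "ph")},
            rm_series=series, hb=float(row["hb"]), bsa=float(row["bsa"]),
            vr=float(row["vr"]), vt_pbw=float(row["vt_pbw"]),
            ideal_body_weight=float(row["ideal_body_weight"]),
        ))
    return cohort


def write_cohort(cohort: list[PatientDataset], out_dir, spec: CohortSpec | None = None):
    """Write baseline/RM CSVs plus a sidecar metadata JSON recording the seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base, rm = cohort_to_frames(cohort)
    base.to_csv(out / "cohort_baseline.csv", index=False)
    rm.to_csv(out / "cohort_rm_series.csv", index=False)
    meta = {"n_patients": len(cohort)}
    if spec is not None:
        meta["spec"] = {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(spec).items()}
        meta["seed"] = spec.seed
    (out / "cohort_meta.json").write_text(json.dumps(meta, indent=1, default=str))
    return out / "cohort_baseline.csv", out / "cohort_rm_series.csv"


def read_cohort(out_dir) -> list[PatientDataset]:
    out = Path(out_dir)
    base_path = out / "cohort_baseline.csv"
    rm_path = out / "cohort_rm_series.csv"
    for path in (base_path, rm_path):
        if not path.exists():
            raise FileNotFoundError(f"missing cohort stage output: {path}")
    try:
        return frames_to_cohort(pd.read_csv(base_path), pd.read_csv(rm_path))
    except (KeyError, ValueError) as exc:
        raise ConfigurationError(f"corrupt cohort files in {out}: {exc}") from exc
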