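"""Driving-pressure / PEEP intervention sweeps over a calibrated cohort.

Three intervention families mirror the epidemiological re-analysis the
study pairs with:

1. vary driving pressure at constant PEEP,
2. vary PEEP at constant driving pressure,
3. raise PEEP while lowering driving pressure.

Each calibrated patient is simulated to steady state at every condition
(respiratory rate and I:E ratio held at their calibration baseline), the
full VILI index set is computed against a per-patient FRC reference taken
once at PEEP 0, and cohort mean +/- SD per condition is correlated with a
relative-risk-of-death table.  An index is flagged "strong" at r > 0.85
with p < 0.05 (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ConfigurationError, RiskTable
from .indices import FRCReference, compute_index_set
from .simulator import (CardioPulmonarySimulator, SimConfig, VentilatorSettings,
                        VirtualPatient)
from .stats import pearson

STRONG_R = 0.85
STRONG_P = 0.05

#: Indices carried into the condition and correlation tables.
SWEEP_INDICES = (
    "dynamic_strain", "mechanical_power", "tidal_recruitment",
    "mean_alveolar_pressure", "c_rs", "static_strain", "do2", "co", "ci",
    "pf_ratio", "vd_vt", "r_aw", "paco2", "svo2", "shunt_fraction",
)

#: Baseline driving pressure (cmH2O) used for the FRC reference breath.
FRC_DELTA_P = 25.0


@dataclass
class InterventionGrid:
    """Ordered (delta_p, peep) conditions of one intervention."""

    intervention_id: int
    conditions: list            # [(delta_p, peep), ...] in cmH2O

    def __post_init__(self):
        if not self.conditions:
            raise ConfigurationError("intervention grid has no conditions")
        dps = [c[0] for c in self.conditions]
        peeps = [c[1] for c in self.conditions]
        if self.intervention_id == 1 and len(set(peeps)) != 1:
            raise ConfigurationError("intervention 1 requires constant PEEP")
        if self.intervention_id == 2 and len(set(dps)) != 1:
            raise ConfigurationError("intervention 2 requires constant delta_p")
        if self.intervention_id == 3:
            if not (np.all(np.diff(peeps) > 0) and np.all(np.diff(dps) < 0)):
                raise ConfigurationError(
                    "intervention 3 requires increasing PEEP and decreasing delta_p")


def default_grids() -> dict[int, InterventionGrid]:
    """Default condition grids (anchor pressures from the study text)."""
    return {
        1: InterventionGrid(1, [(dp, 8.0) for dp in (12.0, 15.0, 18.0, 21.0, 24.0)]),
        2: InterventionGrid(2, [(15.0, p) for p in (5.0, 8.0, 11.0, 14.0, 17.0)]),
        3: InterventionGrid(3, [(21.0, 5.0), (18.0, 8.0), (15.0, 11.0), (12.0, 14.0)]),
    }


def compute_frc_reference(patient: VirtualPatient,
                          sim_config: SimConfig | None = None,
                          delta_p: float = FRC_DELTA_P) -> FRCReference:
    """End-expiratory volume at PEEP 0 under the baseline driving pressure."""
    sim = CardioPulmonarySimulator(patient, sim_config)
    mech = sim.mechanics(VentilatorSettings(0.0, delta_p, patient.vr, patient.ie, 1.0))
    return FRCReference(patient_id=patient.patient_id,
                        v_frc=float(mech.v_exp.sum()),
                        v_alv_exp0=mech.v_exp.copy())


def run_intervention(cohort: list[VirtualPatient], grid: InterventionGrid,
                     frc_refs: dict[str, FRCReference] | None = None,
                     sim_config: SimConfig | None = None) -> pd.DataFrame:
    """Simulate every patient at every condition; one IndexSet per cell.

    The FRC reference is computed exactly once per patient (at PEEP 0) and
    shared across conditions so strains are comparable; pass ``frc_refs`` to
    reuse references across interventions.  Non-converged runs are flagged
    via the ``converged`` column, never dropped.
    """
    if not cohort:
        raise ConfigurationError("empty cohort")
    frc_refs = frc_refs if frc_refs is not None else {}
    rows = []
    for patient in cohort:
        if patient.patient_id not in frc_refs:
            frc_refs[patient.patient_id] = compute_frc_reference(patient, sim_config)
        frc = frc_refs[patient.patient_id]
        sim = CardioPulmonarySimulator(patient, sim_config)
        for dp, peep in grid.conditions:
            vent = VentilatorSettings(peep, peep + dp, patient.vr, patient.ie, 1.0)
            state, breath = sim.simulate(vent)
            idx = compute_index_set(patient.patient_id, state, breath, frc,
                                    patient.hb)
            row = idx.as_dict()
            # key by the prescribed condition (measured values stay in the set)
            row["delta_p"] = dp
            row["peep"] = peep
            row["intervention_id"] = grid.intervention_id
            rows.append(row)
    return pd.DataFrame(rows)


def correlate(index_means, risks) -> tuple[float, float]:
    """Pearson r between cohort index means and relative risks, with the
    two-sided p-value from the t distribution (n-2 df).

    Zero variance in either vector yields (nan, nan) — undefined, reported
    explicitly.
    """
    return pearson(index_means, risks)


@dataclass
class InterventionResults:
    """Cohort summary per condition plus correlations against a risk table."""

    condition_table: pd.DataFrame     # intervention, delta_p, peep, index, mean, sd
    correlation_table: pd.DataFrame   # intervention, index, r, p, strong
    per_patient: pd.DataFrame

    def summary(self) -> str:
        lines = ["Intervention sweep summary", "=" * 64]
        for iid, grp in self.correlation_table.groupby("intervention_id"):
            lines.append(f"intervention {iid}: "
                         f"{len(self.condition_table[self.condition_table.intervention_id == iid].groupby(['delta_p', 'peep']))} conditions")
            lines.append(f"{'index':<24}{'r':>8}{'p':>12}  strong")
            for _, r in grp.sort_values("r", ascending=False).iterrows():
                rs = "nan" if np.isnan(r["r"]) else f"{r['r']:8.3f}"
                ps = "nan" if np.isnan(r["p"]) else f"{r['p']:12.3g}"
                lines.append(f"{r['index']:<24}{rs:>8}{ps:>12}  "
                             f"{'yes' if r['strong'] else 'no'}")
            lines.append("-" * 64)
        return "\n".join(lines)


def summarize(per_patient: pd.DataFrame, risk_table: RiskTable | None = None,
              indices: tuple = SWEEP_INDICES) -> InterventionResults:
    """Condition-level mean +/- SD tables and risk correlations per index."""
    cond_rows = []
    corr_rows = []
    for iid, grp in per_patient.groupby("intervention_id"):
        conditions = list(dict.fromkeys(zip(grp["delta_p"], grp["peep"])))
        means = {name: [] for name in indices}
        for dp, peep in conditions:
            cell = grp[(grp["delta_p"] == dp) & (grp["peep"] == peep)]
            for name in indices:
                vals = cell[name].to_numpy(dtype=float)
                cond_rows.append({
                    "intervention_id": iid, "delta_p": dp, "peep": peep,
                    "index": name, "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "n": int(vals.size),
                })
                means[name].append(float(vals.mean()))
        if risk_table is not None:
            risks = risk_table.risks_for(iid, conditions)
            for name in indices:
                r, p = correlate(means[name], risks)
                strong = bool(np.isfinite(r) and r > STRONG_R
                              and np.isfinite(p) and p < STRONG_P)
                corr_rows.append({"intervention_id": iid, "index": name,
                                  "r": r, "p": p, "strong": strong})
    return InterventionResults(
        condition_table=pd.DataFrame(cond_rows),
        correlation_table=pd.DataFrame(corr_rows),
        per_patient=per_patient,
    )


class InterventionStudy:
    """Sweep a calibrated cohort over intervention grids (model object)."""

    def __init__(self, cohort: list[VirtualPatient],
                 grids: dict[int, InterventionGrid] | None = None,
                 risk_table: RiskTable | None = None,
                 sim_config: SimConfig | None = None):
        if not cohort:
            raise ConfigurationError("empty cohort")
        self.cohort = cohort
        self.grids = grids or default_grids()
        if not self.grids:
            raise ConfigurationError("no intervention grids")
        self.risk_table = risk_table
        self.sim_config = sim_config
        self.frc_refs: dict[str, FRCReference] = {}

    def run(self) -> InterventionResults:
        frames = []
        for grid in self.grids.values():
            frames.append(run_intervention(self.cohort, grid, self.frc_refs,
                                           self.sim_config))
        per_patient = pd.concat(frames, ignore_index=True)
        return summarize(per_patient, self.risk_table)
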