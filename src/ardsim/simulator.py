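"""Integrated cardiopulmonary simulation of one virtual ARDS patient.

One :func:`CardioPulmonarySimulator.simulate` call runs pressure-controlled
ventilation at a given PEEP / inspiratory-pressure setting to a periodic
steady state and returns the converged physiological state together with
the fully-resolved final breath.  The coupling chain is

    lung mechanics  ->  breath-mean alveolar pressure
                    ->  pleural pressure (configurable transmission)
                    ->  pulsatile circulation (cardiac output, MAP, MPAP)
                    ->  steady-state gas exchange with HPV

Steady state: breath-to-breath change in tidal volume and end-expiratory
volume below 0.5% for the mechanics, stroke-volume periodicity for the
circulation, and a converged venous fixed point for gas exchange.
Non-convergence is flagged on the returned state, never silent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .circulation import CardioParams, simulate_circulation
from .gas_exchange import steady_state_gas_exchange
from .mechanics import LungParams, MechanicsResult, simulate_mechanics
from .units import cmh2o_to_mmhg


@dataclass
class VentilatorSettings:
    """Pressure-controlled ventilation settings.

    ``p_insp`` is the applied inspiratory (plateau-target) pressure; the
    driving pressure is ``p_insp - peep``.
    """

    peep: float                 # cmH2O
    p_insp: float               # cmH2O
    vr: float = 12.5            # breaths/min
    ie: float = 0.5             # inspiratory:expiratory time ratio
    fio2: float = 1.0

    def __post_init__(self):
        if self.peep < 0 or self.p_insp < self.peep:
            raise ValueError("require p_insp >= peep >= 0")
        if self.vr <= 0 or self.ie <= 0:
            raise ValueError("respiratory rate and I:E ratio must be positive")
        if not 0.21 <= self.fio2 <= 1.0:
            raise ValueError("FiO2 must lie in [0.21, 1.0]")

    @property
    def delta_p(self) -> float:
        return self.p_insp - self.peep


@dataclass
class VirtualPatient:
    """A calibrated simulator parameter set for one patient."""

    patient_id: str
    lung: LungParams
    cardio: CardioParams
    hb: float = 10.5            # g/dl
    bsa: float = 1.8            # m^2
    vr: float = 12.5            # baseline respiratory rate
    ie: float = 0.5             # baseline I:E ratio
    vo2: float = 250.0          # ml/min
    vco2: float = 200.0         # ml/min
    hco3: float = 24.0          # mmol/L
    severity: str = "unknown"
    diagnostics: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "patient_id": self.patient_id,
            "hb": self.hb, "bsa": self.bsa, "vr": self.vr, "ie": self.ie,
            "vo2": self.vo2, "vco2": self.vco2, "hco3": self.hco3,
            "severity": self.severity,
            "diagnostics": self.diagnostics,
            "cardio": asdict(self.cardio),
            "lung": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                     for k, v in asdict(self.lung).items()},
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "VirtualPatient":
        d = json.loads(text)
        lung_d = {k: (np.asarray(v) if isinstance(v, list) else v)
                  for k, v in d.pop("lung").items()}
        cardio = CardioParams(**d.pop("cardio"))
        return cls(lung=LungParams(**lung_d), cardio=cardio, **d)


@dataclass
class PhysioState:
    """Steady-state physiological variables for one ventilator condition."""

    pao2: float
    paco2: float
    ph: float
    sao2: float
    svo2: float
    co: float                  # L/min
    ci: float                  # L/min/m^2
    map: float                 # mmHg
    mpap: float                # mmHg
    shunt_fraction: float
    peco2: float
    pf_ratio: float
    pit_mmhg: float
    v_alv: np.ndarray          # end-expiratory compartment volumes, ml
    p_alv: np.ndarray          # end-expiratory compartment pressures, cmH2O
    converged: bool = True
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.sao2 <= 1.0 and 0.0 <= self.svo2 <= 1.0):
            raise ValueError("saturations must lie in [0, 1]")
        if not 6.5 < self.ph < 7.9:
            self.flags["ph_out_of_range"] = self.ph


@dataclass
class BreathRecord:
    """Per-compartment and ventilator-side record of one steady-state breath."""

    v_alv_insp: np.ndarray
    v_alv_exp: np.ndarray
    p_alv_insp: np.ndarray
    p_alv_exp: np.ndarray
    open_insp: np.ndarray
    open_exp: np.ndarray
    p_peak: float
    p_plat: float
    peep_total: float
    v_t: float
    t_insp: float
    vr: float
    ie: float
    series: dict
    ventilated_insp: np.ndarray = None
    ventilated_exp: np.ndarray = None

    def __post_init__(self):
        vt = max(self.v_t, 1e-12)
        n = self.v_alv_insp.size
        dv = self.v_alv_insp - self.v_alv_exp
        flow_ok = dv > 0.01 * vt / n
        if self.ventilated_insp is None:
            self.ventilated_insp = self.open_insp & flow_ok
        if self.ventilated_exp is None:
            self.ventilated_exp = self.open_exp & flow_ok

    @property
    def ventilated_fraction_insp(self) -> float:
        return float(self.ventilated_insp.mean())

    @property
    def ventilated_fraction_exp(self) -> float:
        return float(self.ventilated_exp.mean())


def write_breath_series(breath: BreathRecord, series_path, summary_path=None):
    """Write the final breath's 10-ms record as long-format CSV
    (time_s, variable, value), plus an optional one-row breath summary."""
    import pandas as pd

    frames = []
    for var, values in breath.series.items():
        if var == "time_s":
            continue
        frames.append(pd.DataFrame({
            "time_s": breath.series["time_s"], "variable": var,
            "value": values}))
    pd.concat(frames, ignore_index=True).to_csv(series_path, index=False)
    if summary_path is not None:
        pd.DataFrame([{
            "v_t": breath.v_t, "p_peak": breath.p_peak,
            "p_plat": breath.p_plat, "peep_total": breath.peep_total,
            "t_insp": breath.t_insp, "vr": breath.vr, "ie": breath.ie,
            "ventilated_fraction_insp": breath.ventilated_fraction_insp,
            "ventilated_fraction_exp": breath.ventilated_fraction_exp,
        }]).to_csv(summary_path, index=False)
    return series_path


@dataclass
class SimConfig:
    dt: float = 1e-3               # s, internal integration step
    record_dt: float = 1e-2        # s, recording resolution
    max_breaths: int = 300
    mech_tol: float = 0.005
    circ_max_beats: int = 120
    circ_tol: float = 1e-3
    rq_floor: float = 1.0          # clamp on alveolar PO2, mmHg


class CardioPulmonarySimulator:
    """Pressure-controlled ventilation of one virtual patient."""

    def __init__(self, patient: VirtualPatient, config: SimConfig | None = None):
        self.patient = patient
        self.config = config or SimConfig()

    def simulate(self, vent: VentilatorSettings,
                 n_breaths: int | None = None) -> tuple[PhysioState, BreathRecord]:
        """Run to steady state; returns the state and the final breath.

        ``n_breaths`` caps the number of simulated breaths (default: the
        configured maximum of 300).  If any stage fails to converge the
        returned state carries ``converged=False`` plus diagnostics in
        ``flags`` — never a silent failure.
        """
        cfg = self.config
        pat = self.patient
        if n_breaths is not None and n_breaths < 1:
            raise ValueError("n_breaths must be >= 1")
        mech = simulate_mechanics(
            pat.lung, vent.peep, vent.p_insp, vent.vr, vent.ie,
            dt=cfg.dt, record_dt=cfg.record_dt,
            max_breaths=n_breaths or cfg.max_breaths, conv_tol=cfg.mech_tol,
        )
        pit = cmh2o_to_mmhg(pat.cardio.pleural_transmission * mech.mean_palv)
        circ = simulate_circulation(
            pat.cardio, pit_mmhg=pit, dt=cfg.dt,
            max_beats=cfg.circ_max_beats, conv_tol=cfg.circ_tol,
        )
        gas = steady_state_gas_exchange(
            mech.dv, vent.vr, pat.lung.vd_ml, vent.fio2, pat.hb, circ.co,
            pat.lung.q_weights, vo2=pat.vo2, vco2=pat.vco2, hco3=pat.hco3,
            hpv_gain=pat.cardio.hpv_gain,
        )
        flags = {}
        if not mech.converged:
            flags["mechanics_not_converged"] = mech.n_breaths
        if not circ.converged:
            flags["circulation_not_converged"] = circ.n_beats
        if not gas.converged:
            flags["gas_exchange_not_converged"] = gas.iterations

        state = PhysioState(
            pao2=gas.pao2, paco2=gas.paco2, ph=gas.ph, sao2=gas.sao2,
            svo2=gas.svo2, co=circ.co, ci=circ.co / pat.bsa, map=circ.map,
            mpap=circ.mpap, shunt_fraction=gas.shunt_fraction,
            peco2=gas.peco2, pf_ratio=gas.pao2 / vent.fio2, pit_mmhg=pit,
            v_alv=mech.v_exp, p_alv=mech.p_exp_alv,
            converged=not flags, flags=flags,
        )
        breath = BreathRecord(
            v_alv_insp=mech.v_insp, v_alv_exp=mech.v_exp,
            p_alv_insp=mech.p_insp_alv, p_alv_exp=mech.p_exp_alv,
            open_insp=mech.open_insp, open_exp=mech.open_exp,
            p_peak=mech.p_peak, p_plat=mech.p_plat, peep_total=vent.peep,
            v_t=mech.vt, t_insp=mech.t_insp, vr=vent.vr, ie=vent.ie,
            series=mech.series,
        )
        return state, breath

    def mechanics(self, vent: VentilatorSettings) -> MechanicsResult:
        """Lung mechanics only (used to cache breaths during calibration)."""
        cfg = self.config
        return simulate_mechanics(
            self.patient.lung, vent.peep, vent.p_insp, vent.vr, vent.ie,
            dt=cfg.dt, record_dt=cfg.record_dt, max_breaths=cfg.max_breaths,
            conv_tol=cfg.mech_tol,
        )
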