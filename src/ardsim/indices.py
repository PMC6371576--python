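"""Physiological variables and ventilator-induced lung injury (VILI) indices.

All quantities are computed from a steady-state breath record and the
associated physiological state:

- respiratory-system compliance  C_RS = VT / (Pplat - PEEP)
- dynamic strain = dV / V_frc, static strain = V_alv_exp / V_frc, with
  V_frc the total end-expiratory volume at PEEP 0
- intra-tidal recruitment = percentage of the lung ventilated at
  end-inspiration but not at end-expiration
- mean alveolar pressure = mean of the highest 20% of end-inspiratory
  compartment pressures
- mechanical power (J/min):
    0.098 * VR * { VT^2 [E/2 + VR (1+IE)/(60 IE) * Raw] + VT * PEEP }
  with VT in L, E = 1/C_RS in cmH2O/L, Raw = (Ppeak - Pplat)/(VT/Tinsp)
- oxygen delivery DO2 = CO * (1.34 Hb SaO2 + 0.003 PaO2) * 10
- physiological deadspace fraction (Bohr-Enghoff)
  VD/VT = (PaCO2 - PECO2) / PaCO2
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .simulator import BreathRecord, PhysioState

POWER_CONSTANT = 0.098  # J per L.cmH2O


class UndefinedIndexError(ValueError):
    """Raised when an index is undefined for the given inputs."""


@dataclass
class FRCReference:
    """Functional residual capacity reference (end-expiratory state at PEEP 0)."""

    patient_id: str
    v_frc: float                  # ml
    v_alv_exp0: np.ndarray        # per-compartment, ml

    def __post_init__(self):
        if self.v_frc <= 0:
            raise ValueError("FRC must be positive")


def c_rs(v_t: float, p_plat: float, peep: float) -> float:
    """Respiratory-system compliance, ml/cmH2O."""
    if p_plat <= peep:
        raise UndefinedIndexError("C_RS undefined for p_plat <= peep")
    return v_t / (p_plat - peep)


def dynamic_strain(v_t: float, frc: FRCReference) -> float:
    return v_t / frc.v_frc


def static_strain(v_alv_exp_total: float, frc: FRCReference) -> float:
    return v_alv_exp_total / frc.v_frc


def tidal_recruitment(breath: BreathRecord) -> float:
    """Percent of total lung cycling between ventilated and unventilated."""
    fi = breath.ventilated_fraction_insp
    fe = breath.ventilated_fraction_exp
    if not (0.0 <= fi <= 1.0 and 0.0 <= fe <= 1.0):
        raise ValueError("ventilated fractions must lie in [0, 1]")
    return max(100.0 * (fi - fe), 0.0)


def recruitment_fraction(before: BreathRecord, after: BreathRecord) -> float:
    """Fraction of alveoli unventilated before that achieve ventilation after."""
    silent_before = ~(before.ventilated_insp | before.ventilated_exp)
    ventilated_after = after.ventilated_insp | after.ventilated_exp
    return float((silent_before & ventilated_after).sum() / silent_before.size)


def mean_alveolar_pressure(breath_or_pressures) -> float:
    """Mean of the highest 20% of end-inspiratory alveolar pressures, cmH2O."""
    p = (breath_or_pressures.p_alv_insp
         if isinstance(breath_or_pressures, BreathRecord)
         else np.asarray(breath_or_pressures, dtype=float))
    if p.size < 5:
        raise ValueError("need at least 5 compartments")
    k = max(int(round(0.2 * p.size)), 1)
    return float(np.sort(p)[-k:].mean())


def mechanical_power(vr: float, v_t: float, e: float, ie: float,
                     r_aw: float, peep: float) -> float:
    """Mechanical power of ventilation, J/min (VT in L, E in cmH2O/L)."""
    if ie <= 0:
        raise UndefinedIndexError("I:E ratio must be positive")
    if min(vr, v_t, e, r_aw, peep) < 0:
        raise ValueError("inputs must be non-negative")
    resistive = vr * (1.0 + ie) / (60.0 * ie) * r_aw
    return POWER_CONSTANT * vr * (v_t**2 * (e / 2.0 + resistive) + v_t * peep)


def r_aw(p_peak: float, p_plat: float, v_t: float, t_insp: float) -> float:
    """Airway resistance from the peak-plateau difference, cmH2O.s/L (VT in L)."""
    if v_t <= 0 or t_insp <= 0:
        raise UndefinedIndexError("require positive tidal volume and t_insp")
    if p_peak < p_plat:
        raise ValueError("p_peak must be >= p_plat")
    return (p_peak - p_plat) / (v_t / t_insp)


def do2(co: float, sao2: float, pao2: float, hb: float) -> float:
    """Oxygen delivery, ml O2/min (CO in L/min, Hb in g/dl)."""
    if min(co, sao2, pao2, hb) < 0:
        raise ValueError("inputs must be non-negative")
    return co * (1.34 * hb * sao2 + 0.003 * pao2) * 10.0


def vd_vt(paco2: float, peco2: float) -> float:
    """Bohr-Enghoff physiological deadspace fraction."""
    if paco2 <= 0 or not 0.0 <= peco2 <= paco2:
        raise UndefinedIndexError("require paco2 > 0 and 0 <= peco2 <= paco2")
    return (paco2 - peco2) / paco2


@dataclass
class IndexSet:
    """All reported indices for one patient under one ventilator condition."""

    patient_id: str
    delta_p: float
    peep: float
    c_rs: float                 # ml/cmH2O
    elastance: float            # cmH2O/L
    dynamic_strain: float
    static_strain: float
    tidal_recruitment: float    # % of total lung
    mean_alveolar_pressure: float
    mechanical_power: float     # J/min
    r_aw: float                 # cmH2O.s/L
    do2: float                  # ml/min
    pf_ratio: float
    vd_vt: float
    ci: float
    co: float
    map: float
    mpap: float
    pao2: float
    paco2: float
    ph: float
    sao2: float
    svo2: float
    shunt_fraction: float
    v_t: float                  # ml
    converged: bool = True

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_index_set(
    patient_id: str,
    state: PhysioState,
    breath: BreathRecord,
    frc: FRCReference,
    hb: float,
) -> IndexSet:
    """Assemble the full index set from one simulated steady state."""
    dp = breath.p_plat - breath.peep_total
    if dp > 1e-9 and breath.v_t > 1e-9:
        crs = c_rs(breath.v_t, breath.p_plat, breath.peep_total)
        elast = 1000.0 / crs  # cmH2O/L from ml/cmH2O
        raw = r_aw(breath.p_peak, breath.p_plat, breath.v_t / 1000.0, breath.t_insp)
    else:
        crs, elast, raw = 0.0, 0.0, 0.0
    vt_l = breath.v_t / 1000.0
    power = mechanical_power(breath.vr, vt_l, elast, breath.ie, raw,
                             breath.peep_total) if vt_l > 0 else 0.0
    return IndexSet(
        patient_id=patient_id,
        delta_p=dp,
        peep=breath.peep_total,
        c_rs=crs,
        elastance=elast,
        dynamic_strain=dynamic_strain(breath.v_t, frc),
        static_strain=static_strain(float(breath.v_alv_exp.sum()), frc),
        tidal_recruitment=tidal_recruitment(breath),
        mean_alveolar_pressure=mean_alveolar_pressure(breath),
        mechanical_power=power,
        r_aw=raw,
        do2=do2(state.co, state.sao2, state.pao2, hb),
        pf_ratio=state.pf_ratio,
        vd_vt=vd_vt(state.paco2, state.peco2),
        ci=state.ci,
        co=state.co,
        map=state.map,
        mpap=state.mpap,
        pao2=state.pao2,
        paco2=state.paco2,
        ph=state.ph,
        sao2=state.sao2,
        svo2=state.svo2,
        shunt_fraction=state.shunt_fraction,
        v_t=breath.v_t,
        converged=state.converged,
    )
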