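"""Steady-state pulmonary gas exchange over parallel alveolar compartments.

Each ventilated compartment is treated as an ideal alveolar unit: its CO2
tension follows from a ventilation/perfusion mass balance, its O2 tension
from the alveolar gas equation, and its end-capillary blood is equilibrated
with alveolar gas.  Arterial blood is the perfusion-weighted mixture of
end-capillary blood from ventilated units and mixed-venous blood passing
unventilated (shunt) units; mixed-venous composition closes the loop through
the Fick principle at fixed metabolic rates.  Hypoxic pulmonary
vasoconstriction (HPV) scales peri-alveolar vascular resistance with local
alveolar PO2, redistributing perfusion away from hypoxic regions.

Closures used:
- O2 dissociation: Severinghaus (1979), SaO2 = (23400/(P^3 + 150 P) + 1)^-1.
- O2 content: 1.34 * Hb * SaO2 + 0.003 * PaO2  (ml O2 per dl).
- CO2 content: linearised around the operating point, C = 28 + 0.5 * PCO2.
- pH: Henderson-Hasselbalch at fixed bicarbonate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .units import P_BAROMETRIC, P_H2O

O2_HB_CAPACITY = 1.34   # ml O2 per g Hb
O2_SOLUBILITY = 0.003   # ml O2 / dl / mmHg
CCO2_SLOPE = 0.5        # ml CO2 / dl / mmHg (linearised dissociation curve)
CCO2_INTERCEPT = 28.0   # ml CO2 / dl


def severinghaus_sao2(po2):
    """Fractional haemoglobin O2 saturation for PO2 in mmHg."""
    po2 = np.maximum(np.asarray(po2, dtype=float), 1e-9)
    return 1.0 / (1.0 + 23400.0 / (po2**3 + 150.0 * po2))


def severinghaus_p50() -> float:
    """PO2 at half saturation of the Severinghaus curve (mmHg)."""
    return brentq(lambda p: severinghaus_sao2(p) - 0.5, 1.0, 200.0, xtol=1e-12)


def o2_content(po2, hb: float):
    """Blood O2 content (ml/dl) at tension ``po2`` mmHg and Hb in g/dl."""
    return O2_HB_CAPACITY * hb * severinghaus_sao2(po2) + O2_SOLUBILITY * np.asarray(po2)


def po2_from_content(content: float, hb: float) -> float:
    """Invert :func:`o2_content`; clamps to the physical range."""
    lo, hi = 1e-6, 2000.0
    cmax = o2_content(hi, hb)
    if content >= cmax:
        return hi
    if content <= o2_content(lo, hb):
        return lo
    return brentq(lambda p: o2_content(p, hb) - content, lo, hi, xtol=1e-10)


def co2_content(pco2):
    return CCO2_INTERCEPT + CCO2_SLOPE * np.asarray(pco2)


def pco2_from_content(content):
    return (np.asarray(content) - CCO2_INTERCEPT) / CCO2_SLOPE


def alveolar_po2(fio2: float, paco2, rq: float = 0.8, pb: float = P_BAROMETRIC):
    """Alveolar gas equation, mmHg."""
    return np.maximum(fio2 * (pb - P_H2O) - np.asarray(paco2) / rq, 1.0)


def ph_henderson(paco2, hco3: float):
    """Arterial pH from the Henderson-Hasselbalch relation."""
    return 6.1 + np.log10(hco3 / (0.03 * np.asarray(paco2)))


def hco3_for_ph(paco2: float, ph: float) -> float:
    """Bicarbonate (mmol/L) giving pH ``ph`` at tension ``paco2``."""
    return 0.03 * paco2 * 10.0 ** (ph - 6.1)


def hpv_scale(pao2_alv, gain: float, midpoint: float = 40.0, width: float = 8.0):
    """Vascular-resistance scaling by hypoxic pulmonary vasoconstriction.

    Logistic in local alveolar PO2: tends to 1 at high PO2 (no constriction)
    and to ``1 + gain`` under anoxia; equals ``1 + gain/2`` at ``midpoint``.
    Monotonically non-increasing in PO2.
    """
    z = (np.asarray(pao2_alv, dtype=float) - midpoint) / width
    return 1.0 + gain / (1.0 + np.exp(np.clip(z, -50.0, 50.0)))


@dataclass
class GasExchangeResult:
    pao2: float
    paco2: float
    ph: float
    sao2: float
    svo2: float
    pvo2: float
    peco2: float
    shunt_fraction: float
    perfusion: np.ndarray          # ml blood /min per compartment
    alv_po2: np.ndarray            # per-compartment alveolar PO2 (mmHg)
    alv_pco2: np.ndarray
    ventilated: np.ndarray         # bool mask
    converged: bool
    iterations: int


def steady_state_gas_exchange(
    dv_ml: np.ndarray,
    vr: float,
    vd_ml: float,
    fio2: float,
    hb: float,
    co_l_min: float,
    q_weights: np.ndarray,
    vo2: float = 250.0,
    vco2: float = 200.0,
    hco3: float = 24.0,
    hpv_gain: float = 1.0,
    pb: float = P_BAROMETRIC,
    ventilation_floor: float = 0.01,
    max_iter: int = 120,
    tol: float = 1e-9,
) -> GasExchangeResult:
    """Solve the coupled O2/CO2 steady state for one ventilator condition.

    Parameters
    ----------
    dv_ml : per-compartment tidal volume change (ml/breath).
    vr : respiratory rate (breaths/min).
    vd_ml : series (anatomical + apparatus) deadspace, ml.
    q_weights : baseline perfusion conductances (inverse peri-alveolar
        vascular resistance), arbitrary units; HPV rescales them.
    vo2, vco2 : whole-body O2 uptake and CO2 production, ml/min.
    ventilation_floor : a compartment is "ventilated" when its tidal volume
        exceeds this fraction of the mean per-compartment tidal volume.

    Negative per-compartment flows are rejected.
    """
    dv_ml = np.asarray(dv_ml, dtype=float)
    if np.any(dv_ml < -1e-9):
        raise ValueError("negative per-compartment tidal volume")
    q_weights = np.asarray(q_weights, dtype=float)
    n = dv_ml.size
    vt = float(dv_ml.sum())
    rq = vco2 / vo2

    ventilated = dv_ml > ventilation_floor * max(vt, 1e-12) / n
    if vt <= vd_ml or not ventilated.any():
        ventilated = np.zeros(n, dtype=bool)

    # Alveolar (deadspace-corrected) ventilation per compartment, ml/min.
    va = np.zeros(n)
    if ventilated.any():
        alv_frac = max(1.0 - vd_ml / vt, 0.0)
        va[ventilated] = vr * dv_ml[ventilated] * alv_frac

    pio2 = fio2 * (pb - P_H2O)
    # Initial guesses: normal-ish mixed venous blood.
    cv_o2 = o2_content(40.0, hb)
    cv_co2 = co2_content(46.0)
    co_ml = co_l_min * 1000.0

    alv_pco2 = np.full(n, 45.0)
    alv_po2 = np.full(n, pio2)
    q = np.full(n, co_ml / n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # HPV acts on local alveolar PO2; unventilated units see venous PO2.
        pvo2 = po2_from_content(max(cv_o2, 1e-6), hb)
        local_po2 = np.where(ventilated, alv_po2, pvo2)
        scale = hpv_scale(local_po2, hpv_gain)
        cond = q_weights / scale
        q = co_ml * cond / cond.sum()

        # Per-unit CO2 balance with linearised blood CO2 content:
        #   va * PACO2 / (pb - 47) = q/100 * (CvCO2 - (int + slope * PACO2))
        qdl = q / 100.0  # dl blood per min
        denom = va / (pb - P_H2O) + qdl * CCO2_SLOPE
        with np.errstate(divide="ignore", invalid="ignore"):
            pa = qdl * (cv_co2 - CCO2_INTERCEPT) / np.where(denom > 0, denom, 1.0)
        alv_pco2 = np.where(ventilated, np.clip(pa, 0.0, 120.0), np.nan)
        alv_po2 = np.where(
            ventilated, np.maximum(pio2 - alv_pco2 / rq, 1.0), np.nan
        )

        cc_o2 = np.where(ventilated, o2_content(np.nan_to_num(alv_po2), hb), cv_o2)
        cc_co2 = np.where(ventilated, co2_content(np.nan_to_num(alv_pco2)), cv_co2)

        ca_o2 = float((q * cc_o2).sum() / co_ml)
        ca_co2 = float((q * cc_co2).sum() / co_ml)

        new_cv_o2 = ca_o2 - vo2 / (co_ml / 100.0)
        new_cv_co2 = ca_co2 + vco2 / (co_ml / 100.0)
        new_cv_o2 = max(new_cv_o2, 0.5)

        # Half-step damping keeps the HPV feedback loop (venous PO2 ->
        # constriction -> shunt -> arterial PO2) from oscillating.
        err = abs(new_cv_o2 - cv_o2) + abs(new_cv_co2 - cv_co2)
        cv_o2 = 0.5 * cv_o2 + 0.5 * new_cv_o2
        cv_co2 = 0.5 * cv_co2 + 0.5 * new_cv_co2
        if err < tol:
            converged = True
            break

    paco2 = float(pco2_from_content(ca_co2))
    paco2 = max(paco2, 1.0)
    pao2 = po2_from_content(ca_o2, hb)
    sao2 = float(severinghaus_sao2(pao2))
    pvo2 = po2_from_content(max(cv_o2, 1e-6), hb)
    svo2 = float(severinghaus_sao2(pvo2))
    shunt = float(q[~ventilated].sum() / co_ml) if n else 0.0

    # Mixed-expired CO2: all eliminated CO2 diluted into the full minute
    # ventilation (alveolar gas plus CO2-free deadspace gas).
    elim = float((va * np.nan_to_num(alv_pco2)).sum() / (pb - P_H2O))  # ml/min
    peco2 = (pb - P_H2O) * elim / (vr * vt) if vr * vt > 0 else 0.0
    peco2 = min(peco2, paco2)

    return GasExchangeResult(
        pao2=float(pao2),
        paco2=paco2,
        ph=float(ph_henderson(paco2, hco3)),
        sao2=sao2,
        svo2=svo2,
        pvo2=float(pvo2),
        peco2=float(peco2),
        shunt_fraction=shunt,
        perfusion=q,
        alv_po2=alv_po2,
        alv_pco2=alv_pco2,
        ventilated=ventilated,
        converged=converged,
        iterations=it,
    )
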