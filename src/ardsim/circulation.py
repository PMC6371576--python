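"""Lumped-parameter pulsatile circulation with a four-chamber heart.

Eight blood compartments: right atrium (RA), right ventricle (RV),
pulmonary arteries (PA), pulmonary veins (PV), left atrium (LA), left
ventricle (LV), systemic arteries (SA) and systemic veins (SV).  The
ventricles are time-varying elastance chambers (sin^2 activation); the
atria are passive.  Tricuspid, pulmonary, mitral and aortic valves are
ideal diodes with small series resistances.  Intrathoracic compartments
(heart chambers, pulmonary vessels) feel the pleural pressure, which is
how positive-pressure ventilation depresses venous return and cardiac
output.

Pressures in mmHg, volumes in ml, time in s, resistances in mmHg.s/ml,
compliances in ml/mmHg.  Flow-based explicit Euler stepping at 1 ms keeps
total blood volume conserved to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

# state indices
RA, RV, PA, PV, LA, LV, SA, SV = range(8)


@dataclass
class CardioParams:
    """Parameters of the lumped cardiovascular model.

    Defaults represent a sedated, hyperdynamic ARDS patient of ~70 kg ideal
    body weight (cardiac output near 9 L/min, MAP near 90 mmHg), matching
    the cohort this package emulates.
    """

    hr: float = 96.0              # beats/min
    # ventricular elastances (mmHg/ml) and unstressed volumes (ml)
    e_lv_max: float = 2.0
    e_lv_min: float = 0.06
    e_rv_max: float = 0.55
    e_rv_min: float = 0.043
    v0_lv: float = 15.0
    v0_rv: float = 15.0
    # passive atria
    e_la: float = 0.13
    e_ra: float = 0.10
    v0_la: float = 10.0
    v0_ra: float = 10.0
    # vascular compliances (ml/mmHg) and unstressed volumes (ml)
    c_sa: float = 1.4
    c_sv: float = 60.0
    c_pa: float = 4.5
    c_pv: float = 15.0
    v0_sa: float = 600.0
    v0_sv: float = 2650.0
    v0_pa: float = 60.0
    v0_pv: float = 350.0
    # resistances (mmHg.s/ml)
    r_sys: float = 0.53
    r_sv: float = 0.010
    r_pul: float = 0.07
    r_pv: float = 0.006
    r_tricuspid: float = 0.003
    r_pulmonic: float = 0.004
    r_mitral: float = 0.003
    r_aortic: float = 0.004
    blood_volume: float = 5000.0  # ml, total circulating
    hpv_gain: float = 1.0         # carried with the patient; used by gas exchange
    pleural_transmission: float = 0.3  # fraction of alveolar pressure reaching the pleura

    def validate(self) -> None:
        for name in ("e_lv_max", "e_lv_min", "e_rv_max", "e_rv_min", "e_la",
                     "e_ra", "c_sa", "c_sv", "c_pa", "c_pv", "r_sys", "r_sv",
                     "r_pul", "r_pv", "r_tricuspid", "r_pulmonic", "r_mitral",
                     "r_aortic", "hr", "blood_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cardiovascular parameter {name} must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([
            self.hr, self.e_lv_max, self.e_lv_min, self.e_rv_max,
            self.e_rv_min, self.v0_lv, self.v0_rv, self.e_la, self.e_ra,
            self.v0_la, self.v0_ra, self.c_sa, self.c_sv, self.c_pa,
            self.c_pv, self.v0_sa, self.v0_sv, self.v0_pa, self.v0_pv,
            self.r_sys, self.r_sv, self.r_pul, self.r_pv, self.r_tricuspid,
            self.r_pulmonic, self.r_mitral, self.r_aortic, self.blood_volume,
        ])

    def scaled(self, **factors) -> "CardioParams":
        """Return a copy with named parameters multiplied by given factors."""
        changes = {k: getattr(self, k) * f for k, f in factors.items()}
        return replace(self, **changes)


@njit(cache=True)
def _activation(t_in_beat, period):
    t_sys = 0.3 * np.sqrt(period)
    if t_in_beat < t_sys:
        s = np.sin(np.pi * t_in_beat / t_sys)
        return s * s
    return 0.0


@njit(cache=True)
def run_beats_kernel(vols, p, pit, dt, n_beats, record_last):
    """Integrate ``n_beats`` heart beats.

    Returns (per-beat stroke-volume-out array, means over the last beat:
    co_ml_s, map, mpap, p_ra, p_sv, min beat-CO sample count) and, when
    ``record_last``, the last-beat pressure traces are written into the
    returned arrays.
    """
    (hr, e_lv_max, e_lv_min, e_rv_max, e_rv_min, v0_lv, v0_rv, e_la, e_ra,
     v0_la, v0_ra, c_sa, c_sv, c_pa, c_pv, v0_sa, v0_sv, v0_pa, v0_pv,
     r_sys, r_sv, r_pul, r_pv, r_tri, r_pulv, r_mit, r_aor, _bv) = p

    period = 60.0 / hr
    steps_per_beat = int(round(period / dt))
    sv_out = np.zeros(n_beats)
    co_acc = 0.0
    map_acc = 0.0
    mpap_acc = 0.0
    pra_acc = 0.0
    psv_acc = 0.0

    n_rec = steps_per_beat if record_last else 1
    trace = np.zeros((5, n_rec))  # p_sa, p_pa, p_lv, p_ra, q_aortic

    for beat in range(n_beats):
        last = beat == n_beats - 1
        if last:
            co_acc = 0.0
            map_acc = 0.0
            mpap_acc = 0.0
            pra_acc = 0.0
            psv_acc = 0.0
        for s in range(steps_per_beat):
            t = s * dt
            act = _activation(t, period)
            e_lv = e_lv_min + (e_lv_max - e_lv_min) * act
            e_rv = e_rv_min + (e_rv_max - e_rv_min) * act

            p_ra = e_ra * (vols[RA] - v0_ra) + pit
            p_rv = e_rv * (vols[RV] - v0_rv) + pit
            p_pa = (vols[PA] - v0_pa) / c_pa + pit
            p_pv = (vols[PV] - v0_pv) / c_pv + pit
            p_la = e_la * (vols[LA] - v0_la) + pit
            p_lv = e_lv * (vols[LV] - v0_lv) + pit
            p_sa = (vols[SA] - v0_sa) / c_sa
            p_sv = (vols[SV] - v0_sv) / c_sv

            q_sv_ra = (p_sv - p_ra) / r_sv
            q_ra_rv = (p_ra - p_rv) / r_tri if p_ra > p_rv else 0.0
            q_rv_pa = (p_rv - p_pa) / r_pulv if p_rv > p_pa else 0.0
            q_pa_pv = (p_pa - p_pv) / r_pul
            q_pv_la = (p_pv - p_la) / r_pv
            q_la_lv = (p_la - p_lv) / r_mit if p_la > p_lv else 0.0
            q_lv_sa = (p_lv - p_sa) / r_aor if p_lv > p_sa else 0.0
            q_sa_sv = (p_sa - p_sv) / r_sys

            vols[RA] += dt * (q_sv_ra - q_ra_rv)
            vols[RV] += dt * (q_ra_rv - q_rv_pa)
            vols[PA] += dt * (q_rv_pa - q_pa_pv)
            vols[PV] += dt * (q_pa_pv - q_pv_la)
            vols[LA] += dt * (q_pv_la - q_la_lv)
            vols[LV] += dt * (q_la_lv - q_lv_sa)
            vols[SA] += dt * (q_lv_sa - q_sa_sv)
            vols[SV] += dt * (q_sa_sv - q_sv_ra)

            sv_out[beat] += q_lv_sa * dt
            if last:
                co_acc += q_lv_sa
                map_acc += p_sa
                mpap_acc += p_pa - pit  # vascular pressure referenced to atmosphere
                pra_acc += p_ra
                psv_acc += p_sv
                if record_last:
                    trace[0, s] = p_sa
                    trace[1, s] = p_pa
                    trace[2, s] = p_lv
                    trace[3, s] = p_ra
                    trace[4, s] = q_lv_sa

    inv = 1.0 / steps_per_beat
    return (sv_out, co_acc * inv, map_acc * inv, mpap_acc * inv,
            pra_acc * inv, psv_acc * inv, trace)


@dataclass
class CirculationResult:
    co: float          # L/min, mean aortic flow over the last beat
    map: float         # mmHg
    mpap: float        # mmHg (referenced to atmosphere)
    p_ra: float        # mmHg
    p_sv: float        # mmHg
    stroke_volume: float
    hr: float
    n_beats: int
    converged: bool
    beat_sv: np.ndarray
    trace: np.ndarray


def simulate_circulation(
    cardio: CardioParams,
    pit_mmhg: float = 0.0,
    dt: float = 1e-3,
    max_beats: int = 120,
    chunk: int = 10,
    conv_tol: float = 1e-3,
    record: bool = False,
) -> CirculationResult:
    """Run the circulation to a periodic steady state at fixed pleural pressure.

    Convergence: relative change in stroke volume between the last two beats
    of successive chunks below ``conv_tol``.
    """
    cardio.validate()
    p = cardio.as_array()
    # Initial volume distribution: unstressed volumes plus stressed volume
    # spread in proportion to compliance-like weights (RA,RV,PA,PV,LA,LV,SA,SV).
    v0 = np.array([cardio.v0_ra, cardio.v0_rv, cardio.v0_pa, cardio.v0_pv,
                   cardio.v0_la, cardio.v0_lv, cardio.v0_sa, cardio.v0_sv])
    stressed = cardio.blood_volume - v0.sum()
    if stressed <= 0:
        raise ValueError("blood volume below total unstressed volume")
    weights = np.array([1.0 / cardio.e_ra, 1.0 / cardio.e_rv_min, cardio.c_pa,
                        cardio.c_pv, 1.0 / cardio.e_la, 1.0 / cardio.e_lv_min,
                        cardio.c_sa, cardio.c_sv])
    vols = v0 + stressed * weights / weights.sum()

    prev_sv = np.nan
    total_beats = 0
    converged = False
    out = None
    while total_beats < max_beats:
        out = run_beats_kernel(vols, p, pit_mmhg, dt, chunk, record)
        total_beats += chunk
        sv = out[0][-1]
        if np.isfinite(prev_sv) and abs(sv - prev_sv) / max(abs(prev_sv), 1e-9) < conv_tol:
            converged = True
            break
        prev_sv = sv
    if np.any(vols < 0):
        raise RuntimeError(
            "negative compartment volume during circulation integration; "
            f"volumes={vols}"
        )
    sv_arr, co_ml_s, map_, mpap, p_ra, p_sv, trace = out
    return CirculationResult(
        co=co_ml_s * 60.0 / 1000.0,
        map=float(map_),
        mpap=float(mpap),
        p_ra=float(p_ra),
        p_sv=float(p_sv),
        stroke_volume=float(sv_arr[-1]),
        hr=cardio.hr,
        n_beats=total_beats,
        converged=converged,
        beat_sv=sv_arr,
        trace=trace,
    )
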