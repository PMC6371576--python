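"""Multi-compartment lung mechanics under pressure-controlled ventilation.

The respiratory zone is 100 parallel alveolar compartments behind a common
conducting-airway resistance.  Each compartment has its own sigmoidal
pressure-volume relation (Venegas form), bronchiolar resistance, threshold
opening pressure (TOP) and extrinsic pressure.  A collapsed compartment
receives no flow and its volume is frozen; it opens when the local
distending pressure (junction pressure minus extrinsic pressure) reaches
its TOP, and an open compartment re-collapses when that pressure falls
below TOP minus a closing hysteresis (default 2 cmH2O).  Ties open.

The ventilator applies a square pressure waveform (instantaneous rise from
PEEP to the inspiratory pressure).  Integration is fixed-step explicit
Euler at 1 ms, with state recorded every 10 ms.  The model carries no gas
compression, so ventilator-delivered tidal volume equals the summed
compartmental volume excursion exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

#: curve codes for the kernel
CURVE_SIGMOID = 0
CURVE_LINEAR = 1


@njit(cache=True)
def _elastic_pressure(v, vmax, d, c0, curve, c_lin):
    """Elastic recoil pressure of one compartment at volume v (ml -> cmH2O)."""
    if curve == CURVE_LINEAR:
        return v / c_lin
    x = v / vmax
    if x < 0.002:
        x = 0.002
    elif x > 0.998:
        x = 0.998
    return c0 + d * np.log(x / (1.0 - x))


@njit(cache=True)
def _local_compliance(v, vmax, d, c0, curve, c_lin):
    if curve == CURVE_LINEAR:
        return c_lin
    x = v / vmax
    if x < 0.002:
        x = 0.002
    elif x > 0.998:
        x = 0.998
    return vmax * x * (1.0 - x) / d


@njit(cache=True)
def simulate_breath_kernel(
    v, is_open, vmax, d, c0, rb, top, pext, curve, c_lin,
    rc, peep, p_insp, t_insp, t_exp, dt, delta_close,
    rec_stride, record,
    # outputs
    t_rec, paw_rec, pvent_rec, vtot_rec, flow_rec,
    v_insp, v_exp, p_insp_alv, p_exp_alv, open_insp, open_exp,
):
    """Integrate one breath in place.  Returns (vt_inhaled, p_plat, mean_palv).

    ``v``/``is_open`` are the per-compartment state (updated in place).
    ``rb`` and ``rc`` are in cmH2O.s/L; volumes in ml; flow computed in ml/s.
    """
    n = v.size
    n_steps = int(round((t_insp + t_exp) / dt))
    insp_steps = int(round(t_insp / dt))
    rec_i = 0
    mean_palv_acc = 0.0
    vt_in = 0.0
    p_plat = peep
    pel = np.empty(n)

    for step in range(n_steps):
        inspiratory = step < insp_steps
        pvent = p_insp if inspiratory else peep

        # Elastic pressures and open-branch conductances.
        inv_sum = 1.0 / rc
        num = pvent / rc
        for i in range(n):
            pel[i] = _elastic_pressure(v[i], vmax[i], d[i], c0[i], curve[i], c_lin[i])
            if is_open[i]:
                g = 1.0 / rb[i]
                inv_sum += g
                num += (pel[i] + pext[i]) * g
        paw = num / inv_sum

        # Flows into open compartments (ml/s; resistances are per-L).
        # The delivered volume is accumulated from the realised volume
        # increments so the no-compression mass balance is exact even when
        # a compartment hits the sigmoid clamp.
        qtot = 0.0
        for i in range(n):
            if is_open[i]:
                q = (paw - (pel[i] + pext[i])) / rb[i] * 1000.0
                v_old = v[i]
                v_new = v_old + q * dt
                lo = 0.002 * vmax[i]
                hi = 0.998 * vmax[i]
                if curve[i] == CURVE_SIGMOID:
                    if v_new < lo:
                        v_new = lo
                    elif v_new > hi:
                        v_new = hi
                elif v_new < 0.0:
                    v_new = 0.0
                v[i] = v_new
                dvol = v_new - v_old
                qtot += dvol / dt
                if inspiratory:
                    vt_in += dvol

        # Recruitment/derecruitment on the local distending pressure.
        for i in range(n):
            pd = paw - pext[i]
            if is_open[i]:
                if pd < top[i] - delta_close:
                    is_open[i] = False
            else:
                if pd >= top[i]:
                    is_open[i] = True

        # Volume-weighted mean alveolar pressure (for pleural coupling).
        vw = 0.0
        pw = 0.0
        for i in range(n):
            pa = pel[i] + pext[i]
            vw += v[i]
            pw += v[i] * pa
        mean_palv_acc += pw / vw if vw > 0 else paw

        if record and (step % rec_stride == 0):
            if rec_i < t_rec.size:
                t_rec[rec_i] = (step + 1) * dt
                paw_rec[rec_i] = paw
                pvent_rec[rec_i] = pvent
                s = 0.0
                for i in range(n):
                    s += v[i]
                vtot_rec[rec_i] = s
                flow_rec[rec_i] = qtot
                rec_i += 1

        # End-inspiration snapshot (last inspiratory step).
        if step == insp_steps - 1:
            csum = 0.0
            cpsum = 0.0
            for i in range(n):
                v_insp[i] = v[i]
                p_insp_alv[i] = pel[i] + pext[i]
                open_insp[i] = is_open[i]
                if is_open[i]:
                    cl = _local_compliance(v[i], vmax[i], d[i], c0[i], curve[i], c_lin[i])
                    csum += cl
                    cpsum += cl * (pel[i] + pext[i])
            p_plat = cpsum / csum if csum > 0 else pvent

    for i in range(n):
        v_exp[i] = v[i]
        p_exp_alv[i] = _elastic_pressure(v[i], vmax[i], d[i], c0[i], curve[i], c_lin[i]) + pext[i]
        open_exp[i] = is_open[i]

    return vt_in, p_plat, mean_palv_acc / n_steps


@dataclass
class LungParams:
    """Realised per-compartment mechanics of one virtual lung."""

    vmax: np.ndarray            # ml, sigmoid asymptote
    d: np.ndarray               # cmH2O, sigmoid pressure width
    c0: np.ndarray              # cmH2O, sigmoid midpoint pressure
    rb: np.ndarray              # cmH2O.s/L, bronchiolar resistance
    top: np.ndarray             # cmH2O, threshold opening pressure
    pext: np.ndarray            # cmH2O, extrinsic pressure
    q_weights: np.ndarray       # baseline perfusion conductances (a.u.)
    rc: float = 3.0             # cmH2O.s/L, common conducting airway
    vd_ml: float = 150.0        # series deadspace, ml
    delta_close: float = 2.0    # cmH2O, closing hysteresis below TOP
    curve: np.ndarray | None = None   # per-compartment curve code
    c_lin: np.ndarray | None = None   # ml/cmH2O, used when curve == linear

    def __post_init__(self):
        n = self.vmax.size
        if self.curve is None:
            self.curve = np.full(n, CURVE_SIGMOID, dtype=np.int64)
        if self.c_lin is None:
            self.c_lin = np.ones(n)
        for name in ("vmax", "d", "c0", "rb", "top", "pext", "q_weights", "c_lin"):
            setattr(self, name, np.ascontiguousarray(getattr(self, name), dtype=float))
        self.curve = np.ascontiguousarray(self.curve, dtype=np.int64)
        if np.any(self.top < 0):
            raise ValueError("threshold opening pressures must be >= 0")
        if np.any(self.rb <= 0) or self.rc <= 0:
            raise ValueError("resistances must be positive")

    @property
    def n(self) -> int:
        return self.vmax.size


@dataclass
class MechanicsResult:
    """Converged breath-cycle mechanics for one ventilator condition."""

    vt: float                      # ml, summed compartmental excursion
    vt_delivered: float            # ml, net inspiratory volume through the ventilator
    v_start: np.ndarray            # ml, compartment volumes at start of final breath
    p_peak: float                  # cmH2O, applied inspiratory pressure
    p_plat: float                  # cmH2O, compliance-weighted occlusion estimate
    peep: float
    t_insp: float
    mean_palv: float               # cmH2O, breath-mean volume-weighted
    v_insp: np.ndarray
    v_exp: np.ndarray
    p_insp_alv: np.ndarray
    p_exp_alv: np.ndarray
    open_insp: np.ndarray
    open_exp: np.ndarray
    series: dict = field(default_factory=dict)
    n_breaths: int = 0
    converged: bool = True

    @property
    def dv(self) -> np.ndarray:
        return self.v_insp - self.v_exp


def recruitment_rule(is_open: bool, airway_pressure: float, top: float,
                     pext: float = 0.0, delta_close: float = 2.0) -> bool:
    """State-transition rule for one compartment (total function).

    A closed compartment opens when the local distending pressure
    (airway pressure minus extrinsic pressure) reaches TOP; an open one
    closes when it falls below TOP - delta_close.  Ties open.
    """
    pd = airway_pressure - pext
    if is_open:
        return pd >= top - delta_close
    return pd >= top


def initial_state(lung: LungParams, peep: float):
    """Initial volumes/open states before the first breath at given PEEP."""
    n = lung.n
    is_open = (peep - lung.pext) >= lung.top
    v = np.empty(n)
    for i in range(n):
        if lung.curve[i] == CURVE_LINEAR:
            v[i] = max(peep, 0.0) * lung.c_lin[i] if is_open[i] else 0.0
            continue
        if is_open[i]:
            p = peep - lung.pext[i]
            x = 1.0 / (1.0 + np.exp(-(p - lung.c0[i]) / lung.d[i]))
        else:
            x = 0.03  # collapsed
        v[i] = np.clip(x, 0.002, 0.998) * lung.vmax[i]
    return v, is_open.astype(np.bool_)


def simulate_mechanics(
    lung: LungParams,
    peep: float,
    p_insp: float,
    vr: float,
    ie: float,
    dt: float = 1e-3,
    record_dt: float = 1e-2,
    max_breaths: int = 300,
    conv_tol: float = 0.005,
    min_breaths: int = 3,
) -> MechanicsResult:
    """Run breaths until the cycle is periodic; record the final breath.

    Convergence: relative breath-to-breath change of tidal volume and of
    total end-expiratory volume both below ``conv_tol`` (default 0.5%).
    """
    if p_insp < peep:
        raise ValueError("inspiratory pressure below PEEP")
    t_total = 60.0 / vr
    t_insp = t_total * ie / (1.0 + ie)
    t_exp = t_total - t_insp
    rec_stride = max(int(round(record_dt / dt)), 1)
    n_rec = int(round((t_insp + t_exp) / dt)) // rec_stride + 1

    v, is_open = initial_state(lung, peep)
    n = lung.n
    v_insp = np.empty(n)
    v_exp = np.empty(n)
    p_i = np.empty(n)
    p_e = np.empty(n)
    o_i = np.zeros(n, dtype=np.bool_)
    o_e = np.zeros(n, dtype=np.bool_)
    t_rec = np.zeros(n_rec)
    paw_rec = np.zeros(n_rec)
    pvent_rec = np.zeros(n_rec)
    vtot_rec = np.zeros(n_rec)
    flow_rec = np.zeros(n_rec)

    prev_vt = np.nan
    prev_vee = np.nan
    converged = False
    breath = 0
    vt_in = 0.0
    p_plat = peep
    mean_palv = peep
    v_start = v.copy()
    for breath in range(1, max_breaths + 1):
        v_start = v.copy()
        vt_in, p_plat, mean_palv = simulate_breath_kernel(
            v, is_open, lung.vmax, lung.d, lung.c0, lung.rb, lung.top,
            lung.pext, lung.curve, lung.c_lin, lung.rc, peep, p_insp,
            t_insp, t_exp, dt, lung.delta_close, rec_stride, True,
            t_rec, paw_rec, pvent_rec, vtot_rec, flow_rec,
            v_insp, v_exp, p_i, p_e, o_i, o_e,
        )
        vt = float((v_insp - v_exp).sum())
        vee = float(v_exp.sum())
        if breath >= min_breaths and np.isfinite(prev_vt):
            dvt = abs(vt - prev_vt) / max(abs(prev_vt), 1e-9)
            dve = abs(vee - prev_vee) / max(abs(prev_vee), 1e-9)
            if dvt < conv_tol and dve < conv_tol:
                converged = True
                break
        prev_vt, prev_vee = vt, vee

    series = {
        "time_s": t_rec.copy(),
        "p_airway": paw_rec.copy(),
        "p_vent": pvent_rec.copy(),
        "v_total": vtot_rec.copy(),
        "flow": flow_rec.copy(),
    }
    return MechanicsResult(
        vt=float((v_insp - v_exp).sum()),
        vt_delivered=float(vt_in),
        v_start=v_start,
        p_peak=p_insp,
        p_plat=float(min(p_plat, p_insp)),
        peep=peep,
        t_insp=t_insp,
        mean_palv=float(mean_palv),
        v_insp=v_insp.copy(),
        v_exp=v_exp.copy(),
        p_insp_alv=p_i.copy(),
        p_exp_alv=p_e.copy(),
        open_insp=o_i.copy(),
        open_exp=o_e.copy(),
        series=series,
        n_breaths=breath,
        converged=converged,
    )
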