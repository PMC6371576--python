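"""Two-stage genetic-algorithm calibration of virtual patients.

Stage 1 identifies the pulmonary parameters: the PF ratio and static
compliance are matched at PEEP 10 cmH2O and PaCO2/SvO2 at the ventilation
baseline (PEEP 5, plateau 30 cmH2O, FiO2 1.0), with the cardiovascular
model held at its defaults.  Stage 2 identifies the cardiovascular
parameters by matching cardiac index, PaCO2, MAP and SvO2 across the
recruitment-maneuver PEEP ladder with the stage-1 lung held fixed.

Rather than treating each of the 100 alveolar compartments' properties as
free, compartment properties are *realised from parametric distributions*
(e.g. threshold opening pressures from a truncated normal with free
mean/SD, a consolidated never-recruiting fraction, log-normal compliance
and perfusion heterogeneity).  The realisation uses fixed quantile grids
and fixed permutations, so the objective is a deterministic, smooth
function of the ~14 free pulmonary parameters — which both keeps the GA
search tractable and makes calibration reproducible bit-for-bit.

The optimiser is an elitist GA (tournament selection, uniform crossover,
per-gene Gaussian mutation) followed by a bounded Nelder-Mead polish of
the best individual (a standard memetic refinement).  Only output match is
claimed, never unique parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm, truncnorm

from .circulation import CardioParams
from .cohort import ConfigurationError, PatientDataset
from .mechanics import LungParams
from .simulator import (CardioPulmonarySimulator, SimConfig, VentilatorSettings,
                        VirtualPatient)
from .gas_exchange import hco3_for_ph, steady_state_gas_exchange
from .stats import pearson
from .units import cmh2o_to_mmhg

N_COMPARTMENTS = 100
#: TOP assigned to consolidated (never-recruiting) compartments, cmH2O.
TOP_CONSOLIDATED = 80.0
#: reference conditions (cmH2O)
PLATEAU = 30.0
PEEP_BASELINE = 5.0
PEEP_STATIC = 10.0
#: driving pressure held while stepping PEEP during the simulated
#: recruitment maneuver (the baseline plateau-minus-PEEP difference)
RM_DELTA_P = 25.0


@dataclass
class ParameterBounds:
    """Box bounds of one free parameter."""

    name: str
    lower: float
    upper: float
    units: str = ""
    stage: str = "pulmonary"

    def __post_init__(self):
        if not self.lower <= self.upper:
            raise ConfigurationError(f"{self.name}: lower bound above upper")


def default_pulmonary_bounds() -> list[ParameterBounds]:
    """Physiological ranges of the free pulmonary parameters."""
    B = ParameterBounds
    return [
        B("f_consolidated", 0.05, 0.60, "fraction"),
        B("top_mean", 0.0, 6.0, "cmH2O"),
        B("top_sd", 3.0, 6.0, "cmH2O"),
        B("c_total", 15.0, 60.0, "ml/cmH2O"),
        B("c_dispersion", 0.05, 0.60, "log-sd"),
        B("pext_mean", 0.0, 3.0, "cmH2O"),
        B("raw_total", 5.0, 25.0, "cmH2O.s/L"),
        B("vd", 80.0, 230.0, "ml"),
        B("vco2", 130.0, 260.0, "ml/min"),
        B("vo2", 120.0, 330.0, "ml/min"),
        B("q_dispersion", 0.10, 0.80, "log-sd"),
        B("hpv_gain", 0.20, 2.50, ""),
        B("pv_midpoint", 10.0, 20.0, "cmH2O"),
        B("pv_width", 8.0, 25.0, "cmH2O"),
    ]


def default_cardiovascular_bounds() -> list[ParameterBounds]:
    B = ParameterBounds
    s = "cardiovascular"
    return [
        B("contractility_scale", 0.5, 1.7, "x", s),
        B("r_sys_scale", 0.6, 1.6, "x", s),
        B("blood_volume", 4200.0, 6600.0, "ml", s),
        B("c_sv_scale", 0.6, 1.6, "x", s),
        B("hr", 70.0, 115.0, "1/min", s),
        B("r_pul_scale", 0.6, 2.0, "x", s),
        B("pleural_transmission", 0.15, 0.7, "fraction", s),
        B("r_sv_scale", 0.5, 2.0, "x", s),
    ]


# Fixed quantile permutations shared by every patient: they decouple the
# spatial pairing of TOP, compliance and perfusion heterogeneity while
# keeping the realisation deterministic.
_PERM_RNG = np.random.RandomState(20190211)
_PERM_TOP = _PERM_RNG.permutation(N_COMPARTMENTS)
_PERM_C = _PERM_RNG.permutation(N_COMPARTMENTS)
_PERM_Q = _PERM_RNG.permutation(N_COMPARTMENTS)
_QUANTILES = (np.arange(N_COMPARTMENTS) + 0.5) / N_COMPARTMENTS
_Z = norm.ppf(_QUANTILES)
_PEXT_SD = 0.5


def realise_lung(genes: np.ndarray) -> tuple[LungParams, dict]:
    """Build per-compartment mechanics from the pulmonary gene vector."""
    (f_cons, top_mean, top_sd, c_total, c_disp, pext_mean, raw_total,
     vd, vco2, vo2, q_disp, hpv_gain, c0, d) = [float(g) for g in genes]
    n = N_COMPARTMENTS
    n_cons = int(round(f_cons * n))

    top = np.empty(n)
    cons_mask = np.zeros(n, dtype=bool)
    cons_mask[_PERM_TOP[:n_cons]] = True
    n_rec = n - n_cons
    if n_rec > 0:
        u = (np.arange(n_rec) + 0.5) / n_rec
        a, b = (0.0 - top_mean) / top_sd, (60.0 - top_mean) / top_sd
        top_rec = truncnorm.ppf(u, a, b, loc=top_mean, scale=top_sd)
        top[_PERM_TOP[n_cons:]] = top_rec
    top[cons_mask] = TOP_CONSOLIDATED

    c_i = np.exp(c_disp * _Z[_PERM_C] - 0.5 * c_disp**2)
    c_i = c_i / c_i.sum() * c_total           # midpoint compliances, ml/cmH2O
    vmax = 4.0 * d * c_i

    pext = np.clip(pext_mean + _PEXT_SD * _Z[_PERM_TOP], 0.0, None)

    q_w = np.exp(q_disp * _Z[_PERM_Q] - 0.5 * q_disp**2)
    q_w = q_w / q_w.mean()

    lung = LungParams(
        vmax=vmax,
        d=np.full(n, d),
        c0=np.full(n, c0),
        rb=np.full(n, 0.7 * raw_total * n),
        top=top,
        pext=pext,
        q_weights=q_w,
        rc=0.3 * raw_total,
        vd_ml=vd,
    )
    scalars = {"vo2": vo2, "vco2": vco2, "hpv_gain": hpv_gain}
    return lung, scalars


def heuristic_pulmonary_genes(dataset: PatientDataset,
                              bounds: list[ParameterBounds],
                              co_default: float = 8.6) -> np.ndarray:
    """Physiology-based initial guess for the pulmonary gene vector.

    Shunt from the venous-admixture saturation balance at FiO2 1.0, the
    consolidated fraction from that shunt, aerated-lung compliance from the
    static-compliance target, VO2 from the Fick principle and deadspace from
    the alveolar CO2 balance.  Seeded into the GA's initial population.
    """
    from .gas_exchange import o2_content
    b = {x.name: (x.lower, x.upper) for x in bounds}
    t = dataset.baseline
    hb = dataset.hb
    # O2 contents (ml/dl): end-capillary at ideal alveolar PO2, arterial at
    # the PF-ratio tension (FiO2 1.0), venous at the SvO2 target.
    pao2_ideal = 713.0 - t["paco2"] / 0.8
    cc = float(o2_content(pao2_ideal, hb))
    ca = float(o2_content(t["pf_ratio"], hb))
    cv = 1.34 * hb * t["svo2"] + 0.003 * 45.0
    vo2 = np.clip((ca - cv) * 10.0 * co_default, *b["vo2"])
    q_est = (cc - ca) / max(cc - cv, 0.5)
    f_cons = np.clip(1.15 * q_est, *b["f_consolidated"])
    c_total = np.clip(t["cstat"] / max(1.0 - f_cons, 0.4) * 1.15, *b["c_total"])
    vco2 = np.clip(0.8 * vo2, *b["vco2"])
    va = 863.0 * vco2 / t["paco2"]          # ml/min alveolar ventilation
    vd = np.clip(t["cstat"] * 25.0 - va / dataset.vr, *b["vd"])
    mid = {name: 0.5 * (lo + hi) for name, (lo, hi) in b.items()}
    genes = dict(mid)
    genes.update({"f_consolidated": f_cons, "c_total": c_total, "vo2": vo2,
                  "vco2": vco2, "vd": vd})
    return np.array([genes[x.name] for x in bounds])


def build_patient(pulm_genes: np.ndarray, dataset: PatientDataset,
                  cardio: CardioParams | None = None,
                  patient_id: str | None = None) -> VirtualPatient:
    lung, scal = realise_lung(pulm_genes)
    cardio = replace(cardio or CardioParams(), hpv_gain=scal["hpv_gain"])
    return VirtualPatient(
        patient_id=patient_id or dataset.patient_id,
        lung=lung, cardio=cardio,
        hb=dataset.hb, bsa=dataset.bsa, vr=dataset.vr, ie=0.5,
        vo2=scal["vo2"], vco2=scal["vco2"],
        severity=dataset.severity,
    )


def apply_cardio_genes(base: CardioParams, genes: np.ndarray) -> CardioParams:
    (contr, rsys, bv, csv, hr, rpul, ptf, rsv) = [float(g) for g in genes]
    return replace(
        base,
        e_lv_max=base.e_lv_max * contr,
        e_rv_max=base.e_rv_max * contr,
        r_sys=base.r_sys * rsys,
        blood_volume=bv,
        c_sv=base.c_sv * csv,
        hr=hr,
        r_pul=base.r_pul * rpul,
        pleural_transmission=ptf,
        r_sv=base.r_sv * rsv,
    )


# ---------------------------------------------------------------------------
# Fitness and the GA engine
# ---------------------------------------------------------------------------

def fitness(model_outputs: dict, targets: dict, weights: dict | None = None) -> float:
    """Weighted sum of squared relative errors; 0 iff outputs equal targets."""
    total = 0.0
    for name, target in targets.items():
        if name not in model_outputs:
            raise ConfigurationError(f"model output missing target variable {name!r}")
        w = 1.0 if weights is None else weights.get(name, 1.0)
        if w == 0.0:
            continue
        total += w * ((model_outputs[name] - target) / target) ** 2
    return total


@dataclass
class GAConfig:
    """Elitist genetic-algorithm configuration."""

    population: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    mutation_sigma: float = 0.15     # in units of the parameter range
    elitism: int = 2
    tournament: int = 3
    fitness_tol: float = 1e-3
    polish_maxfev: int = 150         # Nelder-Mead refinement budget (0 disables)
    parallel: bool = False           # evaluation is sequential in this implementation

    def __post_init__(self):
        if self.population < 2:
            raise ConfigurationError("population must be >= 2")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError("rates must lie in [0, 1]")


def ga_profile(profile: str) -> tuple[GAConfig, GAConfig]:
    """(stage-1, stage-2) GA configurations for the named profile."""
    if profile == "full":
        return GAConfig(50, 100), GAConfig(50, 50)
    if profile == "fast":
        return (GAConfig(12, 15, polish_maxfev=120),
                GAConfig(12, 15, polish_maxfev=100))
    if profile == "smoke":
        # minimal budget for pipeline plumbing tests; fits are rough
        return (GAConfig(6, 4, polish_maxfev=20),
                GAConfig(6, 4, polish_maxfev=20))
    raise ConfigurationError(f"unknown GA profile {profile!r}")


def ga_minimize(objective, lower: np.ndarray, upper: np.ndarray,
                cfg: GAConfig, rng: np.random.Generator,
                init: np.ndarray | None = None):
    """Minimise ``objective`` over a box; returns (x_best, f_best, history).

    ``history`` rows are (generation, best_fitness, mean_fitness); elitism
    makes the best fitness non-increasing across generations.  ``init``
    optionally supplies individuals (e.g. physiology-based heuristics) that
    replace the first rows of the random initial population.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    span = upper - lower
    ndim = lower.size
    if np.all(span == 0.0):
        # Degenerate search space: single point, single evaluation.
        x = lower.copy()
        f = float(objective(x))
        return x, f, [(0, f, f)]

    pop = lower + rng.random((cfg.population, ndim)) * span
    if init is not None:
        init = np.clip(np.atleast_2d(init), lower, upper)
        pop[:min(len(init), cfg.population)] = init[:cfg.population]
    fit = np.array([objective(x) for x in pop])
    history = [(0, float(fit.min()), float(fit.mean()))]

    def tournament():
        idx = rng.integers(0, cfg.population, size=cfg.tournament)
        return pop[idx[np.argmin(fit[idx])]]

    for gen in range(1, cfg.generations + 1):
        order = np.argsort(fit)
        new_pop = [pop[i].copy() for i in order[:cfg.elitism]]
        while len(new_pop) < cfg.population:
            a, b = tournament().copy(), tournament().copy()
            if rng.random() < cfg.crossover_rate:
                swap = rng.random(ndim) < 0.5
                a[swap], b[swap] = b[swap], a[swap].copy()
            for child in (a, b):
                mut = rng.random(ndim) < cfg.mutation_rate
                child[mut] += rng.normal(0.0, cfg.mutation_sigma, size=ndim)[mut] * span[mut]
                np.clip(child, lower, upper, out=child)
                if len(new_pop) < cfg.population:
                    new_pop.append(child)
        pop = np.array(new_pop)
        fit = np.array([objective(x) for x in pop])
        history.append((gen, float(fit.min()), float(fit.mean())))
        if fit.min() <= 0.0:
            break

    best = int(np.argmin(fit))
    x_best, f_best = pop[best].copy(), float(fit[best])

    if cfg.polish_maxfev > 0 and f_best > 0.0:
        x_p, f_p = nm_polish(objective, x_best, lower, upper,
                             cfg.polish_maxfev)
        if f_p < f_best:
            x_best, f_best = x_p, f_p
        history.append((history[-1][0] + 1, f_best, f_best))

    return x_best, f_best, history


def nm_polish(objective, x0: np.ndarray, lower: np.ndarray, upper: np.ndarray,
              maxfev: int) -> tuple[np.ndarray, float]:
    """Bounded Nelder-Mead refinement on range-normalised coordinates."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    span = upper - lower
    free = span > 0
    x0 = np.clip(np.asarray(x0, dtype=float), lower, upper)
    f0 = float(objective(x0))
    if not free.any():
        return x0, f0

    def penalised(z):
        x = x0.copy()
        x[free] = lower[free] + np.clip(z, 0.0, 1.0) * span[free]
        return objective(x)

    z0 = (x0[free] - lower[free]) / span[free]
    res = minimize(penalised, z0, method="Nelder-Mead",
                   options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 1e-8})
    if float(res.fun) < f0:
        x = x0.copy()
        x[free] = lower[free] + np.clip(res.x, 0.0, 1.0) * span[free]
        return x, float(res.fun)
    return x0, f0


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResults:
    """Calibrated virtual patient with fit diagnostics."""

    patient: VirtualPatient
    stage1_fitness: float
    stage2_fitness: float
    residuals: pd.DataFrame      # variable, condition, target, model, rel_error
    pulm_genes: np.ndarray
    cardio_genes: np.ndarray
    history_stage1: list
    history_stage2: list
    warnings: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Calibration results: {self.patient.patient_id} "
            f"({self.patient.severity})",
            "=" * 58,
            f"stage-1 (pulmonary) fitness      {self.stage1_fitness:12.5g}",
            f"stage-2 (cardiovascular) fitness {self.stage2_fitness:12.5g}",
            "-" * 58,
            f"{'variable':<12}{'condition':<14}{'target':>10}{'model':>10}{'err %':>8}",
        ]
        for _, r in self.residuals.iterrows():
            lines.append(f"{r['variable']:<12}{r['condition']:<14}"
                         f"{r['target']:>10.3g}{r['model']:>10.3g}"
                         f"{100 * r['rel_error']:>8.2f}")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


class PatientCalibration:
    """Fit one virtual patient to one observation set (model object).

    Parameters
    ----------
    dataset : PatientDataset
        Calibration targets (baseline and recruitment-maneuver series).
    pulmonary_bounds, cardiovascular_bounds : lists of ParameterBounds.
    ga_stage1, ga_stage2 : GAConfig for each stage (default: full profile).
    base_cardio : CardioParams used during stage 1 and as the reference the
        stage-2 scale factors act on.
    """

    def __init__(self, dataset: PatientDataset,
                 pulmonary_bounds: list[ParameterBounds] | None = None,
                 cardiovascular_bounds: list[ParameterBounds] | None = None,
                 ga_stage1: GAConfig | None = None,
                 ga_stage2: GAConfig | None = None,
                 base_cardio: CardioParams | None = None,
                 sim_config: SimConfig | None = None,
                 weights_stage1: dict | None = None,
                 weights_stage2: dict | None = None):
        dataset.validate()
        self.dataset = dataset
        self.pulmonary_bounds = pulmonary_bounds or default_pulmonary_bounds()
        self.cardiovascular_bounds = (cardiovascular_bounds
                                      or default_cardiovascular_bounds())
        full = ga_profile("full")
        self.ga_stage1 = ga_stage1 or full[0]
        self.ga_stage2 = ga_stage2 or full[1]
        self.base_cardio = base_cardio or CardioParams()
        self.sim_config = sim_config or SimConfig()
        self.weights_stage1 = weights_stage1
        self.weights_stage2 = weights_stage2

    # -- stage-1 objective --------------------------------------------------
    def _rm_anchor_rows(self) -> list:
        """RM rows whose PaCO2 also constrains the lung's PEEP response.

        The PEEP-response shape of CO2 clearance is otherwise unidentified
        by the four static targets; the mid and top rungs of the ladder pin
        it during stage 1 (with the cardiovascular model at its defaults).
        """
        rm = self.dataset.rm_series
        return [rm[1], rm[-1]] if len(rm) >= 2 else []

    def _stage1_outputs(self, genes: np.ndarray) -> dict:
        patient = build_patient(genes, self.dataset, self.base_cardio)
        sim = CardioPulmonarySimulator(patient, self.sim_config)
        vent10 = VentilatorSettings(PEEP_STATIC, PLATEAU, self.dataset.vr, 0.5, 1.0)
        vent5 = VentilatorSettings(PEEP_BASELINE, PLATEAU, self.dataset.vr, 0.5, 1.0)
        state10, breath10 = sim.simulate(vent10)
        state5, _ = sim.simulate(vent5)
        dp = breath10.p_plat - breath10.peep_total
        cstat = breath10.v_t / dp if dp > 0 else 0.0
        out = {"pf_ratio": state10.pf_ratio, "cstat": cstat,
               "paco2": state5.paco2, "svo2": state5.svo2}
        for row in self._rm_anchor_rows():
            peep = row["peep"]
            vent = VentilatorSettings(peep, peep + RM_DELTA_P,
                                      self.dataset.vr, 0.5, 1.0)
            state, _ = sim.simulate(vent)
            out[f"paco2_rm@{peep:g}"] = state.paco2
        return out

    def _stage1_targets(self) -> dict:
        targets = {k: self.dataset.baseline[k]
                   for k in ("pf_ratio", "cstat", "paco2", "svo2")}
        for row in self._rm_anchor_rows():
            targets[f"paco2_rm@{row['peep']:g}"] = row["paco2"]
        return targets

    def _stage1_objective(self, genes: np.ndarray) -> float:
        try:
            return fitness(self._stage1_outputs(genes), self._stage1_targets(),
                           self.weights_stage1)
        except (RuntimeError, FloatingPointError):
            return 1e6

    # -- stage-2 objective --------------------------------------------------
    def _rm_targets(self) -> dict:
        targets = {}
        for row in self.dataset.rm_series:
            for var in ("ci", "paco2", "map", "svo2"):
                targets[f"{var}@{row['peep']:g}"] = row[var]
        return targets

    def _stage2_outputs(self, genes: np.ndarray, patient: VirtualPatient,
                        rm_mech: dict) -> dict:
        from .circulation import simulate_circulation
        cardio = apply_cardio_genes(self.base_cardio, genes)
        cardio = replace(cardio, hpv_gain=patient.cardio.hpv_gain)
        out = {}
        for peep, mech in rm_mech.items():
            pit = cmh2o_to_mmhg(cardio.pleural_transmission * mech.mean_palv)
            circ = simulate_circulation(cardio, pit_mmhg=pit,
                                        dt=self.sim_config.dt,
                                        max_beats=self.sim_config.circ_max_beats,
                                        conv_tol=self.sim_config.circ_tol)
            gas = steady_state_gas_exchange(
                mech.dv, self.dataset.vr, patient.lung.vd_ml, 1.0,
                patient.hb, circ.co, patient.lung.q_weights,
                vo2=patient.vo2, vco2=patient.vco2, hco3=patient.hco3,
                hpv_gain=patient.cardio.hpv_gain)
            out[f"ci@{peep:g}"] = circ.co / patient.bsa
            out[f"map@{peep:g}"] = circ.map
            out[f"paco2@{peep:g}"] = gas.paco2
            out[f"svo2@{peep:g}"] = gas.svo2
        return out

    # -- fit ----------------------------------------------------------------
    def fit(self, seed: int = 0) -> CalibrationResults:
        """Run both calibration stages; deterministic for a given seed."""
        warnings = []
        rng1 = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        lo1 = np.array([b.lower for b in self.pulmonary_bounds])
        hi1 = np.array([b.upper for b in self.pulmonary_bounds])
        try:
            init1 = heuristic_pulmonary_genes(self.dataset, self.pulmonary_bounds)
        except (KeyError, ZeroDivisionError):
            init1 = None   # custom bounds without the standard names
        genes1, f1, hist1 = ga_minimize(self._stage1_objective, lo1, hi1,
                                        self.ga_stage1, rng1, init=init1)
        if (init1 is not None and f1 > 0.01
                and self.ga_stage1.polish_maxfev > 0):
            # The GA occasionally strands in a poor basin; restart the
            # simplex from the physiology heuristic and keep the better fit.
            genes_h, f_h = nm_polish(self._stage1_objective, init1, lo1, hi1,
                                     self.ga_stage1.polish_maxfev)
            if f_h < f1:
                genes1, f1 = genes_h, f_h
                hist1.append((hist1[-1][0] + 1, f1, f1))
        if f1 > self.ga_stage1.fitness_tol:
            warnings.append(f"stage-1 fitness {f1:.4g} above tolerance "
                            f"{self.ga_stage1.fitness_tol:g}; best-effort result")

        patient = build_patient(genes1, self.dataset, self.base_cardio)

        if len(self.dataset.rm_series) < 2:
            warnings.append("recruitment-maneuver series has a single PEEP "
                            "level; cardiovascular stage is under-determined")

        # Cache lung mechanics per RM PEEP: stage 2 leaves the lung fixed.
        sim = CardioPulmonarySimulator(patient, self.sim_config)
        rm_mech = {}
        for row in self.dataset.rm_series:
            peep = row["peep"]
            vent = VentilatorSettings(peep, peep + RM_DELTA_P, self.dataset.vr, 0.5, 1.0)
            rm_mech[peep] = sim.mechanics(vent)

        targets2 = self._rm_targets()

        def objective2(genes):
            try:
                return fitness(self._stage2_outputs(genes, patient, rm_mech),
                               targets2, self.weights_stage2)
            except (RuntimeError, FloatingPointError, ValueError):
                return 1e6

        rng2 = np.random.default_rng(np.random.SeedSequence([seed, 2]))
        lo2 = np.array([b.lower for b in self.cardiovascular_bounds])
        hi2 = np.array([b.upper for b in self.cardiovascular_bounds])
        genes2, f2, hist2 = ga_minimize(objective2, lo2, hi2,
                                        self.ga_stage2, rng2)
        if f2 > self.ga_stage2.fitness_tol:
            warnings.append(f"stage-2 fitness {f2:.4g} above tolerance "
                            f"{self.ga_stage2.fitness_tol:g}; best-effort result")

        cardio = apply_cardio_genes(self.base_cardio, genes2)
        cardio = replace(cardio, hpv_gain=patient.cardio.hpv_gain)
        patient = replace_patient_cardio(patient, cardio)

        # Fix bicarbonate so the modelled baseline pH matches the patient datum.
        sim = CardioPulmonarySimulator(patient, self.sim_config)
        vent5 = VentilatorSettings(PEEP_BASELINE, PLATEAU, self.dataset.vr, 0.5, 1.0)
        state5, _ = sim.simulate(vent5)
        patient.hco3 = hco3_for_ph(state5.paco2, self.dataset.baseline["ph"])

        residuals = self._residual_table(genes1, genes2, patient, rm_mech)
        patient.diagnostics = {
            "stage1_fitness": f1, "stage2_fitness": f2,
            "warnings": list(warnings),
        }
        return CalibrationResults(
            patient=patient, stage1_fitness=f1, stage2_fitness=f2,
            residuals=residuals, pulm_genes=genes1, cardio_genes=genes2,
            history_stage1=hist1, history_stage2=hist2, warnings=warnings,
        )

    def _residual_table(self, genes1, genes2, patient, rm_mech) -> pd.DataFrame:
        rows = []
        out1 = self._stage1_outputs(genes1)
        targets1 = self._stage1_targets()
        cond1 = {"pf_ratio": "PEEP 10", "cstat": "PEEP 10",
                 "paco2": "baseline", "svo2": "baseline"}
        for var, model in out1.items():
            if "@" in var:
                # RM anchor rows reappear (with the fitted heart) among the
                # stage-2 residuals; listing them here would double count.
                continue
            target = targets1[var]
            rows.append({"variable": var, "condition": cond1[var],
                         "target": target, "model": model,
                         "rel_error": (model - target) / target})
        out2 = self._stage2_outputs(genes2, patient, rm_mech)
        for key, model in out2.items():
            var, peep = key.split("@")
            target = self._rm_targets()[key]
            rows.append({"variable": var, "condition": f"RM PEEP {peep}",
                         "target": target, "model": model,
                         "rel_error": (model - target) / target})
        return pd.DataFrame(rows)


def replace_patient_cardio(patient: VirtualPatient,
                           cardio: CardioParams) -> VirtualPatient:
    return VirtualPatient(
        patient_id=patient.patient_id, lung=patient.lung, cardio=cardio,
        hb=patient.hb, bsa=patient.bsa, vr=patient.vr, ie=patient.ie,
        vo2=patient.vo2, vco2=patient.vco2, hco3=patient.hco3,
        severity=patient.severity, diagnostics=patient.diagnostics,
    )


@dataclass
class CohortCalibrationResults:
    """Per-patient calibration results plus pooled fit quality."""

    results: list
    fit_r2: float
    fit_p: float

    @property
    def patients(self) -> list[VirtualPatient]:
        return [r.patient for r in self.results]

    def summary(self) -> str:
        lines = [f"Cohort calibration: {len(self.results)} patients",
                 "=" * 48,
                 f"pooled model-vs-target r^2 = {self.fit_r2:.4f} "
                 f"(p = {self.fit_p:.3g})",
                 "-" * 48]
        for r in self.results:
            lines.append(f"{r.patient.patient_id:<6}{r.patient.severity:<10}"
                         f"stage1 {r.stage1_fitness:10.4g}  "
                         f"stage2 {r.stage2_fitness:10.4g}")
        return "\n".join(lines)


class CohortCalibration:
    """Calibrate every patient of a cohort (model object)."""

    def __init__(self, datasets: list[PatientDataset], **kwargs):
        if not datasets:
            raise ConfigurationError("empty cohort")
        self.datasets = datasets
        self.kwargs = kwargs

    def fit(self, seed: int = 0, progress=None) -> CohortCalibrationResults:
        results = []
        for i, ds in enumerate(self.datasets):
            cal = PatientCalibration(ds, **self.kwargs)
            results.append(cal.fit(seed=int(np.random.SeedSequence(
                [seed, 100 + i]).generate_state(1)[0] % (2**31))))
            if progress is not None:
                progress(ds.patient_id, results[-1])
        r2, p = cohort_fit_r2(results, self.datasets)
        return CohortCalibrationResults(results=results, fit_r2=r2, fit_p=p)


def cohort_fit_r2(results: list[CalibrationResults],
                  datasets: list[PatientDataset] | None = None):
    """Pooled squared correlation between model outputs and their targets.

    All calibration variables of all patients are pooled after normalising
    each variable by the cohort mean of its targets (so disparate units are
    comparable).  Being a correlation, the measure is insensitive to a
    common affine offset; residual tables carry the per-variable errors.
    Returns (r^2, p); (nan, nan) when the targets have zero variance.
    """
    if len(results) < 2:
        raise ValueError("need at least two calibrated patients")
    frames = pd.concat([r.residuals.assign(patient=i)
                        for i, r in enumerate(results)], ignore_index=True)
    scale = frames.groupby("variable")["target"].transform("mean")
    x = (frames["target"] / scale).to_numpy()
    y = (frames["model"] / scale).to_numpy()
    r, p = pearson(x, y)
    if np.isnan(r):
        return float("nan"), float("nan")
    return r * r, p
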