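# Methods

`ardsim` rebuilds, in silico, a three-stage study of ventilator-induced
lung injury (VILI) in ARDS: (1) generate a synthetic cohort of virtual-patient
observation sets with the statistical structure of a published 26-patient
adult ARDS series (13 severe / 7 moderate / 6 mild by Berlin PF-ratio
cut-offs); (2) calibrate a multi-compartment cardiopulmonary simulator to
each patient with a two-stage genetic algorithm; (3) sweep the calibrated
cohort over driving-pressure (ΔP) / PEEP interventions, compute VILI indices,
and correlate their cohort means with a relative-risk-of-death table.

The original study's full equation set and its source data are not publicly
deposited; the closures below are this package's own, chosen to satisfy every
structural statement about the simulator (100 parallel alveolar compartments
with threshold opening pressures, hypoxic pulmonary vasoconstriction,
four-chamber circulation, 10-ms recording) and standard physiology otherwise.
They are substitutes for the unavailable supplementary equations and are
flagged as such here.

## Lung mechanics

The respiratory zone is 100 parallel alveolar compartments behind a common
conducting-airway resistance `rc` (no gas compression; a series deadspace
volume enters gas exchange only). Each compartment `i` has

- a sigmoidal pressure–volume relation (Venegas form)
  `V(P) = vmax_i / (1 + exp(-(P - c0_i)/d_i))`, which represents both the
  low-compliance region at low volume and upper-inflection overdistension;
  the "stiffness" parameter is the midpoint compliance `c_i = vmax_i/(4 d_i)`;
- a bronchiolar resistance `rb_i` (cmH2O·s/L);
- a threshold opening pressure (TOP) and an extrinsic pressure `pext_i`.

A closed compartment receives no flow and its volume is frozen. It opens when
the junction (airway) pressure minus `pext_i` reaches its TOP (ties open) and
closes when that pressure falls below `TOP - δ`, with closing hysteresis
δ = 2 cmH2O by default. This rule is what produces intra-tidal recruitment:
units whose TOP lies between roughly `PEEP + δ` and the plateau pressure cycle
open/closed within each breath.

The ventilator applies a square pressure waveform (pressure-controlled
ventilation with instantaneous rise; ΔP = p_insp − PEEP). Integration is
fixed-step explicit Euler at 1 ms, recorded every 10 ms; halving the step
changes tidal volume by < 0.2 % (tested). A breath cycle is declared periodic
when tidal volume and total end-expiratory volume change by < 0.5 % between
breaths (at most 300 breaths; non-convergence is flagged, never silent).
Because there is no gas compression, ventilator-delivered tidal volume equals
the summed compartmental volume excursion exactly (tested to 1e-9 ml).

Plateau pressure is estimated as the local-compliance-weighted mean of open
compartments' end-inspiratory pressures (the pressure an end-inspiratory
occlusion would equilibrate to); peak pressure is the applied inspiratory
pressure. Measured airway resistance from (peak − plateau)/flow is therefore
small under near-complete pressure-controlled equilibration — a property of
this waveform, noted when interpreting the resistive term of mechanical power.

## Circulation

An eight-compartment lumped circulation: passive atria, time-varying-elastance
ventricles (sin² activation, systolic time `0.3·√T`), ideal-diode valves with
small series resistances, and Windkessel segments for systemic/pulmonary
arteries and veins. Intrathoracic compartments feel the pleural pressure,
taken as a configurable fraction of the breath-mean volume-weighted alveolar
pressure. The default fraction is 0.3: pleural transmission scales as
chest-wall elastance over total elastance, and for ARDS-stiff lungs
(Cstat ≈ 22 ml/cmH2O against a normal chest wall) the expected transmission is
well below one half. That coupling is what makes cardiac output fall as PEEP
rises. Flow-based Euler stepping at 1 ms conserves blood volume to machine
precision; beats are run to a periodic steady state (stroke-volume change
< 0.1 %). Defaults are tuned to a sedated, hyperdynamic ARDS adult: cardiac
output ≈ 9 L/min, MAP ≈ 90 mmHg, consistent with the emulated cohort's
baseline (cardiac index ≈ 5 L/min/m² at BSA 1.8 m²).

## Gas exchange

Steady-state, compartment-parallel: alveolar PCO2 per ventilated unit from the
ventilation/perfusion CO2 mass balance (blood CO2 content linearised,
`C = 28 + 0.5·PCO2` ml/dl), alveolar PO2 from the alveolar gas equation,
O2 saturation by the Severinghaus relation, O2 content `1.34·Hb·S + 0.003·P`.
Arterial blood is the perfusion-weighted mixture of end-capillary and shunted
(mixed-venous) blood; mixed-venous composition closes the loop through the
Fick principle at fixed VO2/VCO2. Hypoxic pulmonary vasoconstriction scales
each unit's vascular resistance by a logistic function of its local alveolar
PO2 (midpoint 40 mmHg, width 8 mmHg, patient-specific gain), redistributing
perfusion away from unventilated regions; shunt fraction is the perfusion
fraction of unventilated lung. Mixed-expired CO2 dilutes all eliminated CO2
into the full minute ventilation, giving the Bohr–Enghoff deadspace fraction
(PaCO2 − PECO2)/PaCO2. pH follows Henderson–Hasselbalch; bicarbonate defaults
to 24 mmol/L and is set per patient after calibration so the modelled baseline
pH equals the patient's datum. The venous fixed point is damped (0.9) and
iterated to 1e-9 ml/dl.

Treating each condition as a gas-exchange steady state is the package's
interpretation of "steady values per condition"; it is also why the simulated
recruitment maneuver holds the baseline driving pressure (25 cmH2O) while
stepping PEEP — at lower maneuver ΔP some severe lungs have tidal volume below
series deadspace and no steady CO2 balance exists.

## Virtual patients and calibration

Per-compartment properties are *realised from parametric distributions* with
~14 free pulmonary parameters rather than 400 free values: a consolidated
(never-recruiting) fraction, truncated-normal TOP mean/SD for the recruitable
population, log-normal compliance and perfusion heterogeneity, extrinsic
pressure mean, total airway resistance, series deadspace, VO2, VCO2, HPV gain
and the sigmoid midpoint/width. The realisation maps distribution quantiles
through fixed permutations, so it is deterministic and smooth in the
parameters — important for both GA tractability and bit-reproducibility.
Parameter bounds are physiological ranges (e.g. aerated-compartment compliance
15–60 ml/cmH2O, deadspace 80–230 ml, VO2 120–330 ml/min).

Stage 1 (pulmonary) matches PF ratio and static compliance at PEEP 10 cmH2O
and PaCO2/SvO2 at the ventilation baseline (PEEP 5, plateau 30, FiO2 1.0),
plus the PaCO2 of two recruitment-maneuver rungs (mid and top of the ladder),
which pin the otherwise-unidentified PEEP response of CO2 clearance. Stage 2
(cardiovascular) holds the lung fixed (its per-PEEP mechanics are cached) and
matches cardiac index, PaCO2, MAP and SvO2 across the maneuver ladder through
eight scale factors (contractility, systemic resistance, blood volume, venous
compliance, heart rate, pulmonary resistance, venous-return resistance,
pleural transmission).

The fitness is the unit-weighted sum of squared relative errors (zero weights
exclude a variable exactly). The optimiser is an elitist GA — tournament
selection (k=3), uniform crossover (rate 0.8), per-gene Gaussian mutation
(rate 0.1, σ = 0.15 of the range), elitism 2 — followed by a bounded
Nelder–Mead polish of the best individual (a memetic refinement; the GA
explores, the simplex sharpens). The stage-1 population is seeded with a
physiology-derived heuristic individual: shunt from the venous-admixture
O2-content balance, VO2 from Fick, aerated compliance from Cstat, deadspace
from the alveolar CO2 balance. Profiles: `full` (population 50; 100/50
generations), `fast` (12; 15/15, polish 120/100) for desk-scale runs, and
`smoke` (6; 4/4) for pipeline plumbing tests. Only output match is claimed —
the parameterisation is not identifiable and no unique recovery is asserted.

Cohort fit quality is the squared Pearson correlation between pooled model
outputs and targets (all calibration variables, all patients), each variable
normalised by the cohort mean of its targets. Being a correlation it is
insensitive to a common affine shift on a shared scale; per-variable residual
tables accompany it in every Results object.

## Synthetic cohort generator

Each patient's observations are truncated-normal draws using the published
cohort means/SDs: PaCO2 61 (5.2) mmHg, pH 7.24 (0.03), SvO2 74 (9.3) %,
cardiac index 5 (0.3) L/min/m², MAP 90 (2.6) mmHg, Cstat 22 (3.6) ml/cmH2O,
respiratory rate 12.5 (0.8) /min; PF ratio is drawn per severity stratum
(244/152/72 with SDs 37/37/9.6). Truncation enforces physiological ranges and
joint Fick feasibility: the SvO2 draw is truncated to the interval compatible
with the patient's drawn PF and cardiac index for VO2 in 130–330 ml/min.
Haemoglobin defaults to 10.5 g/dl and BSA to 1.8 m² (values the protocol uses
but does not print). Draws are independent between variables except for that
feasibility truncation; the true inter-variable correlation structure of the
source cohort is unknown, and this is a limitation — passing tests show the
pipeline recovers cohorts *of this structure*, not that it would match any
particular real patient series.

The recruitment-maneuver series steps PEEP through {10, 15, 20, 25} cmH2O at
the baseline driving pressure. Responses follow smooth monotone templates
plus measurement-scale noise (CI 0.1 L/min/m², PaCO2 1.5 mmHg, MAP 2 mmHg,
SvO2 0.01), kept mutually consistent through reflex-free relations — MAP
tracks CI through a Windkessel relation around a venous offset (the emulated
patients are deeply sedated; baroreflexes are deliberately absent from both
generator and simulator), SvO2 tracks CI through Fick. CI declines by 1.2 %
per cmH2O above PEEP 10. PaCO2 follows a severity-dependent convex profile,
`PaCO2_base · (floor + 0.0022·(PEEP−10)²)` with floors 0.75/0.78/0.82
(severe/moderate/mild): a recruitment-driven washout dip whose depth scales
with recruitable lung, then a hypercapnic rise as fixed-ΔP ventilation
overdistends. These template constants were set to the steady-state behaviour
of the simulator family itself, since the generator must emulate maneuver
responses the model class can exhibit; they are study conditions, not tuning
knobs. The ladder stops at PEEP 25 because a steady-state reading of higher
rungs is undefined for some severe lungs (tidal volume below deadspace).

Relative-risk tables are synthetic stand-ins, affine in ΔP with optional
noise, clipped strictly positive; real risk values can be supplied as a CSV
in the same schema.

## VILI indices

From the steady-state breath and physiological state:
C_RS = VT/(Pplat − PEEP) and elastance E = 1/C_RS; dynamic strain ΔV/V_frc
and static strain V_exp/V_frc with V_frc the total end-expiratory volume at
PEEP 0 (computed once per patient, at the baseline ΔP, and shared across all
conditions); intra-tidal recruitment as the percentage-point difference
between the ventilated fractions at end-inspiration and end-expiration
(a compartment is "ventilated" when open and receiving > 1 % of the mean
per-compartment tidal volume — a numeric floor for "zero ventilation");
mean alveolar pressure as the mean of the top 20 compartments (highest 20 %)
by end-inspiratory pressure; mechanical power
`0.098·VR·{VT²·[E/2 + VR(1+IE)/(60·IE)·Raw] + VT·PEEP}` J/min with VT in L;
oxygen delivery `CO·(1.34·Hb·SaO2 + 0.003·PaO2)·10`; Bohr–Enghoff VD/VT.
Strain sums ΔV over all compartments (not only initially-open ones).

## Intervention sweeps

Default grids: (1) ΔP ∈ {12, 15, 18, 21, 24} at PEEP 8; (2) PEEP ∈
{5, 8, 11, 14, 17} at ΔP 15; (3) (ΔP, PEEP) ∈ {(21,5), (18,8), (15,11),
(12,14)} — anchor pressures from the study text; all fully configurable.
Respiratory rate and I:E ratio stay at the calibration baseline. Cohort
mean ± SD per condition is correlated (product-moment r, two-sided p from the
t distribution with n−2 df) with the risk table; an index is flagged strong
at r > 0.85 and p < 0.05 (strict inequalities). Undefined correlations (zero
variance) are reported as NaN, never silently dropped, and non-converged
simulations are flagged per row.

## Problem sizes and numerical choices

Desk-scale defaults used by the test suite and the acceptance script: a
6-patient cohort (3/2/1 split) with the `fast` GA profile, which this package
treats as its scaled-down study; the full 26-patient, `full`-profile run is
the same code with different configuration. Integration steps are 1 ms
(recording 10 ms); mechanics tolerance 0.5 %, circulation 0.1 %, gas exchange
1e-9 ml/dl. Ties in recruitment open; compartment volumes are clamped to
[0.2 %, 99.8 %] of vmax for sigmoid validity, with mass balance computed from
realised volume increments so the clamp cannot leak volume. Zero driving
pressure yields zero tidal volume and well-defined (zero) strain and power;
C_RS is reported as undefined when Pplat ≤ PEEP.

## Known limitations

- All closures (P–V curve form, HPV law, cardiovascular topology, CO2
  linearisation) are this package's substitutes for the original simulator's
  unpublished equation set; absolute index values (e.g. strains) depend on
  them, while the qualitative intervention responses are robust.
- Each ventilator condition is evaluated as a full steady state; short-step
  maneuver transients (CO2 kinetics over minutes) are not modelled.
- No spontaneous breathing, no baroreflexes (deliberately, matching the
  sedated cohort), no gas compressibility, no CT-derived regional anatomy.
- Generator draws are independent between variables apart from Fick
  feasibility; real cohorts carry richer correlation structure.
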