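# Methods

## Model

`cvloop` is a closed-loop, lumped-parameter (0D) model of the adult
circulation. Six compartments carry the state — pressures in the left
atrium (la), left ventricle (lv), systemic arteries (sa), right atrium
(ra), right ventricle (rv) and pulmonary arteries (pa) — connected in a
loop by resistive paths: the four heart valves (mitral, aortic, tricuspid,
pulmonic) plus the systemic and pulmonic vascular beds. Three modelling
assumptions define the dynamics:

1. every chamber is a compliance vessel, `V(t) = C(t) P(t) + V_s`, with a
   fixed unstressed volume `V_s`;
2. chamber volume changes equal inflow minus outflow;
3. every resistive path is Ohmic, `Q = ΔP / R`.

Differentiating (1) and substituting (2)–(3) gives six coupled pressure
ODEs. Valves are ideal diodes with an optional leak: the valve coefficient
`U` is 1 when the upstream pressure strictly exceeds the downstream one and
`δ ∈ [0, 1)` otherwise (ties count as closed). `δ = 0` is a competent
valve; `δ > 0` models regurgitation as a proportional reverse conductance.

### Time-varying compliance

The pump function comes entirely from prescribed periodic compliance
waveforms, phase-locked to an ECG. Atria follow a raised-cosine relaxation
bump `u(t) ∈ [0, 2]` starting at `T_a`, so
`C = C_min + 0.5 (C_max − C_min) u`; the left atrium is delayed by `d_la`.
Ventricles follow a two-branch half-cosine activation `u_v(t) ∈ [0, 1]`
that peaks at `T1` and returns to zero at `T2`, delayed by `d`.

The product form `C_v(t) = C_sys · u_v(t − d)` sends ventricular
compliance to zero in diastole, which makes the pressure equations
singular and forbids filling; `cvloop` therefore defaults to an
*interpolated* convention,
`C_v(t) = C_dia − (C_dia − C_sys) u_v(t − d)`,
which preserves the activation shape while keeping `1/C` bounded. The
product form (with a small positive floor, default 0.05 mL/mmHg) is
retained as `ventricular_mode="literal"` for fidelity experiments.

Delayed activation arguments are evaluated modulo the cycle length, so all
compliance traces are continuous and T-periodic; this realises "the la
trace is the ra trace shifted by `d_la`" exactly.

### ECG coupling

A built-in generator synthesizes a clean single-lead PQRST template as a
sum of Gaussians at fixed fractions of the cycle (defaults: P 0.12 T,
Q 0.22 T, R 0.26 T, S 0.30 T, T-wave 0.55 T), with annotated ground-truth
fiducials. The detector finds R peaks as local maxima above 0.6× a centred
rolling maximum (window ±2.2 s, wide enough to always contain an R peak),
then locates P/Q/S/T as signed extrema in windows placed relative to each
R. Cycles are delimited R-to-R; because the activation mapping needs
P<Q<R<S<T inside one cycle, each cycle is anchored at `R − 0.26·RR`
(the generator's R-phase fraction, an overridable parameter), which puts
the boundary in the quiet TP segment. The first partial cycle is
discarded, so n R peaks yield n−1 cycles.

Per cycle the activation parameters are
`T_a = t_P`, `d_la = (t_P + t_Q)/2`, `d = t_R − t_P`,
`T1 = (t_R + t_T)/2`, `T2 = t_T`, `T = RR`.
This mapping is linear in the fiducial times (hence scale-equivariant),
and the generator→detector→mapping round trip reproduces the
annotation-derived timing to within one sample period.

### Integration and steady state

The valve diodes make the right-hand side discontinuous in state, so the
integrator is fixed-step classical RK4 (default `dt = 1e-4 s`) rather than
an adaptive, event-detecting scheme; compliances and their analytic
derivatives are pre-tabulated on the half-step grid per cycle. Output is
decimated (default every 10 steps, 1 ms). Halving the step changes the
steady stroke volume by < 0.5 %.

Steady state is the first cycle whose lv pressure–volume loop differs from
the previous cycle's by less than 1e-3 in range-normalised max-norm, each
loop resampled on a common 400-point phase grid. With the calibrated
profile (whose initial pressures start near the limit cycle) the healthy
run converges in 5 cycles (4.0 s of simulated time at 75 bpm).
Non-convergence is flagged, not fatal.

Closed-loop volume `Σ C_i(t) P_i(t) + Σ V_s` is conserved to machine
precision at steady state (tested at < 0.1 %/cycle).

## Cardiac phases and indices

Within one steady cycle the left-heart phase sequence is delimited by
consecutive aortic-valve closures: isovolumetric relaxation (I) until the
mitral valve opens, filling (II) until it closes, isovolumetric
contraction (III) until the aortic valve opens, ejection (IV) until it
closes. EDV is the lv volume at the II→III boundary, ESV at the IV→I
boundary. When either isovolumetric interval (nearly) vanishes — as under
significant regurgitation — the segmentation is annotated
`no_isovolumetric` rather than raising.

Indices: `SV = EDV − ESV`; forward SV = the cycle integral of rectified
aortic flow; `CO = forward SV × HR`; `EF = SV/EDV`; MAP = time-average of
`P_sa` over the cycle (the full waveform is available, so no
diastolic + pulse/3 approximation is used); ESPVR/EDPVR = `P_lv/V_lv`
ratios at the end-systolic and end-diastolic loop corners, with no volume
offset. Chamber diameters use the prolate-ellipsoid relation
`d = sqrt(6V/(π k l))` (la: k = 1.2, l = 5.5 cm; lv: k = 1.15, l = 8 cm),
which reduces exactly to the sphere `V = πd³/6` for `k = 1, l = d`. The
left-atrial diameter LAEDD is read at the lv end-diastolic instant.

## Valve disease

*Stenosis* raises the trans-mitral resistance. Grade presets are ratios to
the healthy resistance — mild 5×, severe 15×, very severe 50× — applied to
whichever profile is active so they survive recalibration. An orifice-area
formula is also exposed in two orientations; the proportional one
(resistance ∝ area) contradicts the physics of a narrowing orifice and the
grade table's direction, so presets are the default pathway and the
inverted orientation (`R_d = (A_N/A_MS) R_mi`, normal area 4 cm²) is used
for area-based construction.

*Regurgitation* sets the mitral leak `δ_mi` (presets: mild 0.004, moderate
0.024, severe 0.05). Severity is quantified by the regurgitation fraction
`RF = (V_mi − V_ao)/V_mi × 100`, with `V_mi`/`V_ao` the cycle integrals of
rectified mitral/aortic forward flow.

### A structural note on RF versus stroke volume

In any flow-conservative realisation of this model, the forward mitral
volume per steady cycle equals the aortic forward volume plus the mitral
backflow, and the total stroke volume EDV − ESV is (to phase-boundary
accuracy) the forward mitral volume. Hence `RF ≈ 1 − forward SV / total
SV`: a regurgitation fraction near 90 % requires a total stroke volume
about nine times the forward one. Published index sets that combine a
severe RF near 89 % with a total SV under 100 mL and a forward SV near
60 mL cannot be produced by a conservative model; they can arise when
flow integrals and compliance-reconstructed volumes are mutually
inconsistent (as the literal zero-diastolic-compliance convention
permits). `cvloop` keeps conservation; with the calibrated profile the
severe leak yields RF ≈ 74 % at a total SV ≈ 135 mL, and the mild leak
RF ≈ 24 %. All severity orderings (RF and total SV rising, MAP and
forward SV falling with `δ`) hold strictly. The moderate preset's
RF ≈ 63 % classifies as severe under the RF > 49 % band, so the
grade→RF→grade round trip holds for the mild and severe presets only.

## PPG synthesis

The peripheral pulse is `p(t) = (k1 P_sa − k2 P_ra)/R_s` with k1 = 1,
k2 = 2.5, unit-free; only morphology and relative amplitude are
meaningful. Feature extraction re-anchors each analysis window at the
systolic peak (simulation cycles begin mid-diastole) and reports the
systolic peak/amplitude, and — when the falling edge carries a local
extremum pair — the dicrotic-notch time and diastolic amplitude; absent
extrema are reported as missing, not errors. With the fixed k1/k2 and the
calibrated right-atrial dynamics the healthy falling edge is monotone with
inflections (no separate diastolic maximum), and the venous term
contributes a companion peak inside the systolic complex. Across disease
severity the systolic amplitude falls monotonically for both stenosis and
regurgitation.

## ECG point scores

The left-atrial enlargement score awards 5 points per satisfied P-wave
criterion (lead II bifid-P peak separation > 40 ms, lead II P duration
> 110 ms, lead V1 terminal-negative duration > 40 ms, lead V1
terminal-negative amplitude ≥ 1 mm); ≥ 15 is abnormal. The 5-point
weighting is the only uniform one consistent with that threshold and
scores of 20 on all four criteria. The lv-hypertrophy score sums: 3 for
any voltage criterion (limb R/S ≥ 20 mm, S in V1/V2 ≥ 30 mm, R in V5/V6
≥ 30 mm), 3 for an ST-T vector opposite the QRS without digitalis but 1
with digitalis (the standard weighting; a 3-point with-digitalis rule
would be inconsistent with a digitalis-treated patient scoring 4), 3 for
left-atrial enlargement, 1 for QRS ≥ 90 ms, 1 for intrinsicoid deflection
≥ 50 ms in V5/V6; ≥ 5 is abnormal. Measurements recorded as
threshold-qualifying ("≥ 1 mm", "≥ 50 ms") satisfy their criteria, so
those two comparisons are inclusive. Axis-deviation and other omitted
items are out of scope, so the maximum reachable score here is 11.

## Parameter profiles and calibration

Two profiles ship. `published` is the published constant table
verbatim (with the literal, floored ventricular convention). It is not a
working baseline: its systemic resistance (0.05 mmHg·s/mL) would drop only
~4 mmHg at 5 L/min — two orders of magnitude short of a physiological
MAP — and its atrial compliances (0.2–0.3 mL/mmHg) imply atrial volumes of
a few mL.

`calibrated` is the default and the basis of every quantitative claim.
Targets: the healthy steady state at 75 bpm (CO 5.2 L/min, EF ≈ 56 %,
MAP 101 mmHg, LVEDV 125 mL, LVESV 55 mL), with the regurgitation-fraction
and stenosis-severity responses as joint constraints since disease presets
reuse the same profile. Calibration was coordinate-descent-style: each
parameter has one dominant observable, iterated to convergence —

- `R_s = 1.08` from MAP ≈ mean `P_ra` + CO·R_s;
- `C_sa = 1.6` from the arterial pulse pressure ≈ SV/C_sa;
- `R_p = 0.08` from a pulmonary drop of ~7 mmHg at resting CO;
- `C_dia_lv = 10`, `C_sys_lv = 0.20` with `V_s,lv = 30` from the EDV and
  ESV targets; the split between unstressed volume and systolic compliance
  fixes how strongly ESV tracks afterload, and was chosen so EF falls
  (rather than stays flat) as stenosis throttles preload;
- `C_dia_rv = 14`, `C_sys_rv = 0.6` for right-heart volumes of the same
  order at pulmonary pressures;
- atrial `C_min = 3.0`, `C_max = 4.5` for atrial volumes consistent with a
  ~3–4 cm atrial diameter and a ~10 mL atrial kick;
- `R_mi = 0.002` pinned by the mild-regurgitation fraction (RF(δ=0.004) ≈
  23–24 %), the most sensitive single target; valve resistances
  `R_ao = 0.01`, `R_tr = R_pu = 0.005`;
- initial pressures (la/lv 8.5, sa 100, ra/rv 5, pa 16 mmHg) set the total
  blood volume — which the conservative loop preserves forever and which
  therefore determines the limit cycle — and start the run near it.

All values are frozen in `profiles.py`; disease severities perturb only
the mitral parameters.

## What the synthetic data does and does not emulate

The ECG generator produces noiseless, strictly periodic, single-morphology
PQRST beats with fiducials at fixed cycle fractions; optional additive
white noise is available (seeded) but off by default. It does not emulate
heart-rate variability, baseline wander, muscle artifact, ectopy, or
morphology changes with disease — so passing fiducial tests demonstrate
correctness of the detection/mapping pipeline on clean signals, not
robustness on clinical recordings. Likewise the circulation model omits
inertial elements, baroreflex control, mechano-electric feedback and
regional wall mechanics: disease results are trend-level physiology of a
compliance-resistance network, not patient-specific prediction.

## Numerical choices and degenerate inputs

Valve ties (equal pressures) count as closed; no hysteresis is applied, so
the RK4 stages may straddle a switching instant — acceptable at
`dt = 1e-4 s` (step-halving test). Zero or negative compliance raises a
singular-model error; non-finite states abort integration with a
diagnostic. Fiducial detection requires at least two R peaks and raises a
detection failure on flat or too-short signals. `RF` is undefined at zero
forward mitral volume. Phase segmentation requires one cycle beyond the
analysed one, as does PPG feature extraction (its window is re-anchored at
the systolic peak).

## Problem sizes

Default runs integrate 12 cycles at 75 bpm (9.6 s of simulated time,
96 000 RK4 steps) and analyse the first steady cycle; the stress what-if
uses 16 cycles at 120 bpm. These sizes put every reported index on the
limit cycle with loop-to-loop distances below 1e-3.

## Known limitations

- Severe-regurgitation RF and total SV cannot jointly match the published
  pair (see the structural note); reported values are the conservative
  model's.
- ESPVR/EDPVR are simple corner ratios; printed reference values for them
  are not reproducible under any simple convention and are excluded from
  quantitative claims.
- The ventricular activation starts at `t = d` (delay measured from the
  cycle origin, per the activation mapping), slightly before the R peak
  for nonzero `t_P`; consequently isovolumetric contraction is longer than
  in textbook tracings.
- The healthy PPG lacks a distinct diastolic maximum (monotone falling
  edge with inflections) under the fixed k1/k2 weighting.
- Real-ECG ingestion is limited to single-column CSV; standard
  physiological waveform-database formats are out of scope.
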