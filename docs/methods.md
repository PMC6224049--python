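# Methods

This note records the model equations, the default parameter choices and
their rationale, the synthetic-data design, numerical settings, and known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Closed-loop 0D circulation

The circulation is an electrical-analog network: four elastance chambers
(LV, RV, LA, RA), four smooth-diode valves, systemic and pulmonary R-C
chains, and two coronary outlet blocks. The state vector holds one volume
per chamber and per capacitive node plus one flow per inertial element;
the right-hand side is a Kirchhoff flow balance with

    ΔP = R·Q,   dV_C/dt = Q_in − Q_out,   P_C = V_C/C + P_ext,
    L·dQ/dt = ΔP − R·Q.

Every element moves volume between two tracked nodes, so total blood
volume is conserved identically; `volume_conservation_error` audits the
integrated trajectories (observed deviations are at solver tolerance,
orders of magnitude below the 1e-3 acceptance bound). Constant- or
prescribed-pressure reservoirs can be attached for open-loop bench tests
and deliberately break closure.

**Chambers.** `P = E(t)(V − V0)`, `E(t) = E_min + (E_max − E_min)·a(φ)`
with a raised-cosine activation: ascent to 1 at phase `t_peak_fraction`,
descent to 0 at `systole_fraction`, zero in diastole. Absolute systolic
duration follows a cube-root-of-period rule (36% of the cycle at 73 bpm,
so the fraction grows at higher rates while the duration shrinks — the
basis for the increasing diastolic dominance of coronary flow under
stress). Atria reuse the family phase-shifted to fire just before the
R wave (onset 0.85, duration 0.13 of the cycle); their parameters are not
patient-derived and contribute a minor part of ventricular filling.

**Valves.** `Q = dP·(s/R_open + (1−s)·g_leak)` with `s = σ(k·dP)`,
`k = 2 /mmHg` by default: continuously differentiable, `Q(0)=0`,
asymptotically the ideal open/closed laws. The blend has a negligible
non-monotone dip near the closing point (order 1% of forward flow);
accuracy in the simulated waveforms is controlled by the step-refinement
test rather than by event location.

**Wall-derived compliances.** Aortic-root and main-PA compliances come
from the linearized stiffness `E = ΔP/ΔD·D_diast·h` (wall thickness fixed
at 1 mm) through the thin-wall ν=½ membrane relation
`C = 3πD³L/(16Eh)`. The packaged wall specs are synthetic: diameters are
back-solved so the stiffnesses equal the published magnitudes
(2.26e5 systemic, 1.30e5 pulmonary, in g/mm·s²; ratio 1.74) at plausible
pediatric dimensions — the measurements behind those magnitudes are not
published, so the specs are plausibility anchors, not data.

**Units.** The core uses mmHg, mL, s throughout. Conversions (mmHg·mL →
J via 1.33322e-4; resistance → indexed Wood units with the configured
BSA) happen only at the reporting boundary. BSA defaults to 0.75 m²
(typical 6-year-old; never published for the study patient).

## Coronary blocks and metabolic control

Each territory is `R_prox — C_art — R_micro — C_im — R_ven` between the
aortic root and the systemic venous node (coronary return re-enters
upstream of the right atrium). `C_im` is loaded by the broadcast pressure
of its ventricle (LCA→LV, RCA→RV — the mechanism discussion of the source
study attributes RCA systolic impediment to RV compression). Internal
resistance split: 6% proximal, 72% microvascular, 22% venous. `C_im` is
sized so the intramyocardial emptying time constant
`C_im·(R_micro ∥ R_ven)` is 0.25 s — of the order of systole — so
compression blocks forward throughput for the whole systolic interval
rather than a brief transient; `C_art` is small (1.5e-3 mL/mmHg) so the
epicardial inflow waveform follows the microvascular bed instead of being
masked by capacitive surge. In a linear block the P_v oscillation cannot
change the *mean* flow (superposition); it shapes the waveform — systolic
impediment/reversal, early-diastolic refilling surge — which is exactly
what the diastolic/systolic splits measure.

**Demand.** Oxygen demand is computed per heartbeat from the just-closed
PV loop: `MVO2 = (α·PVA + β)·HR`, `PVA = loop work + ½P_es(V_es − V0)`
(end-systole taken at peak activation). Both the mechanical term and the
basal term β are per-beat costs — excitation-contraction coupling and
activation metabolism are paid once per beat, so total demand scales with
heart rate. β defaults to 20% of the Rest anchor at the Rest rate; α
absorbs the remainder (`fit_oxygen_constants`), anchored to the published
Rest MVO2 values (LV 5.42, RV 5.10 mL/min).

**Supply and hunger.** `supply = extraction·CaO2·Q̄_micro·60` with CaO2 =
0.2 mL O2/mL blood and the fixed per-condition extractions (Rest LCA 0.8
/ RCA 0.4; Stress and PRS 1.0 both, applied as instantaneous scenario
constants). Hunger integrates `max(0, demand − supply)` per beat; the
zero clamp encodes "no oxygen credit".

**Controller.** Once per completed beat,
`R_micro ← clip(R_micro·(supply/demand_eff)^κ, R_min, R_max)` with
κ = 0.5. The effective demand adds a hunger-repayment term,
`demand_eff = demand + γ·hunger` with γ = 0.5 /min: without it the
controller would equilibrate at supply = demand and freeze any
accumulated debt, whereas the long-horizon behavior to reproduce is
hunger *normalizing* to zero when demand is reachable. γ sets the debt
repayment time constant (~2 min), comfortably inside the 5-minute
long-run horizon. The multiplicative form has the exact fixed point
supply = demand (as hunger → 0), needs no tuning to the hemodynamic ODE
stiffness, and its one-step linear-limit behavior (halved supply at κ=1
halves the resistance) is tested.

**Reserve floors.** `R_min` is set per territory as a fraction of the
converged Rest microvascular resistance: 0.30 for the LCA (a healthy
reserve of ~3x) and 0.65 for the RCA. The asymmetry encodes the lower
vasodilator reserve of the RCA territory and the capillary-density
inadequacy of a hypertrophied, pressure-loaded RV; a deep uniform floor
would make RCA reserve exhaustion in PRS unreachable under the fixed
extraction schedule, because the required PRS microvascular resistance is
only about half the Rest value. Floors are config-exposed, and the PRS
finding should be read as conditional on this reserve assumption.

## Conditions

- **Rest** (HR 73): staged calibration — ventricular elastances derived
  from (synthetic) cycle data; bulk resistances from algebraic estimates
  `SVR = (MAP − CVP)/CO`, `PVR = (mPAP − LAP)/CO` distributed over the
  chains (70% of the systemic drop arteriolar); then bounded least
  squares over nine parameters (distal resistance scales, compliance
  scales, a proximal-pulmonary scale, elastance scales, venous pressure
  scale) on weighted relative residuals of 13 monitored targets. The
  optimizer restarts its trust region up to twice within the evaluation
  budget; finite-difference Jacobians on warm-started periodic runs are
  mildly noisy and a fresh region escapes premature termination.
  Warm-started runs are volume-rebalanced to the model's prescribed total
  first — in a closed loop the total is conserved, so a stale warm start
  would silently override preload parameters.
- **Stress** (HR 106, extraction 1.0): elastances re-derived from stress
  cycle data (sharing the patient-level V0 — the unstressed volume is a
  property of the ventricle, not of the condition), atria retimed, tissue
  stiffness kept; distal resistances, preload and contractility scalings
  refined against the stress targets. The proximal pulmonary resistance
  is also freed per condition: it is the operating-point linearization of
  the stenotic bed, whose quadratic pressure loss makes the effective
  linear resistance flow-dependent. The stress CO target is volumetric
  (Table-1 volumes); the published flow-based ~45% CO rise is emitted as
  an alternative target basis but not fitted, since the two are mutually
  inconsistent.
- **PRS**: systemic arteriolar + venous resistances scaled by a common
  vasodilation factor found by bracketing root-finding so the converged
  MAP equals 0.69× the Stress MAP (tolerance 0.5%); venous capacitance
  scales inversely with the same factor (generalized vasodilation pools
  blood in dilated veins) — without venodilation the arterial volume dump
  raises preload enough to drive an unphysiologic ~40% CO surge and LV
  demand *rises* into PRS instead of falling. HR, elastances and
  extractions are inherited from Stress. A drop fraction of 0 returns the
  Stress model unchanged.

## Synthetic data

The generator emulates the modality structure of the real inputs: volume
curves at 25 frames/cycle (cine-like), pressure at 256 samples/cycle
(catheter-like), aligned by an R-wave marker. Ground truth: an analytic
elastance designed so E_min reproduces the end-diastolic pressure at EDV
and E_max makes the peak pressure of the elastance-driven beat equal the
ventricular systolic target; the data are that law sampled over a
raised-cosine ejection/filling volume waveform. Noise is multiplicative
log-normal (2% volumes, 1% pressures) plus 5 ms Gaussian R-wave jitter,
all seeded and bit-reproducible; every dataset carries its generating
parameters so recovery tests compare to truth, never to figures.

Default condition targets: Table-1 heart rates and indexed volumes;
aorta 100/60 mmHg at Rest and 110/48 at Stress (high-dose dobutamine
raises systolic pressure while vasodilation lowers diastolic — the
stress protocol is explicitly chosen to mimic reperfusion-level SVR
reduction); RV/aortic systolic ratio 0.75 at Rest ("near-systemic" RV
pressure) and the published 1.14 at Stress; mean PAP 40 → 60 mmHg (the
stress value follows from the RV systolic target at the stiff PA root);
CVP 6, LAP 8, EDP 8/10 (LV/RV Rest), 7/9 (Stress). What passing tests on
these data do *not* show: robustness to real measurement artifacts
(breathing drift, segmentation bias, beat-to-beat variability), to
model-form error in the elastance family, or to atrial/ventricular
interaction absent from the generator.

## Numerical choices

LSODA with rtol 1e-6 / atol 1e-8 (calibration inner loops: 1e-5/1e-6),
dense output on a 1 ms grid, integrated beat by beat so the controller
can act between beats. Periodic steady state: relative L2 change of the
cycle trajectory below 1e-3 (plus, with the controller on, every
territory saturated or within 0.5% of its fixed point). Valve switching
is handled by the smooth law, not event detection; a grid/tolerance
refinement test bounds the residual discretization error at < 0.5% on
cycle-averaged quantities. PRS root-finding: `brentq` on the vasodilation
scale, warm-started probes at relaxed tolerance, final run at full
tolerance. The whole three-condition study runs in about one minute on
one CPU; the long-horizon PRS run uses 250–300 beats (~3 minutes of model
time), enough for the LCA debt (repayment constant ~2 min) to decay well
below its peak while RCA hunger grows linearly.

Single-beat elastance derivation: the reconstruction is linear in
(E_min, E_max) given (V0, t_peak, t_systole), so those enter a
least-squares inner solve while the three shape parameters are
grid-seeded and Nelder-Mead-polished. On noiseless data the generating
parameters are recovered to well under 1%. Under realistic noise, V0 and
E_max trade off along a near-flat valley (only their combination at the
end-systolic samples is well determined): E_max uncertainty is then of
order 10–15% despite sub-percent reconstruction error. This is an
identifiability limit of single-beat data, not an estimator defect;
fixing V0 externally restores ~3% recovery, and the downstream pipeline
is insensitive because calibration re-scales elastances anyway.

## Limitations

- No interventricular dependence (no pressure feedback between the
  ventricles), no pericardium; PRS RV loading is therefore optimistic.
- Metabolic coronary control only — no myogenic or endothelial pathways,
  no oxygen-transport dynamics, no regional heterogeneity; extraction
  fractions are scenario constants.
- The coronary venous side has no valves, so the model shows some
  early-diastolic venous back-filling of the intramyocardial compartment.
- Published coronary flow/resistance magnitudes are not reproduced
  numerically (the source LPN parameter tables are unavailable and the
  published coronary numbers are not mutually consistent with the stated
  extraction schedule under exact supply-demand matching); the package
  asserts the qualitative coronary findings and the table-arithmetic
  derived figures instead.
- Stress aortic systolic/diastolic/MAP targets are over-determined at
  constant linear arterial compliance (pulse pressure is capped by C and
  stroke volume); the calibration resolves the conflict by weight, which
  is why the achieved stress aortic systolic sits below its target while
  MAP is matched.
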