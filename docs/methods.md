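# Methods

## Overview

ssikit estimates, for each candidate site in a coronary tree, how fast
maximum wall shear stress (WSSmax) rises as fractional flow reserve (FFR)
falls when a virtual stenosis at that site grows.  The slope magnitude is
the stenosis susceptibility index (SSI); the minimum-SSI site is the
predicted most plaque-prone location.  The chain is:

1. coronary tree (segment graph with lengths/diameters, RCA territory tags),
2. vessel-length-calibrated lumped-parameter outlet resistances,
3. reduced-order network solves with a virtual lesion at 0/25/50 % severity,
4. per-site OLS slope of WSSmax against FFR, ranking, and concordance
   reporting against PCI observations.

## Tree model

Segments are straight pieces with linearly tapering diameter; hydraulics
use the mean diameter.  The graph is a forest with exactly one rooted tree
per artery (RCA, LAD, LCX); the same inlet pressure is applied at every
artery root (no aortic root model).  RCA segments carry an RV or LV
perfusion tag because the two territories enter the resistance model
differently.  Geometric sanity bounds: positive lengths/diameters and
distal ≤ 1.5 × proximal diameter (configurable).

*Summed length* per artery counts segments whose **proximal** diameter
strictly exceeds a threshold, default 1.5 mm.  The threshold is
deliberately configuration, not a claim: it controls which small branches
count as resistance-relevant vessel length.  Summed length is additive
under segment splitting and nonincreasing in the threshold (both property-
tested).

## Outlet resistance calibration

Microvascular beds are pure resistances.  Longer epicardial supply means
more perfused muscle and less downstream resistance, hence R ∝ 1/l per
artery, with the RCA split into a series pair — the RV-feeding part
up-weighted by α (default 3.45, a typical LV/RV muscle-volume ratio, so
RV-feeding length contributes correspondingly less flow demand):

    R_LAD = k/l_LAD, R_LCX = k/l_LCX, R_RCA = αk/l_RV + k/l_LV.

k is fixed by requiring that the three arteries in parallel carry the
total hyperemic flow Q_total under the aorta-to-venous pressure
difference ΔP:

    k = (ΔP/Q)[ l_LAD + l_LCX + l_RV·l_LV/(l_RV + α·l_LV) ].

This closure is exact algebraically and is enforced to 1e-10 relative
over random physiologies in the tests.  Arteries (or RCA territory
branches) with zero qualifying length receive an infinite-resistance
sentinel rather than being dropped, so network assembly stays uniform.

Within an artery, the allocated resistance is split over the terminal
segments by the same length principle applied recursively: at each
junction, conductance divides in proportion to the downstream total
vessel length of each daughter branch.  The parallel combination of
outlet resistances therefore reproduces the artery value exactly.  A
Murray-law split was considered and rejected to keep a single calibration
principle throughout.

Defaults (all config-exposed): ΔP = 90 mmHg, Q_total = 14 mL/s (hyperemic
total coronary flow), μ = 0.0035 Pa·s, ρ = 1060 kg/m³, venous pressure
0 mmHg — literature-typical hyperemic values.

Collateral flow is an optional on–off switched resistance in parallel
with an outlet, engaging when the local distal pressure falls below a
threshold (default 30 mmHg; collateral resistance default 10 × the outlet
value).  Default off; the switch state is re-evaluated inside each solver
iteration.

## Network solver

A 0D resistive network replaces three-dimensional CFD.  Segment loss is
Poiseuille, R = 128 μL/(π d⁴) at the mean diameter.  A lesion replaces
its own length of the host segment with a Young-type empirical loss

    ΔP = K_v (μ/d_ref) V + K_t (ρ/2)(A_ref/A_min − 1)² V|V|,
    K_v = 32 (L/d_ref)(A_ref/A_min)²,  K_t = 1.52,

with V the mean velocity at the reference (healthy) area.  At 0 %
severity the quadratic term vanishes identically and the viscous term
*is* the Poiseuille drop of the lesioned length, so a zero-severity
lesion is hydraulically null to machine precision (tested at 1e-12
relative).  The residual segment resistance is the full-segment value
minus the lesion-length Poiseuille drop at the reference diameter,
clamped at zero (the clamp can only engage for long lesions parked at the
narrow end of a strongly tapering segment).

Unknowns are the pressures at each segment's distal node.  Junction mass
balances are solved by damped Newton iteration (analytic Jacobian;
step halved while the residual norm would increase; convergence at
max residual ≤ 1e-10 × the largest flow, ≤ 100 iterations).  Flows
through quadratic edges use the cancellation-safe root
q = 2|ΔP|/(c + √(c² + 4b|ΔP|)).  The solver is cross-checked against an
independent generic root-finder (scipy `hybr` with flows recovered by
bisection of the drop law) to 1e-8 relative on random lesioned trees.

Pulsatile mode is quasi-static: the network stores no volume (no
compliance or inertance — the resistive boundary model has none), so each
waveform sample is an independent steady solve.  FFR in pulsatile mode is
the ratio of cycle-averaged distal to cycle-averaged inlet pressure;
WSSmax is the spatiotemporal maximum (peak over cycle samples of the
throat value).  Time-averaged WSS is recoverable from the per-sample
states if preferred.  Because the lesion drop is superlinear in flow, the
cycle-averaged FFR sits slightly below the FFR at the mean pressure
(verified as a Jensen-gap test).

Units: mmHg, mL/s, mm at every interface; SI internally;
1 mmHg = 133.322 Pa; WSS reported in Pa and dyn/cm² (×10).

## Virtual stenosis sweep

Candidate sites default to fractions 0.25/0.5/0.75 of each artery's main
trunk (the root-to-leaf path of greatest cumulative length) — a
convention, since site selection is clinical context in practice.
Severity is percent diameter reduction of an axisymmetric lesion; default
grid {0, 25, 50} %, default lesion length 10 mm (clipped to the host
segment).  The sweep is a pure function of the tree; outlet boundary
conditions are calibrated once from the lesion-free tree and held fixed
across severities (vessel lengths, the only calibration input, are
unchanged by a virtual lumen narrowing), which isolates the lesion's
hemodynamic effect.  One lesion per sweep; serial-lesion interaction is
out of scope.

## SSI estimation and reporting

The primary estimator is the OLS slope of WSSmax (y, dyn/cm² by default)
on FFR (x) over the sweep points, negated so SSI ≥ 0 when the response is
monotone; r² is reported for fits with ≥ 3 points.  The simplified ratio
WSSmax/(1 − FFR) is exposed as a secondary method and coincides with the
two-point slope under the (FFR = 1, WSS = 0) baseline (identity tested to
1e-12).

Ranking returns per-artery minima and the global minimum; exact ties are
flagged and broken by artery order (RCA, LAD, LCX), then proximal-most
position.

Concordance compares predicted minimum-SSI site ids with PCI site ids per
treated vessel.  A vessel matches when the ids coincide; a patient
matches when *every* treated vessel matches (on the encoded pilot table
an any-vessel rule gives the same 5/7, so the stricter rule was chosen
and documented).  Rates are kept unrounded internally and rounded to one
decimal for display.  With zero treated vessels the per-vessel rate is
reported as undefined (None), not 0.

The pilot-cohort fixture encodes the published seven-patient table:
per-artery minimum SSI values, MI flags, and treated/match marks
(o = matched, × = mismatched, blank = artery not evaluated — Case IV's
LCX).  PCI site ids in the fixture are synthetic labels constructed so
that matched vessels share the predicted id and mismatched ones do not;
the SSI magnitudes are treated as unitless labels for ranking only, since
they came from full 3D CFD on CT anatomies that a reduced-order model
does not reproduce.

## Synthetic data generator

Trees: per artery, a trunk (length 40–120 mm, root diameter 2.5–4.5 mm)
plus branches (20–60 mm) attached to uniformly chosen parents, with mild
per-segment taper; RCA territories tagged by cumulative length fraction
(default RV fraction 0.55), forcing both territories present when the
artery has ≥ 2 segments.  Diameters are floored at 1.7 mm proximal /
1.6 mm distal so every generated segment qualifies at the default
summed-length threshold and both RCA territories stay conductive.  All
generation is a pure function of the seed.

What the generator does *not* emulate: sub-threshold twigs, anatomic
curvature and bifurcation angles, inter-patient covariance of diameter
and length, diffuse disease.  Passing tests therefore demonstrate the
method's internal consistency and its qualitative behaviour (monotone
severity response, near-linear WSS–FFR relation with r² ≥ 0.9 over
{0,25,50} %), not agreement with patient-specific 3D CFD magnitudes.

Waveforms: a two-phase parametric cycle — half-sine systolic rise over
the first third of the period, exponential diastolic decay (rate constant
5 per diastole) — affinely rescaled so the sampled max/min equal the
requested systolic/diastolic pressures; the cycle mean then lands near
the clinical estimate DBP + PP/3.

## Problem sizes

Default test and verification sizes: 9-segment trees (3 per artery), 9
default sites, 3 severities; the monotonicity verification spans 100
seeded trees (2 700 steady solves) and the solver cross-check 20 lesioned
trees; the full suite and the acceptance script each complete in seconds
on one core.  Sizes are package choices balancing coverage against a
quick edit-test loop; all scale linearly if raised.

## Known limitations

- Reduced-order hemodynamics: no 3D flow features (recirculation,
  eccentric jets, pressure recovery), so absolute SSI magnitudes are not
  comparable with values derived from 3D CFD; rankings and trends are the
  meaningful outputs.
- Newtonian rheology, rigid walls, no autoregulation, no intramyocardial
  pressure; pulsatile mode is quasi-static.
- Symmetric axisymmetric lesions of fixed default length only.
- The MI risk cut-off for SSI is out of scope (insufficient data to
  define one).
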