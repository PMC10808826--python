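# Methods

## Problem and model overview

After splenectomy for portal hypertension with splenomegaly, the residual
splenic vein (SV) is ligated near the splenic hilum and becomes a dead-end
stump. Blood stagnates there, wall shear stress (WSS) collapses, and portal
venous system thrombosis is a frequent sequela. The package quantifies this
risk with a single hemodynamic score, **ALWSS** — the area of the portal
venous wall exposed to WSS below a patient-specific threshold set at 20% of
the space-averaged WSS of the whole portal venous surface — and evaluates
how well ALWSS predicts thrombosis on synthetic cohorts with known risk
structure.

Rather than a full 3D CFD solve on image-derived surfaces, the portal
venous system is reduced to a centerline network of five vessels — portal
vein (PV), superior mesenteric (SMV), splenic (SV), left gastric (LGV) and
inferior mesenteric (IMV) veins — each a tube with a piecewise-linear
radius profile, a length and a scalar tortuosity. Within each tube, flow is
steady, fully developed, axisymmetric generalized-Newtonian flow in a rigid
no-slip tube. This keeps every quantity the score needs (per-strip wall
area and WSS) while giving up junction recirculation, secondary flows and
pulsatility (see Limitations).

## Geometry

* Coordinates: normalized arclength per segment, 0 = proximal (inflow) end,
  1 = distal end; radii are linearly interpolated between profile samples.
* Junctions are point nodes. Three anatomical variants are wired by where
  the LGV and IMV drain: Type 1 — both into the SV; Type 2 — LGV into the
  PV, IMV into the SV; Type 3 — LGV into the SV, IMV into the SMV.
* Connections "into the SV" are anchored at the SV's distal confluence
  node (where SMV and SV meet to form the PV). Consequence: after ligation
  the SV carries exactly zero flow in every anatomy type, and the stasis
  floor ALWSS ≥ π·D_SV·L_SV holds exactly. Connections into the PV (Type 2)
  and SMV (Type 3) are genuine mid-course junctions at fractional arclength
  0.35 and 0.50 of the host respectively (configurable); the host's flow is
  piecewise constant with a jump at the junction.
* Virtual splenectomy closes the SV's proximal end (role → `stump`) and
  touches nothing else; all geometric fields are preserved exactly,
  reflecting the assumption that the operation does not reshape the rest of
  the portal system.
* The "SV distance" descriptor is defined as the straight-line distance
  between the SV endpoints, computed as length / tortuosity. The stump tip
  cap area is ignored (lateral area only).
* Surface discretization: circumferential strips of axial extent ≈ dx
  (default 1 mm), area 2πR(s_mid)·Δx. The midpoint rule is exact per strip
  for constant and linearly tapered radii; total per-segment area matches
  the analytic lateral area to well under 0.1%. Default dx keeps area
  errors ≤ 0.1% on all plausible vessel sizes at negligible cost.

## Rheology and the tube-flow inversion

Blood viscosity follows the Carreau law
μ(γ̇) = μ∞ + (μ0 − μ∞)[1 + (λγ̇)²]^((n−1)/2) with defaults
μ0 = 0.056 Pa·s, μ∞ = 0.00345 Pa·s, λ = 3.313 s, n = 0.3568 — the blood
parameter set in wide use for large-vessel hemodynamics; all four are
config-overridable. Wall shear stress at given flow Q and radius R solves
the Weissenberg–Rabinowitsch–Mooney relation
Q(τ_w) = (πR³/τ_w³)·∫₀^{τ_w} τ²γ̇(τ) dτ. The integral is evaluated in the
shear-rate variable (the stress law and its derivative are explicit, so no
nested inversion is needed), with adaptive quadrature at absolute tolerance
1e−12 (scaled by τ_w³) and Brent root finding at relative tolerance 1e−12.
Because τ(γ̇) is strictly increasing for 0 < n ≤ 1, Q(τ_w) is strictly
increasing and the bracketed root is global. The parabolic-inlet
assumption of the underlying flow model is honored in reduced order by
using the cross-sectional mean velocity; profile shape has no further
effect on fully developed τ_w. Verified limits: Newtonian (n = 1) matches
4μQ/(πR³) to better than 1e−12 relative; the power-law limit (μ∞ = 0,
λγ̇ ≫ 1) matches K(Q(3n+1)/(nπR³))ⁿ to ~1e−6 relative.

## Boundary conditions and flow propagation

* Outlet: distal PV at fixed pressure, default 25 mmHg (3333.06 Pa, at
  133.3224 Pa/mmHg), the conventional portal-hypertensive value.
* Preoperative total PV flow: Q_PV = V_PV·πD_PV²/4 from the measured PV
  velocity and the model PV diameter (read at mid-length). Inlet flows are
  Q_PV times population-averaged proportions, default
  {SMV 0.40, SV 0.45, LGV 0.05, IMV 0.10}. These proportions are an
  explicit, auditable stand-in for population values not in the public
  record; every report records the split used.
* Postoperative PV flow is genuinely ambiguous (does the preoperative PV
  velocity persist after losing the splenic inflow?). Default
  `subtract_sv`: the SV share is removed and the PV carries
  Q_SMV + Q_LGV + Q_IMV — the ligated vein cannot contribute inflow. The
  alternative `renormalize` mode keeps total Q_PV and rescales the
  remaining proportions; both are selectable.
* Flows propagate by continuity alone (tree topology, no loops); node
  pressures integrate the fully developed wall-friction balance
  ΔP = 2τ_w Δx/R upstream from the outlet. A stump has no flow, hence no
  drop: its tip sits at the junction pressure.
* Stump wall model: default `stasis`, τ_w = 0 on the whole stump —
  consistent with low-WSS regions concentrating on the ligated SV. An
  optional `decay` mode paints τ_junction·exp(−s/D_SV) (s = distance from
  the junction) to mimic the finite penetration of 3D recirculation into
  the stump; the penetration length (one stump diameter) is a modeling
  knob, not a measured value. Pressure computation always uses the
  flow-consistent (stasis) stress.

## ALWSS scoring

Space-averaged WSS is the area-weighted mean over **all** strips of the
postoperative surface, stump included (no exclusions). The threshold is
20% of that mean (fraction configurable in (0,1)); ALWSS is the summed
area of strips with τ_w **strictly** below the threshold, so ties at the
threshold are excluded and a zero threshold yields zero area even on
stagnant walls. Areas are reported in cm², stresses in Pa.

## Synthetic cohort and label model

Covariates are truncated normals (SI units): PV velocity 15 ± 4 cm/s on
[6, 30]; PV diameter 13 ± 2 mm on [9, 18]; SV diameter 12 ± 3 mm on
[7, 20]; SV length 100 ± 25 mm on [50, 180]; SV tortuosity 1.3 ± 0.2 on
[1.0, 2.0]; spleen maximum diameter 16 ± 3 cm on [10, 25] (descriptive
only). Anatomy types are drawn with probabilities (0.5, 0.3, 0.2). These
are plausibility choices for splenomegalic portal hypertension, not values
fitted to any dataset; all are config-exposed. Vessels the cohort model
does not sample are fixed at typical calibers (SMV 10 mm × 80 mm, LGV
5 mm × 40 mm, IMV 5 mm × 60 mm, PV length 60 mm).

Thrombosis labels are Bernoulli with
P = logistic(β0 + β1·ALWSS[cm²]). Default β1 = ln 3 / 30 ≈ 0.0366 cm⁻²
(30 cm² of extra ALWSS triples the odds); β0 = −1.85, calibrated once so
the default cohort's prevalence is ≈ 40%, matching the emulated clinical
cohort (6/15 thrombosed), and frozen. Because the generating model is
known, AUC recovery and logistic-slope recovery are testable properties of
the whole pipeline.

What the generator does **not** emulate: real per-patient geometry
(branching angles, local stenoses, non-circular lumens), correlated
covariates (e.g. spleen size with SV caliber), measurement error in
Doppler velocities, and any label mechanism beyond WSS (blood
constituents, endothelial state). Passing tests therefore demonstrate the
internal consistency and statistical machinery of the method, not its
clinical accuracy on real patients.

## Evaluation statistics

Trapezoidal AUC over the empirical ROC — identical to the Mann–Whitney
probability U/(n₁n₀) with ½-weighted ties (property-tested to 1e−12). The
decision rule is "thrombosis if ALWSS > threshold"; the accuracy-optimal
threshold scans all midpoints between sorted unique scores plus ±∞ and
breaks ties toward the smallest threshold. Pearson r uses the two-sided
t-test p-value on n−2 df. Mood's median test splits at the pooled grand
median, counts values equal to the median as ≤, and uses the 1-df
chi-square without continuity correction (the classical definition;
implementations differ, so this is pinned and tested against the explicit
2×2 formula). With only a handful of patients, ROC tie/orientation
conventions can shift the AUC — a caveat for comparing small-cohort
numbers across implementations.

## Numerical choices and problem sizes

dx = 1 mm default discretization (≈ 340 strips per tree); WRM quadrature
1e−12 absolute, root finding 1e−12 relative — both far below model-form
error; per-(Q, R) memoization inside a field evaluation (constant-radius
segments then cost one inversion per flow region). The shipped analysis
uses a 150-patient cohort; the acceptance script re-runs a 500-patient
cohort, a 10⁵-draw Monte-Carlo oracle for the AUC, and a 13-point SV
diameter sweep. Degenerate inputs are rejected loudly (empty WSS fields,
single-class labels, zero-variance correlations, degenerate median-test
tables, dx larger than the shortest segment).

## Known limitations

* No junction recirculation or secondary flow: low-WSS area at the
  SMV/SV/PV confluence — visible in 3D simulations — is represented only
  through the stump model.
* Steady flow, rigid walls; no pulsatility or fluid–structure interaction.
* Anatomy types differ only through flow routing, so their ALWSS
  differences are much weaker than image-based geometry would produce.
* Oscillatory shear index, residence time and other pulsatile metrics are
  out of scope by design; the score is WSS-only.
* The Carreau constants and flow-split proportions are configurable
  stand-ins for population values; absolute WSS levels shift with them,
  though the ALWSS ranking is less sensitive because the threshold is
  relative (20% of each patient's own mean).
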