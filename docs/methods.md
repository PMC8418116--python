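# Methods

## The index

SmartFFR quantifies the functional severity of a coronary stenosis from
geometry alone.  For a vessel held at a proximal pressure Pa = 100 mmHg,
the distal-to-proximal pressure ratio Pd/Pa is evaluated at staged flows
Q = 1, 2, 3, 4 ml/s, connected into a smooth curve over the full
0–4 ml/s range, and integrated:

    SmartFFR = (1/4) * ∫₀⁴ (Pd/Pa)(Q) dQ

A disease-free vessel keeps Pd/Pa ≈ 1 at every flow, so its curve area
is 4 and its index 1; the denominator is that healthy reference area.
Unlike wire-based FFR, which samples one (unknown, patient-specific)
hyperemic operating point, the index averages the pressure ratio over a
standardized flow range, which makes it computable from geometry and a
pressure-drop model without any microvascular boundary-condition
calibration.

## Reduced-order pressure-drop engine

The engine collapses the 3D steady incompressible flow problem in each
segment to the standard quadratic stenosis law

    ΔP(Q) = f·Q + s·Q²   [mmHg, Q in ml/s]

* **Viscous coefficient** `f = (128 μ / π) ∫ D(z)⁻⁴ dz`, trapezoidal
  along the sampled centerline.  For a uniform tube this is the
  Poiseuille resistance 128 μ L / (π D⁴); narrowings raise it through
  the D⁻⁴ weight.
* **Separation coefficient** (Young–Tsai form)
  `s = ρ K_t / (2 A₀²) · (A₀/A_s − 1)²` with K_t = 1.52, A₀ the
  reference (healthy) lumen area and A_s the throat area.  It vanishes
  for an unobstructed vessel.
* Blood is Newtonian with μ = 0.0035 Pa·s and ρ = 1050 kg/m³; flow is
  laminar and quasi-steady — with no inertial or compliance terms each
  staged flow is an independent steady state, and the 0.25 s stage
  duration is metadata only.
* Units: geometry mm, flow ml/s, pressure mmHg; the single conversion
  constant 1 mmHg = 133.322 Pa is applied inside the coefficient
  computations.
* Computed distal pressure is floored at 0 mmHg (sub-zero distal
  pressure is unphysical; it only occurs for extreme synthetic lesions).

The index itself consumes nothing but (Q, Pa, Pd) triples, so samples
from any external 3D solver can be substituted for the engine through
the `flow_mls,pa_mmhg,pd_mmhg` CSV adapter without touching the rest of
the pipeline.

## Geometry

Segments are arc-length parameterised radius profiles.  Parametric
stenoses are cosine tapers: the radius inside a window of length L
centred at z₀ is scaled by
`1 − (1 − √(1−sa))·(1 + cos(2π(z−z₀)/L))/2`, which reaches throat area
`(1−sa)·A₀` exactly and blends C¹-smoothly into the healthy profile.  A
sample is inserted at the throat so the minimal radius is attained
exactly rather than up to grid resolution.  The reference (healthy)
caliber of a segment is the mean radius over the proximal and distal
10% of its arc length, a convention chosen because focal disease in the
middle of an analysed segment leaves those ends untouched.

## Bifurcations

A parent segment splitting into two daughters is driven by staged total
flows {2, 4, 6, 8} ml/s — four stages reaching the 8 ml/s peak
hyperemic flow of a healthy left coronary system (4 ml/s per branch).
The total flow divides by Murray's law, q₂/q₁ = (d₂/d₁)³, on the
branches' reference diameters.  Each branch's proximal pressure is the
parent's computed distal pressure at that total flow (pressure
continuity), and flow conservation at the junction is exact by
construction.

Branch flows generally do not land on 1–4 ml/s, so branch curves are
**rebased**: an origin-forced quadratic ΔP fit to the branch samples is
evaluated on the standard [0, 4] ml/s grid — interpolation when the
branch carried more than 4 ml/s, extrapolation when less.  Fitting the
physical model class rather than extrapolating the spline keeps the
out-of-range behaviour tame; on data that lie in the model class the
rebased index is exact up to the 1e−5-level quadrature error.  The
branch's reference Pa for the rebased ratio is the mean of the
per-stage branch inlet pressures (they differ only through the parent's
own small drop).

## Numerical choices

* **Curve**: cubic interpolating spline through the staged (Q, Pd/Pa)
  points plus the anchor (0, 1) — zero flow drops no pressure, and
  without the anchor the curve below the first staged flow would be
  unconstrained.  **Not-a-knot** end conditions are used: they
  reproduce polynomials up to cubic exactly, so on the engine's
  quadratic ratio curves the spline is exact and the only pipeline
  error is trapezoidal quadrature on the 100-point grid (≈2e−5).
  Natural end conditions were measured to flatten the curve ends enough
  to move the index by up to 1.5e−3 on admissible quadratic models,
  larger than the package's own 1e−3 internal-consistency tolerance.
* **AUC**: composite trapezoid on the uniform 100-point grid; ratio
  values clipped to [0, 1] (supra-unity ratios are interpolation noise).
* **ΔP fit**: non-negative least squares (f, s ≥ 0) through the origin.
* **Youden cutoff**: candidate thresholds are the observed index
  values; ties in J = sens + spec − 1 resolve to the largest threshold
  (favours sensitivity, the screening-appropriate direction).
* **Positivity orientation**: index ≤ cutoff means ischemic,
  everywhere; reference FFR dichotomised at ≤ 0.80.
* **Limits of agreement**: bias ± 1.96·sd with the classical
  sd·√(3/n)·t(0.975, n−1) confidence intervals for each limit.
* **DeLong**: placement-value (structural-component) covariance
  estimator; degenerate comparisons (identical score vectors) return
  z = 0, p = 1 by convention.

## Synthetic cohorts

The generator emulates a functional-testing population: straight
vessels (diameter lognormal, median 3 mm, σ = 0.15; length uniform
20–60 mm) with one focal cosine stenosis whose area severity is uniform
on 30–90% — the severity band of lesions that reach invasive
physiological assessment — and stenosis length uniform 10–20 mm.
SmartFFR is computed through the full staged-flow + spline pipeline.

The paired "invasive" reference FFR couples the same pressure-drop
model to a constant hyperemic microvascular resistance R = 25
mmHg/(ml/s): the hyperemic operating flow solves
Pa = ΔP(Q) + Q·R, and FFR = Q·R/Pa.  R = 25 makes a lossless vessel's
hyperemic flow exactly 4 ml/s at 100 mmHg, the canonical per-branch
peak flow.  Measurement noise is additive Gaussian (sd 0.03, the scale
of pressure-wire test–retest variability) applied to the reference
only, clipped to [0, 1].  Each case draws from an RNG stream keyed by
(seed, case index), so enlarging a cohort never reshuffles existing
cases.

What the generator does **not** emulate: diffuse or serial disease,
non-circular lumens, vessel taper, pressure-wire drift, adenosine
response variability, or any correlation structure between geometry and
microvascular state.  Tests passing on these cohorts demonstrate
internal consistency of the pipeline and correct recovery of a known
generative model — not clinical diagnostic performance, which can only
be established against measured FFR.  For the same reason the published
clinical correlations, AUCs and optimal cutoffs are not reproduction
targets here: the underlying patient data are not deposited.

## Problem sizes

Default analyses use 201-sample centerlines, 100-point curves, cohorts
of n = 200, and 10⁴ bootstrap replicates where a bootstrap is compared
against the DeLong estimator; the full test suite runs in a few seconds
on one core.

## Known limitations

* The quadratic ΔP law ignores lesion interaction, curvature/tortuosity
  losses and inlet-length effects; K_t = 1.52 is a population constant,
  not lesion-specific.
* Murray's law is an idealisation for laminar flow; in severe stenoses
  the real flow split deviates from the cubic-diameter rule.
* Bifurcation handling covers one parent with two daughters; left-main
  (common-trunk) bifurcation stenosis is out of scope.
* The constant-R_micro reference FFR is a modelling device for
  synthetic validation, not a substitute for measured FFR.
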