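# Methods

## The actuator model

The apical plate is modelled as a two-dimensional longitudinal section in
the plane-strain idealization: in-plane displacements only, zero
out-of-plane strain, non-zero out-of-plane stress. The hydrated
configuration is taken stress-free (supported experimentally by incision
tests in the source literature for this system). Dehydration enters as a
region-wise isotropic eigenstrain

ε\* = (√(1 − s) − 1) I,

so a detached region with a free boundary shrinks to exactly (1 − s) of
its hydrated area — this is the defining property of the intrinsic
swelling factor *s*, and it is what the calibration below fits. No
out-of-plane eigenstrain is applied under plane strain, which keeps that
identity exact. The material is isotropic and linearly elastic with
Young's modulus proportional to the measured relative cell-wall density of
each region (E_region = E_vasc · ρ_region/ρ_vasc) and a shared Poisson
ratio ν = 0.29 (typical of woody tissue). Because the problem is driven
entirely by eigenstrain and prescribed displacement, the global modulus
scale cancels; only the density ratios matter.

Kinematics are linear (small strain) even though area changes reach
~50 %: this matches the linear-elastic model class of the analysis the
package reimplements, and dry positions are defined as wet positions plus
the computed displacement. A geometrically nonlinear extension is out of
scope.

### Geometric construction

The section is determined entirely by the nine measured lengths, with the
origin at the symmetry axis on the base, x radial, y up, μm units. The
construction exploits three near-identities in the measured table — the
podium chord half-width w_pod = √(H_pod (2R − H_pod)) ≈ 163.3 μm nearly
equals D/2 − W_side − W_vasc ≈ 163.6 μm, and D/2 − w_pod ≈ W_vasc +
W_side — which interlock the regions into a consistent tiling:

- the **central cavity** is an isosceles trapezoid flaring upward from
  basal width D_cavity to half-width x_ct = D/2 − W_side − 1.5 W_vasc at
  the podium-chord level (tying x_ct to D, not to the chord, is what gives
  the plate diameter its positive influence on θ);
- the **vascular bands** run along the cavity flanks with horizontal
  width W_vasc; each band top straddles a chord end of the podium, giving
  the podium a finite bearing of about half a band width;
- the **floral podium** is the circular segment of radius R and sagitta
  H_pod capping the section;
- the **side regions** are W_side × H_side rectangles at the upper outer
  flanks, lateral edge at x = ±D/2;
- the **cortex** is a thin rind one band-width (W_vasc) thick outside
  each vascular band — the vasculature–cortex bilayer that actually drives
  the motion — plus the shelf joining the bilayer walls to the side
  regions in the upper block.

This slender-walled reading, rather than a filled rectangular envelope,
is what reproduces the documented actuation: the large cavity leaves the
slanted bilayer free to bend as the cortex shrinks more than the
lignified vasculature, rotating the upper flanks outward. With a filled
envelope the same materials produce θ ≈ 1°, no cavity dependence, and no
inversion scenarios; with the slender walls the model reproduces the
holding angle (≈ 18°), the collapse of θ as the cavity is filled, the
sensitivity sign structure (including the negative H_side sensitivity
caused by the moving measurement line, and near-insensitivity to lateral
resizing of the lower cortex), and the substitution ordering (podium →
vasculature largest among reduction scenarios; vasculature + podium →
side inverts the actuator).

### Boundary conditions

The vascular-base nodes are displaced horizontally toward the symmetry
axis by the measured d_vasc = 15.3 μm; their vertical motion is left
free, with the remaining rigid-body modes pinned at a single reference
node (θ and all reported quantities are invariant to the pin choice). The
prescription stands in for the three-dimensional hoop constraint a 2D
section cannot represent. Leaving the vertical component free is a
deliberate reading of an under-specified condition: clamping it as well
lowers θ by ≈ 5° without changing any qualitative behaviour. Half-domain
solves with a symmetry condition (u_x = 0) on the axis are the default;
full-domain solves agree with the half-model within 0.3°.

### Discretization

Linear (constant-strain) triangles on an unstructured Delaunay mesh.
Region boundaries are sampled at the target edge length and shared
exactly between neighbouring regions, so the triangulation conforms to
the region layout; triangles are labelled by centroid containment. One
sparse direct solve per load case; the stiffness factorization is cached
and reused whenever only swelling factors change (the calibration loop).
The default target edge is 3 μm, at which θ changes by ~0.1° under
further refinement (the convergence criterion used throughout is
|θ(h) − θ(h/2)| < 0.2°). Holding-angle landmarks are material points
(the plate's upper corner and the side region's lowest lateral point)
advected by the displacement field; when a parameter sweep moves the
landmarks (e.g. H_side), θ is always measured with the current geometry's
landmarks.

### Known limitations of the actuator model

The inversion scenarios (vasculature made soft and highly swelling) are
driven mostly by the prescribed base displacement, and in this geometric
reading they overshoot: the model inverts at ≈ −16° where the source
analysis reports ≈ −8°. The swelling-driven scenarios are reproduced
quantitatively. Exact outline details of the section (bulge curvature,
the crease at the waist) are not measured and are represented by straight
segments; they modulate the BC-driven modes most. Time-dependent water
transport, anisotropic wall swelling, and 3D effects are out of scope.

## Swelling-factor calibration

The four intrinsic swelling factors cannot be measured; they are fitted
by minimizing the summed squared mismatch between the model's coupled
regional wet/dry area ratios and target expansions (inverse-variance
weighted when target standard deviations are given). The optimizer is
Nelder–Mead with bounds [0.01, 0.95], restarted from seeded jittered
initial points; each objective evaluation is a load-vector assembly plus
a triangular solve on the cached factorization. On targets generated by
the forward model the fit recovers the generating factors to ~10⁻⁶; with
5 % noise on the targets the median absolute error stays below 0.05.

## Sensitivity analysis and correlation prediction

S_p = (Δθ/θ_ref)/(Δp/p_ref) by central differences at ±5 % (the result is
stable to halving the step). Predicted correlations between θ and
co-varying geometric parameters use first-order propagation: with
gradients g_j = S_j θ_ref/p_j and standard deviations σ_j = CV_j p_j,

cov(θ, p_i) = Σ_j g_j σ_j σ_i ρ_ij,  var θ = Σ_jk g_j g_k σ_j σ_k ρ_jk,

and corr(θ, p_i) = cov(θ, p_i)/(√var θ · σ_i), which is bounded in
[−1, 1] by construction and is validated against a 10⁵-draw Monte-Carlo
linearized oracle to within 0.01. The measured covariation of real
specimens is not published numerically; the synthetic module ships a
plausible positive-semi-definite example (a shared size factor with a
stronger D–H correlation) for testing, and users supply their own CSV
matrices for real data.

## Landmark strain mapping

The triangulation is Delaunay on the dry landmark positions; triangles
not fully enclosed by the dry outline are excluded, as are triangles
whose wet image inverts or overlaps another wet triangle's interior by
more than 10⁻⁶ of its area (the annotation rearrangement case).
Smoothing is a single pass of the arithmetic mean over the triangle and
its edge-adjacent valid neighbours; invalid triangles neither give nor
receive. Note this smoothing is row-stochastic but not mass-conserving:
with unequal neighbour counts the global mean can shift slightly, which
is inherited from the procedure it reimplements. Principal stretches are
singular values of the per-triangle deformation gradient, with
directions the right singular vectors (material frame); the ×3 cross
magnification is display-only. Region assignment uses the ≥ 40 % overlap
rule with largest-overlap, then fixed-priority (podium > vasculature >
side) tie-breaking. Per-region means over smoothed ratios of valid
triangles are the expansion targets consumed by the calibration; empty
regions yield NaN, never zero.

## AFM Sneddon pipeline

Per curve: (1) linear baseline fitted on the 30 % of samples farthest
from the surface and subtracted; (2) contact point as the first
zero-force crossing scanning from the trigger-force end; (3) abscissa
converted to tip–sample separation using the cantilever deflection
(force/spring constant); (4) least squares of the conical Sneddon law
with modulus, contact point and force offset free, evaluated only at
positive indentation depth. Residuals are weighted by inverse force
magnitude (with a 2 % floor), reflecting that AFM force noise grows with
the deflection signal; samples more than five robust standard deviations
below the non-contact baseline (the snap-off adhesion dip, which the
adhesionless model cannot represent) are excluded from the fit domain.
Curves whose adhesion (|minimum force| on the final retraction) reaches
160 nN are discarded as wax contacts before medians are taken per sample
and region. The E–tan α product is the identifiable quantity: doubling
tan α halves the fitted modulus on the same data.

## Synthetic data: what it does and does not emulate

- **Landmarks**: regions are vertical bands; the deformation is
  (x, y) → (G(x), c y) with G′(x) = f(x)/c, where f(x) blends the
  per-region area factors over a 5 μm length and c is the square root of
  the geometric-mean factor. The local area factor equals f(x) exactly
  everywhere and the Jacobian is positive by construction, so strain-map
  exclusions fire only when deliberately injected. Annotation noise is
  isotropic Gaussian. Real tissue deforms bidirectionally with curved
  region boundaries and correlated annotation error; passing closure
  tests therefore validates the pipeline arithmetic, not biological
  inference.
- **Force curves**: the full seven-segment load cycle (trigger 3 μN,
  2 μm ramps at 2000 samples, spring constant 40 N/m) with the exact
  compliance-coupled Sneddon contact branch, a linear baseline, a
  Gaussian snap-off dip of specified depth placed clear of the contact
  edge, and multiplicative force noise. Real curves add plasticity and
  hysteresis, which the seven-segment protocol is designed to mitigate
  and the generator does not model.
- **Geometry samples**: multivariate normal around the measured lengths,
  truncated to geometric validity by resampling (clipping would distort
  correlations); the truncation bias grows with the requested CVs.

All generators are pure functions of their spec, including the seed.

## Problem sizes used in the shipped checks

Reference solves use the 3 μm mesh (~6 × 10³ elements; ~2 × 10⁴ at the
1.5 μm convergence check). Calibration and recovery studies run on 6–8 μm
meshes, where regional area ratios are already converged to ~10⁻³.
Monte-Carlo oracles use 10⁵ draws; AFM noise studies use 50 replicates
per condition.
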