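# Methods

## Geometric model

A vessel is represented as an ordered stack of planar lumen contours
(millimetres throughout).  CTA stacks carry a 3D centerline and a 0.25 mm
frame interval; OCT stacks are probe-local (no centerline) at the pullback
interval 0.2 mm (20 mm/s withdrawal at 100 frames/s).  Contours are simple
counter-clockwise polygons with at least 8 vertices; clockwise vendor
exports are auto-reversed with a logged warning.  Areas and centroids are
always derived from the vertices, never read from files.

**Frames.** Contours are placed along the centerline using
rotation-minimizing frames computed by the double-reflection method.
Frenet frames were rejected because they flip at curvature inflections of
realistic coronary centerlines, which would corrupt circumferential
registration.  Tangents are chord-based, so frame accuracy at the two
endpoints is first order in the point spacing; all registration landmarks
live in the interior where the frames are second order.

**Mother-vessel estimation.** Side branches are removed before meshing so
the model is a single branch.  For each bifurcation marker (longitudinal
position z, ostium direction θ₀, branch diameter d), frames within ±d/2 of
z have their radius function r(θ), over the sector θ₀ ± max(30°, angle
subtended by d at the local mean radius), replaced by linear interpolation
in z between the nearest unaffected frames.  Radii are measured about the
centroid interpolated between those flanking frames, not about the affected
frame's own centroid — the ostium bulge shifts the latter and would bias
the repair.  Frames outside all bifurcation ranges are returned
bit-identical.  The procedure is deliberately isolated behind one function:
it is one defensible automation of a step that clinical workflows perform
manually.

**Surface generation.** Contours are resampled to a common vertex count
(default 96, <1% area error at coronary scale) uniformly in arc length
starting at the θ = 0 crossing from the centroid, and adjacent rings are
stitched point-to-point into triangle strips with planar fan caps
(inlet/outlet labelled).  Ring start indices are cyclically aligned to the
previous ring by default; with alignment disabled, a start-angle mismatch
above 90° is detected and rejected as a self-intersecting strip.  Meshes
are checked watertight (every edge shared by exactly two triangles, Euler
characteristic 2) before any downstream use.

## CTA–OCT fusion

Bifurcation directions are the only registration references.  Landmarks are
matched order-preservingly to minimize Σ|Δz| after a global longitudinal
offset; degenerate matchings (a single shared landmark) are broken in favor
of the smaller offset, since pullback misalignment is small compared with
inter-branch spacing.  The offset is the least-squares fit over matched
pairs; the circumferential rotation is the wrapped direction difference per
landmark, interpolated linearly in z between landmarks (a twist model for
catheter rotation drift) and held constant beyond the outermost ones.

Inside pullback coverage, CTA contours are replaced by OCT radius functions
r(θ) rotated into the CTA frame basis and linearly interpolated in z onto
the CTA interval, then centered on the CTA centerline.  OCT lumens are
exchanged at native size: OCT is treated as the lumen ground truth and is
never rescaled to CTA dimensions.  Outside coverage, CTA contours are
scaled about their centroids by a factor tapering linearly from
√(A_OCT/A_CTA) at the junction to 1 over a configurable 5 mm length; this
automates the manual "adjust the remaining lumens" step and enforces a
continuous area profile (no junction jump above 5%).

## Lattice-Boltzmann flow model

Blood is an incompressible shear-thinning fluid, density 1060 kg/m³, with
Carreau–Yasuda viscosity
μ(γ̇) = μ∞ + (μ₀ − μ∞)[1 + (λγ̇)^a]^((n−1)/a); the default constants are the
canonical whole-blood set μ₀ = 0.056 Pa·s, μ∞ = 0.0035 Pa·s, λ = 3.313 s,
a = 2, n = 0.3568, all overridable.  Setting μ₀ = μ∞ gives the Newtonian
limit used in the validation benchmarks.

The solver is a D3Q19 single-relaxation-time (BGK) scheme on a uniform
grid.  The local relaxation time is recomputed every step from the
shear-rate magnitude obtained from the non-equilibrium momentum-flux tensor
(using the previous step's τ in the closure) and clamped to (0.505, 2.8)
for stability.  Walls use half-way bounce-back.  The watertight surface is
voxelized by vertical-ray parity with coincident-crossing de-duplication
and per-column ray jitter retries — without these, rays grazing shared
triangle edges leave spurious interior solid voxels that act as a porous
obstruction (this failure mode reduced tube conductance by ~40% before it
was diagnosed, and is now regression-tested through the duct benchmarks).
Isolated fluid pockets are removed; the minimal lumen diameter must span at
least 8 cells.

**Boundary conditions.**  Inlet and outlet are one-cell layers adjacent to
the labelled cap planes.  Both impose a fixed density (pressure) through an
equilibrium distribution whose velocity is extrapolated from the interior
node along the cap normal; the inlet density encodes the patient's mean
aortic pressure, taken as the pressure reference.  The outlet follows a
resistance model P_out = P_ref + R·Q.  Because the vessel's own resistance
is not known a priori, the outlet pressure is walked to the operating point
by a load-line fixed-point update (vessel resistance estimated from the
current head and flow), under-relaxed and capped at 1 mmHg per update; the
run starts from a 0.05 mmHg head so the startup transient cannot exceed the
lattice Mach limit.  By default R is sized for a target hyperemic flow of
2 mL/s in an unobstructed LAD-scale vessel, R = (P_in − P_ref)/Q_hyp; the
validation benchmarks run at Q_hyp = 0.5 mL/s (see problem sizes below).

**Units and time step.**  dx is chosen from the geometry (default 0.1 mm).
dt is set so the estimated peak velocity maps to 0.08 lattice units
(Mach ≈ 0.14), raised if necessary so τ(μ∞) ≥ 0.505.  The velocity scale
is estimated from the resistance-limited flow through the minimal lumen
area, or from the Bernoulli velocity of the imposed pressure drop for
fixed-pressure runs.

**Monitors and convergence.**  Volumetric flux is measured on interior
cross-sections at 12% and 88% of the arc length (the cap layers themselves
are velocity-extrapolated and not meaningful flux planes), and the distal
pressure on a one-cell slab three mean lumen diameters proximal to the
outlet cap — mimicking a pressure wire positioned distal to the lesion
while avoiding cap artifacts.  Weakly damped acoustic modes bounce between
the two pressure boundaries, so all monitors are averaged over each check
interval (200 steps) rather than sampled; convergence requires the relative
change of both outflow and FFR over a 500-step window to fall below the
tolerance (default 1e-5; the stenosis-family runs use 1e-4, consistent with
the ≥1e-3 FFR separations they resolve).  Divergence (|u| > 0.3 lattice
units) and non-convergence raise errors with the residual history.

**Derived fields.**  FFR is the cross-section-averaged pressure at the
distal position divided by the inlet pressure.  Wall shear stress is
μ(γ̇)·γ̇ at wall-adjacent fluid nodes from the local non-equilibrium shear
rate (the node sits ~half a cell inside the wall, giving a small systematic
underestimate, within the 10% benchmark band at 30 cells per diameter).
Vorticity is a central-difference curl on the grid with zero velocity
outside the lumen; helicity is u·ω.

**Validation measurement.**  A pressure inlet feeds a near-plug profile, so
a finite tube has a real entrance region (≈0.05·Re·d).  The
Hagen–Poiseuille benchmark therefore drives the flow at Re ≈ 1–2 and fits
the axial pressure gradient over the fully developed middle of the tube,
comparing it with 8μQ/(πr⁴) at the measured flow; end-to-end pressure
drops at higher Re would mix entrance losses into the comparison.

## Synthetic data

The generators define the test conditions.  A vessel is an analytic radius
field on a straight, planar-arc or helical centerline: a Gaussian stenosis
bump of exact area severity (throat area = (1 − s)·πR², so ground-truth MLA
is closed-form) and compactly supported cos² ostium bulges at declared
bifurcations.  Imaging samples the field at the modality intervals; CTA
applies a multiplicative radial bias (default 1.0; 1.2 in the
bias-recovery experiments, i.e. +44% in area) and optional smoothed radial
noise; OCT applies the unknown-to-fusion rotation and longitudinal offset
plus small radial noise.  Bifurcation marker annotations are exact (the
markers are expert annotations, not image measurements); optional jitter
knobs exist but default to zero.  Cohort generation draws wire FFR from a
truncated normal fitted to the clinical summary (median 0.82, IQR
0.74–0.87, range 0.40–1.00), optionally location-shifted so
P(FFR ≤ 0.80) matches a requested prevalence, and adds Gaussian errors with
SDs 0.06/0.08/0.07 (fusion/CTA/OCT) and a −0.02 CTA bias, matching the
reported agreement scale of the three modalities.

What the generators do **not** emulate: image formation (voxel/A-scan
physics), segmentation errors correlated along the pullback, cardiac-phase
mismatch between modalities, eccentric or non-star-shaped lumens, and
multi-branch geometries.  Passing tests therefore demonstrate correctness
of the algorithms under the stated geometric and statistical conditions,
not robustness to every clinical artifact.

## Statistics

Functional significance is FFR ≤ 0.80 inclusive.  Proportions carry exact
Clopper–Pearson 95% intervals (the conservative default; display rounding
is half-up to one decimal in percent).  Steiger's Z compares two dependent
correlations sharing a variable via Fisher transforms with the r₂₃
dependence correction.  AUC is the tie-aware Mann–Whitney statistic
(risk-score convention: 1 − FFR, so a useful estimator scores above 0.5),
and paired AUCs are compared with DeLong's placement-value covariance.
Bland–Altman reports mean ± SD of differences with 1.96·SD limits.
Confusion matrices for the clinical worked examples are reconstructed from
cohort size, prevalence and reported sensitivity/specificity by rounding to
integer counts.

## Problem sizes used in benchmarks and tests

Chosen as the package's standard validation set (single CPU, ≈15 min for
the full acceptance script):

- Hagen–Poiseuille: r = 1.5 mm, L = 12 mm, dx = 0.1 mm (30 cells per
  diameter), ΔP = 0.6 Pa (Re ≈ 1.5), Newtonian; gradient fitted over
  s ∈ [4.0, 8.6] mm.
- Stenosis family: base r = 1.5 mm, L = 10 mm, 4 mm stenosis at
  mid-vessel, severities {0, 40, 60, 75, 90}%, dx = 0.11 mm (the 90%
  throat, 0.95 mm, spans 8.6 cells), Q_hyp = 0.5 mL/s, inlet 90 mmHg.
- Curvature comparison: r = 1.2 mm, L = 10 mm on a straight vs helical
  (helix radius 2 mm, pitch 10 mm) centerline, dx = 0.12 mm, same
  resistance outlet.
- Registration recovery: 20 randomized cases, rotation ∈ [−180°, 180°],
  offset ∈ [0, 5] mm, 2% radial noise on both modalities.
- Statistics oracles: 300 random cohorts n ≤ 12 with heavy ties for the
  AUC oracle; 2000 trivariate-normal replicates (n = 60) for the
  Steiger null.

## Known limitations

- Steady flow, rigid walls, single-branch geometry, one outlet: by design,
  matching the modeling conditions the pipeline targets; no pulsatility,
  FSI, or microvascular network.
- The BGK pressure boundaries are first-order and produce a plug-like
  inflow; entrance effects are physical in form but not matched to any
  upstream arterial geometry.
- The resistance constant stands in for the distal microvascular bed; no
  hyperemia model is applied, so computational FFR values at low target
  flow sit closer to 1 than hyperemic wire FFR for the same anatomy.
- The mother-vessel and taper steps are principled automations of manual
  workflow steps; alternatives (e.g. spline in-painting) would be drop-in
  replacements behind the same interfaces.
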