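# Methods

`progplan` is a self-contained sandbox for *automatic progressive* VMAT
plan optimization: a scripting-style planning loop that starts from a
deliberately loose objective template and repeatedly re-targets the
conformity-driving objectives toward what the current plan actually
achieves, until those objectives become binding.  Everything needed to
exercise the algorithm — anatomy, dose calculation, objectives, inner
solver, metrics — lives in the package; nothing requires a commercial
treatment planning system.

## Synthetic thorax phantom

The phantom is a voxelized analytic geometry on a regular grid (default
4 mm isotropic, 72 × 56 × 48 voxels): an elliptic-cylinder body, two
ellipsoidal lungs (relative electron density 0.26), an ellipsoidal
heart, a cylindrical spinal cord (5 mm radius), and a spherical solid
tumor in the right lung (density 1.0).  Default organ sizes target the
scale of a conventionally fractionated NSCLC cohort: digitized PTV
(CTV + 5 mm isotropic expansion) ≈ 283 cm³, combined lungs ≈ 3.0 L,
heart ≈ 680 cm³.  The lungs organ-at-risk mask excludes the gross tumor
volume, the usual protocol convention for lung DVH reporting
(RTOG-0617-style contouring).  The only randomness is a ±5 mm uniform
jitter of the tumor center, standing in for patient-to-patient
variation; a phantom is bitwise reproducible for a fixed seed.

Auxiliary optimization structures are derived, not contoured:

* `ring` = (PTV + 1.3 cm) \ (PTV + 0.3 cm) — the shell reading of
  "PTV expanded by 1.3 cm minus 0.3 cm"; it keeps the ring disjoint from
  the PTV-adjacent high-dose region, which is the only reading under
  which a ring max-dose objective drives conformity rather than coverage.
* `nt` = body \ (PTV + 1.3 cm) — normal tissue.
* `sp0.3` = spinal cord + 0.3 cm (cord planning organ-at-risk volume).
* `lung-ptv` = lungs \ PTV.

Expansions are Euclidean distance transforms on voxel centers, so they
are anisotropy-aware, monotone in the margin, and exactly idempotent to
re-derivation.  Expansion from digitized voxel centers under-reaches an
analytic surface by up to half a voxel — a known voxelization bias the
tests account for.  Masks are boolean; partial-volume effects are
ignored (all downstream metrics are DVH-based on the same grid).

## Dose engine

A deliberately simple pencil-beam beamlet model replaces a clinical dose
algorithm.  Beamlets are laid out per control point on a lattice at the
isocenter plane (pitch = 0.5 cm leaf width across rows × 0.5 cm along
leaf travel, rotated with the collimator), restricted to the target's
beam's-eye view plus a 10 mm margin.  The dose from beamlet *b* to voxel
*v* is

    exp(−μ · d_rad(v)) · (SAD / (SAD + z))² · exp(−ρ² / 2σ²)

with μ = 0.005 mm⁻¹ (≈6 MV in water), σ = 4 mm lateral penumbra
truncated at 3σ, SAD = 100 cm, ρ the lateral distance from the beamlet
axis (parallel-beam lateral geometry) and d_rad the radiological depth —
the line integral of density from the body surface to the voxel,
evaluated on a beam-aligned resampled grid.  Entries below 10⁻⁸ of the
entrance value are dropped.  The influence matrix is sparse
(float32; ≈33 M nonzeros for the standard case) and dose is exactly
linear in the nonnegative beamlet weights.  Arc geometry is the
conventional six-partial-arc thoracic arrangement (182°→230°, 300°→60°,
130°→178° and their opposites; collimator 10°/350°), discretized at a
configurable control-point spacing (engine default 4°).  The model aims
at qualitative realism — depth falloff, penumbra, lung transmission —
sufficient for validating the optimization algorithm, not at clinical
accuracy: there is no scatter kernel, no divergence of the beamlet
lattice, no buildup region, and heterogeneity enters only through the
attenuation line integral.

## Objective functions

Each template row has a *feedback value*: a dimensionless penalty that
is zero iff the row's constraint is satisfied, normalized by the squared
prescription so one threshold applies across rows.  Forms (d = voxel
dose, T = current target, Rx = prescription): min/max dose are mean
one-sided quadratics over the ROI; DVH rows penalize only the violating
subvolume between the current percentile dose and T (the classic
one-sided DVH objective, percentile treated as constant in the
gradient); EUD rows penalize the one-sided gEUD excess/deficit, with
gEUD = (mean dᵃ)^(1/a) stabilized by extremum scaling so |a| = 150 is
exact, and doses floored at 0.1 cGy before negative exponents; the
dose-falloff row allows H − (H−L)·min(1, dist/r) outside the PTV
(distance-transform distance to the PTV surface) and penalizes the mean
squared excess.  All gradients are analytic and validated against
central finite differences.

Two percentile conventions coexist deliberately: metric queries (D2%,
D50%, …) interpolate linearly on the empirical quantile function, while
the tightening readout and normalization use the sort-based
(`inverted_cdf`) convention that returns an actual voxel dose — so
normalization pins a voxel exactly at the prescription and V(Rx) ≥
coverage holds exactly rather than to interpolation error.

## The progressive loop

Phase 1 assigns the 19-row initial template (dose levels as fixed
multiples of the prescription; weights absolute).  Phase 2 runs cycles
of: inner solve (80 projected-gradient iterations by default, the
midpoint of the usual 60–100) → normalize so 95% of the PTV receives
the prescription → evaluate feedback values.  Any *adaptive* row (ring,
normal tissue, body dose-falloffs — the conformity-driving set) whose
feedback is below the threshold τ = 4·10⁻⁴ has slack: its target is
replaced by 0.98 × min(current target, achieved dose) and re-evaluated,
repeatedly, until feedback ≥ τ or a 50-update cap.  The achieved dose is
the gEUD for EUD rows and the achieved low-level-equivalent falloff dose
for falloff rows (the smallest low level whose allowed-dose curve no
voxel exceeds).  For falloff rows only the low level tightens; the high
level stays at the prescription, which steepens the enforced gradient.
Phase 3: the loop stops as *converged* when every adaptive feedback
exceeds τ after normalization — those constraints are then binding,
i.e. maximally tightened.  If 3 cycles pass without convergence, weights
and template are reset and the whole optimization restarts once; after
that the better of the runs by composite objective (under the initial
template, for comparability) is returned with a best-effort status.
Target-coverage and organ-at-risk rows are never tightened: their levels
are clinical limits, not conformity dials.

The inner solver is projected gradient with Barzilai–Borwein step
lengths safeguarded by Armijo backtracking: weights stay nonnegative at
every iterate, the objective is nonincreasing across accepted steps, and
iteration stops at the cap or at relative improvement < 10⁻⁶.  Direct
aperture optimization is deliberately out of scope: apertures and
monitor units come from a post-hoc unidirectional sliding-window
decomposition of each control point's fluence (integer arithmetic in
0.1 MU quanta; exact reconstruction of the quantized fluence; minimal
total MU per control point equal to the largest per-row sum of positive
increments).  The resulting MU scale is internally consistent
(1 weight unit ≡ 1 MU by default) but not comparable to a clinical
optimizer's absolute MU.

## Metrics

Cumulative DVHs use the ≥-dose convention.  Dxcc interpolates between
sorted voxel doses with each voxel a point mass at the midpoint of its
cumulative volume (a no-interpolation switch exists).  Conformity is the
Paddick index (TV ∩ PIV)² / (TV · PIV) with PIV the prescription
isodose volume — the standard form; a printed variant of the formula is
algebraically degenerate ((TV·PIV)²/(TV·PIV)) and is not used.
Homogeneity is (D2% − D98%) / D50%, which reproduces published
group-mean homogeneity values to ~10⁻³ when evaluated at the published
group-mean percentile doses.  Plan complexity is the MU-weighted edge
metric M = (1/MU) Σ MUᵢ yᵢ/Aᵢ, where yᵢ counts only leaf-side edge
length (top/bottom of open rows plus inter-row steps; the two leaf-end
edges per row are excluded) and Aᵢ is the open area; it is validated
against a pixel-boundary rasterization oracle.  Paired plan comparisons
report mean ± SD, difference of means, percentage difference relative
to the control group (100·(A−B)/B), Shapiro–Wilk normality, and the
two-tailed paired Wilcoxon signed-rank p value via the established
library routines.

## Problem sizes and study conditions

The *standard case* used by the worked example, the acceptance script
and the end-to-end tests is: default phantom (4 mm grid, seed-jittered
tumor), six arcs at 6° control-point spacing (≈78 control points,
≈25 000 active beamlets), 80 inner iterations per cycle, up to 3 cycles
plus one restart.  The 6° spacing is the package's desk-scale choice;
the engine default of 4° and all other parameters are configuration
knobs.  A full standard-case run takes a few minutes on one CPU.
Loop-level unit tests use a coarser 8 mm phantom and wider control-point
spacing; every test states its grid.

Under these conditions the standard-case plan satisfies the protocol
goal set (PTV V60Gy ≥ 95%, PTV D0.03cc < 115% of prescription, Paddick
CI > 0.8, lungs V20Gy < 28%, cord D0.03cc < 4500 cGy).  Lung V20Gy
settles just below 28% by construction: the template's one-sided DVH
objective (MaxDvh 2000 cGy to 28%) penalizes only the subvolume above
that level, so the optimizer equilibrates at it.  Lungs V30Gy and
mean lung dose land near but above their goal levels, which is expected
at this geometry: every beam direction of the coplanar arc arrangement
traverses lung, and the simplified kernel has no scatter-free corridor
to exploit.  The loop typically ends in the best-effort branch (the
dose-falloff feedbacks, averaged over the whole normal-tissue volume,
climb toward τ over several cycles and cross it just beyond the 3-cycle
cap); plan quality is taken from the best cycle, which matches how the
reset rule is meant to bound complexity rather than guarantee
convergence.

## What passing tests do and do not show

The phantom emulates the *geometry and scale* of thoracic planning, not
real patients: convex organs, a spherical tumor, no motion, no CT
texture, and a dose model without scatter or buildup.  Passing the goal
suite shows the progressive loop does what it claims — drives
conformity objectives to binding while holding coverage and OAR limits —
on a faithful miniature of the planning problem.  It does not show
clinical dose accuracy, nor that absolute OAR numbers transfer to real
anatomy, and the package's MU/complexity scale is not comparable to a
clinical optimizer's.

## Known limitations

* Fluence optimization + post-hoc sequencing, not direct aperture
  optimization; deliverability (leaf speed vs gantry speed,
  interdigitation, dual-layer coordination) is not modeled.
* The dose model ignores scatter, buildup and beamlet divergence;
  heterogeneity enters only via the attenuation line integral.
* One restart maximum; a second non-convergence returns best-so-far
  rather than looping.
* Whether a clinical system's EUD penalty is one- or two-sided is not
  public; the one-sided form is used.  The falloff "achieved dose"
  readout is this package's definition.
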