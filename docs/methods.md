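# Methods notes

## Signal model and reconstruction

The package models the single-shell HARDI signal per voxel as a spherical
function of the gradient direction. The attenuation E = S/S₀ is clamped to
[ε, 1−ε] (ε = 1e-3, configurable) and transformed to ln(−ln E), the quantity
that is linear in the constant-solid-angle (CSA) q-ball formulation; the
double log is undefined at E ∈ {0, 1}, which the clamp guards. That
transformed signal is fit by unweighted linear least squares in a real,
symmetric, orthonormal spherical-harmonic basis of even orders l = 0, 2, 4
(15 coefficients), ordered by (l, m) with m = −l..l; m < 0 maps to
√2·Im(Y_l^|m|), m > 0 to √2·Re(Y_l^m), Condon–Shortley phase included. The
basis tag travels with every coefficient array because a silent basis
mismatch is the classic failure mode of SH pipelines. With 55 directions
and 15 coefficients the system is well conditioned, so no Laplace–Beltrami
regularization is applied by default.

The CSA ODF is then exact per harmonic: ODF coefficient (l > 0) =
c_lm · [−l(l+1)] · 2π P_l(0) / (16π²); the l = 0 coefficient is pinned to
1/√(4π) so the ODF integrates to exactly 1. An independent reference route
(`qbtrack.reference`) computes the same estimator with scipy's complex
harmonics, `lstsq`, and a *numerical* great-circle quadrature of the
Funk–Radon transform (exact for band-limited integrands); it shares no code
with the production path and exists purely as a cross-check, which the test
suite exercises to max |Δ| ≤ 1e-6.

Fractional anisotropy comes from an unweighted log-linear tensor fit
(negative eigenvalues clipped to zero before the FA formula). Weighted LS
would be defensible too; the unweighted fit is the simplest choice and is
only used for the stopping criterion and the baseline tracker.

## Residual bootstrap

Bootstrap replicates resample the fit residuals, leverage-corrected as
r̃ᵢ = rᵢ/√(1−hᵢ) with hᵢ the hat-matrix diagonal, i.i.d. with replacement
across directions within a voxel, add them to the fitted values and refit
through the cached pseudo-inverse. A direction with hᵢ ≥ 1 carries no
residual information and is dropped with a warning (impossible for the
default 55-direction/15-coefficient design, where hᵢ ≈ 0.27 on average).
One fresh ODF is drawn per (streamline, voxel-visit), making streamlines
independent samples of the orientation uncertainty. All draws come from a
counter-based Philox generator keyed by (master seed, streamline id, step
index), so results are bit-reproducible regardless of execution order; the
test suite asserts byte-identical TRK output across repeated runs.

## Peak extraction

Peaks are strict local maxima of the nonnegativity-clipped ODF over the
adjacency graph of a 4-times-subdivided icosahedral tessellation (2562
vertices, ≈ 4° resolution, antipodally exact so axes are identified with
their negatives). No sub-vertex refinement is performed: 4° vertex
resolution is ample against a 45° separation rule, and the single-fiber
recovery tests bound the direction error at ≤ 3°. Candidates are retained
greedily by descending value under two rules: reject a peak closer than 45°
to an already-retained larger peak, and reject a peak below 0.25 of the ODF
maximum. The relative threshold is measured *above the ODF minimum over the
sphere*: CSA ODFs ride on an isotropic 1/(4π) baseline, and a threshold on
raw values would depend on that baseline rather than on peak prominence —
with raw values, the order-4 ODF of an equal 90° crossing retains a
spurious third lobe (0.299 of max, computed in the tests) that the
baseline-relative rule correctly rejects at 0.205. This matches the
convention of the reference peak-extraction implementations this rule
descends from. Ties in value break by vertex index, so extraction is
order-stable; at most 3 peaks are kept (configurable).

## Tracking

Seeds are laid on an n³ axis-aligned lattice strictly interior to each ROI
voxel (offsets (i+0.5)/n in voxel fractions; n = 11 by default, matching
the stated seeding density of 1331 points per voxel). Each retained seed
peak spawns one bidirectional streamline — unbiased with respect to the
fiber populations crossing the gate. Propagation steps 1.1 mm (half the
2.2 mm voxel; the step must not exceed the smallest voxel dimension). ODF
and peak lookup is nearest-voxel, because the bootstrap model is per voxel
by construction; FA is interpolated trilinearly to avoid blocky stopping
artifacts. At each visit only the peak closest to the incoming direction
(modulo sign) continues the streamline — this is the collinearity
constraint that makes the permissive 60° angle limit safe in multi-peak
voxels. Growth stops when interpolated FA at the candidate point falls
below 0.15, the turn between consecutive step directions exceeds 60°, the
streamline leaves the grid, no peak survives refinement, or a 2000-step
safety cap is hit. The angle rule compares consecutive *step* directions —
the literal "maximum angle" semantics — and both rules are audited
post-hoc on every emitted streamline in the acceptance suite rather than
trusted.

## Dissection and group maps

The hand-drawn gate ROI of an interactive dissection is replaced by an
explicit voxel mask (with a helper that builds a rectangular patch on an
axis-aligned plane); the traversal plane keeps streamlines with a segment
crossing or touching the plane (inclusive at the boundary). Two automated
artifact rules operationalize visual QC: cumulative unsigned turning
> 360° (a loop by construction), and interior points entering more than 2
distinct cortical labels (endpoints legitimately occupy two labels;
interior threading is the artifact). Cortical labels grow into
white-matter voxels whose centre lies within 2.0 mm of a label voxel's
centre, contested voxels going to the nearest label with ties to the
smaller id — note that at 2.2 mm isotropic voxels a 2.0 mm depth produces
no growth under the centre-distance rule; the growth becomes effective on
finer grids or larger depths, and the rule is kept exact rather than
rounded. Termination classification tests *only* the two endpoints of each
streamline (nearest voxel; labels are categorical, so no interpolation),
and the binary indicator per VOI is 1 at ≥ 1 supporting streamline, with
raw counts preserved so stricter thresholds can be applied post hoc.

Density maps count each streamline at most once per voxel, with membership
by point containment after supersampling segments at half-voxel spacing —
a deliberate simplicity over exact voxel traversal, checked in the tests
against an independent point-by-point enumeration. Visitation masks are
counts ≥ 1; probability maps are exact subject fractions (asserted to be
integer multiples of 1/n); threshold masks use inclusive ≥ and are nested
under increasing level. Spatial normalization to a common grid is outside
the package: group operations verify grid identity and assume registration
happened upstream.

## Synthetic phantoms

The generator emulates the study acquisition — 55 directions at
b = 2000 s/mm² placed by electrostatic repulsion with antipodal terms
(minimum pairwise axis separation ≥ 12° at the converged layout), one b0,
2.2 mm isotropic voxels — and tube-shaped bundles around cubic-spline
centerlines. Fiber voxels mix axially symmetric tensors with eigenvalues
(1.7, 0.3, 0.3)×10⁻³ mm²/s (FA ≈ 0.80, computed by the closed form in the
tests), equal fractions per contributing bundle; background is isotropic
0.9×10⁻³ mm²/s (FA ≈ 0), so the 0.15 FA threshold separates bundle from
background by construction. Rician noise takes the magnitude of a
complex-Gaussian perturbation with σ = S₀/SNR. Three presets cover the
geometries the dissection must handle: a single straight bundle, a
90°-crossing pair with a gate before the crossing, and a gate-and-fan
layout (four anterior branches to frontal-like labels, three posterior
branches, one perpendicular crossing bundle through the fan) that mimics a
bundle gathered in a narrow capsule-like gate and spreading to multiple
cortical targets.

What the phantoms deliberately do **not** emulate: real head geometry,
partial-volume and T2 effects, susceptibility or eddy distortions,
multi-shell schemes, or realistic cortical folding. Passing the phantom
suite therefore demonstrates the correctness of the numerics and the
termination logic, not in-vivo validity of any anatomical claim.

## Packaged termination tables

The subject × VOI binary matrices for the anterior and posterior
termination profiles (20 subjects, both hemispheres) are transcribed into
CSV with `1*` marking entries supported by very few streamlines (counted
as indicator 1; the flag is preserved). The published per-VOI percentage
row is transcribed alongside and acts as an independent audit: the loader
recomputes every column percentage and refuses to load on any mismatch,
and file integrity is guarded by sha256 checksums. One known source
inconsistency (left cuneus stated 30% in narrative text vs 35% in the
table) is resolved in favour of the table.

## Problem sizes and test design

Test and acceptance runs use deliberately small instances: tracking runs
use 2³ seeds per gate voxel (the 11³ default is exercised by the seeding
worked example), the crossing and gate-and-fan phantoms span ≈ 26×30×9 and
36×44×11 voxels, bootstrap statistics use 500 draws per condition, and the
oracle comparison uses 100 random voxels. Bootstrap peak dispersion is
estimated pooled over four independent noise realizations per SNR level,
because the dispersion of a single realization is itself a random
quantity (the residual bootstrap conditions on one noisy acquisition).

## Known limitations

- Order-4 truncation limits angular resolution; crossings much below 60°
  merge into single peaks, and the double-log of a sharp prolate tensor is
  fit with an irreducible truncation RMSE of ≈ 0.03 (measured in the
  tests against the closed-form signal).
- The tensor "baseline" tracker is intentionally naive (principal
  eigenvector, same stopping rules) — it is a comparison arm, not a
  production DTI tracker.
- TRK I/O fixes an internal RAS+ mm convention; files from tools using
  other conventions must carry correct headers to round-trip.
- Loop/threading QC thresholds (360° turning, > 2 interior labels) are
  operational definitions of visual criteria and are configurable.
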