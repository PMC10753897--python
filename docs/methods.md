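# Methods

Models, assumptions, numerical choices and known limitations, stage by stage.
Coordinates are (x, y, z) with y the rod/tilt axis; all lengths are nm; voxels
are isotropic.

## Phantom (`osteotomo.phantom`)

**Geometry.** The sample is a conical rod along y (radius interpolating
linearly from `rod_radius_top` to `rod_radius_bottom`). Fibrils are circular
cylinders parallel to y. Diameters are drawn from
N(`fibril_diameter_mean`, `fibril_diameter_sd`), truncated below at 4 voxels.
Packing draws a diameter *once* and then tries up to 400 uniform positions in
the admissible disc before redrawing: redrawing the diameter on every failed
position would bias the realized distribution toward small fibrils (large ones
fail placement more often), breaking the documented invariant that realized
diameters follow the spec distribution. Overlapping fibrils are rejected; an
unreachable `fibril_fill_fraction` raises `PackingError` rather than looping
forever.

**Classes and contrast.** Voxel classes are vacuum (0.0), resin (0.12),
unmineralized collagen (0.25), overlap band (0.30), gap band (0.55) and
extra-fibrillar mineral (1.0); `matrix_mineralized` selects whether the
intra-rod, extra-fibrillar space is mineral (default) or resin. Each fibril
alternates gap/overlap along y with period `d_spacing` (default 67; overlap
fraction 27/67) and a per-fibril random phase. Plates (default 100 × 35 × 7)
are oriented boxes tangent to fibril surfaces, long axis along y, thickness
radial; they never overwrite fibril voxels but may touch neighbouring fibrils
(this is what makes the mineral phase cross-fibrillar, cf. the
`preset_cross_fibrillar` preset where plates alone carry the mineral).
Elemental volumes are `element_weights[class] × density` per voxel.

**Determinism.** All randomness flows from one `numpy` Generator seeded by
`spec.seed`; identical spec + seed gives bitwise-identical output.

**Limitations.** Fibrils are straight and axis-parallel (no waviness or
tilt distribution); banding is a hard two-level pattern rather than a smooth
density modulation; plates are rigid boxes.

## Tilt simulation (`osteotomo.tiltsim`)

Projection is a parallel-beam line integral about y, implemented per y-row as
a sparse pixel-driven splat matrix (bilinear footprint) that is cached per
(shape, angle set). The same matrix is used transposed in reconstruction, so
the projector/backprojector pair is exactly matched. Mass is conserved to
<0.5% at any angle. On-axis geometry means ±90° covers the full half-circle:
no missing wedge.

EDX channels project the elemental volumes with the same operator, then bin
2×2 by default (coarser detector grid). Noise is Poisson at a given dose plus
Gaussian read noise, negatives clamped by default. Misalignment applies
subpixel random frame shifts (recorded in `applied_shifts`).
`smooth_edx_frames` is a Gaussian followed by a box average with reflective
boundaries (a constant frame stays exactly constant).

**Limitations.** No beam convergence, dynamical scattering, detector MTF or
sample warping; HAADF contrast is assumed strictly linear in density.

## Reconstruction (`osteotomo.recon`)

**Alignment.** Sequential FFT cross-correlation from the central frame
outward, with 3-point parabolic sub-pixel refinement. Recovered shifts are
relative to the reference frame (a global translation is unobservable — the
gauge freedom is documented in the tests). An all-zero frame is rejected by
index. Limitation: a y-degenerate object (a perfect axis-parallel rod) gives
no y signal to correlate on; alignment tests therefore use structured blob
volumes.

**Tilt-axis offset.** Brute-force search over integer x offsets maximizing
0°/180°-equivalent frame consistency, with parabolic refinement.

**SIRT.** Cimmino-style simultaneous iteration
`x += relax · C · Aᵀ R (b − A x)` with row/column inverse-sum normalization,
nonnegativity clamp by default, 25 iterations by default. On an 8×8
single-slice system, 3000 iterations reach the explicit least-squares residual
within 1%; residuals are non-increasing. EDX reconstruction reuses the HAADF
alignment (shifts divided by the binning factor) on the binned grid.

## Segmentation (`osteotomo.segment`)

The "holes" recipe composes `define_range` (inclusive gray band) →
`invert` → `fill_inner_areas` (2D hole filling slice-wise along x, then y,
then z, each pass feeding the next) → `boolean_intersect` with the step-1
band → `process_islands` (drop 6-connected components below 27 voxels). The
band also contains the vacuum background, but the background is never
*enclosed* in any slice, so the fill/intersect pair removes it: the output
cannot contain background voxels (verified as an acceptance property).

**Automatic thresholds.** A reconstructed rod histogram has at least three
modes: background, dark fibril material, bright mineral matrix. A two-class
Otsu threshold lands inside the fibril gray band (dragged by the large
background mode), cutting the "holes" down to the overlap bands only. The
fibril/matrix boundary is therefore the upper threshold of a *three-class*
Otsu split (`threshold_multiotsu(classes=3)[-1]`), falling back to two-class
Otsu on degenerate histograms. With it, segmented holes are whole fibril
cross-sections — the structures the diameter statistics refer to.

## Quantification (`osteotomo.quant`)

**Local thickness.** `volume_thickness_map` assigns every mask voxel the
diameter of the largest sphere that contains it and fits inside the mask:
candidate centers are all mask voxels with their Euclidean distance-transform
radius (volume borders count as background), dominated centers (a 26-neighbour
whose sphere provably contains theirs) are pruned, and remaining spheres are
painted largest-first. Squared distances between voxel centers are exact
integers, so coverage (`|u − c|² < r²`) and domination
(`√b ≥ √a + √s ⇔ b−a−s ≥ 0 ∧ (b−a−s)² ≥ 4as`) are evaluated in int64 — a
float `r*r` at r = √10 rounds up and would leak the open-ball boundary. The
result matches a brute-force oracle exactly on every tested mask. Note that
discrete geometry matters at the voxel scale: a digital ball whose center
falls between voxels (even grid) genuinely has surface values several voxels
low under this definition, while a grid-centered ball is uniform to within a
voxel.

**Periodicity.** `peak_spacing` smooths with a moving average (width 5),
finds local maxima/minima that strictly dominate all neighbours within
±`order` samples — with runs of equal values (plateaus) treated as a single
extremum at the run center, which is essential when a symmetric extremum
falls exactly between samples — drops candidates with prominence below 10% of
the smoothed dynamic range (reconstruction ripple on band plateaus is orders
of magnitude shallower than band contrast), refines single-sample extrema
with a 3-point parabolic fit, and averages consecutive-maxima and
consecutive-minima spacings. For two-level banding, profiles are sampled at
`d_spacing/10` so the 5-sample smoothing spans about half a period and band
extrema localize at band centers; the pipeline helper averages over a disc of
half the fibril radius to suppress off-axis ripple.

**Plate dimensioning.** Per xy slice, the perimeter `2p` is the boundary
length of the convex hull of the pixel squares' corners and the thickness `t`
the minimum Feret diameter (rotating calipers) of the convex hull of the
sub-pixel marching-squares contour; the in-plane dimension is `p − t` and the
out-of-plane dimension is the occupied-slice count times the voxel size
(`orientation_mode` decides which is length vs width). The corner hull makes
the rectangle identity exact (axis-aligned 100 × 7 slice → 2p = 214, l = 100);
a marching-squares *perimeter* would chamfer the corners (212.83) and break
it, while a corner-hull *Feret* would inflate tilted thickness by ~1.1 voxel
(staircase corners). The half-level contour interpolates the boundary between
pixel centers — the same convention scikit-image uses for Feret diameters —
and keeps ≤10°-tilted 7-voxel plates within 15%. An `l ≥ w ≥ t` violation is
reported in `warnings`, never hidden. Limitation: thickness of plates a few
voxels thick is still quantization-limited (~0.9 voxel bias when tilted).

**Connectivity and ROI statistics** are direct: 6-connected component counts,
volume fractions, per-component y extents; ROI/background intensity means and
their ratio, with overlap and emptiness rejected.

## Spectroscopy arithmetic (`osteotomo.spectro`)

Absorbed fraction is `1 − exp(−(μ/ρ)·ρ·L)` with μ/ρ a single tabulated
scalar for cortical bone (3.781×10³ cm²/g at 1 keV), ρ = 1.8 g/cm³ and the
path converted from nm to cm: 37.899% for 700 nm. Hydroxyapatite
Ca₁₀(PO₄)₆(OH)₂ gives an exact Ca/P atomic ratio 10/6 = 1.67 (2 d.p.).
The simplified composition splits a 70 wt% mineral fraction between Ca and P
at the exact stoichiometric *weight* ratio (masses Ca 40.078, P 30.974),
giving 47.8 and 22.2 wt% at 3 s.f. — using the rounded 1.67 instead of 10/6
would give 22.1, which is why the exact ratio is used. Conversion back from
weight to atomic ratio is provided for round-trip checks.

## Verification summary

- Unit and property-based tests (seeded, derandomized Hypothesis) per module:
  projector mass conservation and linearity at arbitrary angles, exact
  adjointness via the least-squares comparison, MRC/TIFF/.tlt round trips,
  segmentation set algebra, thickness-map oracle equality, extrema-spacing
  analytics (pure cosine, trend robustness, error paths).
- Acceptance tests (`tests/test_acceptance.py`): one test per criterion —
  closed-form attenuation/stoichiometry, D-spacing 67 ± 2 nm and hole-diameter
  within 15% through the full default pipeline, oracle exactness, missing
  wedge monotonicity, least-squares agreement, 0.5 px alignment RMS, plate
  recovery, cross-fibrillar dominance, holes/background disjointness.
- `scripts/acceptance.py` recomputes the two headline numbers from scratch
  (closed form, and the full phantom → projection → SIRT → profile → spacing
  chain) for any seed.
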