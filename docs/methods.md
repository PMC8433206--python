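# Methods

This note documents the models, conventions and numerical choices behind
`islet3d`, what the synthetic phantoms do and do not emulate, and the known
limitations.

## Coordinate and unit conventions

Arrays are indexed `(z, y, x)` (TIFF z-pages); all exported physical
coordinates are `(x, y, z)` micrometres measured from the cuboid corner,
with the voxel at index `(iz, iy, ix)` centred at
`((ix+0.5)h, (iy+0.5)h, (iz+0.5)h)` for voxel size `h`. Voxels are assumed
isotropic (true for OPT; light-sheet volumes should be resampled first).
Volumes are µm³, areas µm², densities either dimensionless (volume
fraction) or mm⁻³ (count). The default voxel size of 21 µm matches the
mesoscopic OPT configuration the pipeline targets.

## Enhancement

Enhancement conditions reconstructed volumes for thresholding; it runs per
channel and per z-slice and never mixes channels.

* `rescale_minmax`: affine map of the volume onto [0, 1]; a constant volume
  maps to zeros (documented degenerate case).
* `clahe_slicewise`: scikit-image's contrast-limited adaptive histogram
  equalization per z-slice, with the tile *count* per axis as parameter
  (32 for the labelled channel, 16 for the AF channel). The clip limit
  default is 0.01 — gentle equalization; it is a free parameter because no
  reference value exists for this imaging configuration. Slices are
  normalized by the volume-wide min/max first so slices remain mutually
  comparable. In the originating workflow these operators run on projection
  images *before* tomographic reconstruction; reconstruction is outside
  this package's scope, so the same operators are applied to reconstructed
  slices instead. This is stated openly: the operators are identical, the
  domain differs.
* `fuse_ranges`: the input is stretched into three windows (defaults
  (0, 0.4), (0.2, 0.8), (0.6, 1.0) of the rescaled range) and the copies
  averaged pixelwise, then rescaled. The arithmetic mean is the simplest
  strictly monotone fusion rule; the windows and the combiner are
  configurable. Monotonicity guarantees rank order (hence any threshold
  set) is preserved up to ties.

## Segmentation

**Islets.** Foreground by threshold — Otsu on the non-zero voxels by
default, or a manual value (`threshold_mode`); the manual path exists
because real tissue was thresholded manually per sample and automatic
thresholds are a stand-in, which reports should flag. Touching islets are
split by watershed on the negated Euclidean distance transform. Seeds are
distance-transform maxima found *per connected component* (so a large
neighbour can never absorb the only seed of a small separate object) and
thinned greedily to a minimum Euclidean separation equal to the expected
islet diameter (110 µm); candidates are visited strongest-first with ties
broken by lexicographic voxel index, making the labelling deterministic.
The 110 µm default is the published average human islet 3D diameter.
Components below `min_voxels = 5` are removed. At 21 µm voxels this
corresponds to 46.3·10³ µm³ (5 × 21³ = 46 305 µm³); the filter is defined
in voxels, the volume is derived.

**Spots.** An independent islet counter: the scale-normalized negative
Laplacian of Gaussian, maximized over a small scale pyramid
(0.6–2.4 × the matched scale σ = d/(2√3) for expected diameter d). The
"quality" of a spot is the response divided by the analytic response of an
ideal isotropic Gaussian blob of the expected diameter and unit contrast
(3·C/2^{5/2} at the matched scale), so quality ≈ the blob's contrast;
spots with quality < 1 are discarded by default. The pyramid exists
because a single matched scale systematically under-scores uniform objects
two or more times the expected diameter (their interior is flat at that
scale); maximizing the normalized response over scales restores
contrast-proportional scores across the realistic islet size range while
leaving the ideal-blob normalization unchanged.

**Tissue and outline.** The tissue mask is the AF channel smoothed at a
15 µm grain and thresholded; the largest component plus all components
≥ `min_voxels` are kept. The specimen outline (envelope) replaces the
manual contour-drawing of interactive tools with an automated closure:
binary closing with a ball of 10 voxels followed by per-slice hole
filling, then union with the tissue mask so `outline ⊇ tissue` always
holds exactly.

**Hypointense regions** are the connected components of
`outline AND NOT tissue` — lumens of vessels/ducts and fat deposits.
Each region is classified by Wadell sphericity: spherical ≥ 0.7,
tubular ≤ 0.6, otherwise unclassified. The tubular cutoff derives from
the sphericity of an ideal cylinder of aspect q (length/diameter),
Ψ = 2.618·q^{2/3}/(2q+1): Ψ = 0.6 at q ≈ 9, and a 20:1 lumen has Ψ ≈ 0.47,
so 0.6 separates elongated lumens from compact deposits. (Cutoffs far
below 0.5 are ineffective: even extreme lumens rarely fall under 0.45.)

**Hemorrhage.** The AF channel is masked onto the segmented islets and
thresholded (Otsu on the in-islet intensities or manual); the supra-
threshold volume per islet is its intra-islet hemorrhage volume. Voxels
outside islets are never counted, by construction.

## Morphometry

Axis lengths are *world-axis-aligned ellipsoid-equivalent lengths*: the
variance of a uniform solid ellipsoid's coordinate along an axis with
semi-axis a is a²/5, so length = 2√(5·var), computed along x, y, z — not
PCA principal lengths, because the mean 3D diameter is defined as the
average of the x, y and z axis lengths specifically. A Sheppard-type
intra-voxel term (h²/12 per axis) keeps single-voxel objects from
reporting zero length. For rotated objects the phantom ground truth uses
the identical world-axis definition, making truth and measurement directly
comparable.

Surface area is the area of the marching-cubes isosurface at level 0.5 of
the zero-padded binary mask. The mask is first smoothed with a Gaussian of
σ = 0.8 voxels: marching cubes on a raw binary mask tracks the voxel
staircase and overestimates the area of smooth solids by a persistent
~8 %, which the light anti-aliasing removes (measured on digitized balls:
Ψ = 1.064/1.009/0.997 at r = 5/10/20 voxels, and a 4:1 prolate within
0.1 % of the analytic value). Objects too small to survive the smoothing
(peak under the iso-level) fall back to the raw mask; in that coarse limit
the isosurface of a single voxel is the dual octahedron with area √3·h²,
and sphericity can exceed 1 by ~10 % for objects only a few voxels across
— a discretization artefact to keep in mind when interpreting Ψ of the
smallest retained objects.

## Quantification

Size categories are left-open/right-closed intervals over the standard
volume edges (0, 25·10³, …, 102.4·10⁶ µm³; each bin doubles) or mean-3D-
diameter edges (0, 62.5, …, 328.4 µm), matching the interval-cut semantics
of `pandas.cut`, which these edge lists were designed for: a value equal
to an edge falls in the lower bin; zero and values above the last edge are
unbinned. Unbinned islets are reported in an explicit `overflow` row by
default rather than dropped; `drop_unbinned=True` restores the silent-drop
behaviour of a plain interval cut.

Densities are referenced either to the **outline** volume (specimen
envelope including non-tissue space — the mode to use for cross-species or
literature comparison) or to the **tissue** volume (envelope minus
hypointense regions — the actual parenchyma). Since tissue ≤ outline,
tissue-mode densities are never smaller. Both modes are always computed.

Grouped sphericity summaries report mean/SD/n per size category or across
a single volume split (default 9·10⁶ µm³, the conventional large-islet
threshold); empty groups report n = 0 with NaN statistics.

## Clustering and ROI analysis

Two islets are linked when their centroids are ≤ 300 µm apart; clusters
are the connected components (single linkage — equivalently, a minimum
spanning tree cut at the cutoff; the two formulations are identical for
this rule). Labels are canonical: components numbered by minimum member
index, so the labelling is independent of point order. The implementation
uses a KD-tree pair search plus a disjoint-set union and is verified
against a brute-force O(n²) oracle. Distances are centroid-to-centroid; a
consequence worth noting is that two touching *large* islets can have
centroids farther apart than the cutoff.

A cluster is a **HIDR** (high islet density region) iff its member count
strictly exceeds 100 — count 100 is a LIDR, 101 a HIDR. ROI comparison
uses cubes of 48 voxels edge (1.008 mm at 21 µm voxels, volume
1.0242 mm³): one cube centred on each HIDR centroid (clamped inside the
cuboid with a warning) and `n_random_rois` (default 10) seeded-random
reference cubes. An islet belongs to a cube iff its centroid is inside;
densities are totals over the cube volume.

## Stitching

Placement is pure metadata arithmetic — `global = local + origin`, with
`origin = grid_ijk ⊙ pitch` recorded at slicing time (default grid pitch
5 500 × 3 300 µm; cuboids taller than the scanner bore are handled as
z-blocks on a third grid axis). No image registration is performed; the
grid is assumed to cut ideally, which is exact for phantoms and an
approximation for real tissue (the original workflow aligned cuboids
manually on vessel continuity; a cross-correlation refinement would slot
in here but is intentionally out of scope). Volume re-assembly requires
voxel-aligned, non-overlapping placements and errors otherwise, naming the
offending cuboid.

Catalog merging concatenates per-cuboid records under globally unique ids.
Optional boundary merging (off by default — per-cuboid counting is the
reference behaviour) re-joins objects bisected by a cut: candidates must
lie in grid-adjacent cuboids, touch the shared face within one voxel
(bounding-box test) and have centroids within 55 µm laterally (half the
expected islet diameter); merged volumes are summed and centroids
volume-weighted, while shape features are kept from the larger part
rather than re-triangulated.

## The phantom generator

Phantoms exist because no dataset of this kind is publicly deposited; they
define the conditions under which the pipeline's guarantees are tested.

Geometry is rasterized by the voxel-centre-in-solid rule — the simplest
rule whose voxel-count volume provably converges to the analytic volume.
For objects of ≥ 100 voxels the count is within 15 % of analytic
(typically within a few %); for objects a few voxels across digitization
noise reaches tens of percent — e.g. a 55 µm-radius sphere (2.6 voxels)
digitizes 8–17 % high depending on sub-voxel centring. Emissive objects
combine by maximum; holes overwrite.

Defaults, chosen once to represent the target imaging conditions:

| parameter | default | rationale |
|---|---|---|
| voxel size | 21 µm | mesoscopic OPT pixel size |
| islet diameter | log-normal, median 110 µm, GSD 1.5 | published average human islet diameter; GSD spans ~50–250 µm |
| minimum diameter | 63 µm (3 voxels) | below this an object is not reliably representable on the lattice |
| anisotropy | semi-axis ratios ≤ 1.5 | islets are compact, mildly elongated |
| cluster members | log-normal, median 75 µm, GSD 1.2 | members must sit ≤ 250 µm apart without overlapping, which bounds their size |
| contrast | islets 1.0 vs signal background 0.08; AF tissue 0.3 | free parameters — no published intensity statistics exist for human pancreas AF |
| noise | additive Gaussian, SD 0.02, clipped at 0 | sensor noise is uncharacterized; a small value keeps thresholding realistic but solvable |
| placement gap | 42 µm (2 voxels) | guarantees separability of non-cluster objects |

Objects are placed by rejection sampling with a hard cap of 10 000
attempts per object — deterministic failure (naming the object kind) beats
silent overlap. Clusters grow by chaining: each member is placed within
`cluster_radius_um` of an existing member, making the planted cluster a
single single-linkage component at any cutoff ≥ that radius. Peripheral
clusters seed at ≥ 80 % of the organ ellipsoid's normalized radius,
emulating the observed surface localization of dense islet regions without
claiming biological fidelity. Organ phantoms are rendered once as a
contiguous ellipsoidal body and then cut on the grid, so re-assembly is
bit-exact and per-object voxel counts are conserved across cuts exactly.

What the phantoms do **not** emulate: the optical point-spread function,
projection/reconstruction artefacts (streaks, rings, axis misalignment),
intensity inhomogeneity with depth, autofluorescence spectra, deformation
of cuboids during handling, and biological covariance between islet size,
shape and location beyond the planted cluster structure. Passing the
phantom suite therefore demonstrates the correctness of the *computational
pipeline* under its stated geometric model — not segmentation accuracy on
real tissue, where threshold choice and optical artefacts dominate.

## Problem sizes used in validation

The test suite and the acceptance script size their simulations to be
informative yet quick on a single CPU: recovery tests use a 256³ cuboid
with 200 islets (count recovered exactly; volume error 0 % for ≥ 100-voxel
objects; mean-diameter error ~3 %); the clustering oracle uses 500 points
× 20 seeds; stitching uses 2×2×2 organs of 48³-voxel cuboids. These sizes
are the package's validation conditions, and all scale linearly upward.

## Known limitations

* Otsu auto-thresholding assumes a bimodal histogram; on a uniformly
  tissue-filled AF cuboid it splits texture arbitrarily, so tissue masks
  of full blocks should use manual thresholds (as the interactive
  workflow did).
* Sphericity of objects under ~10 voxels is dominated by discretization.
* The spot detector's quality is contrast-calibrated for blob-like
  objects; heavily concave or hollow objects under-score.
* Boundary merging uses bounding-box face contact, which can over-merge
  two distinct objects that both touch the same face within the lateral
  tolerance; it is off by default.
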