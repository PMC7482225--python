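# Methods

voxsample quantifies relative fluorescence in nuclear, cytoplasmic and
membrane compartments of crowded 3D tissue volumes without segmenting whole
cells. It detects well-resolved reference features (nuclei, or membrane
patches), then *samples* the fluorescence around them; every sample keeps its
3D position so protein levels can be related to tissue geometry (distance to
the exposed surface, distance to user-marked regions of interest). The method
deliberately does not reconstruct cell shapes, does not integrate total
fluorescence per cell, and does not track cells over time.

## Nuclear detection

Nuclei are the most robustly detectable feature in most tissue stains, and
their cross-sections through a confocal stack are near-circular. Detection
therefore runs per z-slice: the slice is Gaussian-blurred, thresholded at the
user's brightness estimate, and the boundary of the binary foreground votes
in a circular Hough transform over a band of radii. Accumulator peaks
(normalized to the vote of a complete circle) above 0.4 are kept, with greedy
non-maximum suppression so no two detections are closer than the smallest
search radius. Per-slice detections are linked greedily across consecutive
slices: a detection joins the open chain whose running vote-weighted mean
centre is nearest and within half a nuclear radius; chains shorter than half
a nuclear diameter in z are discarded as spurious. Each surviving chain
yields one nucleus at the vote-weighted mean of its members.

Only two user parameters exist — the expected nuclear diameter D and the
brightness threshold — and every internal setting derives from them:

| setting | value | rationale |
|---|---|---|
| Hough radius band | [0.3, 0.7] · D / in-plane spacing | off-equator sections of a sphere shrink; the band covers sections within ~±70% of the equator |
| blur sigma | D/8 voxels | scale-proportional smoothing |
| accumulator threshold | 0.4 of a full circle's vote | tolerates partially occluded boundaries without spurious peaks |
| link radius | 0.25 · D (in-plane) | a true centre drifts little between adjacent slices |
| minimum chain length | max(2, ceil(0.5 · D / z-step)) | a sphere spans about its diameter in z |

Blur-then-threshold (rather than the reverse) keeps the pipeline linear
before the single nonlinearity, so scaling the channel and the threshold by
the same constant provably leaves detections unchanged.

## Compartment sampling

Each voxel within a crop radius of 2 D is assigned to its nearest nucleus
(exact physical distance, anisotropy-aware; equidistant voxels go to the
lowest nucleus id for determinism). Assigned voxels at or above the
brightness threshold on the nuclear channel are nuclear, the rest
cytoplasmic. Per channel, the nuclear mean is unweighted; the cytoplasmic
mean weights each voxel by exp(−d²/2σ²) with σ = one nuclear radius — the
weight stands in for the probability that a voxel at distance d still
belongs to the same cell. The weighting function's form is not dictated by
the sampling idea itself; a Gaussian was chosen as smooth, monotone and
single-parameter. Because no bounding tissue surface is computed, sampling
can reach outside the tissue; an optional switch restricts cytoplasm
sampling to the filled membrane foreground (off by default).

The N/C ratio per channel is nuclear mean / weighted cytoplasmic mean, and
its natural log is reported alongside to symmetrize the distribution. A zero
or empty cytoplasmic mean yields a missing value, never an exception.

With a membrane stain present, two more readings are taken per nucleus:

* **exposed membrane** — the membrane channel is thresholded (Otsu when the
  user gives no value), hole-filled, and the foreground voxels 6-adjacent to
  exterior background (background connected to the volume border; the volume
  face itself counts as exterior) form the exposed surface, each voxel
  assigned to its nearest nucleus;
* **contacting membrane** — for every Delaunay-adjacent nucleus pair closer
  than 2.5 D, the membrane channel is sampled along the inter-centre segment
  at 0.25-voxel steps (trilinear); the intensity arg-max (plateau-centred)
  locates the shared membrane and all channels are averaged within ±0.5 µm
  of it along the line, credited to both nuclei.

## Membrane-fragment reference (nucleus-free mode)

When no nuclear stain exists, membrane patches serve as reference points.
The membrane channel is contrast-normalized per slice (CLAHE, clip 0.01),
blurred (0.5 µm, anisotropy-corrected), and passed to a 3D Canny detector:
Gaussian-derivative gradients per axis in physical units, non-maximum
suppression along the quantized 3D gradient direction, and double hysteresis
(0.2/0.5 of the max gradient) with 26-connected linking. Spheres are fitted
to the edge cloud by sequential RANSAC: draw a seed point plus three spatial
neighbours (within 1.5 × the upper radius bound — local sampling keeps the
four points on one cell), solve the exact sphere, count edge points within
0.75 µm of its surface, and accept the best model with ≥ 30 inliers and a
radius within [0.5, 3] × the cell-radius estimate; accepted inliers are
least-squares refined, removed, and the search repeats. Iterations stop
early by the standard adaptive RANSAC bound (confidence 0.999).

Each accepted sphere is split into fragments on a ~45° angular grid; a
fragment's surface point is the bin centroid projected onto the sphere (a
chord centroid lies inside it) and its normal points to the sphere centre.
Because Canny edges sit on the *faces* of a stained shell, not its midline,
each fragment is then snapped along its normal to the membrane-intensity
arg-max within ±2 µm. Fluorescence is read through three thin discs (radius
1 µm, thickness 0.5 µm): tangent at the surface point (membrane) and
displaced ±1.5 µm along the normal (cytoplasm on either side); discs
clipping the volume flag the sample partial.

A resolution caveat quantified during design: sampling a 1 µm membrane shell
requires a z-step finer than the shell. At a 1 µm z-step even discs placed at
the exact shell midline with exact normals read ~15% low (trilinear blending
across unresolved voxels), so the fragment validation phantom renders at
isotropic 0.5 µm spacing, where midline sampling is accurate to ~7% and the
residual error of detected fragments is attributable to sphere-fit geometry.

## Surface-domain partition

Supplied per-cell masks (integer-labeled TIFF, standing in for manual
outlines) are partitioned per surface voxel (6-connectivity throughout):
basolateral if any neighbour belongs to another cell; exposed if any
neighbour is background (enclosed lumens are apical-facing biologically and
count as exposed by default); and junctional — the band of exposed voxels
within 1 µm of a basolateral voxel of the same cell, where cell–cell
junctions concentrate. The three domains are a disjoint cover of each
surface; a zero band width gives a pure exposed/basolateral split. Whether
the junctional band is carved from the exposed or the basolateral side is a
design choice (exposed side here); area fractions are voxel counts, which
track true areas up to an orientation-dependent staircase factor.

## Geometry

Neighbourhood is the Delaunay tetrahedralization of nuclear centres pruned
at 2.5 D (raw Delaunay links distant hull points); rank-deficient inputs
fall back to 2D/1D triangulations. Distances to the exposed surface are
point-to-voxel-centre Euclidean minima (error ≤ half a voxel diagonal);
distances to ROIs use the exact point/point and point-to-segment formulas,
one value per ROI in file order. Geodesic (through-tissue) distances are out
of scope.

## Synthetic phantoms

The generator mirrors a CAD-style validation: clusters of spherical cells
(default radius 15 µm) with concentric nuclei (5 µm), a 1 µm membrane shell,
cytoplasm between, rendered on an anisotropic grid (1 × 0.5 × 0.5 µm, typical
confocal) with per-compartment intensities and additive Gaussian noise
(sigma = 0.1 × cytoplasm intensity ≈ SNR 10; optional Poisson shot noise).
Voxels take the compartment of their centre point — no anti-aliasing — so
compartment masks are exact oracles. The four-model validation suite draws
4–6 cells per model (seeded), arranged as tetrahedron / square pyramid /
octahedron with nearest-neighbour centre distance 1.8 × radius, so every
cell touches its neighbours and shell overlaps form contacting membranes
without unphysical deep interpenetration. Each model's signal channel
carries a different true N/C ratio, covering {0.5, 1, 2, 4} across the
suite; intensity tables span a ≥ 4-fold dynamic range.

What the phantoms do *not* emulate: point-spread-function blur, partial-
volume mixing at compartment boundaries, depth-dependent attenuation,
non-spherical cell shapes, and intensity variation within a compartment.
Passing the phantom tests therefore demonstrates the correctness and
calibration of the sampling machinery, not performance on degraded real
tissue; the known real-data failure modes (poor nuclear contrast at depth,
sampling outside the tissue) are discussed above.

## Problem sizes and numerics

Test and validation volumes are 10⁵–10⁷ voxels (suite models ≈ 70 × 156 ×
156 at the default spacing), sizes at which the full suite renders and
analyses in well under a minute per model on one core; edge clouds larger
than 40 000 points are subsampled (seeded) before RANSAC. All stochastic
steps (phantom noise, RANSAC) take explicit seeds and are bit-reproducible;
detection, linking, voxel assignment and the partition are deterministic with
stated tie-breaks (strongest vote first, nearest chain, lowest id). Degenerate
inputs — blank slices, empty foregrounds, isolated nuclei, coplanar point
clouds, zero cytoplasmic means — yield empty results or missing values with a
logged warning rather than exceptions.

## Known limitations

* Compartment means are biased where another compartment enters the
  weighting range: with touching cells the cytoplasmic mean of a
  membrane-stained channel reads a few percent high (contact shells are
  classified cytoplasmic); conversely background just outside the tissue
  pulls cytoplasmic means down. Both are properties of segmentation-free
  sampling, visible in the phantom error budget (~2% combined, ~4%
  cytoplasmic at SNR 10).
* Fragment-based membrane readings carry the sphere-fit positional error and
  the z-resolution requirement described above; they are the least accurate
  output (~10% on noise-free isotropic phantoms) and intended for relative,
  not absolute, comparisons.
* The Hough path assumes near-spherical nuclei; elongated or mitotic nuclei
  vote weakly and may be dropped.
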