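# Methods

This note records what `voxtract` computes and why each methodological choice
was made, in the package's own terms. Array convention throughout: volumes
are indexed `(z, y, x)`; voxel spacing `(c, b, a)` is given in nm per axis in
the same order; a voxel's physical position is its center. FIB-SEM data are
anisotropic — the milling step `c` (typically 10 nm) exceeds the in-plane
pixel size `a = b` (typically 3.255 nm) — so every nm↔voxel conversion is
per-axis.

## Intensity normalization

Block-face EM stacks drift in brightness and contrast across slices and
across fields of view. `clahe_anisotropic` applies contrast-limited adaptive
histogram equalization as three independent 2D passes over orthogonal plane
stacks (XY, XZ, YZ), combined voxel-wise (mean by default). Window sizes are
specified physically: a 260.4-nm tile is an 80 × 80 px window in XY but a
26 × 80 px window in XZ/YZ on the standard grid. Running an isotropic pixel
window on milling-direction planes would equalize over a physically elongated
region and bias those passes; the rectangular windows remove that bias. The
clip limit is given as the classical CLAHE clip factor (histogram bins clipped
at `factor ×` the mean bin count) and converted internally to the normalized
limit the underlying 2D implementation expects (`factor / nbins`). Median
denoising uses per-axis half-widths `round(radius / spacing)`, so a physical
radius below the milling step smooths only in-plane.

## Voxel extraction (AIVE)

The core operation multiplies an AI-derived class probability (0–1, first
Gaussian-smoothed with a physical sigma, 10 nm by default) into the
normalized 8-bit intensity, voxel by voxel, with round-half-up to 8-bit. Any
voxel where either factor is zero is excluded, so surfaces land where the
electron signal supports them rather than where a model's decision boundary
falls. The center of the product's dynamic range — 50% probability × 50%
intensity = 25% of 255 — gives the default isosurface level of 64.

Instance handling follows the same multiplicative logic: a label volume does
not define an organelle's boundary; its binary mask is blurred (soft edge)
and multiplied into the probability before extraction (`mask_by_label`), and
organelle interiors are filled by a saturating add of the extracted matrix
signal (`fill_organelle`). Membrane subclasses (e.g. general + vesicular) are
merged by voxel-wise maximum before extraction.

Inter-model disagreement ΔV is the per-slice mean |difference| between two
co-registered outputs, expressed as a percentage of each grid's own dynamic
range so 8-bit products and unit-interval probabilities are comparable; a
model's score is its mean ΔV against all others.

## Surface reconstruction and its resolution floor

Surfaces are extracted by marching cubes at a scalar isovalue, with vertices
linearly interpolated along grid edges and scaled into nm. On binary input,
vertices can only sit at midpoints between voxel centers: the surface is
terraced (a digitized sphere's sphericity drops from ~1.0 to ~0.77) and the
smallest nonzero separation measurable between two reconstructed surfaces is
floored at the Pythagorean combination of the two smallest half-spacings,
`sqrt((a/2)² + (b/2)²)` = 2.3 nm on the standard grid. Scalar AIVE input
removes both artifacts. Watertight meshes are oriented with outward normals
(needed because the underlying marching-cubes implementation emits
inward-pointing normals for bright-inside volumes), so signed distances are
negative inside a reference surface. Of the 256 corner-sign configurations a
cube can take, 15 are unique under rotation plus complementation — the
topology pool available to binary data, provided for documentation by
`marching_cubes_case_classes`.

## Surface separations

All separations are exact point-to-nearest-triangle distances in nm (not
vertex-to-vertex), computed with a closest-point-on-triangle test pruned by
two k-d trees (a vertex tree for per-point upper bounds, a triangle-centroid
tree for candidate selection) and batched to bound memory. Summaries follow
membrane-contact-site conventions: closest approach, the fraction of a
population within 35 nm, and area-weighted histograms in half-open 5-nm
brackets from 0 to 250 nm plus an overflow bin, where each vertex carries one
third of its incident triangle areas so percentages sum to exactly 100.

Probe consistency quantifies measurement reproducibility across AI models:
fixed probe points are sampled uniformly (seeded, without replacement) from
an eligibility shell — the membrane dilated by 35 nm minus the membrane
itself, computed with an anisotropy-aware distance transform — and each probe
records one distance per model. Per-probe range (max − min) and RAD (mean
absolute deviation from the mean, divided by the mean) summarize the scatter.

## Morphometry

Equivalent-ellipsoid axes derive from second moments of the solid's voxel
centers in physical coordinates with Sheppard's correction (+spacing²/12 per
axis), so a w-voxel box maps to a w-voxel extent; axes are `2√(5·eigenvalue)`.
Skeleton longest paths thin the solid to a medial-axis skeleton, build a
26-connected graph weighted by physical step lengths, and take the maximum
geodesic between endpoint voxels (falling back to the farthest pair on loops,
and to the geodesic through the solid itself when thinning erases a thin
even-width solid entirely). A nanotunnel is flagged when the thresholded
matrix splits into ≥2 connected components inside a single connected solid.
Intrusion cavities are the difference between the solid closed with a
physically sized ball and the solid itself, kept only when they connect to
the exterior (a sealed pocket is an inclusion, not an intrusion) and reach
deeper than a minimum depth (default 50 nm — morphological closing over a
terraced surface whose curvature radius is comparable to the closing radius
produces shallow artifacts of ~10 nm that the threshold must clear); each
cavity is categorized by the majority foreign label inside it. Occurrence
statistics use the Poisson model λ = events/instances (50 events over 186
organelles gives λ = 0.269, under which ~76% of instances carry none).
Instances clipped by the dataset boundary are excluded from whole-organelle
shape metrics.

## Sectioning model

The probability that a linear structure of length L survives sectioning
intact in a section of thickness d is one minus the classical Buffon's-needle
crossing probability — `2L/(πd)` for L ≤ d, the long-needle form otherwise.
Observing at least half the structure is modeled as the intact probability of
a needle of half length. For the observed mean intrusion length of 367.5 nm,
a 100-nm section captures the structure whole with probability 0.087 and at
least half of it with probability 0.178; a 5000-nm volume captures it whole
with probability 0.953. A Monte-Carlo sampler (uniform center offset and
planar angle) provides an independent check of the closed forms. The printed
half-intact reference value agrees with the analytic evaluation to three
decimal places.

## Synthetic study conditions

The synthetic generators are the package's study material and their defaults
were fixed before the test suite existed:

- **Phantom rendering.** Membrane bands are 30 nm thick — the apparent width
  of a heavy-metal-stained membrane plus the band an AI classifier predicts
  at ~3.3 nm/px, not the ~5-nm bilayer. Contrast polarity is membrane (200)
  > matrix (140) > cytosol (90), with Gaussian noise (SD 10) and 2%
  salt-and-pepper shot corruption.
- **Simulated AI models.** Each variant displaces the true boundary by a
  smooth zero-mean Gaussian random field (pointwise SD 10 nm, correlation
  length 30 nm) — the systematic per-model boundary shift — and adds patchy
  probability speckle (SD 0.5, correlation length 10 nm) within two jitter
  lengths of the boundary, emulating model-specific spurious blobs and
  dropouts. Interiors stay at confidence 0.9. Zero jitter returns the scaled
  truth exactly.
- **Consistency benchmark.** Two shells (radii 70 and 50 nm, ~18 nm apart at
  closest approach) on the standard anisotropic grid; 6 variants; 24 probes;
  each condition is meshed at the center of its own dynamic range (0.5 × max
  for probability maps, 64 for AIVE). Under these conditions the orderings
  raw > blurred > AIVE hold for ΔV and probe RAD at every seed tested (0–7),
  and AIVE always has the smallest probe range. The full range ordering
  between raw and blurred does **not** hold under this generator: blurring a
  smoothly displaced boundary shifts the level set by roughly the local mean
  displacement and slightly magnifies per-probe spread, whereas on real
  predictions blur averages away per-voxel classifier noise the smooth-jitter
  component does not model. The benchmark therefore asserts the ΔV and RAD
  orderings plus AIVE-minimal range, and reports the raw/blurred ranges
  without asserting their order.
- **Intruded spheres.** Two 128-voxel spheres, externally tangent or with one
  intruding 100 nm into a matching invagination (seam gap 0). The intruded
  configuration concentrates the host's surface area in the 0–5 nm separation
  bracket (≈48% vs ≈2% when merely tangent), which is how separation
  histograms distinguish intrusion from contact.
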