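# Methods

## The problem

Transverse (cross-section) images of skeletal muscle stained for laminin
and myosin heavy chain (MyHC) isoforms are the standard readout for fiber
number, fiber cross-sectional area (CSA), fiber-type composition and
myonuclear content. `nsmuscle` implements a fully automated segmentation
of such images based on neutrosophic sets, together with a synthetic
phantom generator that provides exact ground truth, so that every stage
of the pipeline is testable without real microscopy data.

## Neutrosophic image model

Each pixel receives three memberships in [0, 1]: True (T), Indeterminacy
(I) and False (F = 1 − T). After per-channel min-max normalization of the
image C(i,j,k), the raw eligibility score τ is built per target
structure, using the channel triplet (k, max(3−k,1), θ(k+max(3−k,1)))
which is always a permutation of the RGB indices {1, 2, 3}
(k = 1 red / MyHC IIb, k = 2 green / IIa, k = 3 blue / I):

- **boundary mode** (laminin lattice, bright in all channels):
  τ = C₁ + C₂ + C₃;
- **color mode** (stained class k):
  τ_k = C_k + (1 − C_other1) + (1 − C_other2);
- **black mode** (unstained IIx fibers): τ = Σ (1 − C_k);
- **single-channel mode** (DAPI / Pax7 blobs): τ = C.

T is the min-max normalization of τ over the whole image. I is the
min-max normalized deviation |x − local w×w mean of x|, where x is τ in
boundary/black/single mode and the single channel C_k in color mode;
pixels near their local mean are confidently assigned. The fused
membership M = T × (1 − I) is an AND of "high truth" and "low
indeterminacy" and is the plane that gets binarized.

Degenerate min-max normalizations (constant plane) return all zeros with
a warning: a constant input carries no information.

## Segmentation pipelines

**All fibers (boundary workflow).** normalize → boundary T → binarize →
invert (cells into the True set) → 8-connected labeling → small-object
removal → hole filling → per-component measurement. Binarizing T puts
the laminin ridges in the foreground; inversion turns each
laminin-delimited cell into one component.

**Per-class (color workflow).** color or black τ → M = T(1−I) → strict
binarization → positivity gate → labeling → small-object removal → hole
filling → measurement. Hole filling is what recovers "weakly assigned"
interior pixels: a pixel well inside a stained fiber whose intensity sits
far from the class's color distribution has low M, but it is enclosed by
strongly assigned pixels and is reassigned by topology.

**Error correction.** Components smaller than 20% of the mean component
area (mean taken before any removal) are discarded; background regions
not 4-connected to the image border are filled with the label that
borders most of their rim. Foreground components are 8-connected,
background holes 4-connected, avoiding the connectivity paradox. Canny
edges dilated with a disk element are produced for overlays only — all
areas are measured on the filled label maps, so the dilation radius is
purely cosmetic.

## Thresholding policy

The exact "strict threshold" used by the reference workflow is
unpublished; the package's policy is:

- **boundary and nucleus planes** (`otsu_strict`): the exhaustive
  between-class-variance (Otsu) threshold × 1.2, capped at 0.95. These
  planes are essentially bimodal, and "strict" means above the automatic
  split.
- **color/black membership maps** (`multiotsu_upper`): the upper split of
  a 3-class Otsu, capped at 0.95. These maps are inherently tri-level —
  in-class fibers near 1, unstained fibers near the middle (by
  construction τ ≈ 2 for a pixel dark in all channels, hence T ≈ 0.5),
  other-stained fibers low. A 2-class split follows class *masses* and
  can land below the unstained plateau, which would absorb every IIx
  fiber into each color class; the upper 3-class split sits above it by
  construction.
- a fixed threshold can be forced through configuration.

**Stain-positivity gates.** Min-max normalization always stretches
whatever is present to T = 1, so a class absent from the image would
still segment its best-scoring pixels. Color masks therefore additionally
require τ_k > 2.15 on the raw [0, 3] scale (the pixel's own channel
exceeds the complement of the other two by a clear margin), and black
masks require τ > 2.65 (total brightness below 0.35). The black mask is
further intersected with the fiber interior found by the boundary
workflow, since IIx fibers are unstained but still laminin-bounded —
without this the black class would claim the space outside the section.

A data assumption inherited from the per-channel normalization: every
channel must contain near-background (dark) pixels. Real sections always
do; a synthetic image consisting solely of one stained class with no
background violates it and erases that channel's signal.

## Fiber typing

Each laminin-delimited fiber gets the stained class (I, IIa, IIb) whose
mask covers the largest fraction of its pixels. Maximum coverage below
0.5 means unstained → IIx ("not majority-stained" operationalizes
"unstained"). Exact coverage ties break on the higher mean membership M
inside the fiber, then on the fixed priority I > IIa > IIb, making the
rule total and deterministic. Per-fiber CSA always comes from the
boundary-workflow label map, which is insensitive to the few-pixel rim
that membership maps lose at fiber edges (the indeterminacy plane is high
where the local-mean window straddles an edge; at whole-section
microscope resolution this rim is negligible, at small phantom-disc
scale it is visible, which is why per-class area tests use a
perimeter-band bound).

## Myonuclei and satellite cells

DAPI and Pax7 channels run through the single-channel pipeline. The
nucleus window (default 5 px) must be smaller than a nucleus diameter:
with the fiber-scale window (15 px) an entire nucleus registers as a
local deviation, indeterminacy saturates, and M collapses.

A nucleus is a **myonucleus** of a fiber iff its centroid pixel lies
inside that fiber's mask AND strictly more than 50% of its area does
("more than 50%" is read strictly; exactly half is excluded). The host
fiber is the one maximizing overlap; exact ties go to the lower fiber id.
A **satellite cell** is a Pax7⁺ blob with ≥ 50% mutual overlap with a
DAPI nucleus whose centroid lies within `sublaminar_px` (default 2 px) of
the fiber boundary — the geometric reading of "sub-laminar Pax7⁺/DAPI⁺
cell"; the reference workflow never states its geometric criterion, so
this is a documented interpretation. Satellite status overrides the
myonucleus/excluded classification, keeping
myonuclei + satellites + excluded = all detections.

## Phantom generator

`polygonal_packed` emulates normal muscle: Poisson-disk seed points
(minimum spacing 0.62·√(HW/n)), Voronoi tessellation rasterized by
nearest-seed lookup, and a bright ridge of the configured width centred
on the cell interfaces. `round_regenerating` emulates regenerating
muscle: non-overlapping discs with lognormal areas (defaults
μ = 6.2, σ = 0.4 in log-px²), each wrapped in a laminin annulus, some
touching and some isolated on a dark background.

Fiber types are drawn from the configured proportions (default
0.10/0.30/0.20/0.40 for I/IIa/IIx/IIb); rendered intensities are 0.90 in
the stained channel and 0.05 elsewhere, IIx fibers 0.05 everywhere,
ridges 1.0 in all channels (8-bit-like scale in [0, 1]). Nuclei are
4-px-radius discs placed per fiber with Poisson counts; a configurable
fraction straddles the fiber boundary with randomized overlap fractions,
and satellite nuclei are planted on the ridge with a coincident Pax7
disc. Degradations — a multiplicative left-to-right illumination ramp
and additive Gaussian noise, clipped to [0, 1] — are applied *after*
ground truth capture, so recovery error measured against truth is purely
algorithmic.

What the phantoms do not emulate: optical blur of stained edges, chromatic
aberration and channel bleed-through, staining heterogeneity within a
fiber, debris and vessels, or tile-stitching seams. Passing the phantom
suite therefore demonstrates correctness of the algorithmic chain under
controlled geometry and noise, not clinical-grade accuracy on real
sections.

The clustered-IIb factory (`clustered_iib_spec`) builds the
sampling-bias demonstration: a 1536² round-geometry section whose three
oversized IIb fibers (radius 36 px vs ≈ 17 px typical) all sit in one
tile of a 12×12 grid, with otherwise near-uniform areas (lognormal
σ = 0.1). A 12-tile random sample misses that tile with probability
1 − 12/144 ≈ 0.92, and conditional on a miss the subset mean CSA sits
about 3 standard errors below the whole-section mean — so tile-based CSA
estimation systematically underestimates, reproducing the known argument
for whole-section analysis.

## Numerical and interface choices

- Local means use replicate-edge padding (no darkening at borders);
  windows must be odd and ≥ 3 and fit inside the image.
- Channel k is 1-based over (R, G, B) in the public API; storage order is
  arbitrary and resolved through the channel-role mapping, so results are
  invariant to channel shuffling with remapped roles.
- Coordinates are row/column, 0-based, pixel-center; areas are whole
  pixels; µm² areas require `um_per_px` > 0, otherwise px² is reported
  and flagged.
- Border-touching components are kept by default; `exclude_border`
  removes them immediately after labeling — before the 20% rule — so that
  an off-section background component cannot inflate the mean area and
  swallow real fibers in sparse regenerating sections.
- CSA histograms default to 250 µm² (or px²) bins.
- Run manifests capture inputs, the full effective configuration, package
  version, warnings and SHA-256 digests of all outputs, and contain no
  wall-clock timestamps, so identical runs produce byte-identical
  manifests. All file writes are write-then-rename.
- Every random process (phantom placement, tile sampling) flows from a
  single integer seed through `numpy.random.default_rng`.

## Problem sizes used in the test and acceptance suites

Oracle-equivalence checks run on ≤ 32×32 random inputs (200 trials per
primitive); recovery checks use 1024² phantoms with 100 fibers and 3-px
boundaries (clean, and degraded with noise σ = 0.05 plus a 20%
illumination gradient); the myonucleus oracle uses ≈ 200 nuclei with
randomized overlaps; the subset-bias check uses 100 seeded resamples of
12 tiles from a 12×12 grid. These sizes keep a full verification run in
the low minutes on one CPU while leaving each check statistically
meaningful.

## Known limitations

- No manual-correction interface, vessel or macrophage analysis, or
  wrapping of other CSA tools.
- Touching fibers are separated only by the laminin ridge; if the ridge
  is locally absent, adjacent fibers merge (no watershed fallback).
- The positivity gates assume the 3-channel staining semantics described
  above; unusual stain panels need re-configured gates.
- Membership-map segmentation loses a rim of a few pixels at fiber edges
  (edge-indeterminacy); negligible at whole-section resolution, visible
  on few-hundred-px² objects.
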