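# Methods

This note records the models, parameter choices, numerical conventions,
and known limitations of the `noduleant` detection chain.  It states no
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Image model and conventions

All rasters are 2-D `float64` arrays normalized to [0, 1] on load,
whatever the source bit depth, so every threshold in the package is
depth-independent.  Edge maps are boolean arrays with foreground =
`True`; exports render foreground as 255.  Coordinates are `(row, col)`,
0-based, row 0 at the top.  "Edge image" from a segmentation-style
detector means the inner boundary of the segmented foreground: a
foreground pixel with at least one 4-neighbour outside it.  For the
threshold detector the raster border replicates (a bright half-plane
yields only the step column, not a frame); for region growing the border
counts as outside (a region filling the raster yields its border ring),
because there the region, not the image, is the object.

## Baseline detectors

**Otsu.**  256-bin histogram; the threshold minimizes the within-class
variance (equivalently maximizes the between-class variance), computed
in closed form from cumulative sums; ties break toward the smaller bin;
a single-occupied-bin histogram has no split and returns that bin with a
warning.  The test suite checks the vectorized rule against an
exhaustive 256-split scan on 1,000 random histograms.

**Watershed.**  The gradient magnitude (central differences, border
replicated) is flooded from its regional minima (8-connectivity), after
`n_smooth` passes of a 3×3 mean filter that control oversegmentation;
pixels where two catchment basins meet — the dams — are the edge map.
Flooding is delegated to `skimage.segmentation.watershed` with
`watershed_line=True`; dam placement is cross-checked against an
independent 1-D flooding oracle on a ridge profile.  On a noisy raster
the dam network is a single connected web, so watershed output is
structurally hostile to the component-based candidate stage — it scores
poorly there by nature, not by accident.

**Region growing.**  4-connected growth from a seed pixel with a running
region mean: a frontier pixel joins when `|value − mean| ≤ tolerance`
(default 0.1 of the normalized range) and the mean updates after every
admission.  The frontier is a FIFO queue with neighbours enqueued in
N, S, W, E order and each pixel examined once, making the result fully
deterministic.  The pipeline seeds at (0, 0): the background is grown
and nodules appear as interior holes whose boundaries become candidate
components.

## The ant-colony engine

State: a pheromone field τ (initialized at τ₀ = 0.1) over the pixel
lattice and a static heuristic η.

**Heuristic: brightness prominence.**  `η(p) ∝ max_n (I(p) − I(n))` over
the 8 neighbours (border replicated), clamped below at 0 and normalized
to max 1.  The measure is deliberately one-sided.  Nodules, vessels and
lung borders are *bright* structures on dark parenchyma, and a signed
prominence places all desirability on the bright flank of a step.  This
matters most for the self-feeding variants, whose input is a binary edge
map: any symmetric variation kernel is zero *on* a one-pixel edge
(opposite neighbours agree there) and maximal on the flanking pixels on
both sides, so a colony guided by it reconstructs a three-pixel dilated
halo of its input rather than the input's structure; the dilated
components then overrun the 5-pixel candidate ceiling.  With brightness
prominence the support of η on a binary input is exactly the foreground,
and the colony's output is a subset of the structure it was given.  The
cost of one-sidedness: a dark-nodule regime would need the sign flipped,
and η is not invariant under intensity inversion.

**Dynamics.**  Each round, every ant starts at a uniformly random pixel
and takes `steps_per_ant` moves; a move to an admissible (in-bounds, not
in this ant's tabu list) neighbour j is drawn with probability
∝ τ(j)^α·η(j)^β, uniform over admissible neighbours when all weights are
zero; an ant with no admissible neighbour respawns at a fresh random
pixel.  After the round, τ ← (1−ρ)τ and each pixel gains ρ·η per ant
that visited it.  Pheromone is therefore bounded by
[τ₀(1−ρ)^T, τ₀ + T·n_ants·ρ] after T rounds, which the tests assert.

**Binarization at the initial charge.**  A pixel is an edge when its
final pheromone exceeds τ₀: evaporation alone pulls every pixel below
its initial level, so ending above it means cumulative reinforcement
outweighed decay.  The rule introduces no new constant and is robust to
the field's extreme class imbalance: ≳98% of pixels sit at the exact
evaporated floor, and a histogram split (Otsu) of such a field is
dominated by the *spread of the deposited minority* — measured on the
phantom suite, the Otsu cut lands between heavily travelled line
structures and lightly travelled nodule rings and silently deletes every
ring.  The τ₀ rule keeps any structure the colony genuinely reinforced.

**Defaults.**  `n_ants = √(H·W)` (256 for a 256×256 slice), 10 rounds of
40 steps, α = 1, β = 2, ρ = 0.1, τ₀ = 0.1 — standard colony constants;
all exposed in `AcoParams` and on the CLI.  Determinism: one seeded
NumPy generator; per round one batch of starts, then per step one batch
of move uniforms followed by respawn draws, so equal seeds give bitwise
equal fields.

## The ACO variants

*Refined*: round r+1 runs the full detector on round r's edge map cast
to a raster (True → 1.0), each round with seed `base + round − 1` and a
fresh pheromone field; iteration stops when the Hamming fraction between
consecutive rounds falls to `tol` (default 0.01) or `max_rounds`
(default 4) is reached.  *Logical*: pixelwise XOR of the final and
pre-final refined rounds — the pixels still changing; a single-round run
has no pre-final map and errors rather than XOR-ing with an implicit
blank.  *Variant*: exactly `aco_edges(cast(otsu_edges(img)))`.  The
variant composition is the package's default pipeline front end: the
Otsu stage removes smooth intensity texture before the colony runs, so
false positives are suppressed at the first stage.

## Candidate detection (black circular neighbourhood)

Foreground is partitioned into connected components (default
8-connectivity; 4 available), ordered by bounding-box (min_row,
min_col).  A component is discarded as a *line* (lung border, vessel)
when its bounding-box fill ratio `area/(major·minor)` is below 0.3 or
its aspect `major/minor` exceeds 3.  The fill floor is 0.3 rather than a
nominal 0.5 because the closed one-pixel boundary ring of a legitimate
nodule at the 5-pixel size ceiling fills only ≈0.40–0.48 of its box,
while open one-pixel paths (an L-shaped segment fills ≈0.19) and
elongated curves still fail; a 0.5 floor measurably rejects the largest
admissible nodules.  Survivors become candidates unless their equivalent
diameter `2√(area/π)` exceeds `d_max` (default 5; the "unit" is a pixel
and must be rescaled for other image resolutions).  Centre = pixel
centroid rounded with ties toward the smaller index; shape = spherical
when bbox aspect ≤ 1.5, else elliptical.

## Intensity filtering and features

Each candidate is probed on the *original* raster: the mean intensity
over the disk of radius `equiv_diameter/2` (pixels whose centres lie
within the Euclidean radius, clipped to the raster) must strictly exceed
`intensity_threshold` (default 0.5 of the normalized range; global, not
per-image adaptive — exposed for sensitivity studies, as is a
fixed-radius probe mode).  Survivors yield one feature row: mean
intensity, size (component area in pixels), shape class, and optionally
the patient's age; shape is encoded spherical = 0 / elliptical = 1 when
the rows enter a distance computation.

## Clustering

Feature columns are standardized to zero mean and unit spread before any
distance (areas and [0, 1] intensities are incommensurate; constant
columns are left at 0), and results map back to raw units.

**GA-refined k-means** (primary; also exposed as the scikit-learn
estimator `GAKMeans`).  Lloyd's algorithm from k distinct random data
points (≤100 iterations, empty clusters re-seeded with the farthest
point) provides the initial centres.  A chromosome concatenates the k
centres (k·d genes); fitness is `1/(1+SSE)`.  The population (default
20) starts from the k-means chromosome plus Gaussian perturbations
(scale 0.1 of each column's spread); each generation (default 100)
applies size-2 tournament selection, single-point crossover at any gene
boundary (p = 0.8), per-gene Gaussian mutation (p = 0.05, same 0.1-spread
scale), and elitism (1).  The elite survives unchanged, so the best
fitness is monotone and the result is never worse than the k-means
initializer — both asserted in the tests, along with centre recovery on
well-separated synthetic clouds.  `generations=0` returns the
initializer untouched.

**Single linkage** (comparison).  Hand-rolled agglomerative merging of
the pair of groups with the smallest nearest-neighbour Euclidean
distance until k remain, ties broken toward the lexicographically
smallest (min member index, other min member index) pair for
determinism; cross-checked against `scipy.cluster.hierarchy` on random
point sets.

**Labelling.**  With k = 2, the cluster with the larger mean raw size is
malignant (malignant nodules run larger than benign), ties broken by
mean intensity; other k return cluster indices with a warning.

## Evaluation

Object mode matches candidates to true nodules greedily by ascending
centre distance, one-to-one, within `max_dist` (default: each truth's
own radius, so the tolerance scales with nodule size); unmatched
candidates are FP, unmatched truths FN, and there is no TN — specificity
is undefined and accuracy falls back to `tp/(tp+fp+fn)`.  Pixel mode
compares binary masks per pixel and supplies the TN that specificity and
conventional accuracy need.  The recall ratio is `detected/actual` and
may exceed 1 under over-detection.  Any zero denominator leaves a metric
`None`; nothing is silently divided.

## Phantom generator

Each phantom is a dark background (0.2) with `n_nodules` bright nodules
(contrast 0.5; diameters uniform in 3–5 px so candidates fall under the
5-px ceiling; malignant nodules draw from the upper half of the range
and get 10% extra contrast), `n_lines` one-pixel bright polylines at
nodule intensity as false-positive decoys, and additive Gaussian noise
(σ = 0.02), clipped to [0, 1].  Nodules are placed by rejection sampling
with ≥3 px clearance between boundaries and from the border; lines are
re-sampled until they clear every nodule, so nodule components stay
isolated in the ideal edge image (a line that cannot comply after 1,000
draws is dropped — lines are decoys, not ground truth).

Rendering: a plateau profile with a roughly half-pixel soft rim
(coverage 0.5 exactly on the boundary).  An exact-area-coverage
rendering was evaluated and rejected: a 3-px object is mostly boundary
pixels, and its mask-mean intensity falls measurably short of the
generator's contract that every nodule's interior mean exceeds the
background by at least 0.8·contrast at σ ≤ 0.02.  Elliptical nodules use
an axis ratio of 1.8 — clearly above the 1.5 bbox-aspect threshold that
separates the shape classes, mildly oval as real nodules are — and the
recorded `diameter` is the *area-equivalent* diameter for both shape
classes, keeping ground-truth size commensurate with the detector's
equivalent-diameter measure.

What the phantoms do **not** emulate: parenchymal texture, rib and
vessel shadows, Hounsfield-unit physics, nodules attached to the pleural
wall or vasculature, irregular (non-ellipsoidal) nodule shapes, and 3-D
context.  Passing the suite therefore demonstrates the mechanics of the
chain — edge recovery, line rejection, size/shape/intensity filtering,
cluster separation — under controlled conditions; it does not predict
clinical sensitivity on patient data, where nodule/background contrast
is far less benign.

## Problem sizes and determinism

The standard benchmark is 10 phantoms of 256×256 with 6 nodules and 3
lines each (60 nodules), seeds `base_seed + i`; the tests and
`scripts/acceptance.py` both use it, the latter re-deriving every stream
from `--seed`.  With the default colony (256 ants × 10 rounds × 40
steps) one detector run takes well under a second on one CPU, and the
full seven-method comparison completes in tens of seconds.  Identical
seeds reproduce phantoms, pheromone fields, and every pipeline artifact
byte-for-byte; each persisted run's `manifest.json` carries the resolved
configuration and package version for replay.

## Known limitations

- The candidate stage measures the detected *edge component*, so its
  equivalent diameter understates large nodules (a ring's area grows
  with the perimeter, not the disk area); benign/malignant size contrast
  survives but is compressed, which is the main error source of the
  clustering stage.
- Single-linkage chaining makes the hierarchical comparison fragile on
  standardized features; the GA clusterer is consistently the stronger
  of the two on the suite, and that comparison is what the acceptance
  script quantifies.
- The brightness-prominence heuristic assumes bright-on-dark polarity
  throughout; inverted-contrast inputs must be inverted before use.
- Watershed dams form one connected network and thus defeat a
  component-based candidate stage; its rows in the comparison table
  document this structural mismatch rather than a tuning failure.
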