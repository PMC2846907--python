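# Methods

This note documents the model, the numerical choices, and the points where
the design was genuinely open, in the order the pipeline runs.

## Input and preprocessing

Items are rows of a numeric matrix; loaders accept plain TSV, the
Cluster-software PCL dialect (NAME/GWEIGHT columns and the EWEIGHT row are
annotation, not data) and GEO series-matrix text (only the block between
the `!series_matrix_table_begin/end` markers is parsed). Missing values
are imputed with the row mean; rows that are entirely missing are dropped
with a warning. Duplicate row ids are made unique by suffixing, or
averaged when probe collapsing is requested.

Normalization steps run in a fixed order — log2, unit-variance columns,
median-centering of rows and/or columns, iterative sum-of-squares
balancing, 0–100 column range scaling — mirroring common microarray
practice. Two conventions are deliberate and configurable:

* **Standard deviation** is the population form (divide by *n*).
* **Sum-of-squares balancing** alternates row and column rescaling (tol
  1e-6, ≤ 50 sweeps). For a square matrix every row and column reaches
  unit sum of squares; a rectangular *n* × *d* matrix cannot satisfy both
  (the totals *n* and *d* disagree), and the iteration converges to the
  balanced fixed point with unit columns and all row sums equal to *d*/*n*
  — which is what repeatedly "normalizing genes then arrays" produces.

For sample-mode (transcriptome) clustering the matrix is converted to a
square distance matrix (Euclidean, Pearson 1−r, or uncentered 1−r in the
Eisen-Cluster convention of r without mean subtraction) and each sample is
represented by its row of distances. The map trainer needs
fixed-dimension vectors; distance profiles preserve the conversion while
providing them. Zero-variance rows under Pearson get r = 0 (distance 1),
logged.

## Self-organizing map

A 2-D lattice (square, or circular = the square lattice restricted to the
inscribed disc) of nodes with weight vectors in data space. Training is
the standard online Kohonen rule over two phases of *I* = 1000 random item
presentations: winner = nearest node, update
w ← w + η·h·(t − w) with Gaussian lattice neighbourhood
h = exp(−d²/2r²). Phase learning rates are 0.9 and 0.1; the radius starts
at half and a quarter of the grid width. Within each phase η decays
exponentially by a factor of 10 and r decays exponentially to 1 lattice
unit. Weights are initialized on randomly drawn data items — the
untrained lattice is a random scatter of data points — which keeps nodes
on the data manifold from the start; uniform-in-range initialization
measurably degrades map organization on curved cluster shapes.

**Grid sizing.** The default is liberal allocation, about one node per
item: side = clamp(ceil(sqrt(|T|)), 5, 20). Liberal allocation is what
makes boundary detection work for thin or curved clusters: with roughly as
many nodes as items, the few nodes that interpolate across empty regions
carry large weight jumps and therefore high error values. With sparse
allocation (the also-available `auto_grid_size`, ≈ 5·sqrt(|T|) nodes)
inter-cluster gaps are spanned by long chains of interpolating nodes whose
individual steps are small, the error surface loses contrast, and
elongated clusters fragment. Both policies and the clamp bounds are
configurable; the 20 × 20 maximum and 5 × 5 minimum are the intended
defaults for whole-genome matrices.

**Error surface.** Dn_j is the mean Euclidean distance between node j's
weights and its directly adjacent nodes' weights (8-neighbourhood by
default; 4 available). Whether the aggregation is a mean, sum or max was
an open point; the mean is used. The softening exponent is likewise an
inference from its stated behaviour: raw_j = Dn_j^(1/θ) with θ = 1.5 > 1
compresses large neighbour distances and damps outlier nodes. raw is
divided by its maximum and raised to α = 3; the cubic step stretches the
contrast between cluster interiors and boundaries before equalization.

## Density-equalizing cartogram

Each node is a unit square whose top-left corner is its grid position,
carrying En_j as population density; the lattice is scaled by the largest
integer factor fitting a power-of-two grid (default 64 × 64, so a 10 × 10
lattice gets 6 × 6-cell squares). Cells outside all squares (the margins,
and the masked corners of a circular map) take the mean node density —
the standard neutral "sea" — and a floor of 1e-8 · max keeps the field
positive where En = 0.

The transform integrates the diffusion-cartogram flow: the density obeys
the heat equation, and tracer points move with **v** = −∇ρ/ρ until the
field is uniform, so each region's final area is proportional to its
density. Numerics, none of which were prescribed:

* The field is a type-II discrete-cosine series (reflective, zero-flux
  boundaries — the boundary is invariant); mode (j,k) decays as
  exp(−(k_j²+k_k²)t).
* ρ and ∇ρ are evaluated **from the series, exactly at the tracer
  positions**. Grid-sampled finite differences with bilinear interpolation
  were tried first and silently lost 4–25 % of the transported mass: at
  early times the field varies on sub-cell scales where central
  differences under-resolve the gradient, and one-sided boundary stencils
  bias the flow near the domain edge. The series evaluation costs three
  small matrix products per step (modes decayed below 1e-16 are dropped,
  so late steps are cheap) and conserves area to < 0.1 % even on a binary
  ridge fixture.
* Time stepping is adaptive midpoint (predictor–corrector): a step is
  accepted when the Euler and midpoint positions agree within 0.01 cells,
  halving on rejection and growing 1.5× after comfortable steps.
  Integration starts at t = 0.05 (damping the ringing-prone highest
  modes), the pointwise density is clamped below at 1e-3 of the mean when
  dividing (Gibbs overshoot near sharp raster edges can cross zero), and
  stops when the per-step displacement falls below 1e-4 cells after the
  slowest mode has decayed by 1e3 (hard stop at 1e8).
* A uniform field short-circuits to the exact identity: every
  non-constant mode is zero, so v ≡ 0.
* Adjacent squares share corner points; each distinct corner is advected
  once. A node's final coordinate is the centroid of its four displaced
  corners.

## MST cut

An exact Euclidean MST over the equalized node coordinates (Kruskal on
the complete graph; ties broken lexicographically by node index, so the
tree is deterministic; coincident nodes give zero-length edges).
Significance is Monte-Carlo: β = 10 replicates of m uniform points in the
axis-aligned bounding box of the observed coordinates, their MST edge
lengths pooled, and p(e) = fraction of pooled null lengths ≥ length(e).
A small p therefore means an edge *longer* than the null — a real spatial
gap — and every edge with p ≤ 0.1 is removed in a single pass (p-values
are not recomputed between removals; removal order cannot change the
surviving forest). Items inherit the component of their best-matching
node, node components without items are ignored, and single-item clusters
are flagged as outliers. A degenerate (zero-area) bounding box yields
p = 1 everywhere with a warning.

## Ensemble averaging

The pipeline runs E times (per-run seeds seed + 1000·i, so results are
deterministic given the master seed while every run starts from its own
random lattice). How the E partitions become one result is the method's
central interpretation point, and two schemes are provided.

**Affinity consensus (default).** The pairwise affinity matrix —
fraction of runs in which each pair co-clusters — is thresholded at 1/2
and consensus clusters are the connected components of the resulting
majority-co-clustering graph. Rationale: a single map run necessarily
fragments clusters that cannot be embedded flat in the lattice (a closed
ring folds into several patches), but the fragment boundaries move from
run to run while items of *different* true clusters stay separated in
essentially every run. Majority links therefore chain each true cluster
together through its overlapping fragments, while cross-cluster links
never reach the threshold. At E = 1 the components are exactly the single
run's clusters, preserving the one-run contract. The fuzzy matrix **F**
then counts, for each item and consensus cluster, the runs whose
containing fragment is associated (by plurality membership) with that
cluster; rows sum to E. Resolution takes the most frequent cluster (ties
to the lower column id), confidence = 100·F[x, label]/E, and empty
columns are dropped with labels compacted. Items whose confidence falls
below a user threshold can be marked unassigned; they keep their rows in
the affinity matrix.

**Matching consensus (option).** Every run is first adjusted to the mean
cluster count μ (half-up rounded): runs with too many clusters repeatedly
merge the two clusters with nearest centroids in input-feature space;
runs with too few split their largest cluster by 2-means. Columns are
then aligned to the first run's clusters by greedy maximum overlap and F
accumulated directly. This is the simplest reading of the averaging
scheme and behaves identically on compact well-separated clusters, but it
cannot fuse fragments of non-convex clusters — voting preserves the
reference run's fragment structure — which is why it is not the default.

The dense |T|² affinity matrix is the memory bound of the implementation
(≈ 1.4 GB at 13 000 items); for larger inputs run with the matching
consensus or subsample.

## Evaluation metrics

Clustering F-measure: for truth class i and cluster j,
F(i,j) = 2PR/(P+R) with P = |i∩j|/|j|, R = |i∩j|/|i|; the score is the
class-size-weighted sum of each class's best F. NMI is mutual information
normalized by the geometric mean of the two entropies (arithmetic mean
optional), defined as 1 when both partitions are trivial and 0 when
exactly one is. Items labelled −1 (confidence-filtered outliers) are
excluded from both. Note that the F-measure of a perfect solution is 1,
but a single truth class scores 1 only against a single cluster — the
score penalizes splitting even when only one class exists.

## Synthetic benchmarks

Three generators, all deterministic per seed, with geometries chosen so
nearest between-class gaps exceed within-class point spacing at least
threefold (clusterable by construction; all parameters configurable):

* **Gaussians** — k isotropic 2-D blobs (default 4 × 100 points, sd 0.5)
  on a grid of centers 10 apart; warns if blobs overlap at 3 sd.
* **Rings** — two orthogonal interlocked circles in 3-D (radius 1, the
  second centered one radius along x in the xz-plane, so the curves are
  everywhere about one radius apart), 500 points per ring — the scale of
  the classic chain-link benchmark — with isotropic tube noise sd 0.03.
* **Bars** — 6 vertical lines of 100 points (x spacing 2, length 10) plus
  2 horizontal lines of 152 points above and below: 904 points, 8 classes,
  elongated clusters of unequal size.

These fixtures emulate cluster geometry and noise, not the properties of
real expression data: no heavy-tailed measurement noise, no correlated
features, no batch structure, and far lower dimensionality. Passing them
demonstrates the geometric claims of the method (shape-free recovery,
outlier flagging, ensemble stabilization), not performance on any
particular biological dataset.

## Defaults at a glance

| parameter | default | meaning |
| --- | --- | --- |
| I | 1000 | presentations per training phase |
| θ | 1.5 | error-surface softening exponent (1/θ) |
| α | 3 | cubic rescale of the error surface |
| resolution | 64 | cartogram grid (power of two) |
| β | 10 | Monte-Carlo null replicates per run |
| p-threshold | 0.1 | MST edge removal cutoff |
| grid | ceil(sqrt(N)) in [5, 20] | lattice side (liberal allocation) |
| E | 50 (library), 100/500 presets | ensemble size (gene / sample mode) |
| min affinity | 0.5 | majority-co-clustering link threshold |

The benchmark scales used by the test suite and `scripts/acceptance.py` —
400-point Gaussians with E = 10, 1000-point rings with E ≤ 25, ten seeds
per aggregate — are the package's chosen desk-scale study conditions;
each full ensemble takes seconds to tens of seconds on one CPU.

## Known limitations

* The p-value null (uniform points in a box) makes any near-regular point
  set look uniformly "long-edged"; the method relies on the cartogram
  creating strong contrast first. Without equalization the cut fragments
  even clean data — the equalization-benefit check quantifies this.
* Cluster-level merging of the affinity consensus depends on per-run
  cluster purity; if more than half the runs mix two groups, the groups
  merge. Confidence and affinity outputs expose such fuzziness rather
  than hide it.
* Dense affinity storage is quadratic in items (above).
* Hexagonal lattices, batch training and bi-clustering are out of scope.
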