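# Methods

## Model and assumptions

`bandclust` performs hierarchical agglomerative clustering of `p`
linearly ordered objects under an adjacency constraint: only clusters
that are neighbors in the ordering may merge.  Every cluster is
therefore a contiguous interval `[i, j)`, the hierarchy is a sequence
of `p − 1` recorded merges, and cutting it at any level yields a
segmentation of `1..p`.

The linkage is Ward's: the increase in error sum of squares (decrease
in variance) caused by a merge.  For data given only through a
similarity matrix `S`, the kernel-trick identity

    δ(C, C') = S(C)/|C| + S(C')/|C'| − S(C ∪ C')/|C ∪ C'|,
    S(C) = Σ_{(i,j) ∈ C²} s_ij,

defines the linkage without any embedding.  When `S` is an
inner-product (positive semidefinite) similarity of points `x_i`, δ
equals the classical Euclidean Ward criterion
`|C||C'|/(|C|+|C'|) · ||mean(C) − mean(C')||²`; the test suite asserts
this equality to 1e−8 on random embeddings.  (Note the classical,
*unnormalized* ESS is the quantity consistent with the identity above;
a per-cluster `1/|C|` normalization is not.)

For general, possibly indefinite similarities the same formula is used
unchanged: adding `λ` to the diagonal makes `S` positive definite for
large enough `λ` while producing the identical merge sequence with all
linkage values shifted by exactly `+λ` (Miyamoto's theorem), so the
hierarchy is well defined without any internal shift.  Heights may
then be negative or non-monotone ("reversals"); the dendrogram stores
the raw values, exposes a `monotone` flag, and a warning is logged.
Newick export clamps the resulting negative branch lengths at 0 (with
a warning); the analysis path always uses raw heights.

### Band assumption

The quasi-linear complexity rests on `s_ij = 0` for `|i − j| ≥ h`.
`h = p` is always legal (no approximation).  For `h < p` the result is
exact whenever the data's true bandwidth is ≤ h, and in practice
stabilizes at moderate `h`; `select_bandwidth` automates the choice by
increasing `h` until the dendrogram stops changing (first-difference
index against the next bandwidth in the schedule reaches a threshold,
1.0 by default).

## Algorithmics

**Pencil sums.**  `S(C)` for `C = [i, j)`, `k = j − i`, `l = min(h, k)`
is assembled from forward pencils `P(r, l)` (sum of all entries within
`l` diagonals of the leading `r × r` block) and their backward
counterparts as `P(j, l) + P̄(i, l) − P(p, l)`, under the convention
that the forward pencil at boundary `b` covers indices < `b` (0-based
half-open) — the convention is fixed by verification against
brute-force double summation rather than by symbol pushing, since a
naive closed-interval reading double-counts the boundary row.  Both
tables are filled by two cumulative sums over a skewed copy of the
band (`O(ph)` work, `2ph` stored values, plus one all-zero padding row
per table for branch-free queries).  Every linkage then costs three
interval sums, i.e. `O(1)`.

**Fusion heap.**  Candidate fusions (adjacent cluster pairs) are kept
in a binary min-heap keyed by `(linkage, left boundary, id)`; all
mutable state — intervals, the doubly linked list of candidates in
chromosome order, validity flags — lives in a side store addressed by
id.  A merge pops the minimum active fusion, invalidates its ≤ 2
neighbors in `O(1)` (lazy deletion: stale roots are discarded when
they reach the top; ≤ `2p` discards over a run), and inserts the ≤ 2
new candidate fusions with linkages from the pencil tables.  At the
chromosome ends only one neighbor exists and only one new fusion is
inserted.  Total: `O(p(h + log p))` time, `O(ph)` memory.

**Tie-breaking.**  Among equal linkages the fusion with the smaller
left boundary wins (then smaller id, which cannot tie among active
fusions).  The quadratic reference `naive_cluster`, which recomputes
every candidate linkage from scratch on the dense matrix, applies the
same rule, so engine and reference agree exactly — including on fully
degenerate inputs such as the identity similarity at `h = 1`, where
*every* adjacent linkage equals 1 at every step and the rule yields a
left-to-right cascade.

## Model selection

Let `d_k` be the height of the k-th merge counted from the root (the
dispersion decrease of the split producing `k + 1` clusters) and
`T = Σ d_k`.

* **Broken stick**: the expected size of the k-th largest of `p − 1`
  uniformly random pieces of a stick of length `T` is
  `b_k = T/(p−1) · Σ_{i=k}^{p−1} 1/i` (so `Σ b_k = T`).  Starting at
  the root, stop at the first `k` with `d_k ≤ b_k` (inclusive) and
  return `K = k`; if no split stops, `K = p`.  The rule is ad hoc but
  standard; it presumes nonnegative dispersion decreases, so a warning
  is logged when heights are negative or non-monotone and the raw
  values are used.  On structureless PSD similarities it selects
  `K = 1` in the large majority of runs; on data with genuine gradient
  structure (e.g. pure distance decay in contact maps) it legitimately
  reports more, smaller segments.
* **Slope heuristic**: contrast `C(K) = T − Σ_{k<K} d_k` (the
  pseudo-inertia of the K-cluster partition) against penalty shape
  `pen(K) = log C(p−1, K−1)`, evaluated with log-gamma because the raw
  binomial overflows at genomic `p` (the logarithm preserves the
  shape's ordering and curvature for a slope fit).  The slope is
  estimated by Theil–Sen over `K ∈ [⌈K_max/2⌉, K_max]` — a robust fit,
  as is standard slope-heuristic practice — giving `κ̂ = max(−slope,
  0)`; the selected `K` minimizes `C(K) + 2κ̂·pen(K)`.  The default
  `K_max = min(p − 1, 100, max(10, (p−1)//2))` keeps the search on the
  increasing branch of the (symmetric) log-binomial shape, where the
  penalized criterion is meaningful.  A degenerate fit window (no
  variation in `pen`) raises.

## Genomics adapters

* **LD**: `s_ij = r²`, the squared Pearson correlation of unphased
  allele-dosage vectors (composite LD) over pairwise-complete
  individuals — computable without phasing and deterministic.
  Diagonal exactly 1; monomorphic or all-missing pairs get 0 with a
  logged count.  The full r² matrix is a kernel; its band truncation
  need not be, which the engine handles (see above).
* **Hi-C**: `s_ij = log(1 + count_ij)` on raw counts — `log1p` keeps
  absent pairs at exactly 0, consistent with the band assumption,
  while taming the count skew.  No matrix balancing (ICE etc.) is
  applied.
* **BED export**: cluster `k` spans from the start coordinate of its
  first object to the start of cluster `k + 1`'s first object (the
  last cluster ends at the supplied chromosome end), so records tile
  the interval with no gaps or overlaps; output is 0-based half-open,
  while internal object indices stay 0-based and file-level matrix
  triplets are 1-based (MatrixMarket convention).

## Synthetic data

Generators plant `K` contiguous blocks and return ground-truth labels;
all randomness flows through `numpy.random.default_rng(seed)` and
output is bit-identical per (parameters, seed).

* **Block similarity**: `within + ε` on same-block pairs, `between +
  ε` across, `ε ~ N(0, sd²)`, truncated to the band.  Defaults
  `within = 0.75`, `between = 0.25`, `sd = 0.1` (moderate contrast);
  the `strong_contrast()` preset (`1.0 / 0.0 / 0.05`) is the regime
  used for recovery checks.
* **Genotypes**: two independent haplotypes per individual from a
  first-order copying chain — within a block the allele is copied from
  the previous SNP with probability `ρ` (default 0.9), else redrawn at
  its frequency (MAF ~ U(0.1, 0.5)); the chain resets at block
  boundaries.  Expected r² decays like `ρ^{2d}` inside blocks and ≈ 0
  across them.
* **Contact maps**: Poisson counts with mean `base·(1+|i−j|)^{−α}`
  (`base = 100`, `α = 1`), multiplied by `tad_boost = 3` within a
  planted TAD; only in-band, nonzero counts are emitted.  Poisson
  rather than negative binomial: overdispersion is not needed to
  exercise the clustering.

What these generators deliberately do not emulate: recombination
hotspots and realistic MAF spectra (no coalescent simulation), Hi-C
sequencing-depth artefacts and balancing biases, and real cluster-size
distributions.  Passing recovery tests therefore demonstrates the
correctness and calibration of the algorithm on data satisfying its
assumptions, not performance guarantees on any particular real
dataset.

## Numerical and design choices

* Dense-input symmetry is enforced to 1e−8 absolute (then the matrix
  is symmetrized); non-finite entries are rejected.
* `from_dissimilarity` maps `s_ij = (c − d_ij²)/2`, `c = max d_ij²`;
  additive constants and row/column terms cancel in δ, so the
  hierarchy does not depend on `c`, and for Euclidean `d` it equals
  classical Ward exactly.  Restricted to `h = p`: truncating a
  `c`-shifted similarity to 0 outside a band would silently corrupt
  the hierarchy.
* Sparse triplet input: unspecified in-band entries are 0; a missing
  diagonal defaults to 0 with a warning (Hi-C maps often omit
  self-contacts); out-of-band entries are dropped with a logged count.
* Merge tables use the common convention of negated 1-based leaf
  indices and positive step numbers, and convert losslessly to the
  scipy linkage-matrix layout.
* Problem sizes in the validation suite: 100 random instances with
  `p ≤ 60` for engine-vs-reference equality (the quadratic reference
  is the bottleneck), 50 seeds at `p = 500` for model-selection
  recovery, and `p = 2000/4000/8000` at `h = 100` for the runtime
  scaling contract (measured as min-of-7 interleaved repetitions with
  GC paused; the asserted bound, ≤ 2.6 per doubling, is the
  linearithmic contract with headroom for timer noise).

## Known limitations

* Only Ward's linkage; no unconstrained HAC.
* The slope heuristic needs a reasonable `K_max` (≥ 10) to fit a
  slope; on very small `p` it is unstable.
* Broken stick on gradient-structured data (distance decay without
  blocks) reports many segments — a property of the rule, not a bug.
* The engine is pure Python/numpy; constants are small (ca. 0.1 s for
  `p = 8000`, `h = 100` on one core) but a compiled kernel would be
  needed for `p ≫ 10^5` at large `h`.
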