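# Methods

## Problem setting

An agglomerative clustering of n objects is a rooted binary merge tree.
Its clustering content is the set of n−1 clades (the leaf set under each
internal node); its display is one of the 2^(n−1) left-to-right leaf
orders obtained by choosing a child order at every internal node.  All
operations in this package act on the display only: the clade set is
computed before and after every reordering in the test suite and must be
identical.

## Clustering

`cluster_average_linkage` implements UPGMA (Lance–Williams average update)
over a validated symmetric distance matrix.  It is written in-package
rather than delegated to `scipy.cluster.hierarchy` because the reordering
experiments need a fully specified *display* baseline, which requires
pinning down two conventions scipy does not expose:

* **tie-break**: among equal-height candidate merges, the pair whose
  smallest original input index is least (then the smaller partner index);
* **child order**: the cluster containing the lower original index becomes
  the left child.

On tie-free inputs the tree (clades and heights) agrees with scipy's
average linkage; the suite checks this.  Heights are absolute merge
heights; Newick branch lengths are parent minus child height with leaves
at height 0.  Supported sample–sample metrics: Euclidean and the Pearson
correlation distance 1 − r (the conventional metric for expression
profiles); any other metric can be supplied as a precomputed matrix.

## The reordering

For a node with left leaves L (displayed x₁…x_m) and right leaves R
(y₁…y_n), the bilateral symmetric distance B = Σ_{i=1..k} d(x_{m−i+1}, y_i)
with k = min(m, n) sums the distances of the k symmetric pairs counted
inward-out from the shared boundary.  `symOrder`:

1. **Greedy pairing.** Select, k times, the globally minimum-distance pair
   (x, y) among still-unpaired x ∈ L, y ∈ R.  Selection order is
   innermost→outermost, so pair distances are nondecreasing outward by
   construction (asserted on every `PairingResult`).  Equal-distance
   candidates resolve to the lexicographically smallest (x, y) id pair.
   Greedy selection is linear-lookup by design; a globally optimal
   minimum-weight matching is deliberately out of scope.
2. **Unpaired members.** Only the larger side has them.  Each is scored by
   its mean distance to the paired members of its *own* cluster, sorted
   ascending, and placed outward from the paired block (smallest score
   adjacent to it).  An alternative mode (`unpaired_mode="adjacent"`)
   scores against the entire adjacent cluster instead; both are defensible
   readings of "compare the unpaired members", and own-cluster is the
   default because it matches the algorithmic description of ordering "by
   the average distances with the already ordered objects in the same
   cluster".
3. **Flipping.** The concatenation (unpaired-left, L-block reversed,
   R-block, unpaired-right) is the SYM vector; leaf → position 1..|T|.
   Every internal node under the target is flipped iff the mean SYM
   position of its right subtree's leaves is strictly smaller than its
   left subtree's.  Equal means mean no flip.  Decisions are independent
   across nodes (flips never change membership), so traversal order is
   irrelevant.

`hc_sym` applies `symOrder` top-down (pre-order) to every internal node at
depth < `level` (root = depth 0) that passes:

* **balance** min(|L|, |R|) / max(|L|, |R|) ≥ `br` (default 0.3), and
* **size** min(|L|, |R|) / n_total ≥ `sr` (default 0.03), where n_total is
  the leaf count of the whole tree being reordered.

Both filters apply at every depth, including the root: a 1-vs-rest root
split is not a meaningful two-cluster boundary, and reordering it would
only chase outliers.  The target set is computed once up front — node
membership is flip-invariant, only left/right roles can swap under a
parent's flip, which the sequential top-down application picks up
naturally.  The defaults level=1, br=0.3, sr=0.03 are the method's
standard operating point.

## Evaluation

**Seriation rate (supervised).**  With leaves numbered 1..n in display
order and ld the absolute position difference, a class c scores
S(c) = Σ 1/ld over unordered within-class pairs; SR = Σ_c S(c) / Σ_c
S_max(|c|) where S_max(m) = Σ_{g=1..m−1} (m−g)/g is the score of a
contiguous m-block.  This reciprocal-distance form is this package's
concrete definition of the score: it is the simplest pairwise statistic
that is positive, maximised exactly when a class is contiguous, and
normalisable so SR ∈ [0, 1] with SR = 1 iff every class forms one block
(verified exhaustively over all permutations at small n).  The definition
is isolated in `metrics.seriation_score` so an alternative decay (e.g.
n − ld) could be swapped without touching callers.  Degenerate case: all
classes singletons → both sums are 0 and SR is defined as 1.

**Generalized anti-Robinson score (unsupervised).**  A symmetric
similarity matrix is Robinson when values never decrease toward the
diagonal.  GAR(w) counts, in the permuted matrix P, lower-triangle triples
j < k < i with i − j ≤ w and p_ij > p_ik, plus the mirrored upper-triangle
triples.  Ties comply (the non-strict inequality is the compliant form),
counts are raw, and the triple sets nest, so GAR is nondecreasing in w.

**Baselines.**  HC-PCA projects samples onto the first principal axis of
the column-centered data (sign fixed so the largest-magnitude loading is
positive; centering only by default, standardization optional) and flips
nodes so scores ascend.  For small trees an exhaustive flip-orbit search
maximising the sum of adjacent-leaf similarities provides the
optimal-leaf-ordering reference in benchmarks; it is exponential and
capped at 13 leaves.

## Synthetic benchmarks

`make_clustered_data` draws class c's samples from N(μ_c, σ²I) with
centers on orthogonal coordinate axes scaled so every pair of centers is
exactly δ·σ apart.  Defaults used by the benchmark script: 20 features,
σ = 1, δ = 3 for the comparison studies (substantial class overlap, so
trees genuinely mix classes) and δ = 10 for recovery studies (clean
separation).  Class sizes follow the two-tissue design 45 + 32 and the
8-type design [45, 66, 32, 20, 52, 5, 29, 6].  Samples are presented in a
seeded random order rather than grouped by class: the display baseline
breaks ties by input index, so a class-blocked layout would leak labels
into the supposedly unordered baseline and bias every method comparison.

What the generator does *not* emulate: intensity-dependent variance, batch
effects, correlated genes, heavy-tailed noise.  Passing benchmarks
therefore show the reordering behaves correctly on well-posed mixture
geometry, not that it is robust to microarray artefacts.

`make_robinson_similarity` places n points on a line (sorted uniform draws
when seeded, evenly spaced otherwise) and sets s_ij = exp(−λ|t_i − t_j|),
a perfect Robinson matrix under the generating order (and its reversal).

Benchmark problem sizes — 100 seeds for the 77-sample two-class studies,
50 seeds for the 255-sample 8-class study, full-window GAR on a 20-seed
subset — keep each study statistically stable while the whole script
completes in well under a minute.

## Numerical and interface choices

* Matrices must be symmetric within 1e−8 (then exactly symmetrised), with
  zero diagonal and no NaN for distances; violations are reported with the
  offending cell labels.
* Newick: child order in the file is the displayed order; floats are
  written in shortest round-trip form, so write∘read is the identity on
  topology, order and heights.  Parsing uses dendropy and rejects
  non-binary trees.
* Merge tables (3-column TSV) reference the current cluster containing a
  leaf id; on write, each child is represented by its leftmost leaf.
* All CLI outputs are deterministic (sorted JSON keys, fixed float forms):
  reruns on identical inputs are byte-identical.

## Known limitations

* Greedy pairing does not minimise B over all matchings; it implements the
  linear-lookup heuristic that defines the method.
* O(n³) clustering and O(k·mn) pairing are fine for hundreds to a few
  thousand objects, not for 10⁵-leaf trees.
* SR requires complete labels; leaves without labels are an error rather
  than being silently dropped.
* The exhaustive orbit search (optimality reference) is usable only for
  n ≤ 13.
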