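# Methods

## Model

A branching differentiation process is represented as a rooted tree of
split nodes; each directed edge ("path") carries a continuum of hidden
states indexed by pseudotime `t ∈ [0, 1]`.  Gene expression (assumed
already log-transformed; the package never re-normalizes) is emitted
from a per-gene Gaussian whose mean relaxes exponentially from the
path's start-node mean `g_a` toward its end-node mean `g_b` with rate
`K_{p,j} ≥ 0`.  TFs assigned to a path delay the relaxation of their
target genes to an activation time `t_start ∈ [0, 0.5]`: the effective
time is `t' = max(0, t − t_start)`.  When several TFs on one path share
a target, the gene follows the **earliest** of their activation times —
the gene starts changing as soon as its first regulator is active.
Variances are shared across states per gene and floored at `1e-4` so
constant genes cannot blow up the likelihood.

The scalar objective is the penalized complete-data log-likelihood: the
per-cell Gaussian emission terms, plus a path prior equal to the sum of
log branch probabilities along the root chain (deeper, more specific
paths pay a penalty, so noisy cells settle on earlier paths), minus an
L1 penalty `λ_g / (1 + α_{p,j}) · |Δg_{p,j}|` on per-path expression
changes.  `α_{p,j} ∈ [0, 1]` is the probability that gene `j` changes
on path `p`, estimated by logistic regression of DE membership on the
number of selected path TFs targeting the gene (ridge `1e-2` on the
slope; degenerate label sets short-circuit to the constant label).
Genes that the assigned TFs explain are therefore shrunk less.

The initial state places all mass on the root path at `t = 0`; general
state-to-state transitions are represented implicitly by the tree plus
branch probabilities, which is all the likelihood exercises.

## Fitting

`fit` alternates four steps until the relative change of the penalized
log-likelihood falls below `convergence_tol` (default `1e-4`, at most
`max_em_iters = 20` iterations):

1. **TF assignment** per path: TFs expressed in < 20% of the path's
   cells are removed; DE genes come from a per-gene Welch t-test
   against the parent path's cells (the root path is compared against
   all off-path cells — a documented convention, since it has no
   parent); each TF is scored by the inclusive upper-tail
   hypergeometric probability of its target–DE overlap (a binomial
   approximation is available behind a flag); TFs with `p ≤ 0.05` are
   kept, at most 10 per path, ties broken by TF id.  No
   multiple-testing correction is applied by default, matching the raw
   cutoffs of the procedure being implemented; this implies a nominal
   ~5% false path-assignment rate per TF per path, which the test suite
   checks at (rather than below) that rate.
2. **α estimation** per path as above.
3. **E-step**: every cell is independently placed at the argmax of its
   state score over all paths and a uniform grid of `time_grid_size =
   100` pseudotimes.  The per-gene kink at `t_start` makes the per-cell
   objective piecewise, so a grid argmax is more robust than an
   analytic optimum; ties break toward smaller `t`, then the
   lexicographically smaller path id.
4. **M-step**: branch probabilities become the fractions of cells
   assigned into each child subtree (the exact multinomial MLE); node
   means are solved jointly per gene by linear least squares (the
   emission mean is linear in `(g_a, g_b)` given the weights
   `w = exp(−K t')`), then reconciled root-down with each path's change
   soft-thresholded by `λ_g / ((1 + α) · scale)` where `scale` is the
   path's effective sample weight `Σ(1−w)²/σ²` — making the update the
   lasso coordinate step; `K` is re-optimized per (path, gene) by
   vectorized golden-section search on `[0, k_max = 50]` (tolerance
   `1e-3`); `σ²` is the mean squared residual, floored.  The joint
   parameter update is accepted only if it does not decrease the
   penalized log-likelihood on the current assignments, so the fit log
   is non-decreasing over accepted iterations.  Because re-assigning
   TFs changes the objective itself, an iteration that lowers the
   objective is rejected and the previous state is returned.

**Model revision** is limited to pruning paths whose entire subtree
lost its cells and merging a split node left with a single surviving
child (the two incident paths become one; cell pseudotimes are remapped
onto the halves of the merged path and the rates averaged).  Full
structure search is out of scope.

**Initialization** clusters cells per capture time point, links each
cluster to the nearest-centroid cluster at the previous time, hangs the
first time point off a synthetic root, and places cells uniformly at
random (seeded) along their cluster's incoming path.  Two choices here
were genuinely open:

- *Cluster count per time point.*  Common heuristics (silhouette,
  spherical BIC) fail systematically on trajectory data: cells on one
  path form an elongated cloud that spherical criteria over-split,
  while two branch-end clusters can be collinear and fool a
  line-segment criterion into merging them.  The package instead
  scores each candidate clustering by BIC under the model's own path
  kinetics: every cluster is fit by a single exponential path anchored
  at its nearest previous-time cluster (self-anchored at its trailing
  edge for the first time point), with `2G` parameters per cluster.
  A single path then explains its own elongation, while diverging
  branches leave an arm unexplained.  `k ∈ {1..6}` is searched; a
  fixed count can be forced via `clusters_per_timepoint`.
- *Node placement.*  A cluster's centroid sits mid-way along its path
  segment, so using centroids as node means shifts every split node
  half a segment early.  Nodes are instead placed at the cluster's
  *leading edge* (the 0.95 quantile of cell projections on the
  cluster's principal axis, signed toward its successors), and the
  synthetic root at the trailing edge of the first-level clusters.
  This aligns inferred split nodes with the actual branch points.

## TF activation times

For each selected TF, `t_start` is chosen on the grid
`{0, 0.05, …, 0.5}` (the same resolution as the cell-pseudotime grid):
for each candidate the TF's target genes are refit under the delayed
kinetics — endpoints by closed-form least squares, rate by
golden-section search — and scored by their Gaussian log-likelihood
with the model's per-gene variances; the argmax wins, ties to the
smaller (earlier) candidate.  `t_start = 0` defines an "early" TF
(active from the branching point), `t_start > 0` a "late" one.  The
reported effect direction is the sign of the mean expression change of
the TF's targets along the path, computed independently of the timing.

Timing precision is quoted **conditional on cell placement**: with
cells at their generating positions, planted activation times are
recovered within one grid step (±0.05) essentially always at the
simulation's noise levels.  Through the full pipeline the inferred
pseudotime axis of a path is a monotone but warped image of the true
one (cells near a split are genuinely ambiguous between a path's end
and its children's starts), and that warp transfers to the apparent
onset; the acceptance suite therefore evaluates topology, pseudotime
order and TF identity through the full fit, and timing at the
generating placements.

## TF–TF interaction timing enrichment

Within each path, TF pairs are categorized all-vs-all, early-early,
late-late and early-late.  Counts are **per-path pair slots summed over
paths** in both numerator and denominator (a pair co-occurring on two
paths contributes twice; this is the convention consistent with the
published denominator arithmetic, e.g. 10·9/2 × 7 paths = 315), and
pairs spanning two paths are never counted.  The universe is all
`n(n−1)/2` pairs of the dataset's TFs; universe successes are the
known interaction pairs (matched case-insensitively after whitespace
stripping).  The reported p-value is the **strict** upper tail
`P(X > k)` of the exact hypergeometric — the convention that reproduces
the published values to three significant figures, and the common
survival-function convention — with the inclusive tail
`P(X ≥ k)` available everywhere else and as an option.  Categories with
no possible pairs, or an empty database on the universe, report `X`.
The hypergeometric tails are delegated to scipy's exact implementation
and verified exhaustively against direct pmf summation for every
feasible instance with universe ≤ 30.

## Synthetic data

The generator emulates the model's own data-generating process: sparse
per-path mean changes (10% of genes, N(0,1) increments), rates
`K ~ U(1, 10)`, variances `σ² ~ U(0.05, 0.2)`, planted TFs with
disjoint regulons (target changes forced to at least 0.5 in magnitude
so regulons are detectable), activation times on the `t_start` grid,
and capture-time labels obtained by binning `depth + t` — one bin per
tree level by default, mimicking a sampled time course.  Each TF's own
transcript gets a row: post-transcriptional TFs (the default) stay
flat everywhere — only their targets betray their activity, the regime
where expression-only TF selection fails — while an optional fraction
of "transcriptionally regulated" TFs ramp on their own path.  Dropout
augmentation zeroes an *exact* count `round(rate·G)` of uniformly
chosen genes per generated cell (matching the stated augmentation
procedure) rather than Bernoulli thinning.

What the generator does **not** emulate: count-level noise
(negative-binomial dispersion, library-size effects), batch effects,
doublets, overlapping regulons, or TF cooperativity beyond additive
effects.  Passing tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not robustness
to every artifact of real scRNA-seq.

## Evaluation choices

Ordering accuracy is pair concordance: cells are keyed by (root
distance of their path, pseudotime); only pairs with different stage
labels whose paths lie on one root-to-leaf chain are evaluable
(sibling branches have no defined mutual order), and key ties count as
discordant.  The measure is invariant to monotone relabeling of
stages, and a random permutation of pseudotimes scores ~0.5.  The
expression-only baseline ranks TFs per path by a Welch t-test on the
TF's own transcript versus the parent path, returning the top 10 —
exactly constant TFs are never selected.

## Problem sizes and determinism

The standard test fixture is a two-split/three-terminal-path tree with
500 genes (+1 row per TF), 5 planted TFs × 50 targets and 300 cells;
a full fit takes seconds.  All randomness flows through explicit
integer seeds (`numpy.random.default_rng`); identical seeds give
bit-identical fits, and writers emit deterministic, byte-stable files.

## Known limitations

- Tree topologies only; no cyclic or converging trajectories.
- The E-step grid bounds pseudotime resolution at 1/(grid−1).
- Structure learning is initialization plus prune/merge; a poor
  initial clustering cannot be repaired by adding splits later.
- TF effects are additive; combinatorial logic (AND/OR) is out of
  scope, as is inferring novel TF→target edges from the data.
- Activation-time estimates inherit any pseudotime warp of the fitted
  path (see above).
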