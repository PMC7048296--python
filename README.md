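# cshmmtf

Continuous-state HMM trajectory inference for time-series single-cell
RNA-seq, with transcription-factor (TF) activation times assigned along
the trajectory and a timing-aware analysis of TF–TF interactions.

## The problem

Time-series scRNA-seq experiments capture cells at a handful of
time points while the underlying differentiation process is continuous
and branching.  Most trajectory tools order cells without using any
regulatory information, and tools that do consider TFs usually bolt them
on afterwards, or can only place a TF at a discrete branch point.  This
package is for computational biologists who want both at once: a
probabilistic branching model of the cells *and* an estimate of **when**
each TF starts acting on each branch — inferred from the TF's *target
genes*, not its own transcript, so post-transcriptionally regulated TFs
are not missed.

## The model

The process is a rooted tree of **split nodes** `D` connected by
**paths** `p`.  Each path carries a continuum of hidden states
`s_{p,t}`, `t ∈ [0,1]`.  A cell assigned to `s_{p,t}` emits, per gene
`j`, a Gaussian observation

```
x_j ~ N(mu_{j,p,t}, sigma_j^2),
mu_{j,p,t} = g_bj + (g_aj - g_bj) * exp(-K_{p,j} * max(0, t - t_start_j))
```

where `g_a`, `g_b` are the mean expression vectors at the path's two
end nodes, `K_{p,j} >= 0` is a per-gene rate of change, and `t_start_j`
is the activation time of the TF regulating gene `j` on that path
(genes without an assigned regulator change from the path start,
`t' = t`).  Branch probabilities `B` at each split define a path prior
(the product of branch probabilities along the root chain), and
per-path expression changes `Δg_p` carry an L1 penalty
`λ_g / (1 + α_{p,j})` that is relaxed for genes the assigned TFs are
expected to change.

Fitting alternates: (1) assigning TFs to paths by hypergeometric
enrichment of their targets among the path's differentially expressed
genes, with `t_start ∈ [0, 0.5]` chosen by a grid likelihood;
(2) estimating `α` by logistic regression; (3) an E-step placing every
cell at its maximum-score `(path, t)`; (4) an M-step re-estimating `B`,
node means (with TF-aware soft thresholding), `K` and `σ²`.  TFs with
`t_start = 0` are **early**, the rest **late**; known interaction pairs
(e.g. TcoF-DB) can then be counted within early/late categories on each
path and tested for enrichment against all TF pairs with an exact
hypergeometric tail.

## Worked example

Everything below is computed on synthetic data with a known ground
truth (no downloads needed):

```python
from cshmmtf import (
    make_ground_truth, simulate_expression, simulate_interaction_db,
    fit, FitConfig, enrichment_table, ordering_accuracy,
)

truth = make_ground_truth(n_genes=500, n_tfs=5, topology_spec="two_split",
                          targets_per_tf=50, seed=0)
expr, true_states = simulate_expression(truth, cells_per_path=60, seed=0)
result = fit(expr, truth.tf_targets, FitConfig(random_seed=0))
```

The fit converges with a monotone penalized log-likelihood and recovers
the generating two-split tree:

```
converged: True
 iteration  penalized_loglik  n_paths  n_tfs_assigned  accepted
        11     -54287.735436        5              11      True
paths: [('p0', ('D0', 'D1')), ('p1', ('D1', 'D2')), ('p2', ('D1', 'D3')),
        ('p3', ('D3', 'D4')), ('p4', ('D3', 'D5'))]
```

TF assignments carry a path, an activation time and the enrichment
p-value of the TF's targets among the path's DE genes:

```
  p0  TF000  t_start=0.50  p=3.77e-16
  p0  TF001  t_start=0.00  p=2.21e-14
  p1  TF000  t_start=0.00  p=9.17e-24
```

Cell ordering against the true stage labels is perfect on this fixture:

```python
stages = [truth.model.topology.path_depth(p) for p in true_states.path_ids]
ordering_accuracy(result.assignments, result.model.topology, stages)
# accuracy=1.000 over 15422 comparable cell pairs
```

and the interaction-timing report (here against a small simulated
interaction database) mirrors the published table layout — observed
pairs, within-path pair slots, ratio, and a strict upper-tail
hypergeometric p-value per timing category, with `X` marking undefined
cells:

```
category  observed  possible ratio  p_value
   total         2        10 0.200        X
  A_vs_A         2         9 0.222 0.00E+00
  E_vs_E         0         0     X        X
  L_vs_L         0         3 0.000 5.33E-01
  E_vs_L         2         6 0.333 0.00E+00
```

A `cshmmtf` console script exposes the same pipeline as `simulate`,
`fit`, `assign-tfs`, `enrich` and `evaluate` subcommands over
TSV/CSV/MTX inputs.

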