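"""Ground-truth simulation for branching trajectories with planted TFs.

The generator emulates the model's own statistical structure: a rooted
path tree, node mean vectors with sparse per-path changes, exponential
relaxation kinetics with per-gene rates, Gaussian noise on log
expression, planted TF regulons with activation times on the
[0, 0.5] grid, scRNA-seq-style dropout augmentation, and a partially
overlapping TF-TF interaction database.  All generators are pure
functions of (parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .interaction_enrichment import InteractionDB, _canon
from .model_core import (
    CellAssignment,
    ExpressionMatrix,
    ModelParameters,
    TFAssignment,
    TreeTopology,
    path_mean_matrix,
    resolve_gene_t_start,
)
from .tf_assignment import T_START_GRID, TFTargetMap

logger = logging.getLogger("cshmmtf.synthetic_data")

#: Named topologies: edge lists over split nodes (root first).
TOPOLOGY_PRESETS: dict[str, list[tuple[str, str]]] = {
    # simple chain: two consecutive paths
    "chain2": [("D0", "D1"), ("D1", "D2")],
    # one split with two children (3 paths, 4 nodes incl. root)
    "fork2": [("D0", "D1"), ("D1", "D2"), ("D1", "D3")],
    # one early cluster diverging into three terminal fates
    "fork3": [("D0", "D1"), ("D1", "D2"), ("D1", "D3"), ("D1", "D4")],
    # two nested splits, three terminal paths
    "two_split": [
        ("D0", "D1"),
        ("D1", "D2"),
        ("D1", "D3"),
        ("D2", "D4"),
        ("D2", "D5"),
    ],
}


@dataclass
class GroundTruth:
    """Generating model plus everything needed to score recovery."""

    model: ModelParameters
    tf_targets: TFTargetMap
    true_tf_times: list[TFAssignment]
    true_assignments: CellAssignment | None = None
    dropout_mask: np.ndarray | None = None

    @property
    def tf_path(self) -> dict[str, str]:
        return {tfa.tf_id: tfa.path_id for tfa in self.true_tf_times}


def _resolve_topology(topology_spec) -> list[tuple[str, str]]:
    if isinstance(topology_spec, str):
        try:
            return TOPOLOGY_PRESETS[topology_spec]
        except KeyError:
            raise ValueError(
                f"unknown topology preset {topology_spec!r}; "
                f"known: {sorted(TOPOLOGY_PRESETS)}"
            ) from None
    return [tuple(e) for e in topology_spec]


def make_ground_truth(
    n_genes: int = 500,
    n_tfs: int = 5,
    topology_spec="two_split",
    targets_per_tf: int | Sequence[int] = 50,
    seed: int = 0,
    delta_sparsity: float = 0.10,
    sigma2_range: tuple[float, float] = (0.05, 0.2),
    k_range: tuple[float, float] = (1.0, 10.0),
    lambda_g: float = 1.0,
    transcriptional_frac: float = 0.0,
    tf_paths: Sequence[str] | None = None,
) -> GroundTruth:
    """Build a generating model.

    Node means start from a standard-normal root; each path changes a
    sparse ~10% subset of genes by N(0, 1) increments.  Every TF is
    planted on one path (round-robin) with an activation time drawn
    from the t_start grid and a disjoint target set whose per-path
    change is forced away from zero so the regulon is detectable.

    The first ``round(transcriptional_frac * n_tfs)`` TFs are
    "transcriptionally regulated": their own transcript ramps on their
    planted path.  The rest are post-transcriptional — their transcript
    stays flat everywhere and only their targets betray their activity
    (the regime where expression-only TF selection fails).
    """
    n_targets = (
        [int(targets_per_tf)] * n_tfs
        if isinstance(targets_per_tf, (int, np.integer))
        else [int(v) for v in targets_per_tf]
    )
    if len(n_targets) != n_tfs:
        raise ValueError("targets_per_tf must be scalar or one value per TF")
    if sum(n_targets) > n_genes:
        raise ValueError("more TF targets requested than genes available")
    rng = np.random.default_rng(seed)
    n_total = n_genes + n_tfs  # TF transcripts get their own rows
    edges = _resolve_topology(topology_spec)
    nodes = [edges[0][0]] + [b for _, b in edges]
    root = edges[0][0]
    paths = {f"p{i}": e for i, e in enumerate(edges)}
    topo = TreeTopology(nodes=nodes, root=root, paths=paths)
    path_ids = topo.path_ids

    tf_ids = [f"TF{i:03d}" for i in range(n_tfs)]
    gene_ids = [f"G{i:04d}" for i in range(n_genes)] + tf_ids

    # TF transcript rows (the last n_tfs) stay constant along every path:
    # planted TFs are "post-transcriptionally regulated" — their activity
    # shows only through their targets, never through their own expression
    delta = {}
    for pid in path_ids:
        d = np.where(
            rng.random(n_total) < delta_sparsity, rng.normal(0.0, 1.0, n_total), 0.0
        )
        d[n_genes:] = 0.0
        delta[pid] = d

    # plant TFs: path round-robin, grid activation time, disjoint regulons
    perm = rng.permutation(n_genes)
    n_transcriptional = int(round(transcriptional_frac * n_tfs))
    true_tf_times: list[TFAssignment] = []
    targets: dict[str, set[str]] = {}
    offset = 0
    for i, tf in enumerate(tf_ids):
        if tf_paths is not None:
            pid = tf_paths[i % len(tf_paths)]
            if pid not in paths:
                raise ValueError(f"unknown path {pid!r} in tf_paths")
        else:
            pid = path_ids[i % len(path_ids)]
        t_start = float(rng.choice(T_START_GRID))
        idx = perm[offset : offset + n_targets[i]]
        offset += n_targets[i]
        targets[tf] = {gene_ids[j] for j in idx}
        # force a detectable expression change for every target on the path
        d = delta[pid]
        weak = np.abs(d[idx]) < 0.5
        d[idx[weak]] = rng.choice([-1.0, 1.0], size=int(weak.sum())) * rng.uniform(
            0.5, 1.5, size=int(weak.sum())
        )
        if i < n_transcriptional:  # TF's own transcript ramps on its path
            d[n_genes + i] = rng.choice([-1.0, 1.0]) * rng.uniform(1.0, 2.0)
        true_tf_times.append(TFAssignment(pid, tf, t_start, 0.0, n_targets[i]))

    g_root = np.concatenate(
        [rng.normal(0.0, 1.0, n_genes), rng.uniform(1.0, 3.0, n_tfs)]
    )
    g = {root: g_root}
    for pid in sorted(path_ids, key=topo.path_depth):  # parents first
        a, b = paths[pid]
        g[b] = g[a] + delta[pid]

    B = {
        nd: {c: 1.0 / len(topo.child_paths(nd)) for c in topo.child_paths(nd)}
        for nd in nodes
        if topo.child_paths(nd)
    }
    tf_map = TFTargetMap(targets)
    omega = tf_map.to_omega(gene_ids)
    phi = pd.DataFrame(-1.0, index=path_ids, columns=tf_ids)
    for tfa in true_tf_times:
        phi.loc[tfa.path_id, tfa.tf_id] = tfa.t_start
    model = ModelParameters(
        topology=topo,
        g=g,
        K={pid: rng.uniform(*k_range, n_total) for pid in path_ids},
        sigma2=rng.uniform(*sigma2_range, n_total),
        B=B,
        omega=omega,
        phi=phi,
        lambda_g=lambda_g,
        gene_ids=gene_ids,
    )
    return GroundTruth(model=model, tf_targets=tf_map, true_tf_times=true_tf_times)


def simulate_expression(
    truth: GroundTruth,
    cells_per_path: int | Mapping[str, int] = 60,
    seed: int = 0,
    n_time_points: int | None = None,
) -> tuple[ExpressionMatrix, CellAssignment]:
    """Draw cells along each path and emit Gaussian expression.

    Cells sit at Uniform(0, 1) pseudotimes; expression is
    ``N(emission_mean, sigma2)`` with the planted TF activation times
    delaying target-gene kinetics.  Capture-time labels are produced by
    binning (path depth + t) into ``n_time_points`` equal-width bins
    (default: one per depth level), mimicking a sampled time course.
    """
    model = truth.model
    topo = model.topology
    rng = np.random.default_rng(seed)
    path_ids = topo.path_ids
    counts = (
        {pid: int(cells_per_path) for pid in path_ids}
        if isinstance(cells_per_path, int)
        else dict(cells_per_path)
    )
    max_depth = max(topo.path_depth(pid) for pid in path_ids)
    if n_time_points is None:
        n_time_points = max_depth + 1

    cols, cell_paths, cell_times, labels = [], [], [], []
    blocks = []
    cell_no = 0
    for pid in path_ids:
        n = counts.get(pid, 0)
        if n == 0:
            continue
        t = rng.uniform(0.0, 1.0, n)
        ts = resolve_gene_t_start(model, pid, truth.true_tf_times)
        mu = path_mean_matrix(model, pid, t, ts)
        x = mu + rng.normal(0.0, 1.0, mu.shape) * np.sqrt(model.sigma2)[:, None]
        blocks.append(x)
        depth = topo.path_depth(pid)
        progress = (depth + t) / (max_depth + 1)  # in [0, 1)
        labels.extend(np.minimum((progress * n_time_points).astype(int),
                                 n_time_points - 1))
        for ti in t:
            cols.append(f"c{cell_no:05d}")
            cell_no += 1
            cell_paths.append(pid)
            cell_times.append(ti)
    expr = ExpressionMatrix(
        values=np.concatenate(blocks, axis=1),
        gene_ids=list(model.gene_ids),
        cell_ids=cols,
        time_labels=np.array(labels),
    )
    assignment = CellAssignment(cols, np.array(cell_paths, dtype=object),
                                np.array(cell_times))
    truth.true_assignments = assignment
    return expr, assignment


def augment_with_dropout(
    expr: ExpressionMatrix,
    copies: int = 13,
    dropout_rate: float = 0.2,
    seed: int = 0,
    return_mask: bool = False,
):
    """Scalability-style augmentation: every original cell spawns
    ``copies`` new cells, each with exactly ``round(rate * G)`` genes
    (uniformly chosen per cell) set to zero.  Cell ids carry a replicate
    suffix; time labels are inherited."""
    if copies < 1:
        raise ValueError("copies must be at least 1")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    G, N = expr.values.shape
    n_drop = int(round(dropout_rate * G))
    values = np.repeat(expr.values, copies, axis=1).copy()
    mask = np.zeros_like(values, dtype=bool)
    cell_ids = []
    labels = np.repeat(expr.time_labels, copies)
    for j in range(N):
        for r in range(copies):
            col = j * copies + r
            cell_ids.append(f"{expr.cell_ids[j]}_r{r}")
            if n_drop:
                zeroed = rng.choice(G, size=n_drop, replace=False)
                values[zeroed, col] = 0.0
                mask[zeroed, col] = True
    out = ExpressionMatrix(values, list(expr.gene_ids), cell_ids, labels)
    return (out, mask) if return_mask else out


def simulate_interaction_db(
    true_tf_times: Sequence[TFAssignment],
    n_tfs_total: int,
    frac_true_pairs: float = 0.5,
    n_noise_pairs: int = 0,
    seed: int = 0,
) -> InteractionDB:
    """Interaction database overlapping the planted regulatory program:
    a fraction of all same-path TF pairs plus random unrelated pairs
    drawn from the ``TF{i:03d}`` universe."""
    if not 0.0 <= frac_true_pairs <= 1.0:
        raise ValueError("frac_true_pairs must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    by_path: dict[str, list[str]] = {}
    for tfa in true_tf_times:
        by_path.setdefault(tfa.path_id, []).append(tfa.tf_id)
    same_path = sorted(
        {_canon(a, b) for tfs in by_path.values() for a, b in combinations(tfs, 2)}
    )
    n_true = int(round(frac_true_pairs * len(same_path)))
    chosen = set()
    if n_true:
        idx = rng.choice(len(same_path), size=n_true, replace=False)
        chosen = {same_path[i] for i in sorted(idx)}

    universe = [f"TF{i:03d}" for i in range(n_tfs_total)]
    other = sorted(
        {_canon(a, b) for a, b in combinations(universe, 2)} - set(same_path)
    )
    if n_noise_pairs > len(other):
        raise ValueError("not enough non-planted pairs for requested noise")
    if n_noise_pairs:
        idx = rng.choice(len(other), size=n_noise_pairs, replace=False)
        chosen |= {other[i] for i in sorted(idx)}
    return InteractionDB(chosen)
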