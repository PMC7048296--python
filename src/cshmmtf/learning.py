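"""Model initialization and EM fitting.

The fitting loop alternates:

1. TF assignment — regulating TFs are attached to each path with an
   activation time (``tf_assignment`` module).
2. alpha estimation — per-gene change probabilities that relax the L1
   penalty for genes targeted by path TFs.
3. E-step — each cell is independently re-assigned to the best state
   (path, pseudotime) on a uniform time grid.
4. M-step — branch probabilities, node means (with TF-aware soft
   thresholding of per-path changes), rates K and variances are
   re-estimated; the update is only accepted when it does not decrease
   the penalized log-likelihood on the current assignments.

Initialization builds a tree of per-time-point expression clusters:
clusters at each capture time are linked to the nearest-centroid cluster
at the previous time, and the first time point hangs off a synthetic
root whose mean is the grand centroid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import tf_assignment as tfmod
from .model_core import (
    VARIANCE_FLOOR,
    CellAssignment,
    ExpressionMatrix,
    ModelParameters,
    TFAssignment,
    TreeTopology,
    path_mean_matrix,
    path_prior_log_prob,
    penalized_log_likelihood,
    resolve_gene_t_start,
)

logger = logging.getLogger("cshmmtf.learning")

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class FitConfig:
    """Tuning knobs for model fitting.

    time_grid_size
        Number of candidate pseudotimes per path in the E-step (the
        per-gene kink at t_start makes the per-cell objective piecewise,
        so a grid argmax is used rather than an analytic optimum).
    max_em_iters, convergence_tol
        EM stops when the relative change in the penalized log-likelihood
        drops below the tolerance, or after the iteration cap.
    k_max
        Upper bound of the golden-section search for the per-gene rate K.
    clusters_per_timepoint
        Fixed cluster count per capture time, or ``"auto"`` to choose
        k in {1..6} by a curve-segment BIC (see ``_segment_bic``).
    """

    time_grid_size: int = 100
    max_em_iters: int = 20
    convergence_tol: float = 1e-4
    min_cells_per_path: int = 3
    random_seed: int = 0
    k_max: float = 50.0
    clusters_per_timepoint: int | str = "auto"
    lambda_g: float = 1.0
    tf_p_cutoff: float = 0.05
    max_tfs_per_path: int = 10
    expressed_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.time_grid_size < 2:
            raise ValueError("time_grid_size must be at least 2")
        for name in ("convergence_tol", "k_max", "lambda_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_em_iters < 0 or self.min_cells_per_path < 1:
            raise ValueError("invalid iteration/cell-count configuration")


@dataclass
class FitResult:
    model: ModelParameters
    assignments: CellAssignment
    tf_assignments: list[TFAssignment]
    log: pd.DataFrame
    converged: bool
    alpha: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def _leading_direction(xc: np.ndarray, anchor: np.ndarray | None) -> np.ndarray:
    """Unit principal axis of a centered cell cloud, signed to point away
    from ``anchor`` (the upstream state) when one is given."""
    _, _, vt = np.linalg.svd(xc - xc.mean(axis=0), full_matrices=False)
    v = vt[0]
    if anchor is not None and float((xc.mean(axis=0) - anchor) @ v) < 0:
        v = -v
    return v


def _kinetic_path_sse(
    xc: np.ndarray, g_a: np.ndarray, k_max: float = 50.0, n_rounds: int = 3
) -> float:
    """SSE of fitting one exponential-kinetics path through a cell cloud.

    The path runs from the anchor ``g_a`` (the linked state at the
    previous capture time) to the cloud's leading edge; per-gene rates
    and per-cell positions are refined by a few alternations.  Used for
    cluster-count selection: a single path explains an elongated cloud,
    while diverging branches leave one arm unexplained.
    """
    m, G = xc.shape
    cmean = xc.mean(axis=0)
    v = _leading_direction(xc, g_a)
    proj = (xc - cmean) @ v
    g_b = cmean + float(np.quantile(proj, 0.95)) * v
    K = np.ones(G)
    t_grid = np.linspace(0.0, 1.0, 21)
    t = np.zeros(m)
    for _ in range(n_rounds):
        mu = g_b[:, None] + (g_a - g_b)[:, None] * np.exp(-K[:, None] * t_grid[None, :])
        d = xc[:, :, None] - mu[None, :, :]
        t = t_grid[np.argmin(np.einsum("mgt,mgt->mt", d, d), axis=1)]

        def sse_of_k(Kv: np.ndarray) -> np.ndarray:
            mu_c = g_b[None, :] + (g_a - g_b)[None, :] * np.exp(
                -Kv[None, :] * t[:, None]
            )
            return np.sum((xc - mu_c) ** 2, axis=0)

        K = _golden_min_vec(sse_of_k, 0.0, k_max, G, tol=1e-2)
    mu_c = g_b[None, :] + (g_a - g_b)[None, :] * np.exp(-K[None, :] * t[:, None])
    return float(np.sum((xc - mu_c) ** 2))


def _cluster_time_point(
    x: np.ndarray,
    parent_centers: np.ndarray | None,
    k_request: int | str,
    seed: int,
    k_cap: int = 6,
    min_cluster: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster cells (rows) at one capture time; returns (labels, centers).

    With ``k_request="auto"`` the cluster count in {1..6} is chosen by
    BIC under the model's own path kinetics: each candidate cluster is
    scored by the SSE of a single exponential path anchored at its
    nearest previous-time cluster (or self-anchored at the trailing edge
    for the first time point), with 2G parameters (endpoint + rates) per
    cluster.  This deliberately tolerates the elongation a trajectory
    induces within one path while still splitting diverging branches.
    """
    n = x.shape[0]
    if isinstance(k_request, int):
        ks = [max(1, min(k_request, n))]
    else:
        ks = list(range(1, min(k_cap, n) + 1))
    G = x.shape[1]
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for k in ks:
        if k == 1:
            labels = np.zeros(n, dtype=int)
            centers = x.mean(axis=0, keepdims=True)
        else:
            km = KMeans(n_clusters=k, n_init=4, random_state=seed).fit(x)
            labels, centers = km.labels_, km.cluster_centers_
            if np.bincount(labels, minlength=k).min() < min_cluster:
                continue  # re-cluster with fewer clusters
        if len(ks) == 1:
            return labels, centers
        sse = 0.0
        for j in range(k):
            xc = x[labels == j]
            if parent_centers is None:
                cmean = xc.mean(axis=0)
                v = _leading_direction(xc, None)
                proj = (xc - cmean) @ v
                anchor = cmean + float(np.quantile(proj, 0.05)) * v
            else:
                d2 = np.sum((parent_centers - centers[j]) ** 2, axis=1)
                anchor = parent_centers[int(np.argmin(d2))]
            sse += _kinetic_path_sse(xc, anchor)
        var = max(sse / (n * G), 1e-12)
        loglik = -0.5 * n * G * (math.log(2.0 * math.pi * var) + 1.0)
        bic = -2.0 * loglik + (2 * k * G + 1) * math.log(n)
        if best is None or bic < best[0]:
            best = (bic, labels, centers)
    assert best is not None
    return best[1], best[2]


def initialize_model(
    data: ExpressionMatrix,
    config: FitConfig,
    omega: pd.DataFrame | None = None,
) -> tuple[ModelParameters, CellAssignment]:
    """Build the initial tree, parameters and random cell placements.

    Clusters at capture time tau are linked to the nearest-centroid
    cluster at tau - 1 (Euclidean distance); clusters at the first time
    point are children of a synthetic root whose mean is their grand
    centroid.  Cells start on the incoming path of their cluster at a
    uniform random pseudotime.
    """
    times = np.unique(data.time_labels)
    if len(times) < 2:
        raise ValueError("no trajectory to infer: need at least 2 time points")
    for tau in times:
        if np.sum(data.time_labels == tau) < config.min_cells_per_path:
            raise ValueError(f"time point {tau!r} has too few cells")
    rng = np.random.default_rng(config.random_seed)
    X = data.values.T  # cells x genes

    # per-time-point clustering
    level_clusters: list[list[np.ndarray]] = []  # per level, list of cell-index arrays
    level_centers: list[np.ndarray] = []
    for level, tau in enumerate(times):
        idx = np.flatnonzero(data.time_labels == tau)
        labels, centers = _cluster_time_point(
            X[idx],
            level_centers[level - 1] if level > 0 else None,
            config.clusters_per_timepoint,
            config.random_seed,
        )
        level_clusters.append([idx[labels == c] for c in range(centers.shape[0])])
        level_centers.append(centers)

    # tree construction: nodes are clusters, plus a synthetic root
    root = "D0"
    nodes = [root]
    g: dict[str, np.ndarray] = {}
    paths: dict[str, tuple[str, str]] = {}
    node_of: list[list[str]] = []  # per level, node id of each cluster
    n_nodes = 0
    n_paths = 0
    cell_path = np.empty(data.n_cells, dtype=object)
    cluster_cells: dict[str, np.ndarray] = {}
    parent_center: dict[str, np.ndarray] = {}
    level_of: dict[str, int] = {}
    for level, (clusters, centers) in enumerate(zip(level_clusters, level_centers)):
        node_of.append([])
        for c, cell_idx in enumerate(clusters):
            n_nodes += 1
            node = f"D{n_nodes}"
            nodes.append(node)
            g[node] = centers[c]
            if level == 0:
                parent = root
                parent_center[node] = centers[c]  # no informative parent yet
            else:
                d2 = np.sum((level_centers[level - 1] - centers[c]) ** 2, axis=1)
                j = int(np.argmin(d2))
                parent = node_of[level - 1][j]
                parent_center[node] = level_centers[level - 1][j]
            pid = f"p{n_paths}"
            n_paths += 1
            paths[pid] = (parent, node)
            node_of[level].append(node)
            cell_path[cell_idx] = pid
            cluster_cells[node] = cell_idx
            level_of[node] = level

    # A cluster's centroid sits mid-way along its developmental path, so
    # the split node it represents is placed at the cluster's *leading*
    # edge: the high quantile of cell projections on the cluster's
    # principal axis, signed to point toward its successor clusters (or
    # away from its parent for terminal clusters).  The synthetic root
    # gets the trailing edge of the first-level clusters.
    child_centers: dict[str, list[np.ndarray]] = {}
    for pid, (a, b) in paths.items():
        if a != root:
            child_centers.setdefault(a, []).append(g[b])
    trailing_edges = []
    for node, cell_idx in cluster_cells.items():
        xc = X[cell_idx] - g[node]
        if xc.shape[0] < 2:
            continue
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        v = vt[0]
        if node in child_centers:
            forward = np.mean(child_centers[node], axis=0) - g[node]
        else:
            forward = g[node] - parent_center[node]
        if float(forward @ v) < 0:
            v = -v
        proj = xc @ v
        lead = float(np.quantile(proj, 0.95))
        trail = float(np.quantile(proj, 0.05))
        if level_of[node] == 0:
            trailing_edges.append(g[node] + trail * v)
        g[node] = g[node] + lead * v
    g[root] = (
        np.mean(trailing_edges, axis=0)
        if trailing_edges
        else X[data.time_labels == times[0]].mean(axis=0)
    )

    topology = TreeTopology(nodes=nodes, root=root, paths=paths)
    G = data.n_genes
    sigma2 = np.maximum(data.values.var(axis=1), VARIANCE_FLOOR)
    B = {
        node: {c: 1.0 / len(topology.child_paths(node)) for c in topology.child_paths(node)}
        for node in nodes
        if topology.child_paths(node)
    }
    if omega is None:
        omega = pd.DataFrame(index=list(data.gene_ids), dtype=int)
    phi = pd.DataFrame(-1.0, index=sorted(paths), columns=list(omega.columns))
    model = ModelParameters(
        topology=topology,
        g=g,
        K={pid: np.ones(G) for pid in paths},
        sigma2=sigma2,
        B=B,
        omega=omega,
        phi=phi,
        lambda_g=config.lambda_g,
        gene_ids=list(data.gene_ids),
    )
    assignment = CellAssignment(
        cell_ids=list(data.cell_ids),
        path_ids=cell_path,
        times=rng.uniform(0.0, 1.0, size=data.n_cells),
    )
    return model, assignment


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------


def e_step_assign(
    data: ExpressionMatrix,
    model: ModelParameters,
    tf_assignments: Iterable[TFAssignment] = (),
    config: FitConfig | None = None,
) -> CellAssignment:
    """Assign each cell to the argmax state over all paths and a uniform
    pseudotime grid.  Ties break toward smaller t, then the
    lexicographically smaller path id."""
    config = config or FitConfig()
    tf_assignments = list(tf_assignments)
    t_grid = np.linspace(0.0, 1.0, config.time_grid_size)
    inv_s2 = 1.0 / model.sigma2
    const = -0.5 * float(np.sum(np.log(2.0 * np.pi * model.sigma2)))
    x_sq = (data.values**2 * inv_s2[:, None]).sum(axis=0)  # per cell
    xw = data.values * inv_s2[:, None]

    n = data.n_cells
    best_score = np.full(n, -np.inf)
    best_t = np.zeros(n)
    best_path = np.empty(n, dtype=object)
    for pid in model.topology.path_ids:  # sorted => lexicographic tie-break
        ts = resolve_gene_t_start(model, pid, tf_assignments)
        mu = path_mean_matrix(model, pid, t_grid, ts)  # (G, T)
        cross = xw.T @ mu  # (N, T)
        mu_sq = (mu**2 * inv_s2[:, None]).sum(axis=0)  # (T,)
        scores = -0.5 * (x_sq[:, None] - 2.0 * cross + mu_sq[None, :])
        scores += const + path_prior_log_prob(pid, model)
        j = np.argmax(scores, axis=1)  # first max => smallest t
        s = scores[np.arange(n), j]
        better = s > best_score
        best_score[better] = s[better]
        best_t[better] = t_grid[j[better]]
        best_path[better] = pid
    return CellAssignment(list(data.cell_ids), best_path, best_t)


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------


def soft_threshold_delta_g(delta_hat, lambda_g, alpha_pj, scale=1.0):
    """L1 shrinkage of a per-path per-gene expression change.

    The threshold is ``lambda_g / ((1 + alpha) * scale)``: genes likely
    to change on the path (high alpha from the TF evidence) are shrunk
    less.  ``scale`` carries the effective sample weight of the
    least-squares estimate so the update matches the lasso coordinate
    step; with scale = 1 the threshold is exactly lambda_g / (1 + alpha).
    """
    delta_hat = np.asarray(delta_hat, dtype=float)
    alpha_pj = np.asarray(alpha_pj, dtype=float)
    if np.any(lambda_g <= 0):
        raise ValueError("lambda_g must be positive")
    if np.any((alpha_pj < 0) | (alpha_pj > 1)):
        raise ValueError("alpha must lie in [0, 1]")
    thr = lambda_g / ((1.0 + alpha_pj) * np.asarray(scale, dtype=float))
    out = np.sign(delta_hat) * np.maximum(0.0, np.abs(delta_hat) - thr)
    return out if out.ndim else float(out)


def _subtree_paths(topology: TreeTopology, pid: str) -> list[str]:
    out = [pid]
    _, b = topology.paths[pid]
    for child in topology.child_paths(b):
        out.extend(_subtree_paths(topology, child))
    return out


def _subtree_cell_count(
    topology: TreeTopology, assignments: CellAssignment, pid: str
) -> int:
    return int(
        sum(assignments.cells_on_path(q).size for q in _subtree_paths(topology, pid))
    )


def prune_empty_paths(
    model: ModelParameters, assignments: CellAssignment
) -> tuple[ModelParameters, CellAssignment]:
    """Model revision: drop paths whose whole subtree lost its cells and
    merge split nodes left with a single surviving child path."""
    topo = model.topology
    dead = [
        pid for pid in topo.path_ids if _subtree_cell_count(topo, assignments, pid) == 0
    ]
    if not dead:
        return model, assignments
    drop = set()
    for pid in dead:
        drop.update(_subtree_paths(topo, pid))
    logger.info("pruning empty paths: %s", sorted(drop))
    kept = {pid: topo.paths[pid] for pid in topo.path_ids if pid not in drop}
    lost_children = {topo.paths[pid][0] for pid in drop}

    # merge pass-through nodes that lost siblings in this prune
    merged_pairs = []  # (incoming pid kept, outgoing pid removed, node removed)
    for node in lost_children:
        children = [pid for pid, (a, _) in kept.items() if a == node]
        incoming = [pid for pid, (_, b) in kept.items() if b == node]
        if len(children) == 1 and len(incoming) == 1:
            p_in, p_out = incoming[0], children[0]
            kept[p_in] = (kept[p_in][0], kept[p_out][1])
            del kept[p_out]
            merged_pairs.append((p_in, p_out, node))

    used_nodes = {topo.root} | {b for _, b in kept.values()} | {
        a for a, _ in kept.values()
    }
    new_topo = TreeTopology(
        nodes=[nd for nd in topo.nodes if nd in used_nodes],
        root=topo.root,
        paths=kept,
    )
    new_B = {}
    for node in new_topo.nodes:
        children = new_topo.child_paths(node)
        if not children:
            continue
        raw = {c: model.B.get(node, {}).get(c, 1.0) for c in children}
        tot = sum(raw.values()) or 1.0
        new_B[node] = {c: v / tot for c, v in raw.items()}
    new_K = {pid: model.K[pid if pid in model.K else pid] for pid in kept}
    new_phi = model.phi.loc[[p for p in model.phi.index if p in kept]]

    # remap cells from merged-away outgoing paths onto the merged path
    path_ids = assignments.path_ids.copy()
    times = assignments.times.copy()
    for p_in, p_out, _node in merged_pairs:
        on_in = path_ids == p_in
        on_out = path_ids == p_out
        times[on_in] = times[on_in] * 0.5
        times[on_out] = 0.5 + times[on_out] * 0.5
        path_ids[on_out] = p_in
        new_K[p_in] = 0.5 * (model.K[p_in] + model.K[p_out])
    new_model = ModelParameters(
        topology=new_topo,
        g={nd: model.g[nd] for nd in new_topo.nodes},
        K={pid: new_K[pid] for pid in kept},
        sigma2=model.sigma2,
        B=new_B,
        omega=model.omega,
        phi=new_phi,
        lambda_g=model.lambda_g,
        gene_ids=model.gene_ids,
    )
    return new_model, CellAssignment(assignments.cell_ids, path_ids, times)


def _path_weights(
    model: ModelParameters,
    pid: str,
    t: np.ndarray,
    tf_assignments: Sequence[TFAssignment],
) -> np.ndarray:
    """Mixture weights w = exp(-K * max(0, t - t_start)): shape (G, n)."""
    ts = resolve_gene_t_start(model, pid, tf_assignments)
    t_eff = np.maximum(0.0, t[None, :] - ts[:, None])
    return np.exp(-model.K[pid][:, None] * t_eff)


def _update_branch_probs(
    model: ModelParameters, assignments: CellAssignment
) -> dict[str, dict[str, float]]:
    """B at each split = fraction of cells assigned into each child subtree."""
    topo = model.topology
    B: dict[str, dict[str, float]] = {}
    for node in topo.nodes:
        children = topo.child_paths(node)
        if not children:
            continue
        counts = np.array(
            [_subtree_cell_count(topo, assignments, c) for c in children], dtype=float
        )
        total = counts.sum()
        if total == 0:
            B[node] = {c: 1.0 / len(children) for c in children}
        else:
            B[node] = {c: float(cnt / total) for c, cnt in zip(children, counts)}
    return B


def _update_node_means(
    data: ExpressionMatrix,
    assignments: CellAssignment,
    model: ModelParameters,
    tf_assignments: Sequence[TFAssignment],
    alpha: Mapping[str, np.ndarray] | None,
) -> dict[str, np.ndarray]:
    """Joint per-gene least squares for all node means, then a root-down
    pass that soft-thresholds each path's change Delta g."""
    topo = model.topology
    node_idx = {nd: i for i, nd in enumerate(topo.nodes)}
    m, G = len(topo.nodes), model.n_genes
    A = np.zeros((G, m, m))
    rhs = np.zeros((G, m))
    weights: dict[str, np.ndarray] = {}
    for pid in topo.path_ids:
        idx = assignments.cells_on_path(pid)
        if idx.size == 0:
            continue
        w = _path_weights(model, pid, assignments.times[idx], tf_assignments)
        weights[pid] = w
        a, b = topo.paths[pid]
        ia, ib = node_idx[a], node_idx[b]
        x = data.values[:, idx]
        one_w = 1.0 - w
        A[:, ia, ia] += np.sum(w * w, axis=1)
        A[:, ib, ib] += np.sum(one_w * one_w, axis=1)
        cross = np.sum(w * one_w, axis=1)
        A[:, ia, ib] += cross
        A[:, ib, ia] += cross
        rhs[:, ia] += np.sum(w * x, axis=1)
        rhs[:, ib] += np.sum(one_w * x, axis=1)
    # ridge keeps unidentified nodes (no nearby cells) at their old value
    ridge = 1e-6
    old = np.stack([model.g[nd] for nd in topo.nodes], axis=1)  # (G, m)
    A[:, np.arange(m), np.arange(m)] += ridge
    rhs += ridge * old
    g_ls = np.linalg.solve(A, rhs[..., None])[..., 0]  # (G, m)

    new_g: dict[str, np.ndarray] = {topo.root: g_ls[:, node_idx[topo.root]].copy()}
    # breadth-first over paths so parents are reconciled before children
    frontier = topo.child_paths(topo.root)
    while frontier:
        nxt: list[str] = []
        for pid in frontier:
            a, b = topo.paths[pid]
            delta_hat = g_ls[:, node_idx[b]] - new_g[a]
            w = weights.get(pid)
            if w is None:
                scale = np.full(G, 1e-8)
            else:
                scale = np.maximum(
                    np.sum((1.0 - w) ** 2, axis=1) / model.sigma2, 1e-8
                )
            a_p = np.zeros(G) if alpha is None else np.broadcast_to(
                np.asarray(alpha.get(pid, 0.0)), (G,)
            )
            delta = soft_threshold_delta_g(delta_hat, model.lambda_g, a_p, scale)
            new_g[b] = new_g[a] + delta
            nxt.extend(topo.child_paths(b))
        frontier = nxt
    return new_g


def _golden_min_vec(f, lo: float, hi: float, n: int, tol: float = 1e-3) -> np.ndarray:
    """Vectorized golden-section minimization of f: (n,) -> (n,) objective
    evaluated elementwise on [lo, hi]."""
    a = np.full(n, float(lo))
    b = np.full(n, float(hi))
    while float(np.max(b - a)) > tol:
        c = b - _INVPHI * (b - a)
        d = a + _INVPHI * (b - a)
        left = f(c) < f(d)
        b = np.where(left, d, b)
        a = np.where(left, a, c)
    return (a + b) / 2.0


def _update_rates(
    data: ExpressionMatrix,
    assignments: CellAssignment,
    model: ModelParameters,
    g: dict[str, np.ndarray],
    tf_assignments: Sequence[TFAssignment],
    k_max: float,
) -> dict[str, np.ndarray]:
    """Per (path, gene) golden-section maximization of the emission
    log-likelihood over K in [0, k_max] (equivalently SSE minimization)."""
    topo = model.topology
    new_K: dict[str, np.ndarray] = {}
    G = model.n_genes
    for pid in topo.path_ids:
        idx = assignments.cells_on_path(pid)
        if idx.size == 0:
            new_K[pid] = model.K[pid].copy()
            continue
        a, b = topo.paths[pid]
        g_a, g_b = g[a], g[b]
        ts = resolve_gene_t_start(model, pid, tf_assignments)
        t_eff = np.maximum(0.0, assignments.times[idx][None, :] - ts[:, None])
        x = data.values[:, idx]
        dg = (g_a - g_b)[:, None]

        def sse(K: np.ndarray) -> np.ndarray:
            mu = g_b[:, None] + dg * np.exp(-K[:, None] * t_eff)
            return np.sum((x - mu) ** 2, axis=1)

        new_K[pid] = _golden_min_vec(sse, 0.0, k_max, G)
    return new_K


def _update_sigma2(
    data: ExpressionMatrix,
    assignments: CellAssignment,
    model: ModelParameters,
    g: dict[str, np.ndarray],
    K: dict[str, np.ndarray],
    tf_assignments: Sequence[TFAssignment],
) -> np.ndarray:
    ss = np.zeros(model.n_genes)
    n_tot = 0
    topo = model.topology
    for pid in topo.path_ids:
        idx = assignments.cells_on_path(pid)
        if idx.size == 0:
            continue
        a, b = topo.paths[pid]
        ts = resolve_gene_t_start(model, pid, tf_assignments)
        t_eff = np.maximum(0.0, assignments.times[idx][None, :] - ts[:, None])
        mu = g[b][:, None] + (g[a] - g[b])[:, None] * np.exp(-K[pid][:, None] * t_eff)
        ss += np.sum((data.values[:, idx] - mu) ** 2, axis=1)
        n_tot += idx.size
    if n_tot == 0:
        return model.sigma2.copy()
    return np.maximum(ss / n_tot, VARIANCE_FLOOR)


def m_step_update(
    data: ExpressionMatrix,
    assignments: CellAssignment,
    model: ModelParameters,
    tf_assignments: Iterable[TFAssignment] = (),
    alpha: Mapping[str, np.ndarray] | None = None,
    config: FitConfig | None = None,
) -> tuple[ModelParameters, CellAssignment]:
    """One M-step.  Returns (model, assignments); assignments change only
    when empty paths are pruned.  The parameter update is accepted only
    if it does not decrease the penalized log-likelihood on the current
    assignments; otherwise the previous parameters are kept (branch
    probabilities, an exact MLE, are always refreshed)."""
    config = config or FitConfig()
    tf_assignments = list(tf_assignments)
    model, assignments = prune_empty_paths(model, assignments)

    new_B = _update_branch_probs(model, assignments)
    model = replace(model, B=new_B)

    new_g = _update_node_means(data, assignments, model, tf_assignments, alpha)
    new_K = _update_rates(data, assignments, model, new_g, tf_assignments, config.k_max)
    new_s2 = _update_sigma2(data, assignments, model, new_g, new_K, tf_assignments)
    candidate = replace(model, g=new_g, K=new_K, sigma2=new_s2)

    before = penalized_log_likelihood(data, assignments, model, tf_assignments, alpha)
    after = penalized_log_likelihood(data, assignments, candidate, tf_assignments, alpha)
    if after >= before - 1e-9:
        return candidate, assignments
    logger.debug("M-step rejected (%.6g -> %.6g); keeping previous", before, after)
    return model, assignments


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------


def fit(
    data: ExpressionMatrix,
    tf_targets: "tfmod.TFTargetMap | None" = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Full CSHMM-TF fit: initialize, then iterate TF assignment, alpha
    estimation, E-step and M-step until the penalized log-likelihood
    converges.  The fit log records one row per iteration."""
    config = config or FitConfig()
    if tf_targets is None:
        tf_targets = tfmod.TFTargetMap({})
    omega = tf_targets.to_omega(list(data.gene_ids))
    model, assignments = initialize_model(data, config, omega)
    tf_assignments: list[TFAssignment] = []
    alpha: dict[str, np.ndarray] = {}

    ll = penalized_log_likelihood(data, assignments, model, tf_assignments, alpha)
    rows = [
        {
            "iteration": 0,
            "penalized_loglik": ll,
            "n_paths": len(model.topology.paths),
            "n_tfs_assigned": 0,
            "accepted": True,
        }
    ]
    converged = False
    for it in range(1, config.max_em_iters + 1):
        prev_state = (model, assignments, tf_assignments, alpha, ll)
        tf_assignments = tfmod.assign_tfs_to_paths(
            data,
            model,
            assignments,
            tf_targets,
            p_cutoff=config.tf_p_cutoff,
            max_tfs=config.max_tfs_per_path,
            expressed_frac=config.expressed_frac,
        )
        alpha = tfmod.estimate_alpha_all_paths(
            data, model, assignments, tf_assignments, tf_targets
        )
        model = replace(model, phi=tfmod.phi_from_assignments(model, tf_assignments))
        assignments = e_step_assign(data, model, tf_assignments, config)
        model, assignments = m_step_update(
            data, assignments, model, tf_assignments, alpha, config
        )
        new_ll = penalized_log_likelihood(
            data, assignments, model, tf_assignments, alpha
        )
        accepted = new_ll >= ll - 1e-6
        rows.append(
            {
                "iteration": it,
                "penalized_loglik": new_ll,
                "n_paths": len(model.topology.paths),
                "n_tfs_assigned": len(tf_assignments),
                "accepted": accepted,
            }
        )
        if not accepted:
            # objective moved because the TF/alpha configuration changed;
            # keep the best state seen and stop
            model, assignments, tf_assignments, alpha, new_ll = prev_state
            logger.info("iteration %d rejected; stopping at previous state", it)
            break
        rel = abs(new_ll - ll) / max(abs(ll), 1.0)
        ll = new_ll
        if rel < config.convergence_tol:
            converged = True
            break
    else:
        if config.max_em_iters == 0:
            converged = True
    log = pd.DataFrame(rows)
    if not converged and config.max_em_iters > 0:
        logger.warning("EM did not converge within %d iterations", config.max_em_iters)
    return FitResult(model, assignments, tf_assignments, log, converged, alpha)
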