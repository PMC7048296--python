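"""Assigning regulating TFs to trajectory paths with activation times.

TF activity is inferred from target genes rather than the TF's own
expression, since many TFs are post-transcriptionally regulated and
their transcript level is a poor proxy for activity.  For each path:

1. TFs expressed in fewer than 20% of the path's cells are removed.
2. Differentially expressed (DE) genes are found by a per-gene Welch
   t-test between the path's cells and its parent path's cells (the
   root path is compared against all off-path cells).
3. Each remaining TF is scored by the hypergeometric upper-tail
   probability of the overlap between its known targets and the DE set.
4. TFs with p <= 0.05 are kept (at most 10 per path) and each receives
   a continuous activation time t_start in [0, 0.5] by grid-searching
   the target-gene likelihood with per-candidate kinetics refits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .model_core import (
    CellAssignment,
    ExpressionMatrix,
    ModelParameters,
    T_START_MAX,
    TFAssignment,
)

logger = logging.getLogger("cshmmtf.tf_assignment")

#: t_start candidates: Table-style bound [0, 0.5] at the pseudotime grid
#: resolution used for cells.
T_START_GRID = np.round(np.arange(0.0, T_START_MAX + 1e-9, 0.05), 2)


@dataclass
class TFTargetMap:
    """Sparse TF -> target-gene map (the Omega prior)."""

    targets: dict[str, set[str]]

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "TFTargetMap":
        out: dict[str, set[str]] = {}
        for tf, gene in edges:
            out.setdefault(str(tf), set()).add(str(gene))
        return cls(out)

    @property
    def tf_ids(self) -> list[str]:
        return sorted(self.targets)

    def to_omega(self, gene_ids: Sequence[str]) -> pd.DataFrame:
        """Dense binary gene-by-TF matrix restricted to ``gene_ids``."""
        omega = pd.DataFrame(0, index=list(gene_ids), columns=self.tf_ids, dtype=int)
        gene_set = set(gene_ids)
        for tf, genes in self.targets.items():
            hits = sorted(genes & gene_set)
            if hits:
                omega.loc[hits, tf] = 1
        return omega


@dataclass
class PathDEResult:
    """Per-gene differential-expression test for one path vs its parent."""

    path_id: str
    p_values: pd.Series
    threshold: float = 0.05
    de_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.de_genes:
            self.de_genes = set(self.p_values.index[self.p_values <= self.threshold])


# ---------------------------------------------------------------------------
# Per-path building blocks
# ---------------------------------------------------------------------------


def filter_expressed_tfs(
    path_cells: pd.DataFrame, tf_ids: Iterable[str], min_frac: float = 0.2
) -> list[str]:
    """Retain TFs whose own transcript is detected (> 0) in at least
    ``min_frac`` of the path's cells; TFs expressed in strictly less
    than that fraction are removed.  ``path_cells`` is genes x cells."""
    if path_cells.shape[1] == 0:
        raise ValueError("no cells on path; cannot filter TFs")
    retained = []
    for tf in tf_ids:
        if tf not in path_cells.index:
            logger.warning("TF %s absent from expression matrix; removed", tf)
            continue
        frac = float((path_cells.loc[tf] > 0).mean())
        if frac >= min_frac:
            retained.append(tf)
    return retained


def path_de_genes(
    path_cells: pd.DataFrame,
    parent_cells: pd.DataFrame,
    p_threshold: float = 0.05,
    path_id: str = "",
) -> PathDEResult:
    """Per-gene Welch t-test between a path's cells and its parent's.

    Genes with zero variance in both groups get p = 1 when the means are
    equal (no evidence) and p = 0 otherwise (infinite t)."""
    for name, df in (("current", path_cells), ("parent", parent_cells)):
        if df.shape[1] < 2:
            raise ValueError(
                f"path {path_id or '?'}: {name} group has fewer than 2 cells"
            )
    a = path_cells.to_numpy()
    b = parent_cells.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if np.any(degenerate):
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    return PathDEResult(
        path_id=path_id,
        p_values=pd.Series(p, index=path_cells.index),
        threshold=p_threshold,
    )


def tf_target_enrichment(
    de_genes: set[str],
    tf: str,
    targets: TFTargetMap,
    universe: set[str],
    method: str = "hypergeometric",
) -> float:
    """Upper-tail (inclusive) probability that the TF's targets overlap
    the DE set at least as much as observed, drawing |DE| genes from the
    tested universe.  ``method="binomial"`` gives the classical binomial
    approximation with success probability |targets| / |universe|."""
    if not de_genes <= universe:
        raise ValueError("DE genes must be a subset of the tested universe")
    in_universe = targets.targets.get(tf, set()) & universe
    if not in_universe:
        return 1.0
    k = len(in_universe & de_genes)
    N, K, n = len(universe), len(in_universe), len(de_genes)
    if method == "hypergeometric":
        return float(stats.hypergeom.sf(k - 1, N, K, n))
    if method == "binomial":
        return float(stats.binom.sf(k - 1, n, K / N))
    raise ValueError(f"unknown enrichment method {method!r}")


def select_path_tfs(
    p_values: Mapping[str, float], p_cutoff: float = 0.05, max_tfs: int = 10
) -> list[str]:
    """TFs passing the cutoff, ascending by p (ties: lexicographic id),
    truncated to ``max_tfs``."""
    passing = [(p, tf) for tf, p in p_values.items() if p <= p_cutoff]
    passing.sort()
    return [tf for _, tf in passing[:max_tfs]]


# ---------------------------------------------------------------------------
# Activation-time assignment
# ---------------------------------------------------------------------------

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def _endpoint_ls(w: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Per-gene 2-parameter least squares of x ~ w*g_a + (1-w)*g_b.
    ``w``, ``x``: (J, n).  Returns per-gene SSE."""
    one_w = 1.0 - w
    s_ww = np.sum(w * w, axis=1)
    s_11 = np.sum(one_w * one_w, axis=1)
    s_w1 = np.sum(w * one_w, axis=1)
    b1 = np.sum(w * x, axis=1)
    b2 = np.sum(one_w * x, axis=1)
    det = s_ww * s_11 - s_w1**2
    ok = det > 1e-10
    g_a = np.empty(w.shape[0])
    g_b = np.empty(w.shape[0])
    # degenerate design (w constant, e.g. t_start past every cell): single mean
    const = x.mean(axis=1)
    g_a[~ok] = const[~ok]
    g_b[~ok] = const[~ok]
    g_a[ok] = (s_11[ok] * b1[ok] - s_w1[ok] * b2[ok]) / det[ok]
    g_b[ok] = (s_ww[ok] * b2[ok] - s_w1[ok] * b1[ok]) / det[ok]
    mu = g_a[:, None] * w + g_b[:, None] * one_w
    return np.sum((x - mu) ** 2, axis=1)


def _best_sse_over_k(
    x: np.ndarray, t: np.ndarray, t_start: float, k_max: float, tol: float = 1e-3
) -> np.ndarray:
    """For each gene (row of x), minimize over K the SSE of the kinetic
    fit with endpoints refit by least squares at every K probe."""
    t_eff = np.maximum(0.0, t - t_start)[None, :]
    J = x.shape[0]

    def sse(K: np.ndarray) -> np.ndarray:
        return _endpoint_ls(np.exp(-K[:, None] * t_eff), x)

    a = np.zeros(J)
    b = np.full(J, float(k_max))
    while float(np.max(b - a)) > tol:
        c = b - _INVPHI * (b - a)
        d = a + _INVPHI * (b - a)
        left = sse(c) < sse(d)
        b = np.where(left, d, b)
        a = np.where(left, a, c)
    return sse((a + b) / 2.0)


def assign_tf_start_time(
    tf: str,
    path_id: str,
    model: ModelParameters,
    data: ExpressionMatrix,
    assignments: CellAssignment,
    tf_targets: TFTargetMap,
    k_max: float = 50.0,
) -> float:
    """Grid search over t_start in {0, 0.05, ..., 0.5}.

    For each candidate, the TF's target genes are refit (endpoints by
    least squares, rate by golden-section search) under the delayed
    kinetics and scored by their Gaussian log-likelihood with the
    model's per-gene variances; the argmax wins, ties to the smaller
    t_start."""
    gene_index = {gid: i for i, gid in enumerate(data.gene_ids)}
    target_idx = np.array(
        sorted(
            gene_index[gid]
            for gid in tf_targets.targets.get(tf, set())
            if gid in gene_index
        ),
        dtype=int,
    )
    if target_idx.size == 0:
        raise ValueError(f"TF {tf} has no targets among modeled genes")
    cells = assignments.cells_on_path(path_id)
    if cells.size == 0:
        raise ValueError(f"no cells on path {path_id}")
    x = data.values[np.ix_(target_idx, cells)]
    t = assignments.times[cells]
    inv_s2 = 1.0 / model.sigma2[target_idx]

    best_ts, best_score = 0.0, -np.inf
    for ts in T_START_GRID:
        sse = _best_sse_over_k(x, t, float(ts), k_max)
        score = float(-0.5 * np.sum(sse * inv_s2))
        if score > best_score + 1e-12:
            best_ts, best_score = float(ts), score
    return best_ts


# ---------------------------------------------------------------------------
# alpha estimation
# ---------------------------------------------------------------------------


def estimate_alpha(
    path_id: str,
    selected_tfs: Sequence[str],
    tf_targets: TFTargetMap,
    de_result: PathDEResult,
    ridge: float = 1e-2,
) -> pd.Series:
    """Per-gene probability alpha_{p,j} that gene j changes on the path.

    Logistic regression of DE membership on the number of selected path
    TFs targeting the gene (ridge on the slope); degenerate labels (all
    DE or none) short-circuit to the constant label."""
    genes = list(de_result.p_values.index)
    feature = np.zeros(len(genes))
    for tf in selected_tfs:
        tgt = tf_targets.targets.get(tf, set())
        feature += np.fromiter((g in tgt for g in genes), dtype=float, count=len(genes))
    label = np.fromiter((g in de_result.de_genes for g in genes), dtype=int,
                        count=len(genes))
    if label.all() or not label.any():
        return pd.Series(float(label[0]) if len(label) else 0.0, index=genes)
    if np.ptp(feature) == 0:
        # intercept-only MLE: the DE fraction, for every gene
        return pd.Series(float(label.mean()), index=genes)
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs")
    clf.fit(feature[:, None], label)
    alpha = clf.predict_proba(feature[:, None])[:, 1]
    return pd.Series(alpha, index=genes)


# ---------------------------------------------------------------------------
# Whole-model drivers used by the EM loop
# ---------------------------------------------------------------------------


def _group_frames(
    data: ExpressionMatrix, model: ModelParameters, assignments: CellAssignment,
    path_id: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression frames (genes x cells) for a path and its DE baseline:
    the parent path's cells, or all off-path cells for the root path."""
    df = data.to_frame()
    on = assignments.cells_on_path(path_id)
    parent = model.topology.parent_path(path_id)
    if parent is None:
        off = np.setdiff1d(np.arange(data.n_cells), on)
        return df.iloc[:, on], df.iloc[:, off]
    return df.iloc[:, on], df.iloc[:, assignments.cells_on_path(parent)]


def assign_tfs_to_paths(
    data: ExpressionMatrix,
    model: ModelParameters,
    assignments: CellAssignment,
    tf_targets: TFTargetMap,
    p_cutoff: float = 0.05,
    max_tfs: int = 10,
    expressed_frac: float = 0.2,
    k_max: float = 50.0,
    method: str = "hypergeometric",
) -> list[TFAssignment]:
    """Run the full per-path TF assignment pipeline; paths whose DE test
    is undefined (too few cells in either group) are skipped."""
    universe = set(data.gene_ids)
    out: list[TFAssignment] = []
    for pid in model.topology.path_ids:
        try:
            cur, par = _group_frames(data, model, assignments, pid)
            de = path_de_genes(cur, par, p_cutoff, path_id=pid)
            candidates = filter_expressed_tfs(cur, tf_targets.tf_ids, expressed_frac)
        except ValueError as exc:
            logger.debug("skipping path %s: %s", pid, exc)
            continue
        pvals = {
            tf: tf_target_enrichment(de.de_genes, tf, tf_targets, universe, method)
            for tf in candidates
        }
        for tf in select_path_tfs(pvals, p_cutoff, max_tfs):
            try:
                ts = assign_tf_start_time(
                    tf, pid, model, data, assignments, tf_targets, k_max
                )
            except ValueError:
                continue
            n_in_universe = len(tf_targets.targets.get(tf, set()) & universe)
            out.append(TFAssignment(pid, tf, ts, pvals[tf], n_in_universe))
    return out


def estimate_alpha_all_paths(
    data: ExpressionMatrix,
    model: ModelParameters,
    assignments: CellAssignment,
    tf_assignments: Sequence[TFAssignment],
    tf_targets: TFTargetMap,
) -> dict[str, np.ndarray]:
    """alpha_{p,j} for every path, aligned to the model's gene order."""
    alpha: dict[str, np.ndarray] = {}
    by_path: dict[str, list[str]] = {}
    for tfa in tf_assignments:
        by_path.setdefault(tfa.path_id, []).append(tfa.tf_id)
    for pid in model.topology.path_ids:
        try:
            cur, par = _group_frames(data, model, assignments, pid)
            de = path_de_genes(cur, par, path_id=pid)
        except ValueError:
            alpha[pid] = np.zeros(model.n_genes)
            continue
        series = estimate_alpha(pid, by_path.get(pid, []), tf_targets, de)
        alpha[pid] = series.reindex(model.gene_ids).fillna(0.0).to_numpy()
    return alpha


def phi_from_assignments(
    model: ModelParameters, tf_assignments: Sequence[TFAssignment]
) -> pd.DataFrame:
    """Rebuild the path-by-TF Phi matrix (-1 = unassigned) from a TF
    assignment list."""
    phi = pd.DataFrame(
        -1.0, index=model.topology.path_ids, columns=model.tf_ids
    )
    for tfa in tf_assignments:
        if tfa.tf_id in phi.columns and tfa.path_id in phi.index:
            phi.loc[tfa.path_id, tfa.tf_id] = tfa.t_start
    return phi


def tf_assignment_frame(
    tf_assignments: Sequence[TFAssignment],
    model: ModelParameters,
    de_results: Mapping[str, PathDEResult] | None = None,
) -> pd.DataFrame:
    """Tabular view of TF assignments, with the TF's effect direction
    reported as the sign of the mean expression change of its targets
    along the path (independent of the timing assignment)."""
    rows = []
    gene_index = {g: i for i, g in enumerate(model.gene_ids)}
    for tfa in tf_assignments:
        targets = [
            gene_index[g]
            for g in model.omega.index[model.omega.get(tfa.tf_id, pd.Series(0, index=model.omega.index)) == 1]
            if g in gene_index
        ] if tfa.tf_id in model.omega.columns else []
        if targets and tfa.path_id in model.topology.paths:
            mean_dg = float(np.mean(model.delta_g(tfa.path_id)[targets]))
            direction = "activator" if mean_dg >= 0 else "repressor"
        else:
            direction = "unknown"
        n_de = (
            len(
                de_results[tfa.path_id].de_genes
                & {model.gene_ids[i] for i in targets}
            )
            if de_results and tfa.path_id in de_results
            else -1
        )
        rows.append(
            {
                "path_id": tfa.path_id,
                "tf_id": tfa.tf_id,
                "t_start": tfa.t_start,
                "p_value": tfa.p_value,
                "n_targets_in_universe": tfa.n_targets,
                "n_targets_DE": n_de,
                "direction": direction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "path_id",
            "tf_id",
            "t_start",
            "p_value",
            "n_targets_in_universe",
            "n_targets_DE",
            "direction",
        ],
    )
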