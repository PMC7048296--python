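"""Quantitative evaluation of fitted trajectory models.

Covers: cell-ordering accuracy against known ordinal stages, the
expression-only differential-expression TF baseline (the approach
target-based TF assignment is designed to improve upon), and recovery
metrics for planted TF path/time assignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import CellAssignment, ExpressionMatrix, TFAssignment, TreeTopology
from .tf_assignment import path_de_genes

logger = logging.getLogger("cshmmtf.evaluation")


@dataclass
class OrderingScore:
    accuracy: float
    n_pairs_evaluated: int

    def __post_init__(self) -> None:
        if self.n_pairs_evaluated < 0 or not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("invalid ordering score")


def ordering_accuracy(
    assignments: CellAssignment,
    topology: TreeTopology,
    stages: Sequence,
) -> OrderingScore:
    """Pair-concordance between inferred global order and stage labels.

    A cell's global order key is (root distance of its path, pseudotime).
    Only pairs with strictly different stage labels whose paths lie on a
    single root-to-leaf chain are evaluable; sibling-branch pairs have
    no defined order and are excluded from the denominator.  Ties in the
    inferred key count as discordant.  Invariant under strictly monotone
    relabeling of stages.
    """
    stages = np.asarray(stages)
    n = len(assignments.cell_ids)
    if len(stages) != n:
        raise ValueError("one stage label per cell required")
    if len(np.unique(stages)) < 2:
        raise ValueError("all cells share one stage; no evaluable pairs")

    path_list = sorted({str(p) for p in assignments.path_ids})
    p_idx = {p: i for i, p in enumerate(path_list)}
    chain = np.zeros((len(path_list), len(path_list)), dtype=bool)
    for p in path_list:
        for q in path_list:
            chain[p_idx[p], p_idx[q]] = topology.on_same_chain(p, q)
    depth = np.array([topology.path_depth(p) for p in path_list], dtype=float)

    cell_p = np.array([p_idx[str(p)] for p in assignments.path_ids])
    key = depth[cell_p] + assignments.times  # lexicographic via depth gap >= 1

    ii, jj = np.triu_indices(n, k=1)
    evaluable = (stages[ii] != stages[jj]) & chain[cell_p[ii], cell_p[jj]]
    ii, jj = ii[evaluable], jj[evaluable]
    stage_dir = np.sign(
        np.argsort(np.argsort(stages))[ii] - np.argsort(np.argsort(stages))[jj]
    )
    key_dir = np.sign(key[ii] - key[jj])
    concordant = int(np.sum(stage_dir == key_dir))
    n_pairs = int(len(ii))
    if n_pairs == 0:
        raise ValueError("no evaluable cell pairs")
    return OrderingScore(accuracy=concordant / n_pairs, n_pairs_evaluated=n_pairs)


def de_tf_baseline(
    expr: ExpressionMatrix,
    assignments: CellAssignment,
    topology: TreeTopology,
    tf_ids: Sequence[str],
    top_k: int = 10,
) -> dict[str, list[str]]:
    """Expression-only TF selection: per path, Welch t-test on each TF's
    own transcript between the path's cells and its parent path's cells
    (root: all off-path cells), ranked by p-value, top_k returned.

    This is the baseline that misses post-transcriptionally regulated
    TFs whose own expression is flat while their targets change."""
    tf_present = [t for t in tf_ids if t in expr.gene_ids]
    frame = expr.to_frame().loc[tf_present]
    out: dict[str, list[str]] = {}
    for pid in sorted(topology.paths):
        on = assignments.cells_on_path(pid)
        parent = topology.parent_path(pid)
        if parent is None:
            other = np.setdiff1d(np.arange(expr.n_cells), on)
        else:
            other = assignments.cells_on_path(parent)
        if on.size < 2 or other.size < 2:
            out[pid] = []
            continue
        de = path_de_genes(frame.iloc[:, on], frame.iloc[:, other], path_id=pid)
        # constant TFs (p = 1 by the zero-variance convention) are never selected
        ranked = de.p_values[de.p_values < 1.0].sort_values(kind="stable")
        out[pid] = list(ranked.index[:top_k])
    return out


@dataclass
class TFTimeRecovery:
    recovery: float
    mean_time_error: float | None
    n_recovered: int


def tf_time_recovery(
    predicted: Sequence[TFAssignment], truth: Sequence[TFAssignment]
) -> TFTimeRecovery:
    """Fraction of true (path, TF) assignments recovered, and the mean
    |Delta t_start| over the recovered intersection (None when disjoint)."""
    if not truth:
        raise ValueError("truth assignment list is empty")
    pred = {(t.path_id, t.tf_id): t.t_start for t in predicted}
    true = {(t.path_id, t.tf_id): t.t_start for t in truth}
    hits = sorted(set(pred) & set(true))
    recovery = len(hits) / len(true)
    if not hits:
        return TFTimeRecovery(recovery=recovery, mean_time_error=None, n_recovered=0)
    err = float(np.mean([abs(pred[h] - true[h]) for h in hits]))
    return TFTimeRecovery(recovery=recovery, mean_time_error=err, n_recovered=len(hits))


def metrics_frame(
    ordering: OrderingScore | None = None,
    recovery: TFTimeRecovery | None = None,
    extra: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Collect evaluation metrics into a tidy (metric, value) table."""
    rows: list[tuple[str, float | None]] = []
    if ordering is not None:
        rows += [
            ("ordering_accuracy", ordering.accuracy),
            ("ordering_pairs_evaluated", ordering.n_pairs_evaluated),
        ]
    if recovery is not None:
        rows += [
            ("tf_recovery", recovery.recovery),
            ("tf_mean_time_error", recovery.mean_time_error),
            ("tf_n_recovered", recovery.n_recovered),
        ]
    for k, v in (extra or {}).items():
        rows.append((k, v))
    return pd.DataFrame(rows, columns=["metric", "value"])
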