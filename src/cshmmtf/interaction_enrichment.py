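"""TF-TF interaction timing enrichment.

Once TFs are assigned to paths with activation times, pairs of TFs on
the same path can be split by timing: early TFs act from the branching
point (t_start = 0), late TFs after it.  Known protein-protein /
cofactor interactions (a TcoF-DB-style pair list) are counted within
each timing category and compared, by an exact hypergeometric tail test,
against the background rate of known interactions among all TF pairs in
the dataset.  Categories:

- ``A_vs_A``: all pairs of TFs sharing a path;
- ``E_vs_E``: both early; ``L_vs_L``: both late; ``E_vs_L``: one each.

Pair counts are per-path "slots" summed over paths (a pair of TFs that
co-occurs on two paths contributes two slots to both the numerator and
the denominator); pairs spanning different paths are never counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import TFAssignment

logger = logging.getLogger("cshmmtf.interaction_enrichment")

CATEGORIES = ("A_vs_A", "E_vs_E", "L_vs_L", "E_vs_L")


def _canon(a: str, b: str) -> tuple[str, str]:
    a, b = str(a).strip().lower(), str(b).strip().lower()
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionDB:
    """Set of unordered TF-TF interaction pairs.

    Ids are matched case-insensitively after whitespace stripping;
    self-pairs are dropped.
    """

    pairs: set[tuple[str, str]]

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "InteractionDB":
        pairs = set()
        for a, b in edges:
            p = _canon(a, b)
            if p[0] != p[1]:
                pairs.add(p)
        return cls(pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return _canon(*pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def restricted_to(self, tf_ids: Iterable[str]) -> "InteractionDB":
        ids = {str(t).strip().lower() for t in tf_ids}
        return InteractionDB({p for p in self.pairs if p[0] in ids and p[1] in ids})


def pair_universe_size(n_tfs: int) -> int:
    """Number of unordered TF pairs among ``n_tfs`` TFs: n(n-1)/2."""
    if n_tfs < 0:
        raise ValueError("TF count cannot be negative")
    return n_tfs * (n_tfs - 1) // 2


def timing_category_pairs(
    tf_assignments: Sequence[TFAssignment], category: str
) -> dict[str, set[tuple[str, str]]]:
    """Per-path canonical TF pairs restricted by timing category.

    Returns a mapping path id -> pair set; slot counts sum the per-path
    set sizes, and the deduplicated union across paths is available via
    :func:`union_pairs`."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; one of {CATEGORIES}")
    by_path: dict[str, list[TFAssignment]] = {}
    for tfa in tf_assignments:
        by_path.setdefault(tfa.path_id, []).append(tfa)
    out: dict[str, set[tuple[str, str]]] = {}
    for pid, tfas in by_path.items():
        pairs = set()
        for x, y in combinations(tfas, 2):
            if category == "E_vs_E" and not (x.is_early and y.is_early):
                continue
            if category == "L_vs_L" and (x.is_early or y.is_early):
                continue
            if category == "E_vs_L" and (x.is_early == y.is_early):
                continue
            pairs.add(_canon(x.tf_id, y.tf_id))
        out[pid] = pairs
    return out


def union_pairs(per_path: Mapping[str, set[tuple[str, str]]]) -> set[tuple[str, str]]:
    """Deduplicated union of per-path pair sets."""
    out: set[tuple[str, str]] = set()
    for pairs in per_path.values():
        out |= pairs
    return out


def count_known_pairs(
    pairs: Iterable[tuple[str, str]] | Mapping[str, set[tuple[str, str]]],
    db: InteractionDB,
) -> int:
    """Number of pairs present in the interaction database.  For a
    per-path mapping, per-path slots are summed (no deduplication)."""
    if isinstance(pairs, Mapping):
        return sum(count_known_pairs(p, db) for p in pairs.values())
    return sum(1 for p in pairs if p in db)


def hypergeom_upper_tail(
    k: int, N: int, K: int, n: int, mode: str = "inclusive"
) -> float:
    """Exact hypergeometric upper-tail probability.

    Drawing ``n`` from a universe of ``N`` containing ``K`` successes:
    ``inclusive`` gives P(X >= k), ``strict`` gives P(X > k).
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"infeasible counts k={k}, N={N}, K={K}, n={n}")
    if mode not in ("inclusive", "strict"):
        raise ValueError(f"unknown tail mode {mode!r}")
    if n == 0 or K == 0:  # degenerate draw: X = 0 with probability 1
        return 1.0 if (mode == "inclusive" and k == 0) else 0.0
    if mode == "inclusive":
        return float(stats.hypergeom.sf(k - 1, N, K, n))
    if mode == "strict":
        return float(stats.hypergeom.sf(k, N, K, n))
    raise ValueError(f"unknown tail mode {mode!r}")


@dataclass
class CategoryRow:
    observed: int
    possible: int

    @property
    def ratio(self) -> float | None:
        return None if self.possible == 0 else self.observed / self.possible


@dataclass
class EnrichmentReport:
    """Timing-category interaction counts, ratios and tail p-values.

    ``rows`` has one entry per category plus ``total`` (the all-TF-pairs
    universe).  p-values are None where undefined (no possible pairs, or
    a database empty on the universe)."""

    rows: dict[str, CategoryRow]
    p_values: dict[str, float | None]
    tail_mode: str = "strict"

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for cat in ("total",) + CATEGORIES:
            row = self.rows[cat]
            p = self.p_values.get(cat)
            recs.append(
                {
                    "category": cat,
                    "observed": row.observed,
                    "possible": row.possible,
                    "ratio": "X" if row.ratio is None else f"{row.ratio:.3f}",
                    "p_value": "X" if p is None else f"{p:.2E}",
                }
            )
        return pd.DataFrame(recs)


def enrichment_table(
    tf_assignments: Sequence[TFAssignment],
    db: InteractionDB,
    n_tfs_total: int,
    tf_universe: Iterable[str] | None = None,
    tail_mode: str = "strict",
) -> EnrichmentReport:
    """Build the full timing enrichment report.

    The universe is every unordered pair among the dataset's
    ``n_tfs_total`` TFs; universe successes are the database pairs
    (restricted to ``tf_universe`` when given).  Each category's
    observed/possible counts are per-path slots, and p-values compare
    the category against the universe with an exact hypergeometric tail
    (strict by default, matching a survival-function convention).
    """
    N = pair_universe_size(n_tfs_total)
    db_u = db if tf_universe is None else db.restricted_to(tf_universe)
    K = len(db_u)
    rows = {"total": CategoryRow(observed=K, possible=N)}
    p_values: dict[str, float | None] = {"total": None}
    for cat in CATEGORIES:
        per_path = timing_category_pairs(tf_assignments, cat)
        possible = sum(len(p) for p in per_path.values())
        observed = count_known_pairs(per_path, db_u)
        rows[cat] = CategoryRow(observed=observed, possible=possible)
        if possible == 0 or K == 0 or possible > N:
            p_values[cat] = None
            if K == 0 and possible > 0:
                logger.warning("empty interaction DB on universe; p undefined")
        else:
            p_values[cat] = hypergeom_upper_tail(observed, N, K, possible, tail_mode)
    return EnrichmentReport(rows=rows, p_values=p_values, tail_mode=tail_mode)
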