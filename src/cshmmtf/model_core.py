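"""Domain types and likelihood mathematics for the CSHMM-TF model.

The model represents a branching differentiation process as a rooted tree
whose edges ("paths") each carry a continuum of hidden states.  A cell's
hidden state is a pair (path p, pseudotime t in [0, 1]).  Gene expression
is emitted from a Gaussian whose mean relaxes exponentially from the mean
vector at the path's start node (g_a) toward its end node (g_b), with a
per-gene rate K.  Transcription factors (TFs) assigned to a path with an
activation time t_start delay the onset of that relaxation for their
target genes: the effective time is t' = max(0, t - t_start).

The scalar objective is a penalized log-likelihood: per-cell Gaussian
emission terms, a path prior formed by the product of branch probabilities
along the root chain, and an L1 penalty lambda_g / (1 + alpha_{p,j}) on
the per-path expression change Delta g.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cshmmtf")

#: Lower bound applied to per-gene variances everywhere in the package.
VARIANCE_FLOOR = 1e-4

#: Upper bound on TF activation times (activation happens in the first
#: half of a path; t_start = 0 marks an "early" TF, t_start > 0 "late").
T_START_MAX = 0.5

LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Log-transformed gene-by-cell expression with capture-time labels.

    Parameters
    ----------
    values
        ``(G, N)`` float array, genes in rows, cells in columns.  Values
        are assumed already log-transformed; no re-normalization is done.
    gene_ids, cell_ids
        Row / column names, unique.
    time_labels
        Per-cell ordinal capture time point (``N`` integers).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    time_labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_labels = np.asarray(self.time_labels)
        g, n = self.values.shape
        if g != len(self.gene_ids):
            raise ValueError(f"{g} rows but {len(self.gene_ids)} gene ids")
        if n != len(self.cell_ids) or n != len(self.time_labels):
            raise ValueError(
                f"{n} columns but {len(self.cell_ids)} cell ids / "
                f"{len(self.time_labels)} time labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                dup = pd.Index(ids)[pd.Index(ids).duplicated()][0]
                raise ValueError(f"duplicate {name} id: {dup!r}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class TreeTopology:
    """Rooted tree of split nodes with directed paths between them.

    ``paths`` maps a path id to its ``(parent_node, child_node)`` edge.
    Every non-root node has exactly one incoming path, so a path is
    identified with its child node and ``Delta g_p = g[child] - g[parent]``
    is well defined per path.
    """

    nodes: list[str]
    root: str
    paths: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if self.root not in node_set:
            raise ValueError(f"root {self.root!r} not among nodes")
        incoming: dict[str, str] = {}
        for pid, (a, b) in self.paths.items():
            if a not in node_set or b not in node_set:
                raise ValueError(f"path {pid!r} references unknown node")
            if b in incoming:
                raise ValueError(f"node {b!r} has more than one incoming path")
            if b == self.root:
                raise ValueError("root node cannot have an incoming path")
            incoming[b] = pid
        missing = node_set - {self.root} - set(incoming)
        if missing:
            raise ValueError(f"nodes without incoming path: {sorted(missing)}")
        # connectivity: walk up from every node and require reaching the root
        for b, pid in incoming.items():
            seen = {b}
            cur = b
            while cur != self.root:
                cur = self.paths[incoming[cur]][0]
                if cur in seen:
                    raise ValueError("cycle detected in topology")
                seen.add(cur)
        self._incoming = incoming

    @property
    def path_ids(self) -> list[str]:
        return sorted(self.paths)

    def incoming_path(self, node: str) -> str | None:
        """Path ending at ``node`` (None for the root)."""
        return self._incoming.get(node)

    def parent_path(self, path_id: str) -> str | None:
        """The path feeding into this path's start node (None off the root)."""
        a, _ = self.paths[path_id]
        return self._incoming.get(a)

    def child_paths(self, node: str) -> list[str]:
        return sorted(pid for pid, (a, _) in self.paths.items() if a == node)

    def root_chain(self, path_id: str) -> list[str]:
        """Path ids from the root down to (and including) ``path_id``."""
        if path_id not in self.paths:
            raise KeyError(f"unknown path {path_id!r}")
        chain = [path_id]
        parent = self.parent_path(path_id)
        while parent is not None:
            chain.append(parent)
            parent = self.parent_path(parent)
        return chain[::-1]

    def path_depth(self, path_id: str) -> int:
        """Number of paths above this one on the root chain."""
        return len(self.root_chain(path_id)) - 1

    def on_same_chain(self, p: str, q: str) -> bool:
        """True when one path is an ancestor of (or equal to) the other."""
        return p in self.root_chain(q) or q in self.root_chain(p)


@dataclass
class ModelParameters:
    """Full CSHMM-TF parameterization.

    Attributes
    ----------
    topology
        The rooted path tree.
    g
        Per split node, length-``G`` mean expression vector.
    K
        Per path, length-``G`` non-negative rate of change.
    sigma2
        Length-``G`` per-gene variance (> 0), shared across states.
    B
        Branch probabilities: per split node, a mapping over its child
        paths summing to 1.
    omega
        Binary gene-by-TF target matrix (rows gene_ids, columns tf_ids).
    phi
        Path-by-TF matrix; -1 means "TF not assigned to this path",
        otherwise the activation time t_start in [0, 0.5].
    lambda_g
        L1 penalty weight on per-path expression changes (> 0).

    The initial-state distribution places all mass on the root path at
    t = 0 and carries no free parameters.
    """

    topology: TreeTopology
    g: dict[str, np.ndarray]
    K: dict[str, np.ndarray]
    sigma2: np.ndarray
    B: dict[str, dict[str, float]]
    omega: pd.DataFrame
    phi: pd.DataFrame
    lambda_g: float
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        self.g = {n: np.asarray(v, dtype=float) for n, v in self.g.items()}
        self.K = {p: np.asarray(v, dtype=float) for p, v in self.K.items()}
        if not self.gene_ids:
            self.gene_ids = list(self.omega.index)

    @property
    def n_genes(self) -> int:
        return len(self.sigma2)

    @property
    def tf_ids(self) -> list[str]:
        return list(self.omega.columns)

    def path_endpoints(self, path_id: str) -> tuple[np.ndarray, np.ndarray]:
        a, b = self.topology.paths[path_id]
        return self.g[a], self.g[b]

    def delta_g(self, path_id: str) -> np.ndarray:
        g_a, g_b = self.path_endpoints(path_id)
        return g_b - g_a


@dataclass
class CellAssignment:
    """Hidden-state assignment y_i = s_{p, t} for every cell."""

    cell_ids: list[str]
    path_ids: np.ndarray  # dtype object/str, one per cell
    times: np.ndarray  # float in [0, 1], one per cell

    def __post_init__(self) -> None:
        self.path_ids = np.asarray(self.path_ids, dtype=object)
        self.times = np.asarray(self.times, dtype=float)
        n = len(self.cell_ids)
        if len(self.path_ids) != n or len(self.times) != n:
            raise ValueError("assignment arrays must match cell count")
        if np.any((self.times < 0) | (self.times > 1)):
            raise ValueError("pseudotimes must lie in [0, 1]")

    def cells_on_path(self, path_id: str) -> np.ndarray:
        """Column indices of cells assigned to ``path_id``."""
        return np.flatnonzero(self.path_ids == path_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "path_id": self.path_ids,
                "pseudotime": self.times,
            }
        )


@dataclass(frozen=True)
class TFAssignment:
    """A TF assigned to a path with a continuous activation time."""

    path_id: str
    tf_id: str
    t_start: float
    p_value: float
    n_targets: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_start <= T_START_MAX:
            raise ValueError(f"t_start {self.t_start} outside [0, {T_START_MAX}]")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def is_early(self) -> bool:
        """Early TFs act from the branching point (t_start = 0)."""
        return self.t_start == 0.0


# ---------------------------------------------------------------------------
# Emission / prior / likelihood
# ---------------------------------------------------------------------------


def emission_mean(g_a, g_b, K, t, t_start=None):
    """Expected expression at pseudotime ``t`` on a path.

    Implements exponential relaxation from the start-node mean toward the
    end-node mean, ``g_b + (g_a - g_b) * exp(-K * max(0, t - t_start))``,
    with the relaxation onset delayed to the regulating TF's activation
    time.  ``t_start=None`` (gene not regulated by any path TF) means the
    effective time equals ``t``.  All arguments broadcast.
    """
    g_a = np.asarray(g_a, dtype=float)
    g_b = np.asarray(g_b, dtype=float)
    K = np.asarray(K, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(K < 0):
        raise ValueError("rate K must be non-negative")
    if np.any((t < 0) | (t > 1)):
        raise ValueError("pseudotime t must lie in [0, 1]")
    if t_start is None:
        t_eff = t
    else:
        t_start = np.asarray(t_start, dtype=float)
        t_eff = np.maximum(0.0, t - t_start)
    out = g_b + (g_a - g_b) * np.exp(-K * t_eff)
    return out if out.ndim else float(out)


def emission_log_density(x, mu, sigma2):
    """Gaussian log density of an observed expression value."""
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("variance must be positive")
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = -0.5 * (LOG_2PI + np.log(sigma2)) - (x - mu) ** 2 / (2.0 * sigma2)
    return out if out.ndim else float(out)


def path_prior_log_prob(path_id: str, model: ModelParameters) -> float:
    """Log prior of reaching a path: sum of log branch probabilities
    along the unique root chain.  The root path has an empty chain and
    prior 0; deeper paths are penalized whenever branch probabilities
    are below 1, which keeps noisy cells on earlier, less specific paths.
    """
    topo = model.topology
    if path_id not in topo.paths:
        raise KeyError(f"unknown path {path_id!r}")
    total = 0.0
    for pid in topo.root_chain(path_id):
        a, _ = topo.paths[pid]
        b_row = model.B.get(a, {})
        p = b_row.get(pid, 1.0)
        if p <= 0:
            return -np.inf
        total += math.log(p)
    return total


def resolve_gene_t_start(
    model: ModelParameters,
    path_id: str,
    tf_assignments: Iterable[TFAssignment] = (),
) -> np.ndarray:
    """Per-gene activation time on a path, from the TFs assigned there.

    A gene targeted by several TFs on the same path starts changing when
    its earliest regulator activates.  Genes with no assigned regulator
    get t_start = 0 (their effective time is simply t).
    """
    n_genes = model.n_genes
    t_start = np.zeros(n_genes)
    best = np.full(n_genes, np.inf)
    omega = model.omega
    for tfa in tf_assignments:
        if tfa.path_id != path_id or tfa.tf_id not in omega.columns:
            continue
        targets = omega[tfa.tf_id].to_numpy().astype(bool)
        best[targets] = np.minimum(best[targets], tfa.t_start)
    regulated = np.isfinite(best)
    t_start[regulated] = best[regulated]
    return t_start


def path_mean_matrix(
    model: ModelParameters,
    path_id: str,
    t: np.ndarray,
    gene_t_start: np.ndarray | None = None,
) -> np.ndarray:
    """Emission means for all genes at each pseudotime: ``(G, len(t))``."""
    g_a, g_b = model.path_endpoints(path_id)
    K = model.K[path_id]
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if gene_t_start is None:
        t_eff = np.broadcast_to(t, (model.n_genes, len(t)))
    else:
        t_eff = np.maximum(0.0, t[None, :] - gene_t_start[:, None])
    w = np.exp(-K[:, None] * t_eff)
    return g_b[:, None] + (g_a - g_b)[:, None] * w


def cell_state_log_score(
    x: np.ndarray,
    state: tuple[str, float],
    model: ModelParameters,
    tf_assignments: Iterable[TFAssignment] = (),
) -> float:
    """Unnormalized log score of a cell at a candidate state (p, t):
    sum of per-gene emission log densities plus the path prior."""
    path_id, t = state
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_genes,):
        raise ValueError(
            f"expression vector has shape {x.shape}, expected ({model.n_genes},)"
        )
    ts = resolve_gene_t_start(model, path_id, tf_assignments)
    mu = path_mean_matrix(model, path_id, np.array([t]), ts)[:, 0]
    dens = emission_log_density(x, mu, model.sigma2)
    return float(np.sum(dens)) + path_prior_log_prob(path_id, model)


def penalized_log_likelihood(
    data: ExpressionMatrix,
    assignments: CellAssignment,
    model: ModelParameters,
    tf_assignments: Iterable[TFAssignment] = (),
    alpha: Mapping[str, np.ndarray] | None = None,
) -> float:
    """Complete-data penalized log-likelihood.

    Emission + path-prior terms per cell, minus the TF-aware L1 penalty
    ``lambda_g / (1 + alpha_{p,j}) * |Delta g_{p,j}|`` summed over paths
    and genes.  ``alpha`` maps path id -> per-gene change probability
    (default 0 everywhere).
    """
    if data.n_genes != model.n_genes:
        raise ValueError("gene dimension mismatch between data and model")
    tf_assignments = list(tf_assignments)
    total = 0.0
    log_sigma_term = -0.5 * np.sum(LOG_2PI + np.log(model.sigma2))
    for path_id in model.topology.path_ids:
        idx = assignments.cells_on_path(path_id)
        if idx.size:
            ts = resolve_gene_t_start(model, path_id, tf_assignments)
            mu = path_mean_matrix(model, path_id, assignments.times[idx], ts)
            resid = data.values[:, idx] - mu
            quad = np.sum(resid**2 / (2.0 * model.sigma2[:, None]))
            prior = path_prior_log_prob(path_id, model)
            total += idx.size * log_sigma_term - quad + idx.size * prior
        a_p = None if alpha is None else np.asarray(alpha.get(path_id, 0.0))
        if a_p is None:
            a_p = np.zeros(model.n_genes)
        a_p = np.broadcast_to(a_p, (model.n_genes,))
        total -= float(
            np.sum(model.lambda_g / (1.0 + a_p) * np.abs(model.delta_g(path_id)))
        )
    return float(total)


# ---------------------------------------------------------------------------
# Validation and serialization
# ---------------------------------------------------------------------------


def validate_model(model: ModelParameters) -> list[str]:
    """Check every structural invariant; returns a list of violation
    messages (empty when the model is valid).  Reports, never raises."""
    problems: list[str] = []
    topo = model.topology
    G = model.n_genes

    for node in topo.nodes:
        if node not in model.g:
            problems.append(f"missing mean vector g for node {node!r}")
        elif model.g[node].shape != (G,):
            problems.append(f"g[{node!r}] has wrong length")
    for pid in topo.paths:
        if pid not in model.K:
            problems.append(f"missing rate vector K for path {pid!r}")
        elif model.K[pid].shape != (G,):
            problems.append(f"K[{pid!r}] has wrong length")
        elif np.any(model.K[pid] < 0):
            problems.append(f"K[{pid!r}] has negative entries")
    if np.any(model.sigma2 <= 0):
        problems.append("sigma2 has non-positive entries")

    for node in topo.nodes:
        children = topo.child_paths(node)
        if not children:
            continue
        row = model.B.get(node)
        if row is None:
            problems.append(f"missing branch probabilities at split node {node!r}")
            continue
        if set(row) != set(children):
            problems.append(f"B at node {node!r} does not cover its child paths")
            continue
        vals = np.array([row[c] for c in children], dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            problems.append(f"B at node {node!r} outside [0, 1]")
        if not math.isclose(vals.sum(), 1.0, abs_tol=1e-8):
            problems.append(
                f"branch probabilities at split node {node!r} sum to "
                f"{vals.sum():.6g}, not 1"
            )

    phi_vals = model.phi.to_numpy(dtype=float) if model.phi.size else np.empty((0, 0))
    bad = (phi_vals != -1) & ((phi_vals < 0) | (phi_vals > T_START_MAX))
    if np.any(bad):
        problems.append(
            f"phi entries must be -1 or within [0, {T_START_MAX}]; "
            f"found {phi_vals[bad][0]:.6g}"
        )
    if model.phi.size and set(model.phi.index) - set(topo.paths):
        problems.append("phi indexed by unknown path ids")

    omega_vals = model.omega.to_numpy()
    if omega_vals.size and not np.isin(omega_vals, (0, 1)).all():
        problems.append("omega must be binary")
    if model.lambda_g <= 0:
        problems.append("lambda_g must be positive")
    return problems


def model_to_json(model: ModelParameters) -> str:
    """Serialize to a single JSON document (gene-id order preserved)."""
    doc = {
        "topology": {
            "nodes": model.topology.nodes,
            "root": model.topology.root,
            "edges": {pid: list(edge) for pid, edge in model.topology.paths.items()},
        },
        "gene_ids": model.gene_ids,
        "tf_ids": model.tf_ids,
        "g": {n: v.tolist() for n, v in model.g.items()},
        "K": {p: v.tolist() for p, v in model.K.items()},
        "sigma2": model.sigma2.tolist(),
        "B": model.B,
        "phi": {p: model.phi.loc[p].tolist() for p in model.phi.index},
        "omega": {
            tf: [model.gene_ids[i] for i in np.flatnonzero(model.omega[tf].to_numpy())]
            for tf in model.tf_ids
        },
        "lambda_g": model.lambda_g,
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def model_from_json(text: str) -> ModelParameters:
    doc = json.loads(text)
    topo = TreeTopology(
        nodes=list(doc["topology"]["nodes"]),
        root=doc["topology"]["root"],
        paths={pid: tuple(e) for pid, e in doc["topology"]["edges"].items()},
    )
    gene_ids = list(doc["gene_ids"])
    tf_ids = list(doc["tf_ids"])
    omega = pd.DataFrame(0, index=gene_ids, columns=tf_ids, dtype=int)
    for tf, targets in doc["omega"].items():
        omega.loc[targets, tf] = 1
    phi = pd.DataFrame(-1.0, index=sorted(doc["phi"]), columns=tf_ids)
    for pid, row in doc["phi"].items():
        phi.loc[pid] = row
    return ModelParameters(
        topology=topo,
        g={n: np.array(v) for n, v in doc["g"].items()},
        K={p: np.array(v) for p, v in doc["K"].items()},
        sigma2=np.array(doc["sigma2"]),
        B={n: dict(row) for n, row in doc["B"].items()},
        omega=omega,
        phi=phi,
        lambda_g=float(doc["lambda_g"]),
        gene_ids=gene_ids,
    )
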