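"""Weighted small-world metrics over the sparsity sweep.

For each thresholded graph the module computes the weighted
clustering coefficient (geometric-mean triangle form), characteristic
path length, global efficiency and local efficiency, together with
their per-node decompositions, and integrates each metric curve over
the sparsity axis into a threshold-independent area-under-curve (AUC)
scalar per subject.

Conventions
-----------
* Weights are scaled by the mean retained weight before any metric, so
  every subject's network carries the same total cost; a graph whose
  weights are all equal therefore reduces exactly to the binary case.
* Path lengths use reciprocal-weight distances ``d = 1/w`` by default
  (strong couplings are short); a literal mode ``d = w`` is available.
* Disconnected pairs are excluded from the characteristic path length
  (with a flag raised) and contribute zero inverse distance to the
  efficiencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from numba import njit

from .connectome import SparsityGraph

GLOBAL_METRICS = ("Cp", "Lp", "Eg", "Eloc")
NODAL_METRICS = ("Enodal_glob", "Enodal_loc")

RECIPROCAL = "reciprocal"
LITERAL = "literal"


@dataclass
class WeightedGraph:
    """Undirected positive-weight graph held as a dense matrix."""

    matrix: np.ndarray
    scaled: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("weight matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("self-loops are not allowed")
        if np.any(self.matrix < 0):
            raise ValueError("weights must be positive")

    @classmethod
    def from_sparsity(cls, g: SparsityGraph) -> "WeightedGraph":
        return cls(g.to_matrix())

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.matrix, k=1)))


def scale_weights(g: WeightedGraph) -> WeightedGraph:
    """Divide every weight by the mean retained weight (cost control).

    After scaling the mean edge weight is exactly 1; rescaling is a
    no-op.
    """
    iu = np.triu_indices(g.n_nodes, k=1)
    w = g.matrix[iu]
    w = w[w > 0]
    if w.size == 0:
        raise ValueError("cannot scale a graph with no edges")
    return WeightedGraph(g.matrix / w.mean(), scaled=True)


def _require_scaled(g: WeightedGraph) -> None:
    if not g.scaled:
        raise ValueError("graph must be weight-scaled first (scale_weights)")


def clustering_coefficient(g: WeightedGraph) -> tuple[float, np.ndarray]:
    """Weighted clustering coefficient (geometric-mean triangles).

    ``C_i = (2 / (k_i (k_i - 1))) * sum_{j<k} (w_ij w_jk w_ki)^(1/3)``
    over neighbor pairs with an existing (j, k) edge; nodes of degree
    below 2 get 0.  Returns the network mean and the per-node values.
    """
    _require_scaled(g)
    w3 = np.cbrt(g.matrix)
    # diag of (W^(1/3))^3 counts each ordered (j,k) pair once -> the
    # unordered sum times 2, which cancels the formula's factor 2.
    tri = np.diagonal(w3 @ w3 @ w3).copy()
    deg = np.count_nonzero(g.matrix, axis=1)
    denom = deg * (deg - 1)
    c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)
    return float(c.mean()), c


@njit(cache=True)
def _fw(dist: np.ndarray) -> np.ndarray:
    """In-place dense Floyd-Warshall on one distance matrix."""
    n = dist.shape[0]
    for k in range(n):
        for i in range(n):
            dik = dist[i, k]
            if dik == np.inf:
                continue
            for j in range(n):
                alt = dik + dist[k, j]
                if alt < dist[i, j]:
                    dist[i, j] = alt
    return dist


def shortest_path_lengths(g: WeightedGraph, mode: str = RECIPROCAL) -> np.ndarray:
    """All-pairs shortest path lengths L_ij.

    Edge distances are ``1/w`` (reciprocal mode, default) or ``w``
    (literal mode).  Disconnected pairs are +inf; the diagonal is 0.
    """
    if mode not in (RECIPROCAL, LITERAL):
        raise ValueError(f"unknown distance mode {mode!r}")
    w = g.matrix
    with np.errstate(divide="ignore"):
        dist = np.where(w > 0, 1.0 / w if mode == RECIPROCAL else w, np.inf)
    np.fill_diagonal(dist, 0.0)
    return _fw(np.ascontiguousarray(dist, dtype=np.float64))


def characteristic_path_length(lengths: np.ndarray) -> tuple[float, bool]:
    """Mean shortest path length over connected ordered pairs.

    Returns ``(Lp, disconnected)`` where the flag reports whether any
    pair was unreachable (such pairs are excluded from the mean).
    """
    n = lengths.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = lengths[off]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("graph has no edges; path length undefined")
    return float(vals[finite].mean()), bool((~finite).any())


def global_efficiency(lengths: np.ndarray) -> tuple[float, np.ndarray]:
    """Global efficiency and its per-node decomposition.

    ``E_nodal_glob(i) = (1/(N-1)) sum_{j!=i} 1/L_ij`` with 1/inf = 0;
    the network value is the mean over nodes.
    """
    n = lengths.shape[0]
    if n < 2:
        return 0.0, np.zeros(n)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(lengths) & (lengths > 0), 1.0 / lengths, 0.0)
    nodal = inv.sum(axis=1) / (n - 1)
    return float(nodal.mean()), nodal


@njit(cache=True)
def _local_efficiency_kernel(w: np.ndarray, reciprocal: bool) -> np.ndarray:
    n = w.shape[0]
    nodal = np.zeros(n)
    nb = np.empty(n, dtype=np.int64)
    d = np.empty((n, n))
    for i in range(n):
        k = 0
        for j in range(n):
            if w[i, j] > 0:
                nb[k] = j
                k += 1
        if k < 2:
            continue
        for a in range(k):
            for b in range(k):
                if a == b:
                    d[a, b] = 0.0
                else:
                    wab = w[nb[a], nb[b]]
                    if wab > 0:
                        d[a, b] = 1.0 / wab if reciprocal else wab
                    else:
                        d[a, b] = np.inf
        for m in range(k):
            for a in range(k):
                dam = d[a, m]
                if dam == np.inf:
                    continue
                for b in range(k):
                    alt = dam + d[m, b]
                    if alt < d[a, b]:
                        d[a, b] = alt
        total = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and d[a, b] != np.inf and d[a, b] > 0:
                    total += 1.0 / d[a, b]
        nodal[i] = total / (k * (k - 1))
    return nodal


def local_efficiency(g: WeightedGraph, mode: str = RECIPROCAL) -> tuple[float, np.ndarray]:
    """Local efficiency: global efficiency of each neighbor subgraph.

    The subgraph G_i is induced on the neighbors of node i (i itself
    removed) and keeps the original scaled weights; nodes with fewer
    than 2 neighbors get 0.  Subgraph path lengths are confined to the
    subgraph.  Returns the mean and the per-node values.
    """
    _require_scaled(g)
    if mode not in (RECIPROCAL, LITERAL):
        raise ValueError(f"unknown distance mode {mode!r}")
    nodal = _local_efficiency_kernel(
        np.ascontiguousarray(g.matrix), mode == RECIPROCAL
    )
    return float(nodal.mean()), nodal


def auc(thresholds: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal area under a metric curve over the sparsity axis."""
    thresholds = np.asarray(thresholds, dtype=float)
    values = np.asarray(values, dtype=float)
    if thresholds.size < 2:
        raise ValueError("AUC needs at least 2 thresholds")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if values.ndim != 1 or thresholds.shape[0] != values.shape[0]:
        raise ValueError("values must be 1-D and aligned with thresholds")
    return float(np.trapezoid(values, thresholds))


def auc_nodal(thresholds: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Per-node AUC for a node x threshold matrix."""
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size < 2 or np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be >= 2 and strictly increasing")
    return np.trapezoid(np.asarray(values, dtype=float), thresholds, axis=1)


@dataclass
class AUCSummary:
    """Per-subject metric curves and their integrated scalars."""

    thresholds: np.ndarray
    curves: dict[str, np.ndarray]  # metric -> values per threshold
    nodal_curves: dict[str, np.ndarray]  # metric -> node x threshold
    global_auc: dict[str, float] = field(default_factory=dict)
    nodal_auc: dict[str, np.ndarray] = field(default_factory=dict)
    disconnected: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


def subject_metrics(
    sweep: list[SparsityGraph], distance_mode: str = RECIPROCAL
) -> AUCSummary:
    """All metrics for one subject across the sparsity sweep.

    Each graph is weight-scaled, the four global metrics and the two
    nodal efficiency profiles are computed per threshold, and every
    curve is integrated into its AUC.
    """
    if not sweep:
        raise ValueError("empty sparsity sweep")
    thresholds = np.array([g.sparsity for g in sweep])
    n = sweep[0].n_nodes
    curves = {name: np.zeros(len(sweep)) for name in GLOBAL_METRICS}
    nodal = {name: np.zeros((n, len(sweep))) for name in NODAL_METRICS}
    flags = np.zeros(len(sweep), dtype=bool)
    for t, sg in enumerate(sweep):
        g = scale_weights(WeightedGraph.from_sparsity(sg))
        cp, _ = clustering_coefficient(g)
        lengths = shortest_path_lengths(g, distance_mode)
        lp, disc = characteristic_path_length(lengths)
        eg, nodal_glob = global_efficiency(lengths)
        eloc, nodal_loc = local_efficiency(g, distance_mode)
        curves["Cp"][t] = cp
        curves["Lp"][t] = lp
        curves["Eg"][t] = eg
        curves["Eloc"][t] = eloc
        nodal["Enodal_glob"][:, t] = nodal_glob
        nodal["Enodal_loc"][:, t] = nodal_loc
        flags[t] = disc
    summary = AUCSummary(thresholds, curves, nodal, disconnected=flags)
    if len(sweep) >= 2:
        summary.global_auc = {k: auc(thresholds, v) for k, v in curves.items()}
        summary.nodal_auc = {k: auc_nodal(thresholds, v) for k, v in nodal.items()}
    return summary
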