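"""Binary-graph topology at fixed link densities.

Comparing binary graphs across groups at an absolute connectivity
threshold confounds topology with overall connection strength: the group
with weaker connectivity simply has fewer edges.  Binarizing at a fixed
*link density* — retaining the strongest ``round(density * N(N-1)/2)``
edges — guarantees equal edge counts, so any group difference in the
metrics reflects topology alone.  The pipeline sweeps densities from
0.20 to 0.90 in steps of 0.05 (15 values).

Metrics: binary clustering coefficient (fraction of a node's neighbor
pairs that are themselves connected, averaged over nodes) and binary
path length (harmonic mean of minimum edge counts between pairs; at low
densities the graph may disconnect, and disconnected pairs contribute a
zero reciprocal distance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix
from .graph_weighted import _as_weight_matrix, _harmonic_path_length

__all__ = [
    "BinaryGraphMetrics",
    "DEFAULT_DENSITIES",
    "binarize_by_density",
    "binarize_by_threshold",
    "binary_clustering",
    "binary_path_length",
    "density_sweep",
]

#: Density grid 0.20, 0.25, ..., 0.90 (15 values).
DEFAULT_DENSITIES: tuple[float, ...] = tuple(
    np.round(np.arange(0.20, 0.9001, 0.05), 2).tolist())


@dataclass
class BinaryGraphMetrics:
    density: float
    cc: float
    pl: float
    n_edges: int


def binarize_by_density(cm: ConnectivityMatrix | np.ndarray,
                        density: float) -> np.ndarray:
    """Keep the ``round(density * N(N-1)/2)`` strongest edges.

    Ties at the cutoff weight are broken deterministically by ascending
    node-index pair, so the retained edge set is platform-independent.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    w = _as_weight_matrix(cm)
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    weights = w[iu]
    n_pairs = len(weights)
    m = int(np.floor(density * n_pairs + 0.5))
    # lexsort: last key is primary -> weight desc, then (i, j) asc
    order = np.lexsort((iu[1], iu[0], -weights))
    keep = order[:m]
    adj = np.zeros((n, n))
    adj[iu[0][keep], iu[1][keep]] = 1.0
    adj += adj.T
    return adj


def binarize_by_threshold(cm: ConnectivityMatrix | np.ndarray,
                          threshold: float) -> np.ndarray:
    """Absolute-threshold binarization (entries strictly above threshold).

    Provided as a utility only: density-based binarization is what the
    group comparisons use, since an absolute threshold confounds
    topology with mean connectivity strength.
    """
    w = _as_weight_matrix(cm)
    adj = (w > threshold).astype(float)
    np.fill_diagonal(adj, 0.0)
    return adj


def _check_binary(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if not np.isin(adj, (0.0, 1.0)).all():
        raise ValueError("adjacency must be binary")
    adj = adj.copy()
    np.fill_diagonal(adj, 0.0)
    return adj


def binary_clustering(adj: np.ndarray) -> float:
    """Mean fraction of existing edges among each node's neighbors.

    Nodes with fewer than two neighbors contribute 0.
    """
    a = _check_binary(adj)
    n = a.shape[0]
    k = a.sum(axis=1)
    # (A^3)_ii counts ordered connected neighbor pairs of node i
    closed = np.einsum("ik,kl,li->i", a, a, a)
    possible = k * (k - 1)
    cc_i = np.divide(closed, possible, out=np.zeros(n), where=possible > 0)
    return float(cc_i.mean())


def binary_path_length(adj: np.ndarray) -> float:
    """Harmonic mean of minimum-edge-count path lengths over node pairs."""
    a = _check_binary(adj)
    if a.shape[0] < 2:
        raise ValueError("path length needs at least two nodes")
    sp = shortest_path(a, method="D", directed=False, unweighted=True)
    return _harmonic_path_length(sp)


def density_sweep(cm: ConnectivityMatrix | np.ndarray,
                  densities: tuple[float, ...] = DEFAULT_DENSITIES
                  ) -> list[BinaryGraphMetrics]:
    """Binary CC and PL at every density of the grid."""
    if list(densities) != sorted(densities):
        raise ValueError("densities must be sorted ascending")
    out = []
    for d in densities:
        adj = binarize_by_density(cm, d)
        out.append(BinaryGraphMetrics(
            density=float(d),
            cc=binary_clustering(adj),
            pl=binary_path_length(adj),
            n_edges=int(adj.sum() // 2),
        ))
    return out
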