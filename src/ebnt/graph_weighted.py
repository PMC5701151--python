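"""Weighted-graph topology: clustering, harmonic path length, surrogates.

The connectivity matrix is treated directly as a fully connected
weighted graph.  Two classical small-world measures are computed:

* weighted clustering coefficient of node i,

      CC_i = sum_{k!=i} sum_{l!=i,k} w_ik w_il w_kl
             / sum_{k!=i} sum_{l!=i,k} w_ik w_il,

  averaged over nodes for the network CC;

* weighted characteristic path length as the harmonic mean of
  shortest-path distances, with distance d_ij = 1 / w_ij.  The harmonic
  mean lets disconnected pairs (infinite distance) contribute a zero
  reciprocal instead of blowing up the average.

Both raw measures scale with overall connection strength (CC ~ c, PL ~
1/c under w -> c w), so they are normalized by the mean over an ensemble
of surrogate networks obtained by randomly reshuffling the edge weights
over the same node set.  The ratios are scale-invariant and compare the
observed topology against weight-matched random networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .connectivity import ConnectivityMatrix

__all__ = [
    "WeightedGraphMetrics",
    "weighted_clustering",
    "weighted_path_length",
    "surrogate_normalize",
]


@dataclass
class WeightedGraphMetrics:
    cc_raw: float
    pl_raw: float
    cc_norm: float
    pl_norm: float
    n_surrogates: int
    seed: int | None = None


def _as_weight_matrix(cm: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    w = cm.matrix if isinstance(cm, ConnectivityMatrix) else np.asarray(cm,
                                                                dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T):
        raise ValueError("weight matrix must be symmetric")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w


def weighted_clustering(cm: ConnectivityMatrix | np.ndarray) -> float:
    """Network weighted clustering coefficient (mean of node CC_i).

    A node whose weight products vanish (e.g. an isolated node) gets
    CC_i = 0 and still counts in the mean.
    """
    w = _as_weight_matrix(cm)
    n = w.shape[0]
    if n < 3:
        raise ValueError("clustering needs at least three nodes")
    # numerator_i = (W^3)_ii: the k == l terms vanish because w_kk = 0
    numer = np.einsum("ik,kl,li->i", w, w, w)
    strength = w.sum(axis=1)
    denom = strength ** 2 - (w ** 2).sum(axis=1)
    cc_i = np.divide(numer, denom, out=np.zeros(n), where=denom > 0)
    return float(cc_i.mean())


def _harmonic_path_length(dist: np.ndarray) -> float:
    """Harmonic mean over ordered node pairs; infinite distances
    contribute zero reciprocal."""
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        recip = np.where(np.isinf(dist[off]), 0.0, 1.0 / dist[off])
    mean_recip = recip.mean()
    return float(1.0 / mean_recip) if mean_recip > 0 else float("inf")


def weighted_path_length(cm: ConnectivityMatrix | np.ndarray) -> float:
    """Harmonic-mean shortest-path length on distances d = 1/w."""
    w = _as_weight_matrix(cm)
    if w.shape[0] < 2:
        raise ValueError("path length needs at least two nodes")
    with np.errstate(divide="ignore"):
        dist_graph = np.where(w > 0, 1.0 / w, 0.0)  # 0 = no edge for csgraph
    sp = dijkstra(dist_graph, directed=False)
    return _harmonic_path_length(sp)


def _shuffle_weights(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    shuffled = rng.permutation(w[iu])
    out = np.zeros_like(w)
    out[iu] = shuffled
    out += out.T
    return out


def surrogate_normalize(cm: ConnectivityMatrix | np.ndarray,
                        n_surrogates: int = 100,
                        seed: int | None = None) -> WeightedGraphMetrics:
    """Normalize CC and PL by the mean over weight-reshuffled surrogates.

    Each surrogate permutes the upper-triangle weights uniformly at
    random (symmetry and zero diagonal preserved); the surrogate ensemble
    therefore shares the weight multiset and size of the original
    network but none of its topology.
    """
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate")
    w = _as_weight_matrix(cm)
    cc_raw = weighted_clustering(w)
    pl_raw = weighted_path_length(w)
    rng = np.random.default_rng(seed)
    cc_s = np.empty(n_surrogates)
    pl_s = np.empty(n_surrogates)
    for k in range(n_surrogates):
        surr = _shuffle_weights(w, rng)
        cc_s[k] = weighted_clustering(surr)
        pl_s[k] = weighted_path_length(surr)
    return WeightedGraphMetrics(
        cc_raw=cc_raw,
        pl_raw=pl_raw,
        cc_norm=cc_raw / cc_s.mean(),
        pl_norm=pl_raw / pl_s.mean(),
        n_surrogates=n_surrogates,
        seed=seed,
    )
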