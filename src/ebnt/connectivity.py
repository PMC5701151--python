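"""Phase lag index (PLI) functional connectivity.

The PLI between two signals is the absolute mean sign of their wrapped
instantaneous phase-difference series,

    PLI = | < sign(dphi(t_k)) > |,

an asymmetry index of the phase-difference distribution.  It is 1 for a
consistent non-zero lag (perfect phase locking away from 0 mod pi) and 0
either for no coupling or for coupling with phase differences centered
at 0 mod pi — which makes it insensitive to volume-conduction-style
zero-lag crosstalk.  Phases are taken from the analytic signal (Hilbert
transform) of band-limited input; samples with an exactly zero phase
difference contribute 0 to the mean (three-valued sign), so identical
signals score exactly 0.

Per subject and band, the PLI of every channel pair is computed inside
each non-overlapping segment and averaged over segments into a single
symmetric connectivity matrix with zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .preprocess import SegmentedBandData

__all__ = [
    "ConnectivityMatrix",
    "EdgewiseComparison",
    "instantaneous_phase",
    "pli",
    "connectivity_matrix",
    "global_mean_pli",
    "edgewise_group_comparison",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric, zero-diagonal PLI matrix for one subject x band."""

    subject_id: str
    band: str
    matrix: np.ndarray
    n_segments_averaged: int
    group: int | None = None
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("PLI entries must lie in [0, 1]")
        np.fill_diagonal(m, 0.0)
        self.matrix = m

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase (radians) via the analytic signal."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if not np.any(x):
        raise ValueError("phase of an all-zero signal is undefined")
    return np.angle(hilbert(x))


def _wrap_phase(dphi: np.ndarray) -> np.ndarray:
    """Wrap phase differences into (-pi, pi].

    Exact at dphi == 0, so identical signals contribute sign(0) = 0
    throughout and score a PLI of exactly 0.
    """
    return np.pi - np.mod(np.pi - dphi, 2 * np.pi)


def pli(x: np.ndarray, y: np.ndarray) -> float:
    """Phase lag index between two equal-length band-limited signals."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    if x.size < 2:
        raise ValueError("need at least two samples")
    dphi = _wrap_phase(np.angle(hilbert(x)) - np.angle(hilbert(y)))
    return float(np.abs(np.mean(np.sign(dphi))))


def connectivity_matrix(seg_data: SegmentedBandData) -> ConnectivityMatrix:
    """Segment-averaged PLI over all unordered channel pairs."""
    if seg_data.n_segments < 1:
        raise ValueError("need at least one segment")
    n = seg_data.n_channels
    iu = np.triu_indices(n, k=1)
    acc = np.zeros(len(iu[0]))
    for seg in seg_data.segments:
        phase = np.angle(hilbert(seg, axis=-1))
        dphi = _wrap_phase(phase[iu[0]] - phase[iu[1]])
        acc += np.abs(np.mean(np.sign(dphi), axis=-1))
    acc /= seg_data.n_segments
    matrix = np.zeros((n, n))
    matrix[iu] = acc
    matrix += matrix.T
    return ConnectivityMatrix(
        subject_id=seg_data.subject_id,
        band=seg_data.band.name if seg_data.band is not None else "broadband",
        matrix=matrix,
        n_segments_averaged=seg_data.n_segments,
        group=seg_data.group,
        channel_labels=list(seg_data.channel_labels) or None,
    )


def global_mean_pli(cm: ConnectivityMatrix) -> float:
    """Mean PLI over the N(N-1)/2 distinct channel pairs."""
    n = cm.n_channels
    if n < 2:
        raise ValueError("need at least two channels")
    iu = np.triu_indices(n, k=1)
    return float(cm.matrix[iu].mean())


@dataclass
class EdgewiseComparison:
    """Per-edge two-group comparison of connectivity.

    Arrays are indexed by the upper-triangle edge order of
    ``np.triu_indices(n, 1)``.
    """

    n_channels: int
    edges: list[tuple[int, int]]
    t_stat: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    significant: np.ndarray        # boolean, FDR-corrected at alpha
    sign: np.ndarray               # +1 where group1 mean > group2 mean
    degenerate: np.ndarray         # boolean: zero-variance edges, not tested
    alpha: float

    def significant_edges(self) -> list[tuple[int, int]]:
        return [e for e, s in zip(self.edges, self.significant) if s]


def edgewise_group_comparison(group1: list[ConnectivityMatrix],
                              group2: list[ConnectivityMatrix],
                              alpha: float = 0.05) -> EdgewiseComparison:
    """Two-sample t-test per edge with Benjamini-Hochberg FDR control.

    Degenerate edges (zero variance in both groups combined) are flagged
    and excluded from testing rather than producing NaN statistics.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("need at least two subjects per group")
    n = group1[0].n_channels
    for cm in group1 + group2:
        if cm.n_channels != n:
            raise ValueError("all matrices must have the same channel count")
    iu = np.triu_indices(n, k=1)
    x1 = np.stack([cm.matrix[iu] for cm in group1])   # subjects x edges
    x2 = np.stack([cm.matrix[iu] for cm in group2])

    pooled = np.concatenate([x1, x2], axis=0)
    degenerate = pooled.std(axis=0) == 0

    t_stat = np.full(x1.shape[1], np.nan)
    p_raw = np.full(x1.shape[1], np.nan)
    ok = ~degenerate
    if ok.any():
        t_stat[ok], p_raw[ok] = ttest_ind(x1[:, ok], x2[:, ok], axis=0)

    p_fdr = np.full_like(p_raw, np.nan)
    significant = np.zeros(p_raw.shape, dtype=bool)
    if ok.any():
        rej, p_adj, _, _ = multipletests(p_raw[ok], alpha=alpha,
                                         method="fdr_bh")
        p_fdr[ok] = p_adj
        significant[ok] = rej

    sign = np.sign(x1.mean(axis=0) - x2.mean(axis=0)).astype(int)
    return EdgewiseComparison(
        n_channels=n,
        edges=list(zip(iu[0].tolist(), iu[1].tolist())),
        t_stat=t_stat,
        p_raw=p_raw,
        p_fdr=p_fdr,
        significant=significant,
        sign=sign,
        degenerate=degenerate,
        alpha=alpha,
    )
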