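"""Weighted signed graph topology of state connectivity matrices.

A state's connectivity matrix is split into three nonnegative-weight
graphs — positive (max(FC, 0)), negative (max(-FC, 0)) and absolute
(|FC|) — on which node strength and weighted global/local efficiency
are computed.  Path lengths are inverse weights (L = 1/w); global
efficiency is the mean inverse shortest-path length over node pairs,
and local efficiency uses the standard weighted formula with cube-root
weighting of the triangle terms, evaluated on each node's neighborhood
subgraph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from scipy.stats import ttest_rel

from .dfc import DfcSeries, unvectorize
from .states import StateModel

VARIANTS = ("positive", "negative", "absolute")


@dataclass
class SignedGraphSet:
    """Positive / negative / absolute weight decomposition of one FC matrix."""

    positive: np.ndarray
    negative: np.ndarray
    absolute: np.ndarray

    @classmethod
    def from_fc(cls, fc: np.ndarray) -> "SignedGraphSet":
        fc = np.asarray(fc, dtype=float)
        off = fc.copy()
        np.fill_diagonal(off, 0.0)
        return cls(positive=np.maximum(off, 0.0),
                   negative=np.maximum(-off, 0.0),
                   absolute=np.abs(off))

    def weights(self, variant: str) -> np.ndarray:
        if variant not in VARIANTS:
            raise ValueError(f"unknown graph variant {variant!r}")
        return getattr(self, variant)


@dataclass
class NodeMetrics:
    strength: np.ndarray
    local_efficiency: np.ndarray
    global_efficiency: float
    variant: str


def state_mean_dfc(dfc_by_scan: Sequence[DfcSeries], model: StateModel,
                   subject: str, state: int) -> Optional[np.ndarray]:
    """Subject's mean connectivity matrix over windows assigned to a state.

    Returns ``None`` when the subject has no window in the state (a
    missing-value record, not an error): the subject is then excluded
    from that state's comparison.
    """
    vecs = []
    for s in dfc_by_scan:
        if s.subject_id != subject:
            continue
        labels = model.assignments[(s.subject_id, s.scan_id)]
        mask = labels == state
        if mask.any():
            vecs.append(s.vectors[mask])
    if not vecs:
        return None
    mean_vec = np.vstack(vecs).mean(axis=0)
    return unvectorize(mean_vec, unit_diagonal=True)


def node_strength(g: SignedGraphSet, variant: str) -> np.ndarray:
    """Sum of incident edge weights per node."""
    return g.weights(variant).sum(axis=1)


def _inverse_distance(W: np.ndarray) -> np.ndarray:
    """1/d for shortest paths on lengths 1/w; zero where disconnected."""
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, np.inf)
    np.fill_diagonal(L, 0.0)
    D = shortest_path(L, method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv


def global_efficiency(W: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    n = W.shape[0]
    if n < 2 or not (W > 0).any():
        return 0.0
    inv = _inverse_distance(W)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(W: np.ndarray) -> np.ndarray:
    """Weighted local efficiency per node (cube-root triangle weighting).

    For node i with neighbors V (w > 0, k = |V| >= 2), shortest paths are
    computed on the neighborhood subgraph with cube-rooted lengths; the
    efficiency is sum over neighbor pairs of
    (w_ij * w_ih * invd_jh)^(1/3)-style terms divided by k(k-1).
    """
    n = W.shape[0]
    eloc = np.zeros(n)
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, np.inf)
    for i in range(n):
        V = np.flatnonzero(W[i] > 0)
        k = len(V)
        if k < 2:
            continue
        sub = L[np.ix_(V, V)] ** (1.0 / 3.0)
        np.fill_diagonal(sub, 0.0)
        D = shortest_path(sub, method="D", directed=False)
        with np.errstate(divide="ignore"):
            e = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
        sw = np.cbrt(W[i, V])
        numer = ((np.outer(sw, sw)) * (e + e.T)).sum() / 2.0
        eloc[i] = numer / (k * (k - 1))
    return eloc


def efficiency(g: SignedGraphSet, variant: str) -> NodeMetrics:
    """Node strength plus global and local weighted efficiency."""
    W = g.weights(variant)
    return NodeMetrics(strength=W.sum(axis=1),
                       local_efficiency=local_efficiency(W),
                       global_efficiency=global_efficiency(W),
                       variant=variant)


def compare_states(metrics_a: Dict[str, np.ndarray],
                   metrics_b: Dict[str, np.ndarray],
                   fdr_q: float = 0.05) -> pd.DataFrame:
    """Paired t-test per ROI of a node metric between two states.

    ``metrics_a``/``metrics_b`` map subject id -> per-ROI metric vector;
    only subjects present in both states enter the paired test.  ROIs
    with zero-variance differences are flagged with p = 1.  BH-FDR is
    applied across ROIs.
    """
    common = sorted(set(metrics_a) & set(metrics_b))
    if len(common) < 10:
        raise ValueError(f"only {len(common)} subjects with both states")
    A = np.vstack([metrics_a[s] for s in common])
    B = np.vstack([metrics_b[s] for s in common])
    R = A.shape[1]
    t = np.zeros(R)
    p = np.ones(R)
    flagged = np.zeros(R, dtype=bool)
    for j in range(R):
        diff = A[:, j] - B[:, j]
        if np.allclose(diff.std(ddof=1), 0.0):
            flagged[j] = True
            continue
        res = ttest_rel(A[:, j], B[:, j])
        t[j], p[j] = res.statistic, res.pvalue
    from .association import fdr_bh
    _, q = fdr_bh(p, fdr_q)
    return pd.DataFrame({
        "roi": np.arange(R), "t": t, "p": p, "q": q,
        "direction": np.where(t > 0, "A>B", np.where(t < 0, "A<B", "none")),
        "zero_variance": flagged,
    })
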