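"""Reoccurring connectivity states: k-means, elbow selection, occupancy.

Windows from all scans are pooled and clustered by k-means with
Euclidean distance; the optimal number of states comes from the elbow
criterion on the within/between dispersion ratio.  Fractional rates
(percent of a scan's windows assigned to each state) are the per-scan
and per-subject occupancy measures.  Centroid sets from different fits
are matched by maximizing total centroid Pearson correlation with the
Hungarian algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import TruncatedSVD

from .dfc import DfcSeries, pool_series


@dataclass
class StateModel:
    """Fitted k-means state model over pooled windowed connectivity."""

    K: int
    centroids: np.ndarray               # K x P
    assignments: Dict[Tuple[str, str], np.ndarray]  # (subject, scan) -> labels
    inertia: float
    seed: int
    n_init: int
    iteration_trace: Optional[List[float]] = None

    def labels_for(self, subject_id: str, scan_id: str = "") -> np.ndarray:
        return self.assignments[(subject_id, scan_id)]


@dataclass
class OccupancyTable:
    """Fractional rates in percent, per scan and per subject."""

    per_scan: pd.DataFrame      # columns: subject_id, scan_id, state_0..K-1
    per_subject: pd.DataFrame   # scan-averaged; index subject_id

    @property
    def K(self) -> int:
        return sum(c.startswith("state_") for c in self.per_subject.columns)

    def state_columns(self) -> List[str]:
        return [c for c in self.per_subject.columns if c.startswith("state_")]


@dataclass
class StateMatch:
    """Optimal bijection between two centroid sets."""

    permutation: np.ndarray     # index i of A matched to permutation[i] of B
    correlations: np.ndarray    # Pearson r per matched pair

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.correlations))


@dataclass
class ElbowResult:
    """Elbow-criterion selection over a range of cluster counts."""

    k: int
    k_values: np.ndarray
    scores: np.ndarray          # within/between dispersion ratio per k
    drop_ratios: np.ndarray     # slope-collapse statistic at interior k
    weak: bool                  # no pronounced elbow detected

    def __int__(self) -> int:
        return self.k


def fit_kmeans(series: Sequence[DfcSeries], K: int, seed: int = 0,
               n_init: int = 10, trace: bool = False,
               dtype=np.float64) -> StateModel:
    """Cluster pooled windows into K states (best of ``n_init`` restarts).

    With ``trace=True`` a single k-means++ seeded Lloyd run is executed
    in pure numpy instead, recording the objective after every iteration
    (used to inspect convergence on small problems).
    """
    X = pool_series(list(series)).astype(dtype, copy=False)
    if X.shape[0] < K:
        raise ValueError(f"{X.shape[0]} windows < K={K}")
    if trace:
        centroids, labels, inertia, hist = _lloyd_trace(X, K, seed)
        it_trace: Optional[List[float]] = hist
    else:
        km = KMeans(n_clusters=K, n_init=n_init, random_state=seed,
                    algorithm="lloyd").fit(X)
        centroids, labels, inertia = km.cluster_centers_, km.labels_, km.inertia_
        it_trace = None
    assignments: Dict[Tuple[str, str], np.ndarray] = {}
    offset = 0
    for s in series:
        assignments[(s.subject_id, s.scan_id)] = labels[
            offset: offset + s.n_windows].astype(np.int64)
        offset += s.n_windows
    return StateModel(K=K, centroids=np.asarray(centroids, dtype=np.float64),
                      assignments=assignments, inertia=float(inertia),
                      seed=seed, n_init=n_init, iteration_trace=it_trace)


def _lloyd_trace(X: np.ndarray, K: int, seed: int, max_iter: int = 300,
                 tol: float = 1e-10):
    rng = np.random.default_rng(seed)
    centroids = _kmeanspp(X, K, rng)
    history: List[float] = []
    labels = np.zeros(len(X), dtype=np.int64)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None]) ** 2).sum(-1)
        labels = d2.argmin(1)
        inertia = d2[np.arange(len(X)), labels].sum()
        history.append(float(inertia))
        new = np.vstack([
            X[labels == k].mean(0) if (labels == k).any() else centroids[k]
            for k in range(K)])
        if np.allclose(new, centroids, atol=tol):
            centroids = new
            break
        centroids = new
    d2 = ((X[:, None, :] - centroids[None]) ** 2).sum(-1)
    labels = d2.argmin(1)
    inertia = float(d2[np.arange(len(X)), labels].sum())
    history.append(inertia)
    return centroids, labels, inertia, history


def _kmeanspp(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    centroids = [X[rng.integers(len(X))]]
    for _ in range(1, K):
        d2 = np.min([((X - c) ** 2).sum(1) for c in centroids], axis=0)
        p = d2 / d2.sum() if d2.sum() > 0 else None
        centroids.append(X[rng.choice(len(X), p=p)])
    return np.array(centroids)


def dispersion_ratio(X: np.ndarray, centroids: np.ndarray,
                     labels: np.ndarray, extra_within: float = 0.0) -> float:
    """Within-cluster dispersion / between-cluster dispersion.

    ``extra_within`` adds a k-independent sum of squares (variance living
    outside a retained PCA subspace) to the within term.
    """
    within = ((X - centroids[labels]) ** 2).sum() + extra_within
    grand = X.mean(0)
    counts = np.bincount(labels, minlength=len(centroids))
    between = (counts * ((centroids - grand) ** 2).sum(1)).sum()
    return float(within / between) if between > 0 else np.inf


def elbow_select(series: Sequence[DfcSeries], k_range: Sequence[int] = range(2, 11),
                 seed: int = 0, n_init: int = 10,
                 max_windows: int = 20000,
                 pca_dim: int = 150,
                 first_drop_threshold: float = 0.27,
                 elbow_ratio_threshold: float = 2.5,
                 min_drop_frac: float = 0.03,
                 weak_ratio_threshold: float = 4.0,
                 dtype=np.float32) -> ElbowResult:
    """Select the number of states by the elbow criterion.

    For each k the dispersion ratio score(k) = within/between is computed
    from the best k-means fit.  The elbow is located as the point where
    the improvement rate collapses: the selected k maximizes the slope
    ratio

        R(k) = [score(k-1) - score(k)] / [score(k) - score(k+1)]

    (The raw second difference of the score curve is maximized at the
    smallest interior k whenever the curve decays convexly — which it
    does even for perfectly separated clusters — so the scale-free slope
    ratio is used instead.)  Hierarchically structured data can show a
    coarse elbow before the true one, so the selected k is the LARGEST
    interior k with a substantial collapse: slope ratio at least
    ``elbow_ratio_threshold`` (calibrated above the ratio level that
    structureless surrogate data attains at any k beyond the first) and
    a leading drop of at least ``min_drop_frac`` of the curve's total
    decay (so ratios of two near-zero fit-noise drops never qualify).
    If no k qualifies, the maximal ratio wins.

    Two boundary diagnostics accompany the rule.  If the very first step
    beyond ``k_min`` barely improves the score (relative drop below
    ``first_drop_threshold``), the structure is judged already captured
    at ``k_min`` and that value is returned.  On structureless data the
    score decays smoothly, so the slope ratio is maximal at the first
    interior k and only modestly above 1; a selection with that profile
    (peak at the first interior k, below ``weak_ratio_threshold``) is
    flagged weak.

    Sweeps larger than ``max_windows`` windows are subsampled (seeded,
    without replacement).  When ``pca_dim`` is set, clustering runs on
    the leading principal components; the variance orthogonal to the
    retained subspace is constant across k and is added back to the
    within-cluster dispersion, so the score curve's drop structure is
    that of the full space at a fraction of the cost.  The final state
    model should be refit at the chosen k on all windows in double
    precision.
    """
    ks = np.array(sorted(set(int(k) for k in k_range)))
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")
    if ks.min() < 2 or ks.max() > 12:
        raise ValueError("k_range must lie within [2, 12]")
    X = pool_series(list(series)).astype(dtype, copy=False)
    if max_windows and X.shape[0] > max_windows:
        idx = np.random.default_rng(seed).choice(X.shape[0], max_windows,
                                                 replace=False)
        X = X[np.sort(idx)]
    residual_ss = 0.0
    if pca_dim and pca_dim < X.shape[1]:
        Xc = X - X.mean(axis=0)
        total_ss = float((Xc ** 2).sum())
        svd = TruncatedSVD(n_components=int(pca_dim), algorithm="randomized",
                           random_state=seed)
        X = svd.fit_transform(Xc).astype(dtype, copy=False)
        residual_ss = max(0.0, total_ss - float((X ** 2).sum()))
    scores = np.empty(len(ks))
    for i, k in enumerate(ks):
        km = KMeans(n_clusters=int(k), n_init=n_init, random_state=seed,
                    algorithm="lloyd").fit(X)
        scores[i] = dispersion_ratio(X, km.cluster_centers_, km.labels_,
                                     extra_within=residual_ss)
    # enforce monotone non-increasing scores before differencing: a local
    # uptick is k-means fit noise, not structure
    mono = np.minimum.accumulate(scores)
    drops = mono[:-1] - mono[1:]
    total = max(mono[0] - mono[-1], 1e-12)
    floor = 1e-3 * total
    ratios = drops[:-1] / np.maximum(drops[1:], floor)
    # a k whose own improvement is negligible cannot be the elbow, however
    # large the ratio of two near-zero drops happens to be
    ratios[drops[:-1] < min_drop_frac * total] = 0.0
    substantial = np.flatnonzero(ratios >= elbow_ratio_threshold)
    best = int(substantial[-1]) if len(substantial) else int(np.argmax(ratios))
    weak = bool(best == 0 and ratios[best] < weak_ratio_threshold)
    if drops[0] / mono[0] < first_drop_threshold:
        k_sel = int(ks[0])
        weak = False
    else:
        k_sel = int(ks[best + 1])
    return ElbowResult(k=k_sel, k_values=ks, scores=scores,
                       drop_ratios=ratios, weak=weak)


def fractional_rates(model: StateModel) -> OccupancyTable:
    """Percent of windows assigned to each state, per scan and subject."""
    rows = []
    for (sid, scan), labels in model.assignments.items():
        counts = np.bincount(labels, minlength=model.K)
        rows.append({"subject_id": sid, "scan_id": scan,
                     **{f"state_{k}": 100.0 * counts[k] / counts.sum()
                        for k in range(model.K)}})
    per_scan = pd.DataFrame(rows)
    state_cols = [f"state_{k}" for k in range(model.K)]
    per_subject = per_scan.groupby("subject_id")[state_cols].mean()
    return OccupancyTable(per_scan=per_scan, per_subject=per_subject)


def _centroid_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation matrix between two centroid sets."""
    az = (a - a.mean(1, keepdims=True))
    bz = (b - b.mean(1, keepdims=True))
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    bz /= np.linalg.norm(bz, axis=1, keepdims=True)
    return az @ bz.T


def match_states(a: StateModel | np.ndarray, b: StateModel | np.ndarray
                 ) -> StateMatch:
    """Optimal assignment of B's states to A's by centroid correlation."""
    ca = a.centroids if isinstance(a, StateModel) else np.asarray(a)
    cb = b.centroids if isinstance(b, StateModel) else np.asarray(b)
    if ca.shape[0] != cb.shape[0]:
        raise ValueError(f"K mismatch: {ca.shape[0]} vs {cb.shape[0]}")
    r = _centroid_corr(ca, cb)
    row, col = linear_sum_assignment(1.0 - r)
    perm = np.empty(ca.shape[0], dtype=np.int64)
    perm[row] = col
    return StateMatch(permutation=perm,
                      correlations=r[row, perm[row]][np.argsort(row)])


@dataclass
class SplitHalfReport:
    """Test-retest style reliability via a random split of sites."""

    sites_a: List[str]
    sites_b: List[str]
    match_a: StateMatch         # half A vs full-data model
    match_b: StateMatch         # half B vs full-data model
    match_ab: StateMatch        # half A vs half B


def split_half(series: Sequence[DfcSeries], site_of_subject: Dict[str, str],
               full_model: StateModel, seed: int = 0, n_init: int = 10
               ) -> SplitHalfReport:
    """Split sites into random halves, refit states per half, and match
    each half's centroids to the full-data model and to each other."""
    sites = sorted(set(site_of_subject.values()))
    if len(sites) < 2:
        raise ValueError("need at least 2 sites to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(sites))
    half = len(sites) // 2
    sites_a = [sites[i] for i in perm[:half]]
    sites_b = [sites[i] for i in perm[half:]]
    ser_a = [s for s in series if site_of_subject[s.subject_id] in sites_a]
    ser_b = [s for s in series if site_of_subject[s.subject_id] in sites_b]
    K = full_model.K
    for name, ser in (("A", ser_a), ("B", ser_b)):
        if sum(s.n_windows for s in ser) < K:
            raise ValueError(f"half {name} has too few windows")
    model_a = fit_kmeans(ser_a, K, seed=seed, n_init=n_init)
    model_b = fit_kmeans(ser_b, K, seed=seed + 1, n_init=n_init)
    return SplitHalfReport(
        sites_a=sites_a, sites_b=sites_b,
        match_a=match_states(full_model, model_a),
        match_b=match_states(full_model, model_b),
        match_ab=match_states(model_a, model_b),
    )
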