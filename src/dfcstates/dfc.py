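"""Tapered sliding-window dynamic functional connectivity.

A window of 40 TRs (32 s at TR = 0.8 s), tapered by convolving a
rectangle with a Gaussian of sigma = 3 TRs, slides along the scan in
steps of 1 TR.  Within each window the weighted Pearson correlation is
computed for every ROI pair; the upper triangle (row-major, i < j) is
the windowed connectivity vector, P = R(R-1)/2 = 1378 entries for the
53-ROI parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .io import RoiTimecourse

DEFAULT_WIDTH_TR = 40
DEFAULT_SIGMA_TR = 3.0


@dataclass(frozen=True)
class TaperWindow:
    """Unit-sum tapered window weights."""

    weights: np.ndarray
    width_tr: int
    sigma_tr: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        assert len(w) == self.width_tr
        object.__setattr__(self, "weights", w)


@dataclass
class DfcSeries:
    """Windowed connectivity vectors of one scan (or a pooled set)."""

    vectors: np.ndarray                 # N_w x P
    window_start_tr: np.ndarray         # length N_w, 0-based first TR
    subject_id: str = ""
    scan_id: str = ""
    flagged_pairs: Optional[np.ndarray] = None

    @property
    def n_windows(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.vectors.shape[1]


def build_taper(width: int = DEFAULT_WIDTH_TR,
                sigma: float = DEFAULT_SIGMA_TR) -> TaperWindow:
    """Convolve a width-length rectangle with a discrete Gaussian kernel.

    The Gaussian is sampled at integer offsets, truncated at +/-ceil(4*sigma)
    and renormalized; the central ``width`` samples of the full convolution
    are retained and normalized to unit sum, preserving the literal window
    size while down-weighting the edges.
    """
    if width < 4:
        raise ValueError("width must be >= 4")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = int(np.ceil(4 * sigma))
    x = np.arange(-half, half + 1)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    full = np.convolve(np.ones(width), g)     # length width + 2*half
    start = (len(full) - width) // 2
    w = full[start: start + width]
    w = (w + w[::-1]) / 2.0                   # enforce exact symmetry
    w /= w.sum()
    return TaperWindow(weights=w, width_tr=width, sigma_tr=sigma)


def vectorize(mat: np.ndarray) -> np.ndarray:
    """Row-major upper triangle (i < j) of a square matrix."""
    R = mat.shape[0]
    iu = np.triu_indices(R, k=1)
    return mat[iu]


def unvectorize(v: np.ndarray, unit_diagonal: bool = True) -> np.ndarray:
    """Inverse of :func:`vectorize`: symmetric matrix with unit diagonal."""
    v = np.asarray(v, dtype=float)
    P = v.shape[0]
    R = int(round((1 + np.sqrt(1 + 8 * P)) / 2))
    if R * (R - 1) // 2 != P:
        raise ValueError(f"length {P} is not a triangular number")
    M = np.zeros((R, R))
    iu = np.triu_indices(R, k=1)
    M[iu] = v
    M += M.T
    if unit_diagonal:
        np.fill_diagonal(M, 1.0)
    return M


def windowed_corr(tc: RoiTimecourse, taper: Optional[TaperWindow] = None,
                  step: int = 1) -> DfcSeries:
    """Weighted Pearson correlation of every ROI pair in each window.

    Windows are indexed by their first time point (0-based); with step 1
    there are ``T - W + 1`` windows.  A pair with zero weighted variance
    in some window gets correlation 0 there and is flagged.
    """
    taper = taper or build_taper()
    W = taper.width_tr
    T, R = tc.data.shape
    if T < W:
        raise ValueError(f"T={T} shorter than window W={W}")
    if step < 1:
        raise ValueError("step must be >= 1")
    w = taper.weights
    starts = np.arange(0, T - W + 1, step)
    iu = np.triu_indices(R, k=1)
    P = R * (R - 1) // 2
    flagged = np.zeros(P, dtype=bool)
    # batched weighted covariance over all windows via a strided view
    windows = np.lib.stride_tricks.sliding_window_view(
        tc.data, W, axis=0)[starts]              # N_w x R x W
    mu = windows @ w                             # N_w x R
    centered = windows - mu[:, :, None]
    cov = np.einsum("nrt,nst,t->nrs", centered, centered, w, optimize=True)
    var = np.einsum("nrr->nr", cov).copy()       # N_w x R
    bad = var <= 1e-12 * np.maximum(1.0, var.max(axis=1, keepdims=True))
    var[bad] = 1.0
    corr = cov / np.sqrt(var[:, :, None] * var[:, None, :])
    if bad.any():
        bad_rows = np.broadcast_to(bad[:, :, None], corr.shape)
        corr = np.where(bad_rows | bad_rows.transpose(0, 2, 1), 0.0, corr)
        any_bad = bad.any(axis=0)
        flagged = vectorize(np.outer(any_bad, np.ones(R, bool))
                            | np.outer(np.ones(R, bool), any_bad))
    out = np.clip(corr[:, iu[0], iu[1]], -1.0, 1.0)
    return DfcSeries(vectors=out, window_start_tr=starts,
                     subject_id=tc.subject_id, scan_id=tc.scan_id,
                     flagged_pairs=flagged if flagged.any() else None)


def pool_series(series: List[DfcSeries]) -> np.ndarray:
    """Stack windowed connectivity vectors of many scans into one matrix."""
    return np.vstack([s.vectors for s in series])
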