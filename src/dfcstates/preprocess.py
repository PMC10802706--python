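"""Post-processing of ROI time courses before connectivity estimation.

Fixed four-step recipe, applied per ROI column:

1. polynomial detrending (constant through cubic),
2. nuisance regression of 6 motion parameters and their derivatives,
3. outlier repair (robust z on median/MAD, linear interpolation),
4. zero-phase Butterworth band-pass (0.01-0.15 Hz by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import RoiTimecourse


class LengthError(ValueError):
    """Series too short for the requested operation."""


@dataclass
class PreprocConfig:
    detrend_max_order: int = 3
    bandpass_lo_hz: float = 0.01
    bandpass_hi_hz: float = 0.15
    outlier_z: float = 3.0
    use_motion: bool = True
    filter_order: int = 5


def detrend_poly(tc: RoiTimecourse, max_order: int = 3) -> RoiTimecourse:
    """Remove polynomial trends of order 0..max_order from each column.

    Projection onto an orthonormal polynomial basis (via QR of the
    Vandermonde matrix), so residuals have exactly zero projection on
    every polynomial up to the requested order.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    T = tc.n_timepoints
    if T <= max_order + 1:
        raise LengthError(f"T={T} too short for order-{max_order} detrend")
    t = np.linspace(-1.0, 1.0, T)
    V = np.vander(t, max_order + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    resid = tc.data - Q @ (Q.T @ tc.data)
    return tc.with_data(resid)


def motion_regressors(motion: np.ndarray) -> np.ndarray:
    """Six realignment parameters plus backward-difference derivatives
    (first sample zero): a T x 12 design."""
    d = np.diff(motion, axis=0, prepend=motion[:1])
    d[0] = 0.0
    return np.hstack([motion, d])


def regress_nuisance(tc: RoiTimecourse, motion: np.ndarray | None = None
                     ) -> RoiTimecourse:
    """Regress out motion parameters, their derivatives and an intercept."""
    if motion is None:
        motion = tc.motion
    if motion is None:
        raise ValueError("no motion parameters available")
    X = np.column_stack([np.ones(tc.n_timepoints), motion_regressors(motion)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient nuisance design; using pseudoinverse",
                      RuntimeWarning, stacklevel=2)
    beta = np.linalg.pinv(X) @ tc.data
    return tc.with_data(tc.data - X @ beta)


def despike(tc: RoiTimecourse, z: float = 3.0) -> RoiTimecourse:
    """Replace outlier samples by linear interpolation between the nearest
    non-outlier neighbors.

    Outliers are samples whose robust z-score (per-column median/MAD,
    MAD scaled by 1.4826 to match sigma under normality) exceeds ``z``.
    Endpoints clamp to the nearest valid value.  A column with more than
    50% outliers is left unmodified with a warning.
    """
    if z <= 0:
        raise ValueError("z must be positive")
    X = tc.data.copy()
    T = X.shape[0]
    t = np.arange(T)
    for j in range(X.shape[1]):
        col = X[:, j]
        med = np.median(col)
        mad = np.median(np.abs(col - med)) * 1.4826
        if mad == 0:
            continue
        bad = np.abs(col - med) / mad > z
        if not bad.any():
            continue
        if bad.mean() > 0.5:
            warnings.warn(f"column {j}: >50% outliers, left unmodified",
                          RuntimeWarning, stacklevel=2)
            continue
        good = ~bad
        X[bad, j] = np.interp(t[bad], t[good], col[good])
    return tc.with_data(X)


def bandpass(tc: RoiTimecourse, lo_hz: float = 0.01, hi_hz: float = 0.15,
             order: int = 5) -> RoiTimecourse:
    """Zero-phase Butterworth band-pass (forward-backward second-order
    sections)."""
    nyq = 1.0 / (2.0 * tc.tr_seconds)
    if not (0 < lo_hz < hi_hz < nyq):
        raise ValueError(
            f"need 0 < lo < hi < Nyquist={nyq:.4g} Hz, got [{lo_hz}, {hi_hz}]")
    sos = signal.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=1.0 / tc.tr_seconds,
                        output="sos")
    padlen = 3 * (2 * order + 1)
    if tc.n_timepoints <= padlen:
        raise LengthError(
            f"T={tc.n_timepoints} shorter than filter warm-up ({padlen})")
    filtered = signal.sosfiltfilt(sos, tc.data, axis=0)
    return tc.with_data(filtered)


def preprocess(tc: RoiTimecourse, config: PreprocConfig | None = None
               ) -> RoiTimecourse:
    """Apply the full recipe in fixed order:
    detrend -> nuisance regression -> despike -> band-pass."""
    cfg = config or PreprocConfig()
    out = detrend_poly(tc, cfg.detrend_max_order)
    if cfg.use_motion and tc.motion is not None:
        out = regress_nuisance(out, tc.motion)
    out = despike(out, cfg.outlier_z)
    out = bandpass(out, cfg.bandpass_lo_hz, cfg.bandpass_hi_hz,
                   cfg.filter_order)
    return out
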