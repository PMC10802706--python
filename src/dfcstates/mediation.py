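"""Three-variable path mediation with bias-corrected bootstrap inference.

The model is the standard single-mediator path diagram: exposure X
(state occupancy), mediator M (mental-health score), outcome Y
(cognitive score), with confounders regressed in every equation:

    M ~ X + covariates            -> a
    Y ~ X + M + covariates        -> c' (direct), b
    Y ~ X + covariates            -> c  (total)

Indirect effect ab = a*b; with identical covariates across OLS fits the
decomposition c = c' + a*b holds to machine precision.  Inference on ab
uses case-resampling bootstrap with the bias-corrected (BC) percentile
interval.  The analysis quantifies shared covariance, not causal
direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.stats import norm


@dataclass
class MediationResult:
    a: float
    b: float
    c_prime: float
    c: float
    ab: float
    proportion_mediated: float
    ci_ab: Tuple[float, float]
    p_ab: float
    n_boot: int
    seed: int
    n: int
    ci_flagged: bool = False    # point estimate outside its own BC interval

    def summary(self) -> str:
        lo, hi = self.ci_ab
        return (f"a={self.a:.4f} b={self.b:.4f} c'={self.c_prime:.4f} "
                f"c={self.c:.4f} ab={self.ab:.4f} "
                f"({100 * self.proportion_mediated:.2f}% of total effect), "
                f"95% BC CI [{lo:.4f}, {hi:.4f}], p={self.p_ab:.4g}, "
                f"n={self.n}, n_boot={self.n_boot}")


def _design(x: np.ndarray, covariates: Optional[np.ndarray],
            extra: Optional[np.ndarray] = None) -> np.ndarray:
    cols = [np.ones_like(x), x]
    if extra is not None:
        cols.append(extra)
    X = np.column_stack(cols)
    if covariates is not None:
        X = np.column_stack([X, covariates])
    return X


def _ols_coef(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    XtX = X.T @ X
    Xty = X.T @ y
    try:
        return np.linalg.solve(XtX, Xty)
    except np.linalg.LinAlgError:
        warnings.warn("collinear design; using pseudoinverse",
                      RuntimeWarning, stacklevel=2)
        return np.linalg.pinv(X) @ y


def fit_paths(x: np.ndarray, m: np.ndarray, y: np.ndarray,
              covariates: Optional[np.ndarray] = None
              ) -> Tuple[float, float, float, float]:
    """OLS path coefficients (a, b, c_prime, c)."""
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    if covariates is not None:
        covariates = np.asarray(covariates, float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
    mask = np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
    if covariates is not None:
        mask &= np.isfinite(covariates).all(axis=1)
    x, m, y = x[mask], m[mask], y[mask]
    cov = covariates[mask] if covariates is not None else None
    if len(x) < 30:
        raise ValueError(f"only {len(x)} complete cases")
    a = _ols_coef(_design(x, cov), m)[1]
    bc = _ols_coef(_design(x, cov, extra=m), y)
    c_prime, b = bc[1], bc[2]
    c = _ols_coef(_design(x, cov), y)[1]
    return float(a), float(b), float(c_prime), float(c)


def _bc_interval(boot: np.ndarray, estimate: float, alpha: float
                 ) -> Tuple[float, float]:
    n = len(boot)
    frac = np.clip(np.mean(boot < estimate), 1.0 / (n + 1), n / (n + 1.0))
    z0 = norm.ppf(frac)
    zl, zu = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
    lo_q = norm.cdf(2 * z0 + zl)
    hi_q = norm.cdf(2 * z0 + zu)
    return (float(np.quantile(boot, lo_q)), float(np.quantile(boot, hi_q)))


def _bc_pvalue(boot: np.ndarray, estimate: float) -> float:
    """Smallest alpha at which the BC interval excludes zero."""
    n = len(boot)
    frac_est = np.clip(np.mean(boot < estimate), 1.0 / (n + 1), n / (n + 1.0))
    z0 = norm.ppf(frac_est)
    frac_zero = np.clip(np.mean(boot < 0.0), 1.0 / (n + 1), n / (n + 1.0))
    z_zero = norm.ppf(frac_zero)
    return float(min(1.0, 2.0 * norm.cdf(-abs(2 * z0 - z_zero))))


def bootstrap_mediation(x: np.ndarray, m: np.ndarray, y: np.ndarray,
                        covariates: Optional[np.ndarray] = None,
                        n_boot: int = 10000, seed: int = 0,
                        alpha: float = 0.05) -> MediationResult:
    """Case-resampling bootstrap of the indirect effect with BC interval.

    Rows of (x, m, y, covariates) are resampled jointly, preserving the
    covariate structure.  Degenerate resamples (zero variance in x) are
    redrawn, with a bounded number of retries.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    if covariates is not None:
        covariates = np.asarray(covariates, float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
    a, b, c_prime, c = fit_paths(x, m, y, covariates)
    ab = a * b
    n = len(x)
    rng = np.random.default_rng(seed)

    # batched bootstrap OLS via normal equations
    Xm = _design(x, covariates)                 # for m ~ x + covs
    Xy = _design(x, covariates, extra=m)        # for y ~ x + m + covs
    boot = np.empty(n_boot)
    for i in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            if x[idx].std() > 0:
                break
        else:
            raise RuntimeError("could not draw non-degenerate resample")
        Xmi, Xyi = Xm[idx], Xy[idx]
        ai = np.linalg.lstsq(Xmi, m[idx], rcond=None)[0][1]
        bi = np.linalg.lstsq(Xyi, y[idx], rcond=None)[0][2]
        boot[i] = ai * bi

    ci = _bc_interval(boot, ab, alpha)
    p = _bc_pvalue(boot, ab)
    prop = ab / c if c != 0 else (1.0 if ab != 0 else 0.0)
    flagged = not (ci[0] <= ab <= ci[1])
    return MediationResult(a=a, b=b, c_prime=c_prime, c=c, ab=ab,
                           proportion_mediated=prop, ci_ab=ci, p_ab=p,
                           n_boot=n_boot, seed=seed, n=n, ci_flagged=flagged)
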