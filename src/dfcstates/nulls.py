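"""Surrogate-data tests of the stationarity null for windowed connectivity.

Two null models generate stationary surrogates that preserve the static
(co)variance structure of a scan:

* VAR bootstrap — fit a vector autoregression by least squares and
  simulate it driven by resampled residuals;
* phase randomization — add one common random phase vector to every
  column's Fourier transform, preserving each power spectrum and all
  stationary cross-spectra.

The test statistic per ROI pair is the temporal standard deviation of
the windowed correlation; the one-sided surrogate p-value uses the
standard (1 + exceedances) / (1 + n_surr) estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dfc import TaperWindow, build_taper, windowed_corr
from .io import RoiTimecourse


@dataclass
class SurrogateResult:
    statistic: str
    method: str
    observed: np.ndarray        # per-pair std of windowed correlation
    null_samples: np.ndarray    # n_surr x n_pairs
    p_values: np.ndarray

    @property
    def fraction_significant(self) -> float:
        return float(np.mean(self.p_values < 0.05))


def fit_var(data: np.ndarray, order: int = 1):
    """Least-squares VAR(p) fit: returns (coefs [p x R x R], intercept,
    residuals)."""
    T, R = data.shape
    if T <= order + R:
        raise ValueError(f"T={T} too short for VAR({order}) with R={R}")
    Y = data[order:]
    X = np.hstack([data[order - k - 1: T - k - 1] for k in range(order)])
    X = np.column_stack([np.ones(len(Y)), X])
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    intercept = B[0]
    coefs = B[1:].reshape(order, R, R).transpose(0, 2, 1)
    resid = Y - X @ B
    return coefs, intercept, resid


def _companion_radius(coefs: np.ndarray) -> float:
    p, R, _ = coefs.shape
    comp = np.zeros((p * R, p * R))
    comp[:R] = np.hstack([coefs[k] for k in range(p)])
    if p > 1:
        comp[R:, :-R] = np.eye((p - 1) * R)
    return float(np.abs(np.linalg.eigvals(comp)).max())


def var_surrogate(tc: RoiTimecourse, order: int = 1, seed: int = 0
                  ) -> RoiTimecourse:
    """Stationary surrogate from a fitted VAR driven by bootstrapped
    residuals (100-step burn-in discarded).  An unstable fit is shrunk to
    spectral radius 0.98 with a warning."""
    coefs, intercept, resid = fit_var(tc.data, order=order)
    radius = _companion_radius(coefs)
    if radius >= 1.0:
        warnings.warn(
            f"unstable VAR fit (radius {radius:.3f}); shrinking to 0.98",
            RuntimeWarning, stacklevel=2)
        shrink = 0.98 / radius
        coefs = np.array([coefs[k] * shrink ** (k + 1)
                          for k in range(coefs.shape[0])])
    rng = np.random.default_rng(seed)
    T, R = tc.data.shape
    p = coefs.shape[0]
    burn = 100
    eps = resid[rng.integers(0, len(resid), size=T + burn)]
    sim = np.zeros((T + burn + p, R))
    sim[:p] = tc.data[:p]
    for t in range(p, T + burn + p):
        acc = intercept.copy()
        for k in range(p):
            acc = acc + coefs[k] @ sim[t - k - 1]
        sim[t] = acc + eps[t - p]
    return tc.with_data(sim[-T:])


def phase_randomize(tc: RoiTimecourse, seed: int = 0) -> RoiTimecourse:
    """Common-phase randomized surrogate.

    One uniform random phase per positive frequency is added to every
    column (DC and Nyquist untouched), so each column's power spectrum
    and every stationary cross-spectrum — hence the static correlation
    structure — are preserved exactly.
    """
    T, R = tc.data.shape
    if T < 8:
        raise ValueError("T must be >= 8 for phase randomization")
    rng = np.random.default_rng(seed)
    F = np.fft.rfft(tc.data, axis=0)
    n_freq = F.shape[0]
    phases = np.zeros(n_freq)
    hi = n_freq - 1 if T % 2 == 0 else n_freq   # leave Nyquist bin real
    phases[1:hi] = rng.uniform(0, 2 * np.pi, size=hi - 1)
    F = F * np.exp(1j * phases)[:, None]
    out = np.fft.irfft(F, n=T, axis=0)
    return tc.with_data(out)


def dfc_fluctuation(tc: RoiTimecourse, taper: TaperWindow) -> np.ndarray:
    """Per-pair temporal std of the windowed correlation series."""
    series = windowed_corr(tc, taper)
    return series.vectors.std(axis=0, ddof=1)


def stationarity_test(tc: RoiTimecourse, taper: TaperWindow | None = None,
                      n_surr: int = 99, method: str = "phase",
                      seed: int = 0, var_order: int = 1) -> SurrogateResult:
    """Test each ROI pair's DFC fluctuation against a stationary null.

    One-sided p per pair: p = (1 + #{null >= observed}) / (1 + n_surr).
    """
    if n_surr < 19:
        raise ValueError("need at least 19 surrogates")
    if method not in ("var", "phase"):
        raise ValueError(f"unknown method {method!r}")
    taper = taper or build_taper()
    observed = dfc_fluctuation(tc, taper)
    rng = np.random.default_rng(seed)
    null = np.empty((n_surr, observed.shape[0]))
    for i in range(n_surr):
        s = int(rng.integers(2 ** 31))
        surr = (var_surrogate(tc, order=var_order, seed=s)
                if method == "var" else phase_randomize(tc, seed=s))
        null[i] = dfc_fluctuation(surr, taper)
    exceed = (null >= observed[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_surr)
    return SurrogateResult(statistic="windowed_corr_std", method=method,
                           observed=observed, null_samples=null, p_values=p)
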