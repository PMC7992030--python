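"""Fractional long-memory (ARFIMA[0, d, 0]) analysis of log-volatility series.

The Hurst parameter of a rough-volatility model and the fractional
differencing parameter d of an ARFIMA[0, d, 0] fit both summarise the
dependence structure of a log-volatility series, so rank agreement between
per-voxel CNN estimates H_hat and ARFIMA estimates d_hat is an independent
consistency check of the calibration.  The model is fractionally
integrated white noise,

    eps_t = (1 - B)^d log sigma_t,

where B is the backshift operator.  0 < d < 0.5 marks a stationary long-
memory process, d < 0 an anti-persistent short-memory one.  d is estimated
by minimising the Whittle (frequency-domain) likelihood, whose spectral
density is f(lambda) proportional to (2 sin(lambda/2))^(-2d); a
conditional-sum-of-squares (time-domain) estimator is available as an
alternative.  Agreement between H_hat and d_hat collections is measured
with a two-sided Spearman rank correlation (average ranks on ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MemoryEstimate", "AgreementReport",
    "fracdiff", "fracdiff_weights", "estimate_d", "simulate_arfima",
    "spearman_agreement",
]

#: Truncation of the binomial expansion of (1 - B)^d.
MAX_LAG = 1000

#: Optimisation bounds for d.
D_BOUND = 0.99


@dataclass(frozen=True)
class MemoryEstimate:
    """Fractional differencing estimate for one series."""

    d_hat: float
    method: str
    converged: bool
    at_bound: bool


@dataclass(frozen=True)
class AgreementReport:
    """Spearman rank agreement between two per-voxel parameter collections."""

    rho: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {"rho": self.rho, "p_value": self.p_value, "n": self.n}


def fracdiff_weights(d: float, n: int) -> np.ndarray:
    """Binomial coefficients of (1 - B)^d up to lag n-1 (stable recursion).

    w_0 = 1, w_k = w_{k-1} * (k - 1 - d) / k.
    """
    w = np.empty(n)
    w[0] = 1.0
    for k in range(1, n):
        w[k] = w[k - 1] * (k - 1 - d) / k
    return w


def fracdiff(series: np.ndarray, d: float, max_lag: int = MAX_LAG) -> np.ndarray:
    """Apply the truncated fractional difference (1 - B)^d causally.

    Returns a series of the same length: y_t = sum_{k<=t} w_k x_{t-k}.
    The first few values carry truncation (burn-in) error by construction;
    d = 0 is the identity, d = 1 gives first differences from index 1 on
    (index 0 keeps the raw initial observation).  Negative d inverts:
    fracdiff(fracdiff(x, d), -d) recovers x away from the burn-in edge.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    n = len(x)
    w = fracdiff_weights(d, min(n, max_lag + 1))
    return np.convolve(x, w)[:n]


def simulate_arfima(d: float, T: int, seed=None, sigma: float = 1.0) -> np.ndarray:
    """Simulate ARFIMA(0, d, 0): fractionally integrated Gaussian noise.

    Built by applying the truncated (1 - B)^(-d) filter to white noise;
    used as the ground-truth oracle for the d estimator.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    eps = sigma * rng.standard_normal(T)
    return fracdiff(eps, -d)


def _whittle_objective(d: float, logI: np.ndarray, log_g_base: np.ndarray) -> float:
    # g_j(d) = (2 sin(lambda_j/2))^(-2d); profile out the innovation variance
    log_g = -2.0 * d * log_g_base
    ratio = logI - log_g
    # log mean exp, stabilised
    m = ratio.max()
    return float(m + np.log(np.mean(np.exp(ratio - m))) + np.mean(log_g))


def estimate_d(log_vol: np.ndarray, method: str = "whittle",
               bound: float = D_BOUND) -> MemoryEstimate:
    """Estimate the ARFIMA(0, d, 0) memory parameter of a series.

    method = "whittle": minimise the profiled Whittle likelihood over the
    periodogram at the positive Fourier frequencies.  method = "css":
    minimise the conditional sum of squares of the fractionally
    differenced (demeaned) series.  Both search d in (-bound, bound);
    estimates at the boundary are flagged.  Short series (< 50 points)
    trigger a warning; a constant series is rejected.
    """
    x = np.asarray(log_vol, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    T = len(x)
    if T < 8:
        raise ValueError("series too short for memory estimation")
    if T < 50:
        warnings.warn(f"series of length {T} < 50; d estimate will be noisy")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no identifiable memory parameter")
    x = x - x.mean()

    if method == "whittle":
        n_freq = (T - 1) // 2
        lam = 2.0 * np.pi * np.arange(1, n_freq + 1) / T
        I = np.abs(np.fft.rfft(x)[1:n_freq + 1]) ** 2 / (2.0 * np.pi * T)
        logI = np.log(np.maximum(I, np.finfo(float).tiny))
        log_g_base = np.log(2.0 * np.sin(lam / 2.0))
        res = optimize.minimize_scalar(
            _whittle_objective, args=(logI, log_g_base),
            bounds=(-bound, bound), method="bounded",
            options={"xatol": 1e-6})
    elif method == "css":
        def css(d):
            return float(np.sum(fracdiff(x, d)[1:] ** 2))
        res = optimize.minimize_scalar(css, bounds=(-bound, bound),
                                       method="bounded", options={"xatol": 1e-6})
    else:
        raise ValueError(f"unknown method {method!r}")

    d_hat = float(res.x)
    converged = bool(res.success)
    at_bound = abs(d_hat) >= bound - 1e-3
    if not converged:
        warnings.warn("d estimation did not converge; estimate flagged")
    return MemoryEstimate(d_hat=d_hat, method=method, converged=converged,
                          at_bound=at_bound)


def spearman_agreement(H_hats, d_hats) -> AgreementReport:
    """Two-sided Spearman rank correlation between H_hat and d_hat sets."""
    h = np.asarray(H_hats, dtype=float)
    d = np.asarray(d_hats, dtype=float)
    if h.shape != d.shape:
        raise ValueError("H and d collections must have matching lengths")
    if len(h) < 3:
        raise ValueError("need at least 3 voxels for a rank correlation")
    if np.ptp(h) == 0 or np.ptp(d) == 0:
        raise ValueError("zero-variance ranks: correlation undefined")
    rho, p = stats.spearmanr(h, d)
    return AgreementReport(rho=float(rho), p_value=float(p), n=len(h))
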