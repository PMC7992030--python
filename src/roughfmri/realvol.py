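"""T2*-weighted realised volatility of multi-echo fMRI noise.

A multi-echo acquisition reads the signal at N echo times within every
repetition time (TR), so the echoes act as intra-time-point replicates.
After per-echo linear detrending, the weighted dispersion of the echoes
about their weighted mean at each volume t gives a realised-variance proxy
v_hat_t for the latent noise volatility — the imaging analogue of building
daily realised volatility from intraday returns.  Weights follow the
T2*-weighted "optimal combination" convention (tedana-style): a per-voxel
T2* is fitted by log-linear regression of the time-averaged echo signal
against echo time, and echo n receives weight proportional to
``E_n * exp(-E_n / T2*)``.

The log of the (floored) realised-variance series, truncated to the
calibrator's input length and demeaned, is the path handed to the CNN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiEchoSeries",
    "T2StarFit",
    "RealisedVolSeries",
    "FDSeries",
    "T2STAR_CAP_MS",
    "detrend_linear",
    "fit_t2star",
    "echo_weights",
    "weighted_mean",
    "realised_variance",
    "realised_vol_series",
    "unweighted_variant",
    "log_floor_normalise",
    "framewise_displacement",
]

#: Upper cap (ms) on credible T2* fits; longer values flag an invalid fit.
T2STAR_CAP_MS = 500.0

#: Rotation-to-translation radius (mm) for framewise displacement
#: (Power convention, as used by spmup_FD).
FD_RADIUS_MM = 50.0


@dataclass
class MultiEchoSeries:
    """One voxel's signal, indexed by echo (rows) and volume (columns).

    values : (N, T) array of signal intensities (arbitrary units)
    echo_times : N echo times E_n in ms, strictly increasing
    voxel_id : optional grid index for bookkeeping
    """

    values: np.ndarray
    echo_times: np.ndarray
    voxel_id: tuple | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (N, T) array")
        n, t = self.values.shape
        if n != len(self.echo_times):
            raise ValueError("echo_times length must match the echo axis")
        if n < 2 or t < 2:
            raise ValueError("need at least 2 echoes and 2 volumes")
        if np.any(np.diff(self.echo_times) <= 0) or np.any(self.echo_times <= 0):
            raise ValueError("echo times must be positive and strictly increasing")

    @property
    def n_echoes(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class T2StarFit:
    """Log-linear mono-exponential decay fit S_n = S0 exp(-E_n / T2*)."""

    s0_hat: float
    r2star_hat: float
    valid: bool

    @property
    def t2star_hat(self) -> float:
        return np.inf if self.r2star_hat == 0 else 1.0 / self.r2star_hat


@dataclass
class RealisedVolSeries:
    """Realised-variance proxy series for one voxel.

    v_hat : length-T nonnegative intra-TR weighted variances
    log_v : log of the floored series (finite everywhere)
    weighted : True when T2*-weighted, False for the equal-weight variant
    """

    v_hat: np.ndarray
    weighted: bool
    floor: float = field(default=None)
    log_v: np.ndarray = field(default=None)

    def __post_init__(self):
        self.v_hat = np.asarray(self.v_hat, dtype=float)
        if np.any(self.v_hat < 0):
            raise ValueError("realised variance must be nonnegative")
        if self.log_v is None:
            self.floor, self.log_v = _floored_log(self.v_hat)


def _floored_log(v_hat: np.ndarray):
    """Floor a variance series away from zero, then take logs.

    The floor is max(machine epsilon, 1e-12 * median positive value), so
    exact zeros (all echoes identical at a volume) stay finite in log space
    without disturbing the rest of the series.
    """
    pos = v_hat[v_hat > 0]
    if pos.size == 0:
        raise ValueError("all-zero realised-variance series has no log representation")
    floor = max(np.finfo(float).eps, 1e-12 * float(np.median(pos)))
    return floor, np.log(np.maximum(v_hat, floor))


@dataclass
class FDSeries:
    """Framewise displacement (mm) per volume; fd[0] = 0 by convention."""

    fd: np.ndarray

    def __post_init__(self):
        self.fd = np.asarray(self.fd, dtype=float)
        if np.any(self.fd < 0):
            raise ValueError("framewise displacement must be nonnegative")


def detrend_linear(series: np.ndarray, axis: int = -1) -> np.ndarray:
    """Residuals of an OLS fit of the series on [intercept, linear time].

    Applied per voxel per echo before echo combination, mirroring the
    standard removal of scanner drift.  Works along ``axis`` for stacked
    input.  Residuals have zero mean and zero covariance with time.
    """
    x = np.asarray(series, dtype=float)
    T = x.shape[axis]
    if T < 3:
        raise ValueError("detrending needs at least 3 time points")
    t = np.arange(T, dtype=float)
    t = (t - t.mean()) / t.std()
    xm = np.moveaxis(x, axis, -1)
    mean = xm.mean(axis=-1, keepdims=True)
    slope = (xm * t).mean(axis=-1, keepdims=True) / (t * t).mean()
    resid = xm - mean - slope * t
    return np.moveaxis(resid, -1, axis)


def fit_t2star(mean_signal_per_echo: np.ndarray, echo_times: np.ndarray,
               cap_ms: float = T2STAR_CAP_MS) -> T2StarFit:
    """Fit S0 and R2* = 1/T2* by OLS on (E_n, log S_n).

    The mean signal per echo (time-averaged, before detrending) must be
    strictly positive.  Fits with nonnegative slope (no decay) or implied
    T2* above ``cap_ms`` are flagged invalid; callers fall back to the
    unweighted combination.
    """
    s = np.asarray(mean_signal_per_echo, dtype=float)
    e = np.asarray(echo_times, dtype=float)
    if len(s) != len(e):
        raise ValueError("signal and echo-time lengths differ")
    if len(s) < 3:
        raise ValueError("need at least 3 echoes for a log-linear T2* fit")
    if np.any(s <= 0):
        raise ValueError("mean echo signal must be positive to take logs")
    slope, intercept = np.polyfit(e, np.log(s), 1)
    r2star = -slope
    valid = r2star > 0 and (1.0 / r2star) <= cap_ms
    return T2StarFit(s0_hat=float(np.exp(intercept)), r2star_hat=float(r2star),
                     valid=bool(valid))


def echo_weights(echo_times: np.ndarray, t2star: float) -> np.ndarray:
    """T2*-based echo weights w_n proportional to E_n exp(-E_n / T2*).

    Normalised to sum to one.  As T2* -> infinity the exponential drops out
    and the weights become proportional to the echo times alone.
    """
    if t2star <= 0:
        raise ValueError(f"t2star must be positive, got {t2star}")
    e = np.asarray(echo_times, dtype=float)
    w = e * np.exp(-e / t2star)
    return w / w.sum()


def weighted_mean(y_t: np.ndarray, w: np.ndarray) -> float:
    """Weighted echo combination ybar_t = sum_n w_n y_{n,t} / sum_n w_n."""
    y = np.asarray(y_t, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.shape != w.shape:
        raise ValueError("echo values and weights have mismatched lengths")
    return float(np.sum(w * y) / np.sum(w))


def realised_variance(y_t: np.ndarray, w: np.ndarray) -> float:
    """Weighted intra-TR variance about the weighted echo mean.

    ``v_hat_t = sum_n w_n (y_{n,t} - ybar_t)^2 / sum_n w_n``; zero exactly
    when all echo values coincide.
    """
    y = np.asarray(y_t, dtype=float)
    w = np.asarray(w, dtype=float)
    if len(y) != len(w):
        raise ValueError("echo values and weights have mismatched lengths")
    if len(y) < 2:
        raise ValueError("need at least 2 echoes for an intra-TR variance")
    ybar = np.sum(w * y) / np.sum(w)
    return float(np.sum(w * (y - ybar) ** 2) / np.sum(w))


def realised_vol_series(series: MultiEchoSeries, detrend: bool = True,
                        weighted: bool = True,
                        cap_ms: float = T2STAR_CAP_MS) -> RealisedVolSeries:
    """Full per-voxel pipeline: detrend, fit T2*, weight, intra-TR variance.

    T2* is fitted on the time-averaged raw signal per echo (detrending
    would destroy the decay levels).  An invalid T2* fit (no decay, or
    T2* above the cap) silently degrades to the unweighted combination
    with a warning.  Vectorised over volumes.
    """
    vals = series.values
    if weighted:
        mean_per_echo = vals.mean(axis=1)
        if np.any(mean_per_echo <= 0):
            warnings.warn("nonpositive mean echo signal; using unweighted combination")
            fit = None
        else:
            fit = fit_t2star(mean_per_echo, series.echo_times, cap_ms=cap_ms)
            if not fit.valid:
                warnings.warn(
                    f"invalid T2* fit for voxel {series.voxel_id} "
                    "(no decay or above cap); using unweighted combination")
                fit = None
    else:
        fit = None

    if fit is None:
        w = np.full(series.n_echoes, 1.0 / series.n_echoes)
        is_weighted = False
    else:
        w = echo_weights(series.echo_times, fit.t2star_hat)
        is_weighted = True

    y = detrend_linear(vals, axis=1) if detrend else vals
    ybar = w @ y                      # weights already sum to 1
    v_hat = w @ (y - ybar) ** 2
    return RealisedVolSeries(v_hat=v_hat, weighted=is_weighted and weighted)


def unweighted_variant(series: MultiEchoSeries, detrend: bool = True) -> RealisedVolSeries:
    """Equal-weight (w_n = 1/N) realised-volatility series."""
    return realised_vol_series(series, detrend=detrend, weighted=False)


def log_floor_normalise(rv: RealisedVolSeries, target_len: int) -> np.ndarray:
    """Turn a realised-variance series into a CNN-ready log-volatility path.

    Takes the floored log series, truncates to the first ``target_len``
    volumes (truncation preserves the sampling interval, unlike
    interpolation), and removes the mean.  Requires T >= target_len.
    """
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    log_v = rv.log_v
    if len(log_v) < target_len:
        raise ValueError(
            f"series length {len(log_v)} shorter than target length {target_len}")
    path = log_v[:target_len]
    return path - path.mean()


def framewise_displacement(motion: np.ndarray,
                           radius_mm: float = FD_RADIUS_MM) -> FDSeries:
    """Power-style framewise displacement from 6 rigid-body parameters.

    ``fd_t = sum |delta translations| + radius * sum |delta rotations|``
    with columns ordered (x, y, z translations in mm; pitch, roll, yaw in
    rad) as in SPM rp_*.txt files; fd_1 = 0.
    """
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, got shape {m.shape}")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 volumes for framewise displacement")
    d = np.abs(np.diff(m, axis=0))
    fd = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    return FDSeries(fd=np.concatenate([[0.0], fd]))
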