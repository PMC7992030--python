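"""Exact simulation of the rough Bergomi (rBergomi) log-volatility process.

The rBergomi model describes a variance process

    v_t = xi0 * exp( eta * int_0^t (t-s)^(H-1/2) dW_s  -  (1/2) eta^2 t^(2H) )

driven by a Riemann-Liouville fractional kernel with Hurst parameter
``H in (0, 1)``: ``H < 0.5`` produces paths rougher than Brownian motion,
``H = 0.5`` recovers standard Brownian motion.  The *normalised
log-volatility process*

    vtilde_t = eta * int_0^t (t-s)^(H-1/2) dW_s

is a centred Gaussian process whose finite-dimensional law is known in
closed form, so sample paths on a grid can be drawn *exactly* by Cholesky
factorisation of the analytic covariance matrix — no Euler discretisation
error.  This module provides that simulator, the analogous exact fractional
Brownian motion simulator, and the construction of labelled training sets
of log-volatility paths for the CNN calibrator.

Notes on the kernel normalisation
---------------------------------
By the Ito isometry the kernel above gives ``Var(vtilde_t) =
eta^2 t^(2H) / (2H)``, while the drift compensator ``eta^2 t^(2H) / 2``
matches a kernel carrying an extra ``sqrt(2H)`` factor (the convention of
the original rBergomi literature).  Both conventions are supported: the
default implements the kernel exactly as written above; passing
``normalised_kernel=True`` multiplies the kernel by ``sqrt(2H)`` so that
``Var(vtilde_t) = eta^2 t^(2H)`` and ``E[v_t] = xi0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import integrate, linalg, special

__all__ = [
    "RBergomiParams",
    "TimeGrid",
    "LabelledPathSet",
    "rl_covariance",
    "rl_covariance_quad",
    "fbm_covariance",
    "covariance_matrix",
    "cholesky_factor",
    "simulate_logvol",
    "variance_process",
    "simulate_fbm",
    "sample_training_set",
    "split_nested",
]

_JITTER_START = 1e-12
_JITTER_MAX = 1e-8


@dataclass(frozen=True)
class RBergomiParams:
    """Parameters of one voxel's rBergomi noise-volatility process.

    Parameters
    ----------
    H : float
        Hurst (roughness) parameter, in the open interval (0, 1).
    eta : float
        Volatility of volatility, > 0 (``eta = 0`` is accepted and means
        constant volatility).
    xi0 : float
        Initial variance level, > 0; the model's flat forward-variance curve.
    rho : float
        Leverage correlation in [-1, 1].  Stored for completeness; the
        price-path half of the model is not simulated here.
    """

    H: float
    eta: float
    xi0: float = 1.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.H < 1.0:
            raise ValueError(f"H must be in (0, 1), got {self.H}")
        if self.eta < 0.0:
            raise ValueError(f"eta must be >= 0, got {self.eta}")
        if self.xi0 <= 0.0:
            raise ValueError(f"xi0 must be > 0, got {self.xi0}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [-1, 1], got {self.rho}")


@dataclass(frozen=True)
class TimeGrid:
    """Equispaced simulation grid t_i = i/M on (0, 1], i = 1..M.

    The unit-interval convention is harmless for H estimation: H is
    invariant under affine rescaling of time, so a series of T scanner
    volumes is identified with the grid t_i = i/T.
    """

    M: int

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError(f"grid must have at least one point, got M={self.M}")

    @property
    def t(self) -> np.ndarray:
        return np.arange(1, self.M + 1) / self.M


def rl_covariance(s, t, H: float, normalised_kernel: bool = False):
    """Covariance of the unit-eta log-volatility process at times s, t.

    ``Cov(vtilde_s, vtilde_t) / eta^2 = int_0^min(s,t) (s-r)^(H-1/2)
    (t-r)^(H-1/2) dr``, evaluated in closed form through the Gauss
    hypergeometric function: for ``s <= t``

        C(s, t) = s^(H+1/2) t^(H-1/2) / (H+1/2)
                  * 2F1(1/2 - H, 1; H + 3/2; s/t)

    so that ``C(t, t) = t^(2H) / (2H)``.  For ``H = 0.5`` this reduces to
    ``min(s, t)`` (standard Brownian motion).  Accepts scalars or arrays.
    """
    if not 0.0 < H < 1.0:
        raise ValueError(f"H must be in (0, 1), got {H}")
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(s <= 0) or np.any(t <= 0):
        raise ValueError("times must be strictly positive")
    lo = np.minimum(s, t)
    hi = np.maximum(s, t)
    ratio = lo / hi
    c = (
        lo ** (H + 0.5)
        * hi ** (H - 0.5)
        / (H + 0.5)
        * special.hyp2f1(0.5 - H, 1.0, H + 1.5, ratio)
    )
    if normalised_kernel:
        c = 2.0 * H * c
    return c if c.ndim else float(c)


def rl_covariance_quad(s: float, t: float, H: float,
                       normalised_kernel: bool = False) -> float:
    """Adaptive-quadrature evaluation of the same covariance integral.

    Independent of :func:`rl_covariance`; used as a cross-check of the
    hypergeometric closed form (the integrand has an integrable endpoint
    singularity for H < 1/2, handled by quad's weighted endpoints).
    """
    if not 0.0 < H < 1.0:
        raise ValueError(f"H must be in (0, 1), got {H}")
    if s <= 0 or t <= 0:
        raise ValueError("times must be strictly positive")
    lo, hi = min(s, t), max(s, t)
    g = H - 0.5
    val, _ = integrate.quad(
        lambda r: (lo - r) ** g * (hi - r) ** g, 0.0, lo,
        points=[lo], limit=200, epsabs=1e-12, epsrel=1e-12,
    )
    return 2.0 * H * val if normalised_kernel else val


def fbm_covariance(s, t, H: float):
    """Fractional-Brownian-motion covariance (1/2)(s^2H + t^2H - |t-s|^2H)."""
    if not 0.0 < H < 1.0:
        raise ValueError(f"H must be in (0, 1), got {H}")
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    c = 0.5 * (s ** (2 * H) + t ** (2 * H) - np.abs(t - s) ** (2 * H))
    return c if c.ndim else float(c)


def _tri_cache(M: int):
    iu = np.triu_indices(M)
    t = np.arange(1, M + 1) / M
    return iu, t[iu[0]], t[iu[1]]


def covariance_matrix(grid: TimeGrid, H: float, kind: str = "rl",
                      normalised_kernel: bool = False) -> np.ndarray:
    """Dense covariance matrix of the chosen Gaussian process on the grid.

    kind = "rl" gives the Riemann-Liouville log-volatility kernel,
    kind = "fbm" fractional Brownian motion.
    """
    M = grid.M
    iu, s_u, t_u = _tri_cache(M)
    if kind == "rl":
        vals = rl_covariance(s_u, t_u, H, normalised_kernel=normalised_kernel)
    elif kind == "fbm":
        vals = fbm_covariance(s_u, t_u, H)
    else:
        raise ValueError(f"unknown covariance kind {kind!r}")
    C = np.empty((M, M))
    C[iu] = vals
    C[iu[1], iu[0]] = vals
    return C


@lru_cache(maxsize=128)
def _cholesky_cached(M: int, H: float, kind: str, normalised_kernel: bool):
    C = covariance_matrix(TimeGrid(M), H, kind=kind,
                          normalised_kernel=normalised_kernel)
    scale = np.max(np.diag(C))
    jitter = 0.0
    last_err = None
    while True:
        try:
            return linalg.cholesky(C + jitter * np.eye(M), lower=True)
        except linalg.LinAlgError as err:
            last_err = err
            jitter = _JITTER_START * scale if jitter == 0.0 else jitter * 10.0
            if jitter > _JITTER_MAX * scale:
                break
    raise linalg.LinAlgError(
        f"covariance for M={M}, H={H} not positive definite after jitter "
        f"escalation to {jitter:.1e}"
    ) from last_err


def cholesky_factor(grid: TimeGrid, H: float, kind: str = "rl",
                    normalised_kernel: bool = False) -> np.ndarray:
    """Lower-triangular L with L L^T equal to the grid covariance matrix.

    Deterministic for a given (grid, H); factors are cached per unique
    (M, H, kind) so that large path ensembles sharing parameters factorise
    once.  If plain factorisation fails, diagonal jitter starting at
    1e-12 * max(diag) and escalating tenfold up to 1e-8 is applied before
    declaring the (grid, H) combination ill-conditioned.
    """
    if not 0.0 < H < 1.0:
        raise ValueError(f"H must be in (0, 1), got {H}")
    return _cholesky_cached(grid.M, float(H), kind, bool(normalised_kernel))


def simulate_logvol(params: RBergomiParams, grid: TimeGrid, n_paths: int,
                    seed=None, normalised_kernel: bool = False) -> np.ndarray:
    """Draw exact sample paths of the normalised log-volatility process.

    Each path is ``eta * L z`` with ``z`` i.i.d. standard normal and ``L``
    the Cholesky factor of the unit-eta covariance, so the returned
    ``(n_paths, M)`` array has exactly the finite-dimensional law of
    vtilde on the grid.  Reproducible under ``seed`` (an int or a
    ``numpy.random.Generator``).
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    z = rng.standard_normal((n_paths, grid.M))
    if params.eta == 0.0:
        return np.zeros((n_paths, grid.M))
    L = cholesky_factor(grid, params.H, normalised_kernel=normalised_kernel)
    return params.eta * (z @ L.T)


def variance_process(logvol: np.ndarray, params: RBergomiParams,
                     grid: TimeGrid) -> np.ndarray:
    """Map log-volatility paths to the strictly positive variance process.

    ``v_t = xi0 * exp(vtilde_t - (1/2) eta^2 t^(2H))``.  With the
    sqrt(2H)-normalised kernel the compensator makes v a martingale in
    expectation (``E[v_t] = xi0``); with the verbatim kernel the
    compensator over-corrects by the factor 2H in the variance.
    """
    t = grid.t
    comp = 0.5 * params.eta ** 2 * t ** (2 * params.H)
    v = params.xi0 * np.exp(np.asarray(logvol) - comp)
    return v


def simulate_fbm(H: float, grid: TimeGrid, n_paths: int, seed=None) -> np.ndarray:
    """Exact fractional Brownian motion paths on the grid via Cholesky."""
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    L = cholesky_factor(grid, H, kind="fbm")
    z = rng.standard_normal((n_paths, grid.M))
    return z @ L.T


@dataclass
class LabelledPathSet:
    """Simulated log-volatility paths with per-path (H, eta) ground truth.

    ``labels`` holds the CNN regression targets ``(H, tanh(eta))`` — the
    eta axis is tanh-compressed so that both targets are bounded and
    comparably scaled.  ``partition`` tags each path 'train' / 'val' /
    'test' once :func:`split_nested` has run (empty string before).
    """

    paths: np.ndarray          # (P, M) float
    H: np.ndarray              # (P,) raw Hurst labels
    eta: np.ndarray            # (P,) raw vol-of-vol labels
    grid: TimeGrid
    seed: int | None = None
    partition: np.ndarray = field(default=None)  # (P,) of {'', 'train', 'val', 'test'}

    def __post_init__(self):
        if self.partition is None:
            self.partition = np.full(len(self.H), "", dtype="<U5")
        if not (len(self.paths) == len(self.H) == len(self.eta) == len(self.partition)):
            raise ValueError("inconsistent path/label/partition lengths")

    @property
    def labels(self) -> np.ndarray:
        return np.column_stack([self.H, np.tanh(self.eta)])

    def subset(self, tag: str) -> "LabelledPathSet":
        m = self.partition == tag
        return LabelledPathSet(self.paths[m], self.H[m], self.eta[m],
                               self.grid, self.seed, self.partition[m])

    def save(self, path) -> None:
        """Serialise to a single .npz container (format version 1)."""
        np.savez_compressed(
            path, format_version=1, paths=self.paths, H=self.H, eta=self.eta,
            M=self.grid.M, seed=-1 if self.seed is None else self.seed,
            partition=self.partition,
        )

    @classmethod
    def load(cls, path) -> "LabelledPathSet":
        with np.load(path, allow_pickle=False) as z:
            seed = int(z["seed"])
            return cls(z["paths"], z["H"], z["eta"], TimeGrid(int(z["M"])),
                       None if seed == -1 else seed, z["partition"].astype("<U5"))


def sample_training_set(P: int, grid: TimeGrid, H_range=(0.0, 1.0),
                        eta_range=(0.0, 3.0), seed=None,
                        normalised_kernel: bool = False) -> LabelledPathSet:
    """Simulate P labelled log-volatility paths for calibrator training.

    Per path, H ~ Unif(H_range) and eta ~ Unif(eta_range) are drawn
    independently and the path is simulated exactly with its own (H, eta);
    every (H, eta) pair is unique (duplicates and boundary values are
    rejection-resampled).  Paths are stored float32.
    """
    if P < 10:
        raise ValueError("P must be >= 10")
    h_lo, h_hi = H_range
    e_lo, e_hi = eta_range
    if not (0.0 <= h_lo < h_hi <= 1.0) or not (0.0 <= e_lo < e_hi):
        raise ValueError("degenerate or invalid H/eta ranges")
    rng = np.random.default_rng(seed)

    H = rng.uniform(h_lo, h_hi, P)
    eta = rng.uniform(e_lo, e_hi, P)
    # open-interval + uniqueness contract: resample boundary hits and duplicates
    for _ in range(100):
        bad = (H <= max(h_lo, 0.0)) | (H >= min(h_hi, 1.0)) | (eta <= e_lo)
        pairs, first = np.unique(np.column_stack([H, eta]), axis=0, return_index=True)
        dup = np.ones(P, dtype=bool)
        dup[first] = False
        bad |= dup
        if not bad.any():
            break
        H[bad] = rng.uniform(h_lo, h_hi, bad.sum())
        eta[bad] = rng.uniform(e_lo, e_hi, bad.sum())
    else:  # pragma: no cover - probability ~0
        raise RuntimeError("could not draw unique (H, eta) pairs")

    iu, s_u, t_u = _tri_cache(grid.M)
    paths = np.empty((P, grid.M), dtype=np.float32)
    C = np.empty((grid.M, grid.M))
    z = rng.standard_normal((P, grid.M))
    for p in range(P):
        vals = rl_covariance(s_u, t_u, H[p], normalised_kernel=normalised_kernel)
        C[iu] = vals
        C[iu[1], iu[0]] = vals
        try:
            L = linalg.cholesky(C, lower=True)
        except linalg.LinAlgError:
            L = cholesky_factor(grid, H[p], normalised_kernel=normalised_kernel)
        paths[p] = (eta[p] * (L @ z[p])).astype(np.float32)
    return LabelledPathSet(paths, H, eta, grid,
                           seed if isinstance(seed, (int, np.integer)) else None)


def split_nested(pathset: LabelledPathSet, test_frac: float = 0.3,
                 val_frac: float = 0.2, seed=None) -> LabelledPathSet:
    """Assign the nested train/validation/test partition in place.

    First ``round(P * test_frac)`` paths are held out as the test set; the
    remainder is split again with ``round(remainder * val_frac)``
    validation paths.  At P = 50,000 with the default 30%/20% holdouts
    this gives 28,000 / 7,000 / 15,000 train/val/test.  Assignment is a
    seeded permutation; the partition is disjoint and exhaustive.
    """
    if not (0.0 < test_frac < 1.0 and 0.0 < val_frac < 1.0):
        raise ValueError("fractions must lie in (0, 1)")
    P = len(pathset.H)
    n_test = int(round(P * test_frac))
    rem = P - n_test
    n_val = int(round(rem * val_frac))
    n_train = rem - n_val
    if min(n_test, n_val, n_train) < 1:
        raise ValueError(f"P={P} too small for nonempty train/val/test partitions")
    rng = np.random.default_rng(seed)
    order = rng.permutation(P)
    part = np.empty(P, dtype="<U5")
    part[order[:n_train]] = "train"
    part[order[n_train:n_train + n_val]] = "val"
    part[order[n_train + n_val:]] = "test"
    pathset.partition = part
    return pathset
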