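"""Synthetic multi-echo phantoms with known rBergomi noise volatility.

Every downstream stage (realised volatility, CNN calibration, ARFIMA
memory) is testable against ground truth because this generator builds
multi-echo 4-D volumes whose noise has a *known* (H, eta, xi0) volatility
structure.  Per voxel, the clean signal decays mono-exponentially over the
echo train,

    mu_n = S0 * exp(-E_n / T2*),

and each volume t adds heteroscedastic Gaussian noise, independent across
echoes within a TR,

    y_{n,t} = mu_n + noise_scale * sqrt(v_t) * eps_{n,t},

with v_t an exact rBergomi variance path on the unit-interval grid
t_i = i/T.  Echo-wise independence of the noise is the generator's core
assumption: it is what lets the intra-TR echo dispersion estimate v_t.

Seeding is counter-based: each voxel's noise stream is derived from the
master seed and the voxel's flattened grid index, so traversal order can
never change the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .rbergomi import RBergomiParams, TimeGrid, simulate_logvol, variance_process
from .realvol import MultiEchoSeries

__all__ = [
    "PhantomSpec",
    "SyntheticDataset",
    "simulate_voxel_series",
    "simulate_phantom",
    "write_nifti_per_echo",
    "read_multi_echo",
    "make_motion_fixture",
    "DEFAULT_ECHO_TIMES_MS",
]

#: Eight-echo train of a 3T multi-echo EPI phantom acquisition (ms).
DEFAULT_ECHO_TIMES_MS = (12.0, 28.0, 44.0, 60.0, 76.0, 92.0, 108.0, 124.0)

#: Refuse to materialise datasets above this element count (memory guard).
MAX_ELEMENTS = int(2e8)


@dataclass
class PhantomSpec:
    """Full description of one synthetic multi-echo phantom.

    Per-voxel maps may be scalars (broadcast) or arrays of ``grid_shape``.
    ``h_map``/``eta_map``/``xi0_map`` hold the rBergomi parameters of each
    voxel's noise-volatility process; ``s0_map``/``t2star_map`` the decay
    model; ``noise_scale`` converts sqrt-variance to signal units.
    """

    grid_shape: tuple
    echo_times: tuple = DEFAULT_ECHO_TIMES_MS
    n_volumes: int = 200
    s0_map: np.ndarray | float = 1000.0
    t2star_map: np.ndarray | float = 50.0
    h_map: np.ndarray | float = 0.1
    eta_map: np.ndarray | float = 1.5
    xi0_map: np.ndarray | float = 1.0
    noise_scale: float = 20.0
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if len(self.grid_shape) != 3 or any(g < 1 for g in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        et = np.asarray(self.echo_times, dtype=float)
        if len(et) < 3:
            raise ValueError("need at least 3 echoes (variance needs replicates, "
                             "T2* fit needs 3 points)")
        if np.any(et <= 0) or np.any(np.diff(et) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        if self.n_volumes < 2:
            raise ValueError("need at least 2 volumes")
        for name in ("s0_map", "t2star_map", "h_map", "eta_map", "xi0_map"):
            arr = np.broadcast_to(np.asarray(getattr(self, name), dtype=float),
                                  self.grid_shape).copy()
            setattr(self, name, arr)
        if np.any(self.s0_map <= 0) or np.any(self.t2star_map <= 0):
            raise ValueError("S0 and T2* must be positive everywhere")
        if np.any((self.h_map <= 0) | (self.h_map >= 1)):
            raise ValueError("H must lie in (0, 1) everywhere")
        if np.any(self.eta_map < 0) or np.any(self.xi0_map <= 0):
            raise ValueError("eta must be >= 0 and xi0 > 0 everywhere")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        n_elem = int(np.prod(self.grid_shape)) * len(et) * self.n_volumes
        if n_elem > MAX_ELEMENTS:
            raise ValueError(
                f"dataset would hold {n_elem:.2e} elements, above the "
                f"{MAX_ELEMENTS:.0e} guard; shrink the grid or raise MAX_ELEMENTS")

    @classmethod
    def stratified_h(cls, grid_shape, h_values=(0.05, 0.2, 0.4), **kwargs):
        """Phantom whose voxels cycle through fixed H strata.

        Voxels are assigned H values round-robin in flattened order, giving
        (near-)equal strata for parameter-recovery experiments.
        """
        n_vox = int(np.prod(grid_shape))
        h = np.asarray(h_values, dtype=float)[np.arange(n_vox) % len(h_values)]
        return cls(grid_shape=tuple(grid_shape), h_map=h.reshape(tuple(grid_shape)),
                   **kwargs)

    def voxel_params(self, idx: tuple) -> RBergomiParams:
        return RBergomiParams(H=float(self.h_map[idx]), eta=float(self.eta_map[idx]),
                              xi0=float(self.xi0_map[idx]))


@dataclass
class SyntheticDataset:
    """Ground-truth container: 5-D volumes plus the latent variance paths.

    volumes : (x, y, z, echo, time) signal array
    v_true  : (x, y, z, time) variance path each voxel's noise actually used
    spec    : the generating PhantomSpec
    """

    volumes: np.ndarray
    v_true: np.ndarray
    spec: PhantomSpec

    def __post_init__(self):
        gx = self.spec.grid_shape
        n, t = len(self.spec.echo_times), self.spec.n_volumes
        if self.volumes.shape != gx + (n, t):
            raise ValueError("volumes shape inconsistent with spec")
        if self.v_true.shape != gx + (t,):
            raise ValueError("truth shape inconsistent with spec")
        if np.any(self.v_true <= 0):
            raise ValueError("stored truth variance paths must be strictly positive")

    def voxel_series(self, idx: tuple) -> MultiEchoSeries:
        return MultiEchoSeries(self.volumes[idx], np.asarray(self.spec.echo_times),
                               voxel_id=idx)

    def truth_table(self):
        """Flat (voxel index, H, eta, xi0) table as a pandas DataFrame."""
        import pandas as pd
        idx = np.array(list(np.ndindex(self.spec.grid_shape)))
        return pd.DataFrame({
            "x": idx[:, 0], "y": idx[:, 1], "z": idx[:, 2],
            "H": self.spec.h_map.ravel(), "eta": self.spec.eta_map.ravel(),
            "xi0": self.spec.xi0_map.ravel(),
        })


def _voxel_rng(seed: int, flat_index: int) -> np.random.Generator:
    """Counter-based per-voxel stream: independent of traversal order."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(flat_index,)))


def simulate_voxel_series(params: RBergomiParams, echo_times, T: int, seed,
                          s0: float = 1000.0, t2star: float = 50.0,
                          noise_scale: float = 20.0,
                          normalised_kernel: bool = False):
    """Simulate one voxel's multi-echo series with known volatility truth.

    Returns ``(series, truth)`` where ``truth`` is a dict with the exact
    variance path ``v`` (length T), the log-volatility path ``logvol``,
    and ``params``.  ``seed`` may be an int or a Generator.
    """
    echo_times = np.asarray(echo_times, dtype=float)
    if len(echo_times) < 2 or np.any(np.diff(echo_times) <= 0):
        raise ValueError("need >= 2 strictly increasing echo times")
    if T < 2:
        raise ValueError("need at least T = 2 volumes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = TimeGrid(T)
    logvol = simulate_logvol(params, grid, 1, seed=rng,
                             normalised_kernel=normalised_kernel)[0]
    v = variance_process(logvol, params, grid)
    mu = s0 * np.exp(-echo_times / t2star)             # (N,)
    eps = rng.standard_normal((len(echo_times), T))
    values = mu[:, None] + noise_scale * np.sqrt(v)[None, :] * eps
    series = MultiEchoSeries(values, echo_times)
    return series, {"v": v, "logvol": logvol, "params": params}


def simulate_phantom(spec: PhantomSpec,
                     normalised_kernel: bool = False) -> SyntheticDataset:
    """Vectorised multi-echo phantom: one independent noise stream per voxel.

    Identical seeds give bit-identical datasets.  Cholesky factors are
    cached per unique H, so stratified phantoms cost one factorisation per
    stratum.
    """
    gx = spec.grid_shape
    n_echo, T = len(spec.echo_times), spec.n_volumes
    volumes = np.empty(gx + (n_echo, T))
    v_true = np.empty(gx + (T,))
    for flat, idx in enumerate(np.ndindex(gx)):
        series, truth = simulate_voxel_series(
            spec.voxel_params(idx), spec.echo_times, T,
            _voxel_rng(spec.seed, flat),
            s0=float(spec.s0_map[idx]), t2star=float(spec.t2star_map[idx]),
            noise_scale=spec.noise_scale, normalised_kernel=normalised_kernel)
        volumes[idx] = series.values
        v_true[idx] = truth["v"]
    return SyntheticDataset(volumes=volumes, v_true=v_true, spec=spec)


def write_nifti_per_echo(dataset: SyntheticDataset, out_dir) -> list:
    """Write one 4-D NIfTI-1 file per echo (identity affine, float32).

    Also writes ``truth.tsv`` (voxel index, H, eta, xi0) and
    ``echo_times_ms.txt`` sidecars.  Returns the echo file paths.
    """
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for n in range(len(dataset.spec.echo_times)):
        img = nib.Nifti1Image(dataset.volumes[..., n, :].astype(np.float32),
                              np.eye(4))
        p = out_dir / f"echo-{n + 1:02d}_bold.nii"
        nib.save(img, p)
        paths.append(p)
    dataset.truth_table().to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    np.savetxt(out_dir / "echo_times_ms.txt",
               np.asarray(dataset.spec.echo_times), fmt="%.6g")
    return paths


def read_multi_echo(paths, echo_times, mask=None) -> list:
    """Read per-echo 4-D NIfTI files into per-voxel MultiEchoSeries.

    All echo files must share grid shape and volume count.  ``mask`` may
    be a NIfTI path or a boolean/binary array of the grid shape; voxels
    are returned in flattened-index order.  An all-zero mask yields an
    empty list with a warning (degenerate but not an error, mirroring
    empty anatomical masks).
    """
    data = []
    shape = None
    for p in paths:
        arr = np.asanyarray(nib.load(str(p)).dataobj).astype(float)
        if arr.ndim != 4:
            raise ValueError(f"{p} is not a 4-D NIfTI file")
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(
                f"echo file {p} has shape {arr.shape}, expected {shape}")
        data.append(arr)
    echo_times = np.asarray(echo_times, dtype=float)
    if len(echo_times) != len(data):
        raise ValueError("number of echo files and echo times differ")
    stack = np.stack(data, axis=3)      # (x, y, z, echo, time)

    if mask is None:
        mask_arr = np.ones(shape[:3], dtype=bool)
    else:
        if isinstance(mask, (str, bytes)) or hasattr(mask, "__fspath__"):
            mask_arr = np.asanyarray(nib.load(str(mask)).dataobj) > 0
        else:
            mask_arr = np.asarray(mask) > 0
        if mask_arr.shape != shape[:3]:
            raise ValueError(
                f"mask shape {mask_arr.shape} does not match grid {shape[:3]}")
    if not mask_arr.any():
        warnings.warn("mask selects no voxels; returning an empty collection")
        return []
    return [MultiEchoSeries(stack[idx], echo_times, voxel_id=idx)
            for idx in np.ndindex(shape[:3]) if mask_arr[idx]]


def make_motion_fixture(T: int, spikes=()) -> np.ndarray:
    """Toy 6-column rigid-body motion table (SPM rp_*.txt convention).

    Zero everywhere except x-translation spikes at the given 1-based
    ``(frame, magnitude_mm)`` pairs.
    """
    if T < 2:
        raise ValueError("need at least 2 frames")
    table = np.zeros((T, 6))
    for frame, mag in spikes:
        if not 1 <= frame <= T:
            raise ValueError(f"spike frame {frame} outside 1..{T}")
        table[frame - 1, 0] = mag
    return table
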