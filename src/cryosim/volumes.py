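"""Volume representations of the scattering potential.

Two concrete representations are provided:

* :class:`GaussianMixtureVolume` — an atomic model where each center carries
  one isotropic 3D Gaussian with amplitude ``a`` (integrated potential) and
  variance ``b`` in Å².  Each Gaussian is normalized to unit integral before
  scaling, so the total integrated potential is ``sum(amplitudes)``.
* :class:`RealVoxelVolume` / :class:`FourierVoxelVolume` — a cubic voxel grid
  of the potential and its centered discrete Fourier transform, used for
  Fourier-slice projection.

Grids are cubic with even side; the real-space origin is the voxel at index
``side // 2`` on each axis.  Voxel arrays are indexed ``[z, y, x]`` so the
slowest axis is z, matching the single-particle MRC convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._grids import coords_1d, ft3, ift3

__all__ = [
    "GaussianMixtureVolume",
    "RealVoxelVolume",
    "FourierVoxelVolume",
    "evaluate_gmm",
    "rasterize_gmm",
    "fourier_from_real",
    "real_from_fourier",
    "uniform_gmm",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GaussianMixtureVolume:
    """Sum of isotropic 3D Gaussians: one (amplitude, variance) pair per center.

    Parameters
    ----------
    centers : (N, 3) float array, Å
    amplitudes : (N,) nonnegative floats — integrated potential per Gaussian
    variances : (N,) positive floats, Å²
    """

    centers: np.ndarray
    amplitudes: np.ndarray
    variances: np.ndarray

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.centers, dtype=float))
        a = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        b = np.atleast_1d(np.asarray(self.variances, dtype=float))
        if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 1:
            raise ValueError("centers must be an (N, 3) array with N >= 1")
        if a.shape == (1,) and c.shape[0] > 1:
            a = np.full(c.shape[0], a[0])
        if b.shape == (1,) and c.shape[0] > 1:
            b = np.full(c.shape[0], b[0])
        if a.shape != (c.shape[0],) or b.shape != (c.shape[0],):
            raise ValueError("amplitudes and variances must match the number of centers")
        if not np.all(np.isfinite(c)):
            raise ValueError("centers must be finite")
        if np.any(b <= 0):
            raise ValueError("variances must be positive")
        if np.any(a < 0):
            raise ValueError("amplitudes must be nonnegative")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "variances", b)

    @property
    def n_centers(self) -> int:
        return self.centers.shape[0]

    @property
    def total_amplitude(self) -> float:
        return float(self.amplitudes.sum())

    def with_centers(self, centers: np.ndarray) -> "GaussianMixtureVolume":
        return GaussianMixtureVolume(centers, self.amplitudes, self.variances)


def uniform_gmm(
    centers: np.ndarray, amplitude: float = 1.0, variance: float = 1.0
) -> GaussianMixtureVolume:
    """Mixture with equal weight and variance at every center (coarse-grained
    C-alpha style model)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    n = centers.shape[0]
    return GaussianMixtureVolume(centers, np.full(n, amplitude), np.full(n, variance))


@dataclass(frozen=True)
class RealVoxelVolume:
    """Real-valued potential on a cubic voxel grid (axis order z, y, x)."""

    grid: np.ndarray
    voxel_size: float

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 3 or len(set(g.shape)) != 1:
            raise ValueError("grid must be a cubic 3D array")
        if g.shape[0] % 2 != 0:
            raise ValueError("grid side must be even")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        object.__setattr__(self, "grid", g)

    @property
    def side(self) -> int:
        return self.grid.shape[0]

    @property
    def integral(self) -> float:
        return float(self.grid.sum() * self.voxel_size**3)


@dataclass(frozen=True)
class FourierVoxelVolume:
    """Centered DFT of a real cubic volume; Hermitian up to roundoff."""

    grid: np.ndarray
    voxel_size: float

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=complex)
        if g.ndim != 3 or len(set(g.shape)) != 1:
            raise ValueError("grid must be a cubic 3D array")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        object.__setattr__(self, "grid", g)

    @property
    def side(self) -> int:
        return self.grid.shape[0]


def evaluate_gmm(vol: GaussianMixtureVolume, points: np.ndarray) -> np.ndarray:
    """Evaluate the mixture potential at M points (Å); returns M values.

    value(p) = sum_i a_i (2 pi b_i)^(-3/2) exp(-|p - c_i|^2 / (2 b_i))
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")
    d2 = np.sum((points[:, None, :] - vol.centers[None, :, :]) ** 2, axis=-1)
    norm = vol.amplitudes * (2.0 * np.pi * vol.variances) ** (-1.5)
    return np.sum(norm[None, :] * np.exp(-d2 / (2.0 * vol.variances[None, :])), axis=1)


def rasterize_gmm(
    vol: GaussianMixtureVolume, side: int, voxel_size: float
) -> RealVoxelVolume:
    """Sample the mixture at voxel centers on a cubic grid.

    Exploits separability: each isotropic Gaussian is an outer product of
    three 1D Gaussians, so the cost is O(N · side) vector work plus one
    rank-1-accumulation per atom instead of O(N · side³) distance evaluations.
    """
    if side % 2 != 0:
        raise ValueError("side must be even")
    x = coords_1d(side, voxel_size)
    half = side // 2 * voxel_size
    lo, hi = -half, half - voxel_size
    outside = np.any((vol.centers < lo) | (vol.centers > hi), axis=1)
    if np.any(outside):
        logger.warning(
            "%d of %d Gaussian centers fall outside the box; their mass is clipped",
            int(outside.sum()),
            vol.n_centers,
        )
    grid = np.zeros((side, side, side))
    for c, a, b in zip(vol.centers, vol.amplitudes, vol.variances):
        norm = a * (2.0 * np.pi * b) ** (-1.5)
        gx = np.exp(-((x - c[0]) ** 2) / (2.0 * b))
        gy = np.exp(-((x - c[1]) ** 2) / (2.0 * b))
        gz = np.exp(-((x - c[2]) ** 2) / (2.0 * b))
        grid += norm * np.einsum("i,j,k->ijk", gz, gy, gx)
    return RealVoxelVolume(grid, voxel_size)


def fourier_from_real(vol: RealVoxelVolume, pad_factor: int = 1) -> FourierVoxelVolume:
    """Centered forward FFT; the zero-frequency coefficient is the voxel sum.

    ``pad_factor > 1`` zero-pads the real volume (centered) before the
    transform, refining the spectral sample spacing by that factor.  This
    reduces trilinear interpolation error in Fourier-slice extraction at the
    cost of memory; the represented potential is unchanged.
    """
    if pad_factor < 1 or int(pad_factor) != pad_factor:
        raise ValueError("pad_factor must be a positive integer")
    grid = vol.grid
    if pad_factor > 1:
        n = vol.side
        big = n * int(pad_factor)
        start = (big - n) // 2
        padded = np.zeros((big, big, big))
        padded[start : start + n, start : start + n, start : start + n] = grid
        grid = padded
    return FourierVoxelVolume(ft3(grid), vol.voxel_size)


def real_from_fourier(vol: FourierVoxelVolume) -> RealVoxelVolume:
    return RealVoxelVolume(ift3(vol.grid).real, vol.voxel_size)
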