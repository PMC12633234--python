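"""Projection of a potential along the beam axis, three ways.

The z-projection of the rotated potential, ``p(x, y) = ∫ dz U(R⁻¹ r)``, is
the signal part of the linear contrast model.  It is computed either

* analytically, for Gaussian mixtures — the z-integral of each isotropic 3D
  Gaussian is a 2D Gaussian of the same variance centered on the first two
  components of the rotated center;
* by the Fourier slice theorem, for voxel volumes — the 2D transform of the
  projection is the central plane of the 3D transform sampled at body-frame
  frequencies ``Rᵀ (qx, qy, 0)``, here by trilinear interpolation; or
* by a brute-force real-space rotate-and-sum, kept as an independent test
  oracle only.

The active convention of :mod:`cryosim.pose` is used throughout: a pose
rotates the volume into the lab frame, so slice coordinates carry the
inverse rotation.  In-plane translation is *not* applied here; it is a
Fourier-space phase applied by :mod:`cryosim.imaging`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from ._grids import coords_1d, freq_grid_2d, ift2
from .pose import Rotation
from .volumes import FourierVoxelVolume, GaussianMixtureVolume, RealVoxelVolume

__all__ = [
    "ProjectionImage",
    "FourierSlice",
    "project_gmm_analytic",
    "extract_fourier_slice",
    "project_real_space_oracle",
]


@dataclass(frozen=True)
class ProjectionImage:
    """A 2D real projection image with its pixel size in Å."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2:
            raise ValueError("pixels must be 2D")
        if not np.all(np.isfinite(p)):
            raise ValueError("pixels must be finite")
        object.__setattr__(self, "pixels", p)


@dataclass(frozen=True)
class FourierSlice:
    """Centered 2D spectrum of a projection, plus the count of frequency
    samples that fell outside the source volume's Nyquist box (zeroed)."""

    coefficients: np.ndarray
    pixel_size: float
    n_clipped: int = 0

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=complex)
        if c.ndim != 2:
            raise ValueError("coefficients must be 2D")
        object.__setattr__(self, "coefficients", c)


def _check_even_shape(shape):
    ny, nx = shape
    if ny % 2 or nx % 2:
        raise ValueError("image shape must be even in both dimensions")
    return ny, nx


def project_gmm_analytic(
    vol: GaussianMixtureVolume,
    rot: Rotation,
    shape: tuple[int, int],
    pixel_size: float,
) -> ProjectionImage:
    """Closed-form z-projection of a rotated Gaussian mixture.

    Each Gaussian contributes ``a (2πb)^(-1) exp(-((x-u)² + (y-v)²)/(2b))``
    with ``(u, v)`` the in-plane components of the rotated center ``R c``.
    Sampled at pixel centers ``(i - n//2) * pixel_size``.
    """
    ny, nx = _check_even_shape(shape)
    rotated = rot.apply(vol.centers)
    x = coords_1d(nx, pixel_size)
    y = coords_1d(ny, pixel_size)
    img = np.zeros((ny, nx))
    for (u, v, _), a, b in zip(rotated, vol.amplitudes, vol.variances):
        gx = np.exp(-((x - u) ** 2) / (2.0 * b))
        gy = np.exp(-((y - v) ** 2) / (2.0 * b))
        img += (a / (2.0 * np.pi * b)) * np.outer(gy, gx)
    return ProjectionImage(img, pixel_size)


def extract_fourier_slice(
    vol: FourierVoxelVolume,
    rot: Rotation,
    shape: tuple[int, int],
) -> FourierSlice:
    """Sample the central slice ``{Rᵀ (qx, qy, 0)}`` of the 3D spectrum.

    Trilinear interpolation on the centered spectrum; frequencies outside the
    volume's Nyquist box are set to 0 and counted.  Coefficients are scaled
    by the voxel size so that the inverse 2D transform is the projection in
    the same units as the analytic path (potential · Å); the slice pixel
    size equals the volume's voxel size.
    """
    ny, nx = _check_even_shape(shape)
    n = vol.side
    if ny > n or nx > n:
        raise ValueError("slice shape must not exceed the volume side")
    qx, qy = freq_grid_2d((ny, nx), vol.voxel_size)
    lab = np.stack([qx, qy, np.zeros_like(qx)], axis=-1)  # (ny, nx, 3)
    body = lab @ rot.as_matrix()  # row-vector form of Rᵀ q
    dq = 1.0 / (n * vol.voxel_size)
    # body columns are (kx, ky, kz); grid axes are (z, y, x)
    idx = body[..., ::-1] / dq + n // 2
    inside = np.all((idx >= 0.0) & (idx <= n - 1.0), axis=-1)
    coords = np.moveaxis(idx, -1, 0)
    re = map_coordinates(vol.grid.real, coords, order=1, mode="constant", cval=0.0)
    im = map_coordinates(vol.grid.imag, coords, order=1, mode="constant", cval=0.0)
    coeff = (re + 1j * im) * vol.voxel_size
    coeff[~inside] = 0.0
    return FourierSlice(coeff, vol.voxel_size, n_clipped=int((~inside).sum()))


def slice_to_image(fslice: FourierSlice) -> ProjectionImage:
    """Inverse-transform a Fourier slice to the real-space projection."""
    return ProjectionImage(ift2(fslice.coefficients).real, fslice.pixel_size)


def project_real_space_oracle(
    vol: RealVoxelVolume,
    rot: Rotation,
    shape: tuple[int, int],
) -> ProjectionImage:
    """Brute-force oracle: trilinearly resample the rotated volume, sum along z.

    Samples ``U(R⁻¹ r_lab)`` on the lab grid and integrates along z with a
    Riemann sum.  Intended for small test volumes only; the identity rotation
    reduces exactly to ``grid.sum(axis=0) * voxel_size``.
    """
    ny, nx = _check_even_shape(shape)
    n = vol.side
    if ny > n or nx > n:
        raise ValueError("projection shape must not exceed the volume side")
    rinv = rot.inverse().as_matrix()
    x = coords_1d(nx, vol.voxel_size)
    y = coords_1d(ny, vol.voxel_size)
    z = coords_1d(n, vol.voxel_size)
    Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
    lab = np.stack([X, Y, Z], axis=-1)
    body = lab @ rinv.T
    idx = body[..., ::-1] / vol.voxel_size + n // 2  # (z, y, x) index order
    coords = np.moveaxis(idx, -1, 0)
    samples = map_coordinates(vol.grid, coords, order=1, mode="constant", cval=0.0)
    return ProjectionImage(samples.sum(axis=0) * vol.voxel_size, vol.voxel_size)
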