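"""Centered coordinate grids and FFT wrappers shared across modules.

Conventions (fixed package-wide):

* Real-space sample ``i`` of an even-length axis of ``n`` samples sits at
  coordinate ``(i - n//2) * step`` — the origin is the voxel/pixel at index
  ``n//2`` (FFT-center convention).
* Fourier transforms are unnormalized-forward and *centered*: the zero
  frequency sits at index ``n//2`` and equals the plain sum of the samples.
  Frequencies are ``fftshift(fftfreq(n, step))`` in 1/units of ``step``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "coords_1d",
    "freqs_1d",
    "freq_grid_2d",
    "ft2",
    "ift2",
    "ft3",
    "ift3",
]


def coords_1d(n: int, step: float) -> np.ndarray:
    """Centered real-space coordinates for an axis of ``n`` samples."""
    return (np.arange(n) - n // 2) * step


def freqs_1d(n: int, step: float) -> np.ndarray:
    """Centered DFT frequencies (cycles per unit) for an axis of ``n`` samples."""
    return np.fft.fftshift(np.fft.fftfreq(n, d=step))


def freq_grid_2d(shape: tuple[int, int], pixel_size: float):
    """Return ``(qx, qy)`` 2D arrays (units 1/Å) for an image of ``shape``.

    Row index runs over y, column index over x, matching image arrays.
    """
    ny, nx = shape
    qy = freqs_1d(ny, pixel_size)
    qx = freqs_1d(nx, pixel_size)
    QY, QX = np.meshgrid(qy, qx, indexing="ij")
    return QX, QY


def ft2(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1))), axes=(-2, -1))


def ift2(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x, axes=(-2, -1))), axes=(-2, -1))


def ft3(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x)))


def ift3(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(x)))
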