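"""The linear image-formation model, noise models, and power-spectrum tools.

A simulated contrast image is

    C(x, y) = σe · F⁻¹[ CTF(q) · e^(−2πi q·t) · P̂(q) ],

where ``P̂`` is the 2D spectrum of the z-projection of the rotated potential,
``t = (tx, ty)`` the in-plane translation, CTF the transfer function from
:mod:`cryosim.optics`, and σe the electron interaction constant relating
projected potential to phase contrast (default 1; potentials here are in
arbitrary units, so σe is an overall scale).

Translation is applied in Fourier space and therefore wraps periodically;
keep particles away from the image boundary.

Noise is zero-mean Gaussian, either white (per-pixel variance) or colored
(white noise shaped in Fourier space by the square root of a radial power
profile).  The SNR convention throughout is the ratio of per-pixel signal
variance to noise variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from ._grids import freq_grid_2d, ft2, ift2
from .optics import CTFParams, FrequencyGrid2D, evaluate_ctf
from .pose import EulerPose, QuaternionPose
from .projection import (
    FourierSlice,
    extract_fourier_slice,
    project_gmm_analytic,
)
from .volumes import (
    FourierVoxelVolume,
    GaussianMixtureVolume,
    RealVoxelVolume,
    fourier_from_real,
)

__all__ = [
    "ImageConfig",
    "NoiseModel",
    "SimulatedImage",
    "ImageStack",
    "apply_translation",
    "simulate_image",
    "sample_noise",
    "radial_power_spectrum",
    "add_noise_at_snr",
    "fit_power_law_profile",
]


@dataclass(frozen=True)
class ImageConfig:
    """Image geometry plus the contrast scale σe."""

    shape: tuple[int, int]
    pixel_size: float
    sigma_e: float = 1.0

    def __post_init__(self):
        ny, nx = self.shape
        if ny % 2 or nx % 2:
            raise ValueError("image shape must be even")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not self.sigma_e > 0:
            raise ValueError("sigma_e must be positive")
        object.__setattr__(self, "shape", (int(ny), int(nx)))


@dataclass(frozen=True)
class NoiseModel:
    """White or colored zero-mean Gaussian noise.

    ``variance`` is the per-pixel variance for white noise.  For colored
    noise, ``profile`` maps |q| (Å⁻¹) to a nonnegative per-pixel power
    density; the field is white noise shaped by sqrt(profile) in Fourier
    space, so its radially averaged power spectrum (as computed by
    :func:`radial_power_spectrum`) approaches ``n_pixels · profile(|q|)``
    and its per-pixel variance approaches the grid mean of the profile.
    """

    kind: str = "white"
    variance: float = 1.0
    profile: Callable[[np.ndarray], np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("white", "colored"):
            raise ValueError("kind must be 'white' or 'colored'")
        if self.kind == "white" and not self.variance > 0:
            raise ValueError("white noise variance must be positive")
        if self.kind == "colored" and self.profile is None:
            raise ValueError("colored noise requires a radial power profile")


@dataclass(frozen=True)
class SimulatedImage:
    """A contrast image plus the metadata that produced it."""

    pixels: np.ndarray
    config: ImageConfig
    pose: EulerPose | QuaternionPose | None = None
    ctf: CTFParams | None = None

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=float)
        if p.shape != self.config.shape:
            raise ValueError("pixel array shape must match the image config")
        object.__setattr__(self, "pixels", p)


@dataclass
class ImageStack:
    """A set of images with shared geometry and per-image pose/CTF metadata."""

    images: np.ndarray  # (n, ny, nx)
    pixel_size: float
    poses: Sequence[EulerPose | QuaternionPose] = field(default_factory=list)
    ctfs: Sequence[CTFParams] = field(default_factory=list)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n, ny, nx) array")
        n = self.images.shape[0]
        if self.poses and len(self.poses) != n:
            raise ValueError("one pose per image required")
        if self.ctfs and len(self.ctfs) != n:
            raise ValueError("one CTF per image required")

    def __len__(self) -> int:
        return self.images.shape[0]


def apply_translation(fslice: FourierSlice, tx: float, ty: float) -> FourierSlice:
    """Shift theorem: multiply coefficients by exp(−2πi (qx tx + qy ty))."""
    qx, qy = freq_grid_2d(fslice.coefficients.shape, fslice.pixel_size)
    phase = np.exp(-2j * np.pi * (qx * tx + qy * ty))
    return FourierSlice(fslice.coefficients * phase, fslice.pixel_size, fslice.n_clipped)


def _projection_spectrum(vol, rotation, cfg: ImageConfig) -> FourierSlice:
    if isinstance(vol, GaussianMixtureVolume):
        proj = project_gmm_analytic(vol, rotation, cfg.shape, cfg.pixel_size)
        return FourierSlice(ft2(proj.pixels), cfg.pixel_size)
    if isinstance(vol, RealVoxelVolume):
        vol = fourier_from_real(vol)
    if isinstance(vol, FourierVoxelVolume):
        if not np.isclose(vol.voxel_size, cfg.pixel_size):
            raise ValueError(
                "Fourier-slice projection requires pixel_size equal to the "
                f"volume voxel size ({vol.voxel_size} Å)"
            )
        return extract_fourier_slice(vol, rotation, cfg.shape)
    raise TypeError(f"unsupported volume representation: {type(vol).__name__}")


def simulate_image(
    vol,
    pose: EulerPose | QuaternionPose,
    ctf: CTFParams,
    cfg: ImageConfig,
    no_ctf: bool = False,
    chi_fn=None,
    ctf_sign: float = 1.0,
) -> SimulatedImage:
    """Run the linear pipeline: project → translate → CTF → scale by σe.

    Gaussian mixtures take the analytic projection path; real or Fourier
    voxel volumes take the Fourier-slice path.  With ``no_ctf=True`` the
    transfer function is identically 1 and the result is σe times the
    shifted projection.
    """
    fslice = _projection_spectrum(vol, pose.rotation, cfg)
    tx, ty = pose.translation
    fslice = apply_translation(fslice, tx, ty)
    coeff = fslice.coefficients
    if not no_ctf:
        grid = FrequencyGrid2D.from_shape(cfg.shape, cfg.pixel_size)
        coeff = coeff * evaluate_ctf(grid, ctf, chi_fn=chi_fn, sign=ctf_sign)
    pixels = cfg.sigma_e * ift2(coeff).real
    return SimulatedImage(pixels, cfg, pose=pose, ctf=ctf)


def sample_noise(
    model: NoiseModel,
    shape: tuple[int, int],
    pixel_size: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one noise field; reproducible from ``model.seed`` unless an
    explicit generator is supplied."""
    if rng is None:
        rng = np.random.default_rng(model.seed)
    white = rng.normal(size=shape)
    if model.kind == "white":
        return np.sqrt(model.variance) * white
    qx, qy = freq_grid_2d(shape, pixel_size)
    power = np.asarray(model.profile(np.hypot(qx, qy)), dtype=float)
    if np.any(power < 0):
        raise ValueError("power profile must be nonnegative")
    field = ift2(ft2(white) * np.sqrt(power)).real
    return field - field.mean()


def radial_power_spectrum(
    img: np.ndarray, pixel_size: float, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged power spectrum: mean |FT(img)|² over annuli of |q|.

    Returns ``(bin_centers, power)`` with centers in Å⁻¹.  Bins span 0 to
    Nyquist; Parseval holds as Σ power·counts = Σ|FT|² over binned samples.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    img = np.asarray(img, dtype=float)
    f2 = np.abs(ft2(img)) ** 2
    qx, qy = freq_grid_2d(img.shape, pixel_size)
    qmag = np.hypot(qx, qy)
    nyquist = 1.0 / (2.0 * pixel_size)
    edges = np.linspace(0.0, nyquist, n_bins + 1)
    which = np.clip(np.digitize(qmag.ravel(), edges) - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=f2.ravel(), minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        power = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, power


def add_noise_at_snr(
    img: SimulatedImage,
    model: NoiseModel,
    snr: float,
    rng: np.random.Generator | None = None,
) -> SimulatedImage:
    """Add noise rescaled so Var(signal)/Var(noise) = snr for this image.

    The drawn field is renormalized by its own sample standard deviation, so
    the realized per-image variance ratio is exact rather than only an
    expectation.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    sig_var = float(np.var(img.pixels))
    if sig_var == 0.0:
        raise ValueError("signal image has zero variance; SNR is undefined")
    noise = sample_noise(model, img.config.shape, img.config.pixel_size, rng=rng)
    noise = noise - noise.mean()
    noise *= np.sqrt(sig_var / snr) / noise.std()
    return SimulatedImage(img.pixels + noise, img.config, pose=img.pose, ctf=img.ctf)


def fit_power_law_profile(
    q: np.ndarray, power: np.ndarray
) -> tuple[float, float, float]:
    """Least-squares fit of the convenience family P(q) = A q^(−α) + c.

    Used to align a simulated radial power spectrum with a measured one.
    Returns (A, alpha, c); the DC bin (q = 0) is excluded.
    """
    q = np.asarray(q, dtype=float)
    power = np.asarray(power, dtype=float)
    keep = (q > 0) & np.isfinite(power)
    q, power = q[keep], power[keep]

    def resid(params):
        a, alpha, c = params
        return np.log(np.abs(a) * q ** (-alpha) + np.abs(c) + 1e-300) - np.log(power + 1e-300)

    scale = float(np.median(power))
    sol = least_squares(resid, x0=[scale, 1.0, 0.1 * scale], max_nfev=2000)
    a, alpha, c = sol.x
    return float(abs(a)), float(alpha), float(abs(c))
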