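"""Microscope optics: the aberration function χ and the CTF sin χ.

The weak-phase contrast transfer function is evaluated on a 2D frequency
grid from an aberration phase

    χ(q, φ) = −π λ Δf(φ) |q|² + (π/2) Cs λ³ |q|⁴ + phase_shift,

with direction-dependent (astigmatic) defocus

    Δf(φ) = ½ [du + dv + (du − dv) cos 2(φ − φ_a)],

the CTFFIND-style parametrization.  Positive defocus means underfocus.  With
amplitude contrast ``w`` the transfer function is
``sqrt(1 − w²) sin χ + w cos χ``; ``w = 0`` gives exactly ``sin χ``.

Custom aberration models plug in through ``chi_fn`` in
:func:`evaluate_ctf` — any callable mapping ``(FrequencyGrid2D, CTFParams)``
to a phase array can stand in for the built-in astigmatic model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import constants

from ._grids import freq_grid_2d

__all__ = [
    "CTFParams",
    "FrequencyGrid2D",
    "electron_wavelength",
    "aberration_phase_defocus",
    "aberration_phase_astigmatic",
    "evaluate_ctf",
]

_MM_TO_ANGSTROM = 1.0e7


@dataclass(frozen=True)
class FrequencyGrid2D:
    """2D spatial-frequency grids (Å⁻¹) matching an image shape/pixel size."""

    qx: np.ndarray
    qy: np.ndarray

    def __post_init__(self):
        qx = np.asarray(self.qx, dtype=float)
        qy = np.asarray(self.qy, dtype=float)
        if qx.shape != qy.shape or qx.ndim != 2:
            raise ValueError("qx and qy must be matching 2D arrays")
        object.__setattr__(self, "qx", qx)
        object.__setattr__(self, "qy", qy)

    @classmethod
    def from_shape(cls, shape: tuple[int, int], pixel_size: float) -> "FrequencyGrid2D":
        qx, qy = freq_grid_2d(shape, pixel_size)
        return cls(qx, qy)

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.qx, self.qy)


@dataclass(frozen=True)
class CTFParams:
    """CTFFIND-style CTF parameters.

    defocus_u/defocus_v in Å (canonicalized so defocus_u >= defocus_v, with
    the astigmatism angle rotated by 90° and wrapped to [0°, 180°) when the
    pair is swapped), astig_angle in degrees, cs in mm, voltage in kV,
    amplitude_contrast a fraction in [0, 1), phase_shift in degrees.
    """

    defocus_u: float = 10000.0
    defocus_v: float = 10000.0
    astig_angle: float = 0.0
    cs: float = 2.7
    voltage: float = 300.0
    amplitude_contrast: float = 0.0
    phase_shift: float = 0.0

    def __post_init__(self):
        if not self.voltage > 0:
            raise ValueError("voltage must be positive")
        if not (0.0 <= self.amplitude_contrast < 1.0):
            raise ValueError("amplitude_contrast must lie in [0, 1)")
        du, dv, ang = self.defocus_u, self.defocus_v, self.astig_angle
        if du < dv:
            du, dv = dv, du
            ang = ang + 90.0
        object.__setattr__(self, "defocus_u", float(du))
        object.__setattr__(self, "defocus_v", float(dv))
        object.__setattr__(self, "astig_angle", float(ang % 180.0))

    @property
    def wavelength(self) -> float:
        return electron_wavelength(self.voltage)

    def with_defocus(self, defocus: float) -> "CTFParams":
        return replace(self, defocus_u=defocus, defocus_v=defocus)


def electron_wavelength(voltage: float) -> float:
    """Relativistic de Broglie wavelength (Å) of electrons at ``voltage`` kV.

    λ = h / sqrt(2 m₀ e V (1 + eV / (2 m₀ c²)))
    """
    if not voltage > 0:
        raise ValueError("voltage must be positive")
    v = voltage * 1e3  # volts
    h = constants.h
    m0 = constants.m_e
    e = constants.e
    c = constants.c
    lam_m = h / np.sqrt(2 * m0 * e * v * (1 + e * v / (2 * m0 * c**2)))
    return float(lam_m * 1e10)


def aberration_phase_defocus(
    q: FrequencyGrid2D, defocus: float, wavelength: float
) -> np.ndarray:
    """Defocus-only aberration phase χ(q) = −π λ Δf |q|² (radians)."""
    q2 = q.qx**2 + q.qy**2
    return -np.pi * wavelength * defocus * q2


def aberration_phase_astigmatic(q: FrequencyGrid2D, p: CTFParams) -> np.ndarray:
    """Astigmatic defocus + spherical aberration + phase shift (radians).

    Reduces exactly to :func:`aberration_phase_defocus` when the defoci are
    equal and cs and phase_shift vanish.
    """
    lam = p.wavelength
    q2 = q.qx**2 + q.qy**2
    phi = np.arctan2(q.qy, q.qx)
    ang = np.deg2rad(p.astig_angle)
    df = 0.5 * (
        p.defocus_u
        + p.defocus_v
        + (p.defocus_u - p.defocus_v) * np.cos(2.0 * (phi - ang))
    )
    cs_angstrom = p.cs * _MM_TO_ANGSTROM
    chi = -np.pi * lam * df * q2 + 0.5 * np.pi * cs_angstrom * lam**3 * q2**2
    return chi + np.deg2rad(p.phase_shift)


def evaluate_ctf(
    q: FrequencyGrid2D,
    p: CTFParams,
    chi_fn=None,
    sign: float = 1.0,
) -> np.ndarray:
    """CTF = sqrt(1 − w²) sin χ + w cos χ, with w the amplitude contrast.

    ``chi_fn(q, p) -> phase array`` swaps in a custom aberration model; the
    default is :func:`aberration_phase_astigmatic`.  ``sign`` (±1) flips the
    global contrast convention.
    """
    if chi_fn is None:
        chi_fn = aberration_phase_astigmatic
    chi = np.asarray(chi_fn(q, p), dtype=float)
    if chi.shape != q.qx.shape:
        raise ValueError(
            f"chi_fn returned shape {chi.shape}, expected {q.qx.shape}"
        )
    w = p.amplitude_contrast
    return sign * (np.sqrt(1.0 - w**2) * np.sin(chi) + w * np.cos(chi))
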