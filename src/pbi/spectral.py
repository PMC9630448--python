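"""Dual-energy decomposition into photoelectric and electron-density maps.

The linearised TIE in the Alvarez-Macovski attenuation basis couples, per
spatial frequency, the projected photoelectric coefficient P (the E^-3
basis amplitude) and the projected electron density rho_e (cm^-2) to the
negative log intensities at two energies:

    [ E_A^-3   sigma_KN(E_A) + chi_A k^2 ] [ F P      ]   [ -F ln I(E_A) ]
    [ E_B^-3   sigma_KN(E_B) + chi_B k^2 ] [ F rho_e  ] = [ -F ln I(E_B) ]

with chi = h^2 c^2 r_e Delta / (2 pi E^2).  The 2x2 system is inverted in
closed form frequency by frequency; ``k^2`` uses either the continuous or
the discrete-Laplacian kernel.  Internal unit system: cm and keV, so P is
in keV^3 / cm^2 and chi in keV^-2 cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft

from .geometry import ImagingGeometry, KernelChoice

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "DualEnergyPair",
    "DecompositionResult",
    "klein_nishina",
    "chi",
    "forward_dual_energy",
    "dual_energy_decompose",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA values in the package's keV/cm unit system."""

    hc_kev_cm: float = 1.23984198e-7  # Planck constant x speed of light
    r_e_cm: float = 2.8179403262e-13  # classical electron radius
    electron_rest_kev: float = 510.99895
    thomson_cross_section_cm2: float = 6.6524587321e-25


CONSTANTS = PhysicalConstants()


def klein_nishina(energy_keV: float | np.ndarray) -> float | np.ndarray:
    """Total Klein-Nishina cross section per electron (cm^2).

    Standard closed form in x = E / (m_e c^2); tends to the Thomson cross
    section as E -> 0 and decreases monotonically with E.
    """
    e = np.asarray(energy_keV, dtype=float)
    if np.any(e <= 0):
        raise ValueError("energy must be positive")
    x = e / CONSTANTS.electron_rest_kev
    log_term = np.log1p(2.0 * x)
    sigma = (
        2.0
        * np.pi
        * CONSTANTS.r_e_cm**2
        * (
            (1.0 + x) / x**2 * (2.0 * (1.0 + x) / (1.0 + 2.0 * x) - log_term / x)
            + log_term / (2.0 * x)
            - (1.0 + 3.0 * x) / (1.0 + 2.0 * x) ** 2
        )
    )
    return sigma if sigma.ndim else float(sigma)


def chi(energy_keV: float, distance: float) -> float:
    """Phase-coupling coefficient chi = h^2 c^2 r_e Delta / (2 pi E^2).

    ``distance`` in metres; the result is in keV^-2 cm^3 (k^2 in rad^2/cm^2
    makes chi * k^2 commensurate with sigma_KN in cm^2).
    """
    if energy_keV <= 0:
        raise ValueError("energy must be positive")
    if distance < 0:
        raise ValueError("distance must be non-negative")
    delta_cm = distance * 100.0
    return (
        CONSTANTS.hc_kev_cm**2 * CONSTANTS.r_e_cm * delta_cm
        / (2.0 * np.pi * energy_keV**2)
    )


@dataclass(frozen=True)
class DualEnergyPair:
    """Normalised intensity images at two distinct energies on one grid."""

    i_a: np.ndarray
    i_b: np.ndarray
    energy_a_keV: float
    energy_b_keV: float
    geometry: ImagingGeometry

    def __post_init__(self) -> None:
        if self.energy_a_keV == self.energy_b_keV:
            raise ValueError("the two energies must differ (singular system)")
        if self.i_a.shape != self.i_b.shape:
            raise ValueError("the two images must share one grid")


@dataclass(frozen=True)
class DecompositionResult:
    """Photoelectric map P (keV^3/cm^2), projected electron density (cm^-2)."""

    photoelectric: np.ndarray
    electron_density: np.ndarray
    n_clamped: int = 0  # frequencies whose determinant needed regularisation


def _k2_half(shape: tuple[int, int], pixel_size_cm: float, kernel: KernelChoice):
    n0, n1 = shape
    ky = 2.0 * np.pi * fft.fftfreq(n0, d=pixel_size_cm)
    kx = 2.0 * np.pi * fft.rfftfreq(n1, d=pixel_size_cm)
    if kernel is KernelChoice.PM:
        return ky[:, None] ** 2 + kx[None, :] ** 2
    w = pixel_size_cm
    return (-2.0 / w**2) * (np.cos(w * ky)[:, None] + np.cos(w * kx)[None, :] - 2.0)


def _matrix_entries(
    energy_keV: float, distance: float, k2: np.ndarray
) -> tuple[float, np.ndarray]:
    return energy_keV**-3, klein_nishina(energy_keV) + chi(energy_keV, distance) * k2


def forward_dual_energy(
    photoelectric: np.ndarray,
    electron_density: np.ndarray,
    energy_keV: float,
    distance: float,
    geometry: ImagingGeometry,
    kernel: KernelChoice = KernelChoice.GPM,
) -> np.ndarray:
    """Forward model: the -ln I(E) map implied by (P, rho_e).

    Used for synthetic data generation and round-trip verification of the
    decomposition; exactly the linear system the decomposition inverts.
    """
    p = np.asarray(photoelectric, dtype=float)
    rho = np.asarray(electron_density, dtype=float)
    if p.shape != rho.shape:
        raise ValueError("P and rho_e must share one grid")
    k2 = _k2_half(p.shape, geometry.pixel_size * 100.0, kernel)
    a1, a2 = _matrix_entries(energy_keV, distance, k2)
    spec = a1 * fft.rfft2(p) + a2 * fft.rfft2(rho)
    return fft.irfft2(spec, s=p.shape)


def dual_energy_decompose(
    pair: DualEnergyPair,
    distance: float,
    kernel: KernelChoice = KernelChoice.GPM,
    det_rtol: float = 1e-12,
) -> DecompositionResult:
    """Invert the two-energy system for (P, projected rho_e).

    Intensities are clipped at 1e-12 of their median before the logarithm.
    Frequencies where |det| falls below ``det_rtol`` times its DC value are
    clamped to that floor (count reported in the result).
    """
    w_cm = pair.geometry.pixel_size * 100.0
    k2 = _k2_half(pair.i_a.shape, w_cm, kernel)
    a11, a12 = _matrix_entries(pair.energy_a_keV, distance, k2)
    a21, a22 = _matrix_entries(pair.energy_b_keV, distance, k2)

    def neg_log(img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, dtype=float)
        floor = 1e-12 * float(np.median(img))
        return -np.log(np.clip(img, max(floor, np.finfo(float).tiny), None))

    la = fft.rfft2(neg_log(pair.i_a))
    lb = fft.rfft2(neg_log(pair.i_b))
    det = a11 * a22 - a12 * a21
    det_dc = abs(a11 * a22[0, 0] - a12[0, 0] * a21)
    if det_dc == 0:
        raise ValueError("singular energy pair: zero determinant at DC")
    floor = det_rtol * det_dc
    small = np.abs(det) < floor
    det_safe = np.where(small, np.sign(det) * floor + (det == 0) * floor, det)
    p_spec = (a22 * la - a12 * lb) / det_safe
    rho_spec = (-a21 * la + a11 * lb) / det_safe
    shape = pair.i_a.shape
    return DecompositionResult(
        photoelectric=fft.irfft2(p_spec, s=shape),
        electron_density=fft.irfft2(rho_spec, s=shape),
        n_clamped=int(small.sum()),
    )
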