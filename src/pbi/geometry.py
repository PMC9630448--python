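"""Core domain types: imaging geometry, frequency grids and material optics.

All lengths are stored in SI metres, energies in keV.  Frequencies are
*angular* spatial frequencies (rad/m): on a grid of pixel size ``W`` the
Nyquist frequency is ``pi / W``, so ``W * k`` spans ``[-pi, pi]``.  This is
the convention in which the discrete-Laplacian kernel ``cos(W k)`` is
naturally expressed, and every map in the package shares it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import fft

__all__ = [
    "FWHM_TO_SIGMA",
    "HC_KEV_M",
    "FrequencyGrid",
    "ImagingGeometry",
    "KernelChoice",
    "MaterialOptics",
    "MATERIALS",
]

#: FWHM -> Gaussian sigma conversion, 1 / (2 sqrt(2 ln 2)).
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: h*c in keV * m (CODATA): lambda = HC_KEV_M / E[keV].
HC_KEV_M = 1.23984198e-9


class KernelChoice(enum.Enum):
    """Which squared-frequency kernel the Lorentzian filter uses.

    ``PM`` is the continuous-mathematics kernel ``kx^2 + ky^2``; ``GPM`` is
    the discrete-Laplacian (five-point) kernel that accounts for pixel
    sampling and suppresses high frequencies less.
    """

    PM = "pm"
    GPM = "gpm"


@dataclass(frozen=True)
class ImagingGeometry:
    """Physical description of the imaging system.

    Parameters
    ----------
    pixel_size : float
        Detector pixel size ``W`` in metres.
    distance : float
        Sample-detector propagation distance in metres.
    psf_fwhm_px : float
        FWHM of the (Gaussian) detector point-spread function, in pixels.
    shape : tuple of int
        Grid dimensions ``(rows, cols)``.
    """

    pixel_size: float
    distance: float = 0.0
    psf_fwhm_px: float = 0.0
    shape: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.distance < 0:
            raise ValueError("distance must be non-negative")
        if self.psf_fwhm_px < 0:
            raise ValueError("psf_fwhm_px must be non-negative")

    def frequency_grid(self, shape: tuple[int, int] | None = None) -> "FrequencyGrid":
        shape = tuple(shape if shape is not None else self.shape)
        return FrequencyGrid(shape=shape, pixel_size=self.pixel_size)

    def rebinned(self, n: int) -> "ImagingGeometry":
        """Geometry after n x n pixel rebinning: W grows, PSF (in px) shrinks."""
        if any(s % n for s in self.shape):
            raise ValueError(f"shape {self.shape} not divisible by rebin factor {n}")
        return ImagingGeometry(
            pixel_size=self.pixel_size * n,
            distance=self.distance,
            psf_fwhm_px=self.psf_fwhm_px / n,
            shape=(self.shape[0] // n, self.shape[1] // n),
        )


@dataclass(frozen=True)
class FrequencyGrid:
    """DFT angular-frequency maps for a 2-D grid of pixel size ``W``.

    ``kx`` varies along axis 1 (columns, image x) and ``ky`` along axis 0.
    Values follow the standard DFT ordering: the value at index ``n`` equals
    minus the value at index ``N - n`` and ``|W k| <= pi`` everywhere.  For
    even-sized grids the single unpaired Nyquist sample is assigned ``+pi/W``
    (the kernels are even in k, so the sign never matters; fixing it keeps
    tests unambiguous).
    """

    shape: tuple[int, int]
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if len(self.shape) != 2 or any(s < 1 for s in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")

    def _axis_freq(self, n: int) -> np.ndarray:
        k = 2.0 * np.pi * fft.fftfreq(n, d=self.pixel_size)
        if n % 2 == 0:
            k[n // 2] = abs(k[n // 2])  # unpaired Nyquist sample -> +pi/W
        return k

    @property
    def ky_1d(self) -> np.ndarray:
        return self._axis_freq(self.shape[0])

    @property
    def kx_1d(self) -> np.ndarray:
        return self._axis_freq(self.shape[1])

    @property
    def kx(self) -> np.ndarray:
        """Full 2-D map of kx (rad/m)."""
        return np.broadcast_to(self.kx_1d[None, :], self.shape).copy()

    @property
    def ky(self) -> np.ndarray:
        """Full 2-D map of ky (rad/m)."""
        return np.broadcast_to(self.ky_1d[:, None], self.shape).copy()

    @property
    def nyquist(self) -> float:
        """pi / W, the highest representable angular frequency."""
        return np.pi / self.pixel_size


@dataclass(frozen=True)
class MaterialOptics:
    """Optical constants of one material at one X-ray energy.

    ``mu = 4 pi beta / lambda`` ties the imaginary refractive index to the
    linear attenuation coefficient; it is enforced at construction.

    Attributes
    ----------
    delta : float
        Refractive index decrement (n = 1 - delta + i beta).
    beta : float
        Imaginary part of the refractive index.
    mu : float
        Linear attenuation coefficient, 1/m.
    wavelength : float
        X-ray wavelength, m.
    energy_keV : float
        Photon energy, keV.
    density : float
        Mass density in g/cm^3, carried as metadata.
    name : str
    """

    delta: float
    beta: float
    mu: float
    wavelength: float
    energy_keV: float
    density: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if min(self.delta, self.beta, self.mu) < 0:
            raise ValueError("delta, beta, mu must be non-negative")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.beta > 0 and self.mu > 0:
            implied = 4.0 * np.pi * self.beta / self.wavelength
            if abs(implied - self.mu) > 1e-10 * max(self.mu, implied):
                raise ValueError(
                    f"inconsistent optics: mu={self.mu} but 4*pi*beta/lambda={implied}"
                )

    @classmethod
    def from_delta_mu(
        cls,
        delta: float,
        mu: float,
        energy_keV: float,
        density: float = 0.0,
        name: str = "",
    ) -> "MaterialOptics":
        """Build from (delta, mu, E); beta follows from mu = 4 pi beta / lambda."""
        wavelength = HC_KEV_M / energy_keV
        beta = mu * wavelength / (4.0 * np.pi)
        return cls(
            delta=delta,
            beta=beta,
            mu=mu,
            wavelength=wavelength,
            energy_keV=energy_keV,
            density=density,
            name=name,
        )

    @property
    def delta_over_mu(self) -> float:
        if self.mu <= 0:
            raise ValueError("material has mu <= 0; delta/mu undefined")
        return self.delta / self.mu

    def vacuum_like(self) -> bool:
        return self.delta == 0.0 and self.mu == 0.0


def _vacuum(energy_keV: float = 24.0) -> MaterialOptics:
    return MaterialOptics(
        delta=0.0,
        beta=0.0,
        mu=0.0,
        wavelength=HC_KEV_M / energy_keV,
        energy_keV=energy_keV,
        name="vacuum",
    )


# Tabulated optical constants at 24 keV.  delta = rho_e r_e lambda^2 / (2 pi)
# with rho_e from the stated densities (water 0.998, PMMA 1.19 g/cm^3);
# mu from NIST mass-attenuation coefficients (log-log interpolated to 24 keV).
MATERIALS: dict[str, MaterialOptics] = {
    "water": MaterialOptics.from_delta_mu(
        3.993e-7, 57.2, energy_keV=24.0, density=0.998, name="water"
    ),
    "pmma": MaterialOptics.from_delta_mu(
        4.627e-7, 51.1, energy_keV=24.0, density=1.19, name="pmma"
    ),
    "vacuum": _vacuum(),
}
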