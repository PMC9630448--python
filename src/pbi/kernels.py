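"""Frequency-space kernels, transfer functions and single-distance retrieval.

The single-material retrieval filter is the Lorentzian low-pass

    H(k) = 1 / (1 + (delta * Delta / mu) * k_perp^2),

where ``k_perp^2`` is either the continuous squared frequency
``kx^2 + ky^2`` (the classic method, "PM") or the discrete five-point
Laplacian kernel ``-(2/W^2)[cos(W kx) + cos(W ky) - 2]`` ("GPM"), which is
what the DFT actually diagonalises on a pixel grid.  Because
``cos``-kernel values never exceed the continuous ones inside the Nyquist
square, the GPM filter suppresses high spatial frequencies strictly less,
which is the source of its resolution advantage.
"""

from __future__ import annotations

import numpy as np
from scipy import fft

from .geometry import FWHM_TO_SIGMA, FrequencyGrid, ImagingGeometry, KernelChoice, MaterialOptics

__all__ = [
    "k_perp2_pm",
    "k_perp2_gpm",
    "transfer_function",
    "gaussian_ctf",
    "transfer_ratio",
    "fractional_difference",
    "phase_retrieve",
    "beltran_retrieve",
    "lorentzian_filter",
]


def k_perp2_pm(grid: FrequencyGrid) -> np.ndarray:
    """Continuous squared transverse frequency kx^2 + ky^2 (rad^2/m^2)."""
    return grid.ky_1d[:, None] ** 2 + grid.kx_1d[None, :] ** 2


def k_perp2_gpm(grid: FrequencyGrid) -> np.ndarray:
    """Discrete-Laplacian squared frequency -(2/W^2)[cos(W kx)+cos(W ky)-2].

    Equals the continuous kernel to second order near DC and is bounded by
    8/W^2 at the DFT corner (the continuous kernel reaches 2 pi^2/W^2 there).
    """
    w = grid.pixel_size
    cx = np.cos(w * grid.kx_1d)[None, :]
    cy = np.cos(w * grid.ky_1d)[:, None]
    return (-2.0 / w**2) * (cx + cy - 2.0)


def _k_perp2(grid: FrequencyGrid, kernel: KernelChoice) -> np.ndarray:
    if kernel is KernelChoice.PM:
        return k_perp2_pm(grid)
    return k_perp2_gpm(grid)


def _coefficient(delta: float, mu: float, distance: float) -> float:
    if mu <= 0:
        raise ValueError("invalid material: mu must be positive")
    if delta < 0 or distance < 0:
        raise ValueError("delta and distance must be non-negative")
    return delta * distance / mu


def transfer_function(
    grid: FrequencyGrid,
    delta: float,
    mu: float,
    distance: float,
    kernel: KernelChoice = KernelChoice.GPM,
) -> np.ndarray:
    """Amplification H = 1/(1 + (delta*Delta/mu) k_perp^2), in (0, 1]."""
    c = _coefficient(delta, mu, distance)
    return 1.0 / (1.0 + c * _k_perp2(grid, kernel))


def gaussian_ctf(grid: FrequencyGrid, psf_fwhm_px: float) -> np.ndarray:
    """Contrast transfer function of a Gaussian detector PSF.

    The PSF is the unit-integral, azimuthally symmetric real-space Gaussian
    whose FWHM is ``psf_fwhm_px`` detector pixels; its transform in the
    angular convention is exp(-sigma^2 (kx^2+ky^2)/2) with
    sigma = FWHM * W / (2 sqrt(2 ln 2)).  Equals 1 at DC; identically 1 for
    a zero-width (delta-function) PSF.
    """
    if psf_fwhm_px < 0:
        raise ValueError("psf_fwhm_px must be non-negative")
    sigma = psf_fwhm_px * grid.pixel_size * FWHM_TO_SIGMA
    return np.exp(-0.5 * sigma**2 * k_perp2_pm(grid))


def transfer_ratio(
    grid: FrequencyGrid, delta: float, mu: float, distance: float
) -> np.ndarray:
    """R = H_GPM / H_PM >= 1: the per-frequency boost of the discrete kernel."""
    c = _coefficient(delta, mu, distance)
    return (1.0 + c * k_perp2_pm(grid)) / (1.0 + c * k_perp2_gpm(grid))


def fractional_difference(
    grid: FrequencyGrid,
    delta: float,
    mu: float,
    distance: float,
    psf_fwhm_px: float | None = None,
) -> np.ndarray:
    """Fractional difference D = (H_GPM - H_PM)/H_PM (= R - 1), >= 0.

    With a detector PSF the blurred transfer functions are G*H, but the
    denominator stays the *unblurred* H_PM, so the result is simply G * D.
    """
    d = transfer_ratio(grid, delta, mu, distance) - 1.0
    if psf_fwhm_px is not None:
        d = d * gaussian_ctf(grid, psf_fwhm_px)
    return d


def transfer_table(
    pixel_size: float,
    delta: float,
    mu: float,
    distance: float,
    psf_fwhm_px: float | None = None,
    direction: str = "axis",
    n: int = 256,
) -> dict[str, np.ndarray]:
    """Sample H_PM, H_GPM, R, D and D-bar along a 1-D frequency line.

    ``direction='axis'`` walks the (kx, ky=0) line, normalised abscissa
    ``W kx`` in [0, pi]; ``direction='diagonal'`` walks |kx| = |ky|, where
    the normalised radius ``W sqrt(kx^2+ky^2)`` extends to pi*sqrt(2) at the
    DFT corner.
    """
    c = _coefficient(delta, mu, distance)
    w = pixel_size
    if direction == "axis":
        kx = np.linspace(0.0, np.pi / w, n)
        ky = np.zeros_like(kx)
    elif direction == "diagonal":
        kx = np.linspace(0.0, np.pi / w, n)
        ky = kx
    else:
        raise ValueError("direction must be 'axis' or 'diagonal'")
    k2_pm = kx**2 + ky**2
    k2_gpm = (-2.0 / w**2) * (np.cos(w * kx) + np.cos(w * ky) - 2.0)
    h_pm = 1.0 / (1.0 + c * k2_pm)
    h_gpm = 1.0 / (1.0 + c * k2_gpm)
    d = h_gpm / h_pm - 1.0
    table = {
        "k_normalized": w * np.hypot(kx, ky),
        "H_PM": h_pm,
        "H_GPM": h_gpm,
        "R": h_gpm / h_pm,
        "D": d,
    }
    if psf_fwhm_px is not None:
        sigma = psf_fwhm_px * w * FWHM_TO_SIGMA
        table["D_bar"] = d * np.exp(-0.5 * sigma**2 * k2_pm)
    return table


def _prepare_ratio(
    image: np.ndarray, i0: float | np.ndarray, repair: bool
) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    i0 = np.asarray(i0, dtype=float)
    if i0.ndim not in (0, 2):
        raise ValueError("I0 must be a scalar or a 2-D map")
    if i0.ndim == 2 and i0.shape != image.shape:
        raise ValueError(f"I0 shape {i0.shape} != image shape {image.shape}")
    if np.any(i0 <= 0):
        raise ValueError("I0 must be strictly positive")
    ratio = image / i0
    bad = ~np.isfinite(ratio) | (ratio <= 0)
    if np.any(bad):
        if not repair:
            raise ValueError(
                f"{int(bad.sum())} non-positive or non-finite pixels in image/I0 "
                "(pass repair=True to clip them)"
            )
        eps = 1e-12 * float(np.median(ratio[~bad])) if (~bad).any() else 1e-12
        ratio = np.where(bad, max(eps, np.finfo(float).tiny), ratio)
    return ratio


def lorentzian_filter(
    ratio: np.ndarray,
    pixel_size: float,
    coefficient: float,
    kernel: KernelChoice,
    forward: bool = False,
) -> np.ndarray:
    """Apply (or, with ``forward=True``, invert) 1/(1 + c k_perp^2) to a real image.

    Uses the real-input FFT; for real images this matches the full complex
    transform to machine precision.
    """
    ratio = np.asarray(ratio, dtype=float)
    if ratio.ndim != 2:
        raise ValueError("expected a 2-D image")
    n0, n1 = ratio.shape
    ky = 2.0 * np.pi * fft.fftfreq(n0, d=pixel_size)
    kx = 2.0 * np.pi * fft.rfftfreq(n1, d=pixel_size)
    if kernel is KernelChoice.PM:
        k2 = ky[:, None] ** 2 + kx[None, :] ** 2
    else:
        k2 = (-2.0 / pixel_size**2) * (
            np.cos(pixel_size * ky)[:, None] + np.cos(pixel_size * kx)[None, :] - 2.0
        )
    filt = 1.0 + coefficient * k2
    spec = fft.rfft2(ratio)
    spec = spec * filt if forward else spec / filt
    return fft.irfft2(spec, s=ratio.shape)


def _pad_symmetric(img: np.ndarray) -> tuple[np.ndarray, tuple[slice, slice]]:
    p0, p1 = img.shape[0] // 2, img.shape[1] // 2
    padded = np.pad(img, ((p0, p0), (p1, p1)), mode="symmetric")
    return padded, (slice(p0, p0 + img.shape[0]), slice(p1, p1 + img.shape[1]))


def phase_retrieve(
    image: np.ndarray,
    i0: float | np.ndarray,
    optics: MaterialOptics,
    geometry: ImagingGeometry,
    kernel: KernelChoice = KernelChoice.GPM,
    pad: bool = False,
    repair: bool = False,
) -> np.ndarray:
    """Single-material retrieval of the contact-plane transmission I/I0.

    Divides the DFT of ``image / i0`` by ``1 + (delta Delta / mu) k_perp^2``
    with the chosen kernel.  The DC gain is one, so the image mean is
    preserved exactly; the operation is linear and shift-invariant.

    Parameters
    ----------
    pad : bool
        Symmetrically extend the image before filtering (for inputs where
        DFT wraparound at the frame edge matters), cropping afterwards.
    repair : bool
        Clip non-positive / non-finite pixels instead of raising.
    """
    c = _coefficient(optics.delta, optics.mu, geometry.distance)
    ratio = _prepare_ratio(image, i0, repair)
    if pad:
        ratio, crop = _pad_symmetric(ratio)
        return lorentzian_filter(ratio, geometry.pixel_size, c, kernel)[crop]
    return lorentzian_filter(ratio, geometry.pixel_size, c, kernel)


def beltran_retrieve(
    image: np.ndarray,
    i0: float | np.ndarray,
    optics1: MaterialOptics,
    optics2: MaterialOptics,
    geometry: ImagingGeometry,
    kernel: KernelChoice = KernelChoice.GPM,
    pad: bool = False,
    repair: bool = False,
) -> np.ndarray:
    """Two-material retrieval at the boundary between materials 1 and 2.

    Identical filter structure to :func:`phase_retrieve` with coefficient
    ``(delta2 - delta1) Delta / (mu2 - mu1)``; with material 1 vacuum it
    reduces exactly to the single-material form.
    """
    dmu = optics2.mu - optics1.mu
    if dmu == 0:
        raise ValueError("degenerate material pair: mu1 == mu2")
    c = (optics2.delta - optics1.delta) * geometry.distance / dmu
    if c < 0:
        raise ValueError("filter coefficient (delta2-delta1)*Delta/(mu2-mu1) is negative")
    ratio = _prepare_ratio(image, i0, repair)
    if pad:
        ratio, crop = _pad_symmetric(ratio)
        return lorentzian_filter(ratio, geometry.pixel_size, c, kernel)[crop]
    return lorentzian_filter(ratio, geometry.pixel_size, c, kernel)
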