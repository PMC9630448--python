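"""Spatial-resolution metrology from circular edges.

The resolution of a retrieved image is measured at the rim of the disc
phantom: pixel values are azimuthally averaged into fine radial bins, the
radial profile is differentiated to a line-spread function (LSF), and a
Pearson VII peak

    P(x) = A [1 + 4 (x - x0)^2 / Gamma^2 (2^(1/m) - 1)]^(-m)

is fitted, whose ``Gamma`` parameter is by construction the FWHM (``m``
interpolates Lorentzian, m=1, to Gaussian, m >~ 10).  The figure of merit
comparing two retrievals is the fractional improvement
``(Gamma_PM - Gamma_GPM) / Gamma_PM``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "RadialProfile",
    "Pearson7Fit",
    "ImprovementResult",
    "pearson7",
    "azimuthal_profile",
    "lsf_from_profile",
    "fit_pearson7",
    "improvement",
    "measure_snr",
    "measure_edge_fwhm",
]


@dataclass(frozen=True)
class RadialProfile:
    """Azimuthally averaged profile: bin centres r (px), mean value, counts."""

    r: np.ndarray
    value: np.ndarray
    count: np.ndarray
    arc: tuple[float, float] = (0.0, 360.0)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("radial bin centres must be strictly increasing")
        if np.any(self.count <= 0):
            raise ValueError("every reported bin must contain samples")


@dataclass(frozen=True)
class Pearson7Fit:
    """Fitted Pearson VII parameters; ``fwhm`` is Gamma, exactly the FWHM."""

    amplitude: float
    x0: float
    fwhm: float
    m: float
    covariance: np.ndarray
    rmse: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0 or self.m <= 0:
            raise ValueError("fwhm and m must be positive")

    @property
    def fwhm_stderr(self) -> float:
        return float(np.sqrt(self.covariance[2, 2]))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return pearson7(x, self.amplitude, self.x0, self.fwhm, self.m)


@dataclass(frozen=True)
class ImprovementResult:
    """Fractional resolution improvement (Gamma_PM - Gamma_GPM)/Gamma_PM."""

    gamma_pm: float
    gamma_gpm: float
    improvement: float
    uncertainty: float = 0.0


def pearson7(x: np.ndarray, amplitude: float, x0: float, fwhm: float, m: float) -> np.ndarray:
    """Pearson VII peak; satisfies P(x0 +/- fwhm/2) = amplitude/2 identically."""
    u = 4.0 * (np.asarray(x, dtype=float) - x0) ** 2 / fwhm**2
    return amplitude * (1.0 + u * (2.0 ** (1.0 / m) - 1.0)) ** (-m)


def azimuthal_profile(
    image: np.ndarray,
    centre: tuple[float, float],
    r_range: tuple[float, float],
    arc: tuple[float, float] = (0.0, 360.0),
    bin_width: float = 0.25,
) -> RadialProfile:
    """Mean pixel value in radial bins around ``centre`` within an angular arc.

    Angles are measured from the upward (-row) direction at the centre,
    increasing clockwise on screen, in degrees.  ``r_range`` and
    ``bin_width`` are in pixels.  Raises if any bin in range is empty.
    """
    image = np.asarray(image, dtype=float)
    r0, r1 = r_range
    a0, a1 = arc
    if not (0 < r0 < r1):
        raise ValueError("need 0 < r0 < r1")
    if a0 >= a1:
        raise ValueError("need a0 < a1")
    cy, cx = centre
    n0, n1 = image.shape
    # candidate window, to avoid building full-frame distance maps
    lo0, hi0 = max(0, int(cy - r1) - 1), min(n0, int(cy + r1) + 2)
    lo1, hi1 = max(0, int(cx - r1) - 1), min(n1, int(cx + r1) + 2)
    yy = np.arange(lo0, hi0)[:, None] - cy
    xx = np.arange(lo1, hi1)[None, :] - cx
    r = np.hypot(yy, xx)
    sel = (r >= r0) & (r < r1)
    if (a0, a1) != (0.0, 360.0):
        ang = np.degrees(np.arctan2(xx, -yy)) % 360.0  # 0 deg at top, clockwise
        sel &= (ang >= a0) & (ang <= a1)
    rv = r[sel]
    iv = image[lo0:hi0, lo1:hi1][sel]
    edges = np.arange(r0, r1 + bin_width * 0.5, bin_width)
    nb = len(edges) - 1
    idx = np.clip(((rv - r0) / bin_width).astype(int), 0, nb - 1)
    count = np.bincount(idx, minlength=nb)
    if np.any(count == 0):
        raise ValueError("empty radial bins in the requested range; widen bin_width")
    total = np.bincount(idx, weights=iv, minlength=nb)
    return RadialProfile(
        r=edges[:-1] + bin_width / 2.0, value=total / count, count=count, arc=(a0, a1)
    )


def lsf_from_profile(profile: RadialProfile) -> RadialProfile:
    """Differentiate the edge profile to a line-spread function.

    Central differences inside, one-sided at the ends; the sign is flipped
    if needed so a falling edge gives a positive peak (only the magnitude
    carries resolution information).
    """
    if len(profile.r) < 3:
        raise ValueError("need at least 3 bins to differentiate")
    d = np.gradient(profile.value, profile.r)
    if abs(d.min()) > abs(d.max()):
        d = -d
    return RadialProfile(r=profile.r, value=d, count=profile.count, arc=profile.arc)


def fit_pearson7(x: np.ndarray, y: np.ndarray) -> Pearson7Fit:
    """Nonlinear least-squares Pearson VII fit of a peaked curve.

    Initialised from the sample peak and its half-maximum crossings with
    m = 2, m bounded to [0.5, 50]; restarts from m = 1 and m = 10 if the
    first attempt fails to converge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 8:
        raise ValueError("need at least 8 points spanning the peak")
    i0 = int(np.argmax(y))
    if i0 == 0 or i0 == len(x) - 1:
        raise ValueError("peak not contained in the x-range")
    a0, x0 = y[i0], x[i0]
    above = x[y > a0 / 2.0]
    dx = float(np.min(np.diff(x)))
    g0 = max(float(above[-1] - above[0]), dx)
    bounds = (
        [0.0, x[0], dx * 0.1, 0.5],
        [np.inf, x[-1], (x[-1] - x[0]) * 4.0, 50.0],
    )
    last_err: Exception | None = None
    for m0 in (2.0, 1.0, 10.0):
        try:
            popt, pcov = optimize.curve_fit(
                pearson7, x, y, p0=[a0, x0, g0, m0], bounds=bounds, maxfev=20000
            )
            resid = y - pearson7(x, *popt)
            return Pearson7Fit(
                amplitude=float(popt[0]),
                x0=float(popt[1]),
                fwhm=float(popt[2]),
                m=float(popt[3]),
                covariance=pcov,
                rmse=float(np.sqrt(np.mean(resid**2))),
            )
        except RuntimeError as err:  # no convergence; restart with another m
            last_err = err
    raise RuntimeError(f"Pearson VII fit did not converge: {last_err}")


def improvement(
    gamma_pm: float,
    gamma_gpm: float,
    stderr_pm: float = 0.0,
    stderr_gpm: float = 0.0,
) -> ImprovementResult:
    """Fractional improvement (Gamma_PM - Gamma_GPM)/Gamma_PM.

    The uncertainty is first-order propagation of the two FWHM standard
    errors: with f = 1 - g/p, var(f) = (g/p^2)^2 var(p) + (1/p)^2 var(g).
    """
    if gamma_pm <= 0:
        raise ValueError("gamma_pm must be positive")
    frac = (gamma_pm - gamma_gpm) / gamma_pm
    var = (gamma_gpm / gamma_pm**2 * stderr_pm) ** 2 + (stderr_gpm / gamma_pm) ** 2
    return ImprovementResult(
        gamma_pm=gamma_pm,
        gamma_gpm=gamma_gpm,
        improvement=frac,
        uncertainty=float(np.sqrt(var)),
    )


def measure_snr(image: np.ndarray, roi: tuple[slice, slice]) -> tuple[float, float, float]:
    """SNR = mean/std over a homogeneous region of interest."""
    patch = np.asarray(image, dtype=float)[roi]
    if patch.size < 16:
        raise ValueError("ROI must contain at least 16 pixels")
    mean = float(patch.mean())
    std = float(patch.std(ddof=1))
    if std == 0:
        raise ValueError("degenerate ROI: zero variance")
    return mean / std, mean, std


def measure_edge_fwhm(
    image: np.ndarray,
    centre: tuple[float, float],
    radius_px: float,
    halfwidth_px: float = 10.0,
    arc: tuple[float, float] = (0.0, 360.0),
    bin_width: float = 0.25,
) -> Pearson7Fit:
    """Edge profile -> LSF -> Pearson VII FWHM, around a circular boundary."""
    prof = azimuthal_profile(
        image,
        centre,
        (radius_px - halfwidth_px, radius_px + halfwidth_px),
        arc=arc,
        bin_width=bin_width,
    )
    lsf = lsf_from_profile(prof)
    return fit_pearson7(lsf.r, lsf.value)
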