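"""Horizontal-cell ring quantification from 1-D line profiles.

Side-on images of a division ring are reduced to two line profiles — lateral
(along the septal axis) and axial (along the cell's long axis) — from which
this module measures:

* diameter, by fitting the lateral profile to the line-of-sight projection of
  a uniform-intensity circle viewed edge-on, convolved with a Gaussian PSF
  ("tilted circle" model);
* axial thickness, as the FWHM of a super-Gaussian fit to the axial profile;
* septal density, total septal intensity divided by the ring circumference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .errors import FitError, ParameterError

BAND_HALF_WIDTH_PX = 2  # profiles average over +/- 2 px (5 rows)


@dataclass
class LineProfile:
    """Uniformly sampled intensity profile along one image axis."""

    positions_nm: np.ndarray
    intensities: np.ndarray
    axis: str  # "lateral" or "axial"

    def __post_init__(self):
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions_nm.size < 8:
            raise ParameterError("profile needs at least 8 samples")
        if self.positions_nm.shape != self.intensities.shape:
            raise ParameterError("positions and intensities must match")
        steps = np.diff(self.positions_nm)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ParameterError("profile must be uniformly spaced")
        if self.axis not in ("lateral", "axial"):
            raise ParameterError("axis must be 'lateral' or 'axial'")

    @property
    def spacing_nm(self) -> float:
        return float(self.positions_nm[1] - self.positions_nm[0])


def extract_septal_profiles(image, centroid_xy_px, septal_axis_angle_deg,
                            pixel_size_nm: float = 65.0):
    """Rotate about the centroid and average +/-2 px bands into two profiles.

    The image is rotated (bilinear interpolation) so the septal axis lies
    horizontal; the lateral profile is the mean over the 5 rows centred on
    the centroid, the axial profile the mean over the 5 columns.  Positions
    are nm relative to the centroid.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    cx, cy = centroid_xy_px
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise ParameterError("centroid must lie inside the image")
    b = BAND_HALF_WIDTH_PX
    if cy - b < 0 or cy + b > h - 1 or cx - b < 0 or cx + b > w - 1:
        raise ParameterError("averaging band exceeds image bounds")

    theta = math.radians(septal_axis_angle_deg)
    if septal_axis_angle_deg % 360.0 == 0.0:
        rotated = image
    else:
        yy, xx = np.mgrid[0:h, 0:w]
        # output pixel (x, y) samples the input at the position rotated by
        # +theta about the centroid (so a feature at angle theta lands flat)
        dx, dy = xx - cx, yy - cy
        sx = cx + dx * math.cos(theta) - dy * math.sin(theta)
        sy = cy + dx * math.sin(theta) + dy * math.cos(theta)
        rotated = ndimage.map_coordinates(image, [sy, sx], order=1,
                                          mode="constant", cval=np.nan)

    r0 = int(round(cy))
    c0 = int(round(cx))
    lateral = np.nanmean(rotated[r0 - b:r0 + b + 1, :], axis=0)
    axial = np.nanmean(rotated[:, c0 - b:c0 + b + 1], axis=1)
    lat_pos = (np.arange(w) - cx) * pixel_size_nm
    ax_pos = (np.arange(h) - cy) * pixel_size_nm
    lat_ok = ~np.isnan(lateral)
    ax_ok = ~np.isnan(axial)
    return (LineProfile(lat_pos[lat_ok], lateral[lat_ok], "lateral"),
            LineProfile(ax_pos[ax_ok], axial[ax_ok], "axial"))


# ---------------------------------------------------------------------------
# Tilted circle model (diameter)


def tilted_circle_profile(positions_nm, d_nm, centre_nm, total_intensity,
                          psf_sigma_nm, baseline=0.0, oversample: int = 8):
    """Edge-on projection of a uniform circle, blurred by a Gaussian PSF.

    The line-of-sight projection of a uniform circle of diameter ``d`` has
    density proportional to ``1 / sqrt((d/2)^2 - u^2)`` with integrable
    singularities at the rim.  Each fine-grid bin receives its exact mass via
    the arcsine antiderivative, the result is convolved with a discrete
    Gaussian kernel and resampled onto ``positions_nm``.  The projected mass
    integrates to ``total_intensity`` regardless of ``d``.
    """
    if d_nm <= 0 or psf_sigma_nm <= 0:
        raise ParameterError("d and psf_sigma must be positive")
    positions = np.asarray(positions_nm, dtype=float)
    spacing = positions[1] - positions[0]
    fine = spacing / oversample
    R = d_nm / 2.0
    pad = 4.0 * psf_sigma_nm + spacing
    lo = min(positions[0], centre_nm - R) - pad
    hi = max(positions[-1], centre_nm + R) + pad
    grid = np.arange(lo, hi + fine, fine)

    edges = np.concatenate([grid - fine / 2, [grid[-1] + fine / 2]])
    u = np.clip((edges - centre_nm) / R, -1.0, 1.0)
    cdf = (np.arcsin(u) + math.pi / 2) / math.pi  # mass fraction below edge
    mass = np.diff(cdf) * total_intensity

    half = int(math.ceil(4.0 * psf_sigma_nm / fine))
    kx = np.arange(-half, half + 1) * fine
    kernel = np.exp(-kx**2 / (2.0 * psf_sigma_nm**2))
    kernel /= kernel.sum()
    blurred = np.convolve(mass, kernel, mode="same") / fine  # intensity per nm

    interp = np.interp(positions, grid, blurred)
    return interp * spacing + baseline  # per-sample intensity units


@dataclass
class TiltedCircleFit:
    d_nm: float
    centre_nm: float
    total_intensity: float
    psf_sigma_nm: float
    baseline: float
    rss: float
    converged: bool


def fit_tilted_circle(profile: LineProfile, psf_sigma_nm: float | None = None
                      ) -> TiltedCircleFit:
    """Fit the tilted-circle model to a lateral profile; returns the diameter.

    ``psf_sigma_nm`` fixes the PSF width; by default it is fitted.
    """
    pos, inten = profile.positions_nm, profile.intensities
    span = pos[-1] - pos[0]
    baseline0 = float(inten.min())
    net = np.clip(inten - baseline0, 0, None)
    if net.sum() <= 0:
        raise FitError("profile has no signal above baseline")
    centre0 = float((pos * net).sum() / net.sum())
    above = pos[net > 0.5 * net.max()]
    d0 = float(max(above[-1] - above[0], 4 * profile.spacing_nm)) \
        if above.size >= 2 else span / 2
    total0 = float(net.sum())
    fit_psf = psf_sigma_nm is None
    psf0 = 120.0 if fit_psf else psf_sigma_nm

    def model(p):
        d, centre, total, baseline = p[:4]
        psf = p[4] if fit_psf else psf_sigma_nm
        return tilted_circle_profile(pos, d, centre, total, psf, baseline)

    p0 = [d0, centre0, total0, baseline0]
    lower = [2 * profile.spacing_nm, pos[0], 0.0, -np.inf]
    upper = [1.5 * span, pos[-1], np.inf, np.inf]
    if fit_psf:
        p0.append(psf0)
        lower.append(profile.spacing_nm / 4)
        upper.append(span)
    sol = optimize.least_squares(lambda p: model(p) - inten, p0,
                                 bounds=(lower, upper), xtol=1e-12,
                                 ftol=1e-12, gtol=1e-12)
    d, centre, total, baseline = sol.x[:4]
    psf = sol.x[4] if fit_psf else psf_sigma_nm
    if d > span:
        raise FitError("fitted diameter exceeds the profile span")
    return TiltedCircleFit(float(d), float(centre), float(total), float(psf),
                           float(baseline), float(np.sum(sol.fun**2)),
                           bool(sol.status > 0))


# ---------------------------------------------------------------------------
# Super-Gaussian (axial thickness)


def super_gaussian_fwhm(sigma_nm: float, p: float) -> float:
    """FWHM of ``exp(-((x^2)/(2 sigma^2))^P)``: 2 sqrt(2) sigma (ln 2)^(1/2P)."""
    return 2.0 * math.sqrt(2.0) * sigma_nm * math.log(2.0) ** (1.0 / (2.0 * p))


@dataclass
class SuperGaussianFit:
    x0_nm: float
    sigma_nm: float
    p: float
    amplitude: float
    baseline: float
    rss: float
    converged: bool

    @property
    def fwhm_nm(self) -> float:
        return super_gaussian_fwhm(self.sigma_nm, self.p)


def fit_super_gaussian(profile: LineProfile,
                       fix_p: float | None = None) -> SuperGaussianFit:
    """Least-squares super-Gaussian fit of a single-peaked axial profile.

    With ``fix_p=1`` this reduces exactly to an ordinary Gaussian fit.
    """
    pos, inten = profile.positions_nm, profile.intensities
    baseline0 = float(inten.min())
    amp0 = float(inten.max() - baseline0)
    if amp0 <= 0:
        raise FitError("profile has no peak above baseline")
    x00 = float(pos[np.argmax(inten)])
    above = pos[inten - baseline0 > amp0 / 2]
    fwhm0 = float(above[-1] - above[0]) if above.size >= 2 \
        else 4 * profile.spacing_nm
    sigma0 = max(fwhm0 / 2.355, profile.spacing_nm / 2)
    fit_p = fix_p is None

    def model(q):
        x0, sigma, amp, baseline = q[:4]
        p = q[4] if fit_p else fix_p
        z = ((pos - x0) ** 2 / (2.0 * sigma**2)) ** p
        return amp * np.exp(-z) + baseline

    q0 = [x00, sigma0, amp0, baseline0]
    lower = [pos[0], profile.spacing_nm / 10, 0.0, -np.inf]
    upper = [pos[-1], pos[-1] - pos[0], np.inf, np.inf]
    if fit_p:
        q0.append(1.0)
        lower.append(1.0)
        upper.append(10.0)
    sol = optimize.least_squares(lambda q: model(q) - inten, q0,
                                 bounds=(lower, upper), xtol=1e-12,
                                 ftol=1e-12, gtol=1e-12)
    x0, sigma, amp, baseline = sol.x[:4]
    p = sol.x[4] if fit_p else fix_p
    return SuperGaussianFit(float(x0), float(sigma), float(p), float(amp),
                            float(baseline), float(np.sum(sol.fun**2)),
                            bool(sol.status > 0))


# ---------------------------------------------------------------------------
# Septal density


def total_septal_intensity(profile: LineProfile,
                           baseline: float | None = None) -> float:
    """Baseline-subtracted sum of the lateral profile (ADU)."""
    if baseline is None:
        baseline = float(profile.intensities.min())
    return float(np.sum(profile.intensities - baseline))


def septal_density(total_intensity: float, diameter_nm: float) -> float:
    """Total septal intensity divided by the ring circumference (ADU/nm)."""
    if diameter_nm <= 0:
        raise ParameterError("diameter must be positive")
    return total_intensity / (math.pi * diameter_nm)
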