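"""Pixel-integrated 2D Gaussian point-spread-function models.

Two model variants are used:

* an isotropic Gaussian integrated exactly over square pixels via the
  error function — the rendering model of the TIRF simulator;
* a general elliptical Gaussian with rotation,
  ``A * exp(-(a dx^2 + 2 b dx dy + c dy^2)) + B``, integrated over each
  pixel by 5-point Gauss-Legendre quadrature per axis — the fitting model
  of the localization pipeline.

Coordinate convention: pixel centres sit at integer coordinates, the
origin is the region corner, pixel (ix, iy) covers
[ix-0.5, ix+0.5) x [iy-0.5, iy+0.5).  Images are indexed ``img[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf

_SQRT2 = np.sqrt(2.0)

# Gauss-Legendre nodes/weights on [-1/2, 1/2]
_GL_X, _GL_W = np.polynomial.legendre.leggauss(5)
_GL_X = 0.5 * _GL_X
_GL_W = 0.5 * _GL_W


def render_isotropic(shape: tuple[int, int], x0: float, y0: float,
                     sigma: float, total_photons: float) -> np.ndarray:
    """Expected photons per pixel for an isotropic emitter.

    Exact pixel integration via the error function; the array sums to
    ``total_photons`` up to the (negligible) tail mass outside the frame.
    """
    ny, nx = shape
    xs = np.arange(nx)
    ys = np.arange(ny)
    fx = 0.5 * (erf((xs + 0.5 - x0) / (_SQRT2 * sigma))
                - erf((xs - 0.5 - x0) / (_SQRT2 * sigma)))
    fy = 0.5 * (erf((ys + 0.5 - y0) / (_SQRT2 * sigma))
                - erf((ys - 0.5 - y0) / (_SQRT2 * sigma)))
    return total_photons * np.outer(fy, fx)


def _abc(sigma_x: float, sigma_y: float, theta: float):
    ct, st = np.cos(theta), np.sin(theta)
    a = ct**2 / (2 * sigma_x**2) + st**2 / (2 * sigma_y**2)
    b = -np.sin(2 * theta) / (4 * sigma_x**2) + np.sin(2 * theta) / (4 * sigma_y**2)
    c = st**2 / (2 * sigma_x**2) + ct**2 / (2 * sigma_y**2)
    return a, b, c


def model_image(shape: tuple[int, int], amp: float, x0: float, y0: float,
                sigma_x: float, sigma_y: float, theta: float,
                background: float) -> np.ndarray:
    """Rotated elliptical Gaussian integrated over pixels (quadrature)."""
    ny, nx = shape
    a, b, c = _abc(sigma_x, sigma_y, theta)
    xs = np.arange(nx)[None, :, None, None] + _GL_X[None, None, :, None]
    ys = np.arange(ny)[:, None, None, None] + _GL_X[None, None, None, :]
    dx = xs - x0
    dy = ys - y0
    g = np.exp(-(a * dx**2 + 2 * b * dx * dy + c * dy**2))
    w = _GL_W[None, None, :, None] * _GL_W[None, None, None, :]
    return amp * np.sum(g * w, axis=(2, 3)) + background


@dataclass
class PSFFit:
    """Result of a pixel-integrated elliptical Gaussian fit."""

    amplitude: float
    x0: float
    y0: float
    sigma_x: float
    sigma_y: float
    theta: float
    background: float
    converged: bool
    residual_norm: float

    @property
    def centre(self) -> tuple[float, float]:
        return (self.x0, self.y0)


def eccentricity(fit: PSFFit) -> float:
    """e = sqrt(1 - (sigma_min/sigma_max)^2), dimensionless in [0, 1).

    0 for a circular spot; approaches 1 as the spot flattens.  Defined
    only for converged fits.
    """
    if not fit.converged:
        raise ValueError("eccentricity is undefined for a failed fit")
    lo, hi = sorted((abs(fit.sigma_x), abs(fit.sigma_y)))
    if hi == 0:
        raise ValueError("degenerate widths")
    return float(np.sqrt(max(0.0, 1.0 - (lo / hi) ** 2)))


def fit_psf(image: np.ndarray, initial: dict | None = None,
            noise_floor: float | None = None) -> PSFFit:
    """Least-squares fit of the pixel-integrated rotated Gaussian.

    ``initial`` may override the automatic starting guess (keys: amp, x0,
    y0, sigma, background).  A fit is marked failed (``converged=False``)
    rather than raising when the optimizer does not converge or the
    fitted amplitude is below the noise floor (3x the residual MAD by
    default).
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    ny, nx = img.shape

    bg0 = float(np.median(img))
    amp0 = float(img.max() - bg0)
    initial = initial or {}
    if amp0 <= 0 and "amp" not in initial:
        return PSFFit(0.0, nx / 2, ny / 2, 1.0, 1.0, 0.0, bg0, False,
                      float(np.linalg.norm(img - bg0)))
    w = np.clip(img - bg0, 0, None)
    tot = w.sum()
    if tot > 0:
        yy, xx = np.mgrid[0:ny, 0:nx]
        x0g = float((w * xx).sum() / tot)
        y0g = float((w * yy).sum() / tot)
    else:
        x0g, y0g = nx / 2.0, ny / 2.0
    sig0 = initial.get("sigma", 0.8)
    p0 = np.array([
        initial.get("amp", max(amp0, 1e-9)),
        initial.get("x0", x0g),
        initial.get("y0", y0g),
        sig0, sig0, 0.0,
        initial.get("background", bg0),
    ])
    if not (0 <= p0[1] <= nx - 1 and 0 <= p0[2] <= ny - 1):
        raise ValueError("initial centre must lie inside the region")

    def resid(p):
        return (model_image(img.shape, p[0], p[1], p[2], p[3], p[4], p[5],
                            p[6]) - img).ravel()

    lb = [0.0, -1.0, -1.0, 0.15, 0.15, -np.pi, -np.inf]
    ub = [np.inf, nx, ny, nx, ny, np.pi, np.inf]
    sol = least_squares(resid, p0, bounds=(lb, ub), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
    amp, x0, y0, sx, sy, th, bg = sol.x
    th = float(np.mod(th, np.pi))
    res_norm = float(np.linalg.norm(sol.fun))
    ok = bool(sol.success)
    if noise_floor is None:
        mad = float(np.median(np.abs(sol.fun - np.median(sol.fun))))
        noise_floor = 3.0 * 1.4826 * mad
    if amp <= noise_floor or amp <= 0:
        ok = False
    return PSFFit(float(amp), float(x0), float(y0), float(abs(sx)),
                  float(abs(sy)), th, float(bg), ok, res_norm)
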