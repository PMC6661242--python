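"""Empirical microbubble echo appearance model.

A microbubble echo is rendered as an anisotropic 2D Gaussian (elliptical,
variable orientation) — the empirical appearance extracted from contrast
loops, not an acoustic model.  What is calibrated is the *footprint*: the
number of pixels above half the peak at the reference 132-um pitch.  The
target distribution of that pixel area has minimum 5 px and quartiles
8 / 12 / 20 px.

Calibration is analytic: at threshold fraction ``t`` of the peak, the
footprint of a Gaussian with axis sigmas (sa, sb) is the ellipse
``area_px = 2 pi ln(1/t) sa sb / pitch^2``, so a target area plus an
aspect ratio fixes both sigmas.  Target areas are drawn from a two-piece
log-normal pinned to the quartiles (scale ln(12/8)/z75 below the median,
ln(20/12)/z75 above), floored at 5 px.  Aspect ratio is uniform in
[1, 2.5] and orientation uniform in [0, pi) — the shape is described only
qualitatively in the source data, as ellipsoid with variable orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["EchoAppearance", "EchoSizeModel", "sample_echo_appearance",
           "render_appearance_patch", "footprint_area_px"]

#: Threshold fraction defining the calibrated footprint (half maximum).
FOOTPRINT_FRACTION = 0.5

_Z75 = norm.ppf(0.75)  # 0.6745


@dataclass(frozen=True)
class EchoAppearance:
    """One echo's rendered shape: elliptical Gaussian axes and peak."""

    sigma_major_um: float
    sigma_minor_um: float
    orientation_rad: float
    peak_intensity: float

    def __post_init__(self) -> None:
        if not (self.sigma_major_um >= self.sigma_minor_um > 0):
            raise ValueError("require sigma_major >= sigma_minor > 0")
        if self.peak_intensity <= 0:
            raise ValueError("peak intensity must be positive")

    def covariance_um2(self) -> np.ndarray:
        """2x2 covariance of the intensity profile in (x, y) um."""
        c, s = np.cos(self.orientation_rad), np.sin(self.orientation_rad)
        rot = np.array([[c, -s], [s, c]])
        d = np.diag([self.sigma_major_um ** 2, self.sigma_minor_um ** 2])
        return rot @ d @ rot.T

    def analytic_footprint_px(self, pixel_pitch_um: float,
                              fraction: float = FOOTPRINT_FRACTION) -> float:
        """Continuous area (px) of the above-``fraction``-of-peak ellipse."""
        return (2.0 * np.pi * np.log(1.0 / fraction)
                * self.sigma_major_um * self.sigma_minor_um / pixel_pitch_um ** 2)


@dataclass(frozen=True)
class EchoSizeModel:
    """Target footprint-area distribution and intensity range.

    Quartiles are in pixels at ``pixel_pitch_um``.  Peak intensities are
    uniform in ``peak_range``; with the default noise rule (noise sigma =
    faintest peak / 3) this puts single-echo peak SNR in the upper part of
    the low-SNR regime the method is designed for.
    """

    min_area_px: float = 5.0
    q1_px: float = 8.0
    median_px: float = 12.0
    q3_px: float = 20.0
    aspect_range: tuple[float, float] = (1.0, 2.5)
    peak_range: tuple[float, float] = (60.0, 200.0)
    pixel_pitch_um: float = 132.0

    def validate(self) -> None:
        if not (0 < self.min_area_px <= self.q1_px <= self.median_px <= self.q3_px):
            raise ValueError(
                f"infeasible size model: need 0 < min <= Q1 <= median <= Q3, got "
                f"({self.min_area_px}, {self.q1_px}, {self.median_px}, {self.q3_px})")
        if self.aspect_range[0] < 1.0 or self.aspect_range[1] < self.aspect_range[0]:
            raise ValueError("aspect range must satisfy 1 <= lo <= hi")
        if self.peak_range[0] <= 0 or self.peak_range[1] < self.peak_range[0]:
            raise ValueError("invalid peak intensity range")

    def sample_area_px(self, rng: np.random.Generator) -> float:
        """Draw a footprint area from the quartile-pinned two-piece
        log-normal, floored at the minimum area."""
        z = rng.standard_normal()
        lo = np.log(self.median_px / self.q1_px) / _Z75
        hi = np.log(self.q3_px / self.median_px) / _Z75
        area = self.median_px * np.exp((lo if z < 0 else hi) * z)
        return max(area, self.min_area_px)


def sample_echo_appearance(rng: np.random.Generator,
                           size_model: EchoSizeModel | None = None) -> EchoAppearance:
    """Sample one echo appearance consistent with the size model.

    The pair (sigma_major, sigma_minor) is solved from the drawn footprint
    area and aspect ratio so that the above-half-maximum ellipse has
    exactly the drawn continuous area; pixelation then quantizes the
    rendered footprint to within about one pixel of it.
    """
    model = size_model or EchoSizeModel()
    model.validate()
    area = model.sample_area_px(rng)
    aspect = rng.uniform(*model.aspect_range)
    theta = rng.uniform(0.0, np.pi)
    peak = rng.uniform(*model.peak_range)
    p = model.pixel_pitch_um
    sigma_minor = p * np.sqrt(area / (2.0 * np.pi * np.log(1.0 / FOOTPRINT_FRACTION) * aspect))
    app = EchoAppearance(sigma_major_um=aspect * sigma_minor,
                         sigma_minor_um=sigma_minor,
                         orientation_rad=theta,
                         peak_intensity=peak)
    # Pixelation can shave a floor-sized ellipse below the minimum count;
    # inflate marginally until the pixel-centered footprint honors the floor.
    while footprint_area_px(app, p) < int(np.floor(model.min_area_px)):
        app = EchoAppearance(sigma_major_um=app.sigma_major_um * 1.03,
                             sigma_minor_um=app.sigma_minor_um * 1.03,
                             orientation_rad=theta,
                             peak_intensity=peak)
    return app


def render_appearance_patch(appearance: EchoAppearance,
                            pixel_pitch_um: float,
                            center_offset_um: tuple[float, float] = (0.0, 0.0),
                            half_width_px: int | None = None) -> np.ndarray:
    """Render one echo on a local patch, center near the patch middle.

    Used for footprint measurements and tests; the sequence renderer
    composes the same Gaussian onto the full canvas.
    """
    if half_width_px is None:
        half_width_px = int(np.ceil(4 * appearance.sigma_major_um / pixel_pitch_um)) + 2
    n = 2 * half_width_px + 1
    cx = (half_width_px + 0.5) * pixel_pitch_um + center_offset_um[0]
    cy = (half_width_px + 0.5) * pixel_pitch_um + center_offset_um[1]
    xs = (np.arange(n) + 0.5) * pixel_pitch_um
    gx, gy = np.meshgrid(xs, xs)
    cov = appearance.covariance_um2()
    prec = np.linalg.inv(cov)
    dx, dy = gx - cx, gy - cy
    quad = prec[0, 0] * dx ** 2 + 2 * prec[0, 1] * dx * dy + prec[1, 1] * dy ** 2
    return appearance.peak_intensity * np.exp(-0.5 * quad)


def footprint_area_px(appearance: EchoAppearance,
                      pixel_pitch_um: float,
                      center_offset_um: tuple[float, float] = (0.0, 0.0),
                      fraction: float = FOOTPRINT_FRACTION) -> int:
    """Rendered pixel count above ``fraction`` of the peak."""
    patch = render_appearance_patch(appearance, pixel_pitch_um, center_offset_um)
    return int(np.count_nonzero(patch >= fraction * appearance.peak_intensity))
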