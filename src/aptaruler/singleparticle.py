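"""Single-particle mode: spot detection, per-particle RG, spacing stats.

Under dark-field illumination each tethered AuNP appears as an isolated
diffraction-limited colored spot on the color camera.  Detection works
on the channel-summed image: Gaussian smoothing, a robust global
threshold (background median plus ``threshold_sigmas`` robust standard
deviations, estimated from the median absolute deviation), and
non-maximum suppression at a minimum separation.  Each detection is
photometered with a fixed-radius disk aperture after subtracting the
median of a surrounding annulus per channel, and its RG ratio is the
background-subtracted mean red over mean green.

Pixel convention: 0-based coordinates with pixel centers at integer
positions, (x, y) = (column, row).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import gaussian

from .ensemble import GroupComparison, compare_groups

__all__ = [
    "DarkFieldImage",
    "Detection",
    "detect_particles",
    "particle_rg",
    "population_shift",
    "nn_spacing",
]

DEFAULT_APERTURE_RADIUS = 3  # px
DEFAULT_ANNULUS_WIDTH = 2  # px
DEFAULT_SMOOTH_SIGMA = 1.0  # px


@dataclass
class DarkFieldImage:
    """RGB dark-field frame; ``pixels`` is H x W x 3, channel order RGB."""

    pixels: np.ndarray
    pixel_size: float  # um per pixel
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3 (RGB)")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class Detection:
    """One detected particle with aperture photometry."""

    x: float  # px, column
    y: float  # px, row
    radius: float  # aperture radius, px
    mean_red: float  # background-subtracted
    mean_green: float
    rg: float


def _aperture_masks(
    shape: tuple[int, int], x: float, y: float, radius: int, annulus: int
):
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    r2 = (xx - x) ** 2 + (yy - y) ** 2
    disk = r2 <= radius**2
    ring = (r2 > radius**2) & (r2 <= (radius + annulus) ** 2)
    return disk, ring


def particle_rg(
    image: DarkFieldImage,
    detection: Detection | tuple[float, float],
    aperture_radius: int = DEFAULT_APERTURE_RADIUS,
    annulus_width: int = DEFAULT_ANNULUS_WIDTH,
) -> float:
    """Background-subtracted red/green ratio at one particle.

    The annulus median per channel estimates the local background, so
    the ratio is immune to global gain and additive offsets.
    """
    if isinstance(detection, Detection):
        x, y = detection.x, detection.y
        aperture_radius = int(round(detection.radius))
    else:
        x, y = detection
    h, w, _ = image.pixels.shape
    r_out = aperture_radius + annulus_width
    if not (r_out <= x <= w - 1 - r_out and r_out <= y <= h - 1 - r_out):
        raise ValueError("aperture (with annulus) extends outside the image")
    disk, ring = _aperture_masks((h, w), x, y, aperture_radius, annulus_width)
    red = image.pixels[..., 0]
    green = image.pixels[..., 1]
    mean_red = red[disk].mean() - np.median(red[ring])
    mean_green = green[disk].mean() - np.median(green[ring])
    if mean_green <= 0:
        raise ValueError("non-positive background-subtracted green mean")
    return float(mean_red / mean_green)


def detect_particles(
    image: DarkFieldImage,
    min_separation: int = 5,
    threshold_sigmas: float = 5.0,
    aperture_radius: int = DEFAULT_APERTURE_RADIUS,
    annulus_width: int = DEFAULT_ANNULUS_WIDTH,
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
) -> list[Detection]:
    """Detect isolated bright spots and photometer each one.

    Local maxima of the smoothed channel-sum above
    ``median + threshold_sigmas * sigma_robust`` (sigma from the
    normal-consistent MAD) are kept, non-maximum-suppressed at
    ``min_separation`` pixels, then refined to an intensity-weighted
    centroid inside the aperture.  Detections whose aperture or
    background annulus would leave the frame, or whose green photometry
    is non-positive, are dropped.  An empty list is a valid result.
    """
    px = image.pixels
    if image.bit_depth is not None:
        sat = float(2**image.bit_depth - 1)
        if (px >= sat).mean() > 0.01:
            warnings.warn("more than 1% of pixels saturated", stacklevel=2)
    total = px.sum(axis=2)
    smoothed = gaussian(total, sigma=smooth_sigma, preserve_range=True)
    med = np.median(smoothed)
    mad = np.median(np.abs(smoothed - med))
    sigma_robust = 1.4826 * mad
    threshold = med + threshold_sigmas * sigma_robust

    border = aperture_radius + annulus_width
    peaks = peak_local_max(
        smoothed,
        min_distance=int(min_separation),
        threshold_abs=float(threshold),
        exclude_border=border,
    )
    detections: list[Detection] = []
    h, w = total.shape
    for row, col in peaks:
        # subpixel refinement: weighted centroid of the local excess signal
        disk, ring = _aperture_masks((h, w), col, row, aperture_radius, annulus_width)
        local = smoothed - med
        weights = np.where(disk, np.clip(local, 0, None), 0.0)
        wsum = weights.sum()
        if wsum > 0:
            yy, xx = np.mgrid[:h, :w]
            x_c = float((weights * xx).sum() / wsum)
            y_c = float((weights * yy).sum() / wsum)
        else:
            x_c, y_c = float(col), float(row)
        red = px[..., 0]
        green = px[..., 1]
        mean_red = red[disk].mean() - np.median(red[ring])
        mean_green = green[disk].mean() - np.median(green[ring])
        if mean_green <= 0:
            continue
        detections.append(
            Detection(
                x=x_c,
                y=y_c,
                radius=float(aperture_radius),
                mean_red=float(mean_red),
                mean_green=float(mean_green),
                rg=float(mean_red / mean_green),
            )
        )
    return detections


def population_shift(
    before: Sequence[float], after: Sequence[float]
) -> tuple[GroupComparison, dict[str, float]]:
    """Compare per-particle RG populations before/after incubation.

    Frames before and after are independent particle sets (no
    tracking), so this is an unpaired two-sided Student's t test plus
    summary moments.
    """
    comparison = compare_groups([before, after], mode="two-sample", labels=("before", "after"))
    b = np.asarray(before, float)
    a = np.asarray(after, float)
    summary = {
        "mean_before": float(b.mean()),
        "sd_before": float(b.std(ddof=1)),
        "n_before": int(b.size),
        "mean_after": float(a.mean()),
        "sd_after": float(a.std(ddof=1)),
        "n_after": int(a.size),
        "shift": float(a.mean() - b.mean()),
    }
    return comparison, summary


def nn_spacing(
    points: Sequence[Detection] | np.ndarray,
    pixel_size: float = 1.0,
) -> tuple[float, float]:
    """Mean and SD of the nearest-neighbour distance, in um.

    ``points`` is either a list of detections (coordinates in px,
    scaled by ``pixel_size``) or an (N, 2) coordinate array already in
    the units ``pixel_size`` maps from.
    """
    if len(points) >= 1 and isinstance(points[0], Detection):
        xy = np.array([(d.x, d.y) for d in points], dtype=float)
    else:
        xy = np.asarray(points, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 2:
        raise ValueError("need at least 2 points of shape (N, 2)")
    tree = cKDTree(xy)
    dist, _ = tree.query(xy, k=2)
    nn = dist[:, 1] * pixel_size
    if np.any(nn == 0):
        warnings.warn("duplicate coordinates: zero nearest-neighbour distance", stacklevel=2)
    return float(nn.mean()), float(nn.std(ddof=0))
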