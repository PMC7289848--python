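"""Ring detection and FWHM diameter measurement.

The ring (septin or actomyosin, viewed edge-on in a single epifluorescence
frame) appears as a short bright bar. Detection thresholds the frame,
rejects components below a minimum area and fits a moment-equivalent
ellipse to the largest surviving component. A brightness profile is then
read along the ellipse major axis, averaged over a perpendicular width,
smoothed with a 3-sample gliding average, background-subtracted using the
outermost three samples on each side, and the ring diameter is the full
width at half maximum of that profile.

A second, contour-based diameter (used around bud emergence) samples a
3x3-mean-filtered image along the cell contour and takes the arc-length
FWHM above the profile minimum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.measure import label as sk_label

from ._moments import equivalent_ellipse
from .exceptions import InsufficientDataError


@dataclass(frozen=True)
class RingDetection:
    """Moment ellipse fitted to the thresholded ring component."""

    center: tuple[float, float]  # (x, y) px
    orientation: float  # radians in [-pi/2, pi/2), major axis vs +x
    major_length: float  # px
    minor_length: float  # px
    area: int  # px of the component
    frame: int = 0


@dataclass(frozen=True)
class IntensityProfile:
    """1D fluorescence samples with uniform spacing.

    ``positions`` are in px relative to the profile center; ``values`` in a.u.
    """

    positions: np.ndarray
    values: np.ndarray
    spacing: float = 1.0  # px between samples
    smoothed: bool = False
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)
        if pos.shape != val.shape or pos.ndim != 1:
            raise ValueError("positions and values must be 1D and congruent")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class RingMeasurement:
    """Per-frame ring diameter and integrated intensity."""

    diameter: float  # µm; NaN when not valid
    total_intensity: float  # a.u.
    frame: int = 0
    valid: bool = True


def detect_ring(
    image: np.ndarray, threshold: float, min_area: int = 10, frame: int = 0
) -> RingDetection | None:
    """Threshold, reject small components, fit ellipse to the largest.

    Returns None when no component of at least ``min_area`` pixels survives
    (absence of a ring is a valid outcome, not an error). Components are
    8-connected; area ties are broken by the lowest label index.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    binary = np.asarray(image, dtype=float) > threshold
    if not binary.any():
        return None
    lab = sk_label(binary, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    counts[counts < min_area] = 0
    if counts.max() == 0:
        return None
    best = int(np.argmax(counts))
    rows, cols = np.nonzero(lab == best)
    ell = equivalent_ellipse(rows, cols)
    return RingDetection(
        center=(ell.centroid_x, ell.centroid_y),
        orientation=ell.orientation,
        major_length=ell.major_length,
        minor_length=ell.minor_length,
        area=int(counts[best]),
        frame=frame,
    )


def extract_profile(
    image: np.ndarray,
    detection: RingDetection,
    half_length: int = 30,
    avg_width: int = 10,
) -> IntensityProfile:
    """Brightness profile along the ring ellipse major axis.

    ``2*half_length + 1`` samples are taken through the ellipse center;
    each sample is the mean of ``avg_width`` bilinear samples perpendicular
    to the axis, centered on the line. Samples falling outside the image are
    clamped to the border (with a warning).
    """
    if detection is None:
        raise ValueError("detection is None; no ring to profile")
    img = np.asarray(image, dtype=float)
    cx, cy = detection.center
    theta = detection.orientation
    ux, uy = math.cos(theta), math.sin(theta)
    nx, ny = -math.sin(theta), math.cos(theta)
    t = np.arange(-half_length, half_length + 1, dtype=float)
    offsets = np.arange(avg_width, dtype=float) - (avg_width - 1) / 2.0
    xs = cx + t[:, None] * ux + offsets[None, :] * nx
    ys = cy + t[:, None] * uy + offsets[None, :] * ny
    if (
        xs.min() < 0
        or ys.min() < 0
        or xs.max() > img.shape[1] - 1
        or ys.max() > img.shape[0] - 1
    ):
        warnings.warn(
            "profile line extends beyond the image; samples clamped to border",
            stacklevel=2,
        )
    values = ndimage.map_coordinates(
        img, [ys.ravel(), xs.ravel()], order=1, mode="nearest"
    ).reshape(xs.shape)
    return IntensityProfile(positions=t, values=values.mean(axis=1))


def smooth_subtract_background(profile: IntensityProfile) -> IntensityProfile:
    """3-sample gliding average, then outermost-3 background subtraction.

    The moving mean uses a shrinking window at the profile ends so the
    sample count is preserved; the background is the mean of the first and
    last three smoothed samples.
    """
    v = profile.values
    if len(v) < 7:
        raise InsufficientDataError("profile needs at least 7 samples")
    smoothed = v.copy()
    smoothed[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
    smoothed[0] = (v[0] + v[1]) / 2.0
    smoothed[-1] = (v[-2] + v[-1]) / 2.0
    background = float(np.mean(np.concatenate([smoothed[:3], smoothed[-3:]])))
    return replace(
        profile,
        values=smoothed - background,
        smoothed=True,
        background_subtracted=True,
    )


def _crossings(values: np.ndarray, half: float) -> tuple[float, float] | None:
    """Outermost half-max crossings, scanning inward from each profile end.

    Returns fractional index positions, or None if the signal touches either
    end (no crossing can be bracketed).
    """
    above = values >= half
    idx = np.nonzero(above)[0]
    left = idx[0]
    right = idx[-1]
    if left == 0 or right == len(values) - 1:
        return None
    xl = (left - 1) + (half - values[left - 1]) / (values[left] - values[left - 1])
    xr = right + (values[right] - half) / (values[right] - values[right + 1])
    return xl, xr


def fwhm_diameter(profile: IntensityProfile, pixel_size: float) -> float:
    """Full width at half maximum of a background-subtracted profile, in µm.

    Half-max crossings are the first samples at or above half maximum when
    scanning inward from each end, refined by linear interpolation between
    the bracketing samples. Returns NaN (invalid measurement) when the
    maximum is non-positive or the signal touches a profile end.
    """
    v = profile.values
    m = float(v.max()) if len(v) else 0.0
    if m <= 0:
        return float("nan")
    res = _crossings(v, m / 2.0)
    if res is None:
        return float("nan")
    xl, xr = res
    return (xr - xl) * profile.spacing * pixel_size


def ring_total_intensity(profile: IntensityProfile) -> float:
    """Integrated background-subtracted profile intensity (negatives clipped)."""
    return float(np.clip(profile.values, 0.0, None).sum())


def measure_ring_frame(
    image: np.ndarray,
    threshold: float,
    pixel_size: float,
    min_area: int = 10,
    half_length: int = 30,
    avg_width: int = 10,
    frame: int = 0,
) -> RingMeasurement:
    """detect -> profile -> smooth/subtract -> FWHM for one frame."""
    det = detect_ring(image, threshold, min_area=min_area, frame=frame)
    if det is None:
        return RingMeasurement(float("nan"), 0.0, frame=frame, valid=False)
    prof = smooth_subtract_background(
        extract_profile(image, det, half_length=half_length, avg_width=avg_width)
    )
    d = fwhm_diameter(prof, pixel_size)
    return RingMeasurement(
        diameter=d,
        total_intensity=ring_total_intensity(prof),
        frame=frame,
        valid=not math.isnan(d),
    )


def _contour_arclength(contour: np.ndarray) -> tuple[np.ndarray, float]:
    """Cumulative arc length at each vertex and total closed length (px)."""
    pts = np.asarray(contour, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0, append=pts[:1]), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg[:-1])])
    return cum, float(seg.sum())


def _sample_contour(image: np.ndarray, contour: np.ndarray) -> np.ndarray:
    pts = np.asarray(contour, dtype=float)
    return ndimage.map_coordinates(
        np.asarray(image, dtype=float), [pts[:, 1], pts[:, 0]], order=1, mode="nearest"
    )


def contour_ring_diameter(
    frames: list[np.ndarray] | np.ndarray,
    contour: np.ndarray,
    pixel_size: float,
) -> float:
    """Arc-length FWHM ring diameter from a contour profile, in µm.

    Each frame is 3x3-mean-filtered and sampled at the contour vertices;
    the per-vertex mean over the frames is taken, the profile minimum is
    the baseline, and the diameter is the arc length between the half-max
    crossings around the profile maximum (circularly indexed). Returns NaN
    for a flat profile.
    """
    profs = [
        _sample_contour(ndimage.uniform_filter(np.asarray(f, float), 3, mode="nearest"), contour)
        for f in frames
    ]
    mean_prof = np.mean(profs, axis=0)
    lo = float(mean_prof.min())
    hi = float(mean_prof.max())
    if hi <= lo:
        return float("nan")
    half = lo + (hi - lo) / 2.0
    n = len(mean_prof)
    cum, total = _contour_arclength(contour)
    # center the peak, then find crossings as in the linear case
    shift = n // 2 - int(np.argmax(mean_prof))
    rolled = np.roll(mean_prof, shift)
    res = _crossings(rolled, half)
    if res is None:
        return float("nan")
    xl, xr = res
    gap = total / n  # vertices are assumed (re)sampled at equal arc length
    return (xr - xl) * gap * pixel_size


def resample_contour(contour: np.ndarray, n_vertices: int = 65) -> np.ndarray:
    """Resample a closed contour to ``n_vertices`` equal-arc-length vertices."""
    pts = np.asarray(contour, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("contour has zero length")
    s = np.linspace(0.0, total, n_vertices, endpoint=False)
    x = np.interp(s, cum, closed[:, 0])
    y = np.interp(s, cum, closed[:, 1])
    return np.column_stack([x, y])
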