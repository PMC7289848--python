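"""Cdc42-GTP cluster morphometry and local cell curvature.

The cortical cluster of active Cdc42 marks the incipient bud site. Its size
is quantified three ways — pixel-count area above an adaptive threshold
(median + 2 SD of in-cell intensities), moment axes of the largest cluster
component, and arc length of the suprathreshold peak in a contour intensity
profile — plus the local radius of cell curvature at the site, from a
least-squares circle fit to a 7-vertex contour window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from ._moments import equivalent_ellipse
from .exceptions import DegenerateFitError, EmptyMaskError
from .geometry import CellMask, largest_component
from .ring import _contour_arclength, _sample_contour


@dataclass(frozen=True)
class ClusterMeasurement:
    """Cdc42-GTP cluster size measures for one cell."""

    area: float  # µm², median over the 3-frame window; NaN if invalid
    major_axis: float  # µm
    minor_axis: float  # µm
    contour_length: float  # µm
    threshold: float  # a.u., threshold used at the peak frame
    valid: bool = True


@dataclass(frozen=True)
class CurvatureMeasurement:
    """Local radius of cell curvature at the incipient bud site."""

    radius: float  # µm
    anchor: int  # contour vertex index at the window center
    residual: float  # µm, mean |distance - radius| of the fitted vertices


def cluster_threshold(image: np.ndarray, mask: CellMask) -> float:
    """Median + 2 population standard deviations of in-mask intensities."""
    values = np.asarray(image, dtype=float)[mask.pixels]
    if values.size == 0:
        raise EmptyMaskError("mask selects no pixels")
    return float(np.median(values) + 2.0 * np.std(values))


def cluster_pixels(image: np.ndarray, mask: CellMask) -> np.ndarray:
    """Boolean cluster mask: in-mask pixels strictly above the threshold."""
    thr = cluster_threshold(image, mask)
    return (np.asarray(image, dtype=float) > thr) & mask.pixels


def cluster_area(
    frames: Sequence[np.ndarray],
    masks: CellMask | Sequence[CellMask],
    pixel_size: float,
) -> float:
    """Median cluster pixel count over the frames, converted to µm².

    The paper's window is the 3 frames centered on peak Cdc42 localization;
    each frame uses its own adaptive threshold. Returns NaN when the
    cluster is empty in every frame.
    """
    if isinstance(masks, CellMask):
        masks = [masks] * len(frames)
    counts = [int(cluster_pixels(f, m).sum()) for f, m in zip(frames, masks)]
    if all(c == 0 for c in counts):
        return float("nan")
    return float(np.median(counts)) * pixel_size**2


def cluster_axes(cluster: np.ndarray, pixel_size: float) -> tuple[float, float]:
    """Moment-ellipse (major, minor) axis lengths (µm) of the largest
    8-connected component of a boolean cluster mask."""
    comp = largest_component(np.asarray(cluster, dtype=bool))
    rows, cols = np.nonzero(comp)
    ell = equivalent_ellipse(rows, cols)
    return ell.major_length * pixel_size, ell.minor_length * pixel_size


def cluster_contour_length(
    frames: Sequence[np.ndarray],
    masks: CellMask | Sequence[CellMask],
    contour: np.ndarray,
    pixel_size: float,
) -> float:
    """Arc length (µm) of the suprathreshold peak in the contour profile.

    Each frame is 5x5-maximum-filtered (the cluster sits slightly inside
    the segmentation contour) and sampled at the contour vertices; the mean
    profile over the frames is thresholded at the median of the per-frame
    adaptive thresholds, and the length is the arc length of the contiguous
    suprathreshold run (circularly indexed) containing the profile maximum.
    Returns NaN when no vertex is above the threshold.
    """
    if isinstance(masks, CellMask):
        masks = [masks] * len(frames)
    thresholds = [cluster_threshold(f, m) for f, m in zip(frames, masks)]
    profs = [
        _sample_contour(
            ndimage.maximum_filter(np.asarray(f, float), size=5, mode="nearest"),
            contour,
        )
        for f in frames
    ]
    mean_prof = np.mean(profs, axis=0)
    thr = float(np.median(thresholds))
    above = mean_prof > thr
    if not above.any():
        return float("nan")
    n = len(mean_prof)
    peak = int(np.argmax(mean_prof))
    # walk outward from the peak while vertices stay above threshold
    left = peak
    while above[(left - 1) % n] and (peak - left) < n - 1:
        left -= 1
    right = peak
    while above[(right + 1) % n] and (right - peak) < n - 1:
        right += 1
    run_gaps = right - left  # number of inter-vertex gaps spanned by the run
    _, total = _contour_arclength(contour)
    return run_gaps * (total / n) * pixel_size


def measure_cluster(
    frames: Sequence[np.ndarray],
    masks: CellMask | Sequence[CellMask],
    contour: np.ndarray,
    pixel_size: float,
) -> ClusterMeasurement:
    """Bundle the three cluster size measures for one peak window."""
    if isinstance(masks, CellMask):
        masks = [masks] * len(frames)
    mid = len(frames) // 2
    area = cluster_area(frames, masks, pixel_size)
    valid = not np.isnan(area)
    if valid:
        cl = cluster_pixels(frames[mid], masks[mid])
        if cl.any():
            major, minor = cluster_axes(cl, pixel_size)
        else:
            major = minor = float("nan")
    else:
        major = minor = float("nan")
    length = cluster_contour_length(frames, masks, contour, pixel_size)
    return ClusterMeasurement(
        area=area,
        major_axis=major,
        minor_axis=minor,
        contour_length=length,
        threshold=cluster_threshold(frames[mid], masks[mid]),
        valid=valid,
    )


def fit_circle(points: np.ndarray) -> tuple[float, float, float, float]:
    """Kåsa algebraic least-squares circle fit.

    Returns (cx, cy, radius, residual) in the units of ``points``;
    residual is the mean absolute radial misfit. Raises DegenerateFitError
    for collinear points.
    """
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2.0 * x, 2.0 * y, np.ones_like(x)])
    b = x**2 + y**2
    if np.linalg.matrix_rank(A, tol=1e-10 * max(1.0, np.abs(A).max())) < 3:
        raise DegenerateFitError("circle fit is singular (collinear vertices)")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r2 = c + cx**2 + cy**2
    if r2 <= 0:
        raise DegenerateFitError("circle fit produced a non-positive radius")
    r = float(np.sqrt(r2))
    resid = float(np.mean(np.abs(np.hypot(x - cx, y - cy) - r)))
    return float(cx), float(cy), r, resid


def local_curvature_radius(
    contour: np.ndarray,
    anchor: int,
    pixel_size: float,
    window: int = 7,
) -> CurvatureMeasurement:
    """Radius (µm) of the circle fitted to ``window`` contour vertices
    centered (circularly) on ``anchor``."""
    pts = np.asarray(contour, dtype=float)
    n = len(pts)
    if n < window:
        raise ValueError(f"contour needs at least {window} vertices")
    half = window // 2
    idx = (np.arange(anchor - half, anchor - half + window)) % n
    _, _, r, resid = fit_circle(pts[idx])
    return CurvatureMeasurement(
        radius=r * pixel_size, anchor=int(anchor) % n, residual=resid * pixel_size
    )


def curvature_radius_median(
    contours: Sequence[np.ndarray],
    anchors: Sequence[int] | int,
    pixel_size: float,
    window: int = 7,
) -> float:
    """Median curvature radius over a window of frames (the paper uses the
    5 frames centered on bud emergence)."""
    if isinstance(anchors, (int, np.integer)):
        anchors = [int(anchors)] * len(contours)
    radii = [
        local_curvature_radius(c, a, pixel_size, window=window).radius
        for c, a in zip(contours, anchors)
    ]
    return float(np.median(radii))
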