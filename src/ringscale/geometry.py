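"""Cell-level geometry from 2D masks and confocal stacks.

The central quantity is the *revolution volume*: the segmented 2D cell area
is aligned along its moment major axis, cut into 1-px slices perpendicular
to that axis, and each slice is treated as a cylinder of height 1 px whose
diameter is the slice width. This approximates the volume of an ovoid yeast
cell from a single widefield segmentation. A confocal-stack reconstruction
(hysteresis thresholding with an automatic low/high threshold pair) serves
as the independent volume estimate for validation.

Units: pixel coordinates everywhere internally; physical outputs in µm and
fL (1 fL = 1 µm³).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import apply_hysteresis_threshold
from skimage.measure import label as sk_label

from ._moments import equivalent_ellipse
from .exceptions import EmptyMaskError, NoForegroundError

SPHERE_NORM = (math.pi / 6.0) ** (1.0 / 3.0)  # makes elongation 1 for a sphere


@dataclass(frozen=True)
class CellMask:
    """Binary mask of one cell in one frame.

    ``pixels`` is a 2D boolean array (row-major). ``contour`` is an optional
    ordered (N, 2) array of (x, y) vertex coordinates in px, closed
    implicitly (last vertex connects to the first).
    """

    pixels: np.ndarray
    pixel_size: float  # µm/px
    frame: int = 0
    cell_id: str = "cell"
    contour: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2 or not px.any():
            raise EmptyMaskError(f"mask for {self.cell_id!r} is empty")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class CellGeometry:
    """Scalar geometry of one cell in one frame."""

    volume: float  # fL
    length: float  # µm, moment major-axis length
    elongation: float  # dimensionless, 1 for a sphere
    total_fluorescence: float = float("nan")  # a.u.
    frame: int = 0
    cell_id: str = "cell"


def revolution_volume(mask: CellMask) -> float:
    """Solid-of-revolution volume of a 2D mask, in fL.

    Foreground pixel centers are rotated into the major-axis frame
    (continuous rotation, no re-rasterization), binned into 1-px slices
    along the axis; each slice contributes ``pi/4 * width**2`` px³ where
    width is the slice extent (max - min + 1) perpendicular to the axis.
    """
    rows, cols = np.nonzero(mask.pixels)
    ell = equivalent_ellipse(rows, cols)
    theta = ell.orientation
    x = cols.astype(float)
    y = rows.astype(float)
    u = x * math.cos(theta) + y * math.sin(theta)  # along major axis
    v = -x * math.sin(theta) + y * math.cos(theta)  # perpendicular
    slices = np.floor(u - u.min() + 0.5).astype(int)
    vol_px = 0.0
    for s in np.unique(slices):
        vs = v[slices == s]
        width = vs.max() - vs.min() + 1.0
        vol_px += math.pi / 4.0 * width**2
    return vol_px * mask.pixel_size**3


def major_axis_length(mask: CellMask) -> float:
    """Major-axis length (µm) of the moment-equivalent ellipse."""
    rows, cols = np.nonzero(mask.pixels)
    ell = equivalent_ellipse(rows, cols)
    return ell.major_length * mask.pixel_size


def elongation(length: float, volume: float) -> float:
    """Cell length over cube root of volume, normalized to 1 for a sphere.

    ``(pi/6)**(1/3) * L / V**(1/3)``; for a prolate spheroid with axis ratio
    q = a/b this equals q**(2/3).
    """
    if length <= 0 or volume <= 0:
        raise ValueError("length and volume must be positive")
    return SPHERE_NORM * length / volume ** (1.0 / 3.0)


def total_cell_fluorescence(image: np.ndarray, mask: CellMask) -> float:
    """Background-subtracted total fluorescence over the mask, in a.u.

    Background is the median pixel value of the non-cell area of the
    4-px-average-filtered image; the sum of (pixel - background) is taken
    over the raw in-mask pixels.
    """
    img = np.asarray(image, dtype=float)
    if img.shape != mask.pixels.shape:
        raise ValueError("image and mask shapes differ")
    outside = ~mask.pixels
    if not outside.any():
        raise EmptyMaskError("mask covers the entire image; no background region")
    filtered = ndimage.uniform_filter(img, size=4, mode="nearest")
    background = float(np.median(filtered[outside]))
    return float(np.sum(img[mask.pixels] - background))


def li_threshold(values: np.ndarray, tol: float = 1e-6) -> float:
    """Li minimum-cross-entropy threshold by fixed-point iteration.

    ``t <- (mu_above - mu_below) / (ln mu_above - ln mu_below)`` iterated to
    ``tol`` (absolute), starting from the mean. Operates on the raw
    (positive) intensities; ties (values exactly at t) go to the lower
    class. For a constant image the single intensity value is returned.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = np.clip(v, 1e-12, None)
    if v.max() == v.min():
        return float(v[0])
    t = float(v.mean())
    for _ in range(500):
        below = v[v <= t]
        above = v[v > t]
        if below.size == 0 or above.size == 0:
            break
        m0 = below.mean()
        m1 = above.mean()
        t_new = (m1 - m0) / (math.log(m1) - math.log(m0))
        if abs(t_new - t) < tol:
            return float(t_new)
        t = t_new
    return float(t)


def reconstruct_volume_3d(
    zstack: np.ndarray, mask2d: CellMask, z_step: float
) -> float:
    """Confocal 3D-reconstruction volume (fL) by hysteresis thresholding.

    Per slice, foreground = pixels above a low threshold (Li minimum
    cross-entropy, computed per slice) connected to pixels above the high
    threshold. The high threshold is 90% of the maximum intensity inside
    the widefield 2D mask, taken over the whole stack so that slices
    containing only background contribute no seed pixels.
    """
    if z_step <= 0:
        raise ValueError("z_step must be positive")
    stack = np.asarray(zstack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("zstack must be a 3D array (z, y, x)")
    if stack.shape[1:] != mask2d.pixels.shape:
        raise ValueError("stack slices and mask2d shapes differ")
    in_mask_max = stack[:, mask2d.pixels].max()
    if in_mask_max <= 0:
        raise NoForegroundError("no voxel above the high threshold in any slice")
    high = 0.9 * in_mask_max
    voxels = 0
    for sl in stack:
        if sl.max() < high:
            continue  # no seed pixel in this slice
        low = li_threshold(sl)
        low = min(low, 0.999 * high)
        seg = apply_hysteresis_threshold(sl, low, high)
        voxels += int(seg.sum())
    if voxels == 0:
        raise NoForegroundError("no voxel above the high threshold in any slice")
    return voxels * mask2d.pixel_size**2 * z_step


def measure_geometry(
    mask: CellMask, image: np.ndarray | None = None
) -> CellGeometry:
    """Bundle volume, length, elongation and (optional) total fluorescence."""
    vol = revolution_volume(mask)
    length = major_axis_length(mask)
    fluor = float("nan")
    if image is not None:
        fluor = total_cell_fluorescence(image, mask)
    return CellGeometry(
        volume=vol,
        length=length,
        elongation=elongation(length, vol),
        total_fluorescence=fluor,
        frame=mask.frame,
        cell_id=mask.cell_id,
    )


def largest_component(binary: np.ndarray) -> np.ndarray:
    """Largest 8-connected component of a boolean image (ties: lowest label)."""
    lab = sk_label(binary, connectivity=2)
    if lab.max() == 0:
        raise EmptyMaskError("no foreground component")
    counts = np.bincount(lab.ravel())[1:]
    best = int(np.argmax(counts)) + 1  # argmax returns first max -> lowest label
    return lab == best
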