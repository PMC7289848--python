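"""Moment-equivalent ellipse of a pixel set.

Axis lengths follow the unit-square pixel model (each foreground pixel is a
1x1 square, adding 1/12 to each diagonal second moment), i.e. the convention
of MATLAB ``regionprops`` rather than skimage's point-mass convention. The
downstream line-profile geometry was established with that tool, so the same
convention is kept here.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np

from .exceptions import EmptyMaskError


class EquivalentEllipse(NamedTuple):
    centroid_x: float  # column coordinate, px
    centroid_y: float  # row coordinate, px
    orientation: float  # radians, major axis vs +x (column) axis, [-pi/2, pi/2)
    major_length: float  # px
    minor_length: float  # px


def equivalent_ellipse(rows: np.ndarray, cols: np.ndarray) -> EquivalentEllipse:
    """Ellipse with the same normalized second central moments as the pixels.

    ``rows``/``cols`` are the integer coordinates of the foreground pixel
    centers. Orientation is measured in image coordinates (x = column,
    y = row, y increasing downward).
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    if rows.size == 0:
        raise EmptyMaskError("cannot fit an ellipse to an empty pixel set")
    x = cols
    y = rows
    mx = x.mean()
    my = y.mean()
    # unit-square pixel model: +1/12 per diagonal moment
    uxx = np.mean((x - mx) ** 2) + 1.0 / 12.0
    uyy = np.mean((y - my) ** 2) + 1.0 / 12.0
    uxy = np.mean((x - mx) * (y - my))
    common = math.sqrt((uxx - uyy) ** 2 + 4.0 * uxy**2)
    lam1 = (uxx + uyy + common) / 2.0
    lam2 = (uxx + uyy - common) / 2.0
    major = 4.0 * math.sqrt(max(lam1, 0.0))
    minor = 4.0 * math.sqrt(max(lam2, 0.0))
    if uxy == 0.0 and uxx >= uyy:
        theta = 0.0
    elif uxy == 0.0:
        theta = -math.pi / 2.0
    else:
        theta = 0.5 * math.atan2(2.0 * uxy, uxx - uyy)
    # normalize to [-pi/2, pi/2)
    if theta >= math.pi / 2.0:
        theta -= math.pi
    elif theta < -math.pi / 2.0:
        theta += math.pi
    return EquivalentEllipse(mx, my, theta, major, minor)
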