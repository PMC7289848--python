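"""Shared fixtures and rasterization helpers."""

import math

import numpy as np
import pytest

from ringscale.geometry import CellMask


def rasterize_ellipse(
    semi_x: float, semi_y: float, theta: float = 0.0, margin: int = 5
) -> np.ndarray:
    """Pixel-center rasterization of a rotated ellipse, as a bool image."""
    half_w = abs(semi_x * math.cos(theta)) + abs(semi_y * math.sin(theta)) + margin
    half_h = abs(semi_x * math.sin(theta)) + abs(semi_y * math.cos(theta)) + margin
    n_w = 2 * int(math.ceil(half_w)) + 1
    n_h = 2 * int(math.ceil(half_h)) + 1
    yy, xx = np.mgrid[0:n_h, 0:n_w]
    dx = xx - (n_w - 1) / 2.0
    dy = yy - (n_h - 1) / 2.0
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    return (u / semi_x) ** 2 + (v / semi_y) ** 2 <= 1.0


def disk_mask(radius_px: float, pixel_size: float) -> CellMask:
    return CellMask(rasterize_ellipse(radius_px, radius_px), pixel_size)


def circle_contour(
    radius_px: float, n_vertices: int = 65, center: float = None
) -> np.ndarray:
    if center is None:
        center = radius_px + 5.0
    t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    return np.column_stack(
        [center + radius_px * np.cos(t), center + radius_px * np.sin(t)]
    )


@pytest.fixture(scope="session")
def noiseless_population():
    """50 rendered noiseless cells with their single-frame measurements.

    Reused wherever a measured-vs-truth comparison on realistic scenes is
    needed (end-to-end recovery, invariances).
    """
    from ringscale.ring import measure_ring_frame
    from ringscale.synthetic import (
        PopulationConfig,
        RenderConfig,
        generate_population,
        suggested_threshold,
    )

    config = PopulationConfig(n_cells=50, diameter_noise_cv=0.0, seed=11)
    render = RenderConfig()
    threshold = suggested_threshold(render)
    cells = generate_population(config)
    rendered = []
    from ringscale.synthetic import render_cell_frame

    for cell in cells:
        img, mask = render_cell_frame(cell, render)
        meas = measure_ring_frame(img, threshold, cell.pixel_size)
        rendered.append((cell, img, mask, meas))
    return {"config": config, "render": render, "threshold": threshold, "cells": rendered}
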