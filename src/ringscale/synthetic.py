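"""Synthetic microscopy scenes with known ground truth.

Emulates the study system: a steady-state population of budding-yeast-like
cells whose volumes are lognormally distributed (spanning roughly 30-300 fL
at the default spread), shaped as prolate spheroids, each carrying a
bud-neck ring whose true diameter follows a configurable power law of cell
volume with multiplicative lognormal noise, and a cortical Cdc42-GTP
cluster whose diameter scales with the cube root of volume. Scenes are
rendered as widefield-like frames (uniform-intensity bar for the edge-on
ring, Gaussian PSF, optional read noise), confocal-like z-stacks of
cytoplasmic signal, polarization-to-budding timecourses, and replicative
aging tracks.

All randomness flows from one seed through a hierarchical stream split
(population -> cell -> frame), so adding cells or frames never perturbs
earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage

from .exceptions import ConfigurationError, RenderError
from .geometry import CellMask

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class PopulationConfig:
    """Ground-truth population parameters.

    ``ring_diameter_true = prefactor_c * V**exponent_alpha * noise`` with
    multiplicative lognormal noise of coefficient of variation
    ``diameter_noise_cv`` (median-preserving). Volumes are lognormal with
    the given median (fL) and log10 standard deviation. The default
    exponent/prefactor reproduce the wild-type glycerol/ethanol scaling
    (alpha 0.31, ~1.2 µm at 50 fL); the default log10 spread of 0.25 gives
    a population covering roughly 30-300 fL, as in the pooled
    inducible-Whi5 experiments.
    """

    n_cells: int = 200
    volume_median: float = 80.0  # fL
    volume_log10_sd: float = 0.25
    exponent_alpha: float = 0.31
    prefactor_c: float = 0.36  # µm * fL^-alpha
    diameter_noise_cv: float = 0.10
    aspect_ratio_mean: float = 1.2
    aspect_ratio_sd: float = 0.1
    pixel_size: float = 0.1  # µm/px
    seed: int = 0
    cluster_exponent: float = 1.0 / 3.0
    cluster_prefactor: float = 0.25  # µm * fL^-1/3

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        for name in ("volume_median", "prefactor_c", "pixel_size", "cluster_prefactor"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("volume_log10_sd", "diameter_noise_cv", "aspect_ratio_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.aspect_ratio_mean < 1.0:
            raise ConfigurationError("aspect_ratio_mean must be >= 1 (prolate)")


@dataclass(frozen=True)
class RenderConfig:
    """Image-formation parameters (all intensities in camera a.u.)."""

    psf_sigma: float = 1.0  # px
    background_level: float = 100.0
    read_noise_sd: float = 0.0
    ring_peak_intensity: float = 500.0
    ring_bar_width: float = 3.0  # px, transverse width of the edge-on ring
    cytoplasm_level: float = 300.0
    cluster_peak_intensity: float = 400.0
    frame_count_ring: int = 12
    cluster_peak_frame: int = 3
    bud_emergence_frame: int = 8
    z_step: float = 0.3  # µm, confocal stacks
    margin: int = 36  # px of padding around the cell bounding box

    def __post_init__(self) -> None:
        if self.frame_count_ring < 1:
            raise ConfigurationError("frame_count_ring must be >= 1")
        if self.cluster_peak_frame >= self.bud_emergence_frame:
            raise ConfigurationError(
                "cluster_peak_frame must precede bud_emergence_frame"
            )
        if self.psf_sigma <= 0 or self.margin < 0:
            raise ConfigurationError("psf_sigma must be positive, margin >= 0")


@dataclass(frozen=True)
class SyntheticCell:
    """Ground-truth geometry of one synthetic cell.

    The shape is a prolate spheroid with semi-axes (a, b, b), so
    ``volume_true == (4/3) * pi * a * b**2`` and ``length_true == 2 a``.
    """

    cell_id: str
    volume_true: float  # fL
    length_true: float  # µm
    ring_diameter_true: float  # µm
    cluster_diameter_true: float  # µm
    semi_axis_a: float  # µm
    semi_axis_b: float  # µm
    orientation: float  # radians, major axis vs image x axis
    pixel_size: float  # µm/px
    generation: int = 1
    seed: int = 0  # per-cell noise stream


def _spawn_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _truncated_normal_geq1(
    rng: np.random.Generator, mean: float, sd: float
) -> float:
    if sd == 0:
        return max(mean, 1.0)
    for _ in range(1000):
        q = rng.normal(mean, sd)
        if q >= 1.0:
            return q
    return 1.0


def generate_population(config: PopulationConfig) -> list[SyntheticCell]:
    """Draw a steady-state population with known scaling ground truth."""
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_cells)
    sigma_ln = math.sqrt(math.log(1.0 + config.diameter_noise_cv**2))
    cells = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        volume = 10.0 ** (
            math.log10(config.volume_median)
            + rng.normal(0.0, config.volume_log10_sd)
        )
        q = _truncated_normal_geq1(rng, config.aspect_ratio_mean, config.aspect_ratio_sd)
        b = (3.0 * volume / (4.0 * math.pi * q)) ** (1.0 / 3.0)
        a = q * b
        noise = math.exp(rng.normal(0.0, sigma_ln)) if sigma_ln > 0 else 1.0
        d_true = config.prefactor_c * volume**config.exponent_alpha * noise
        cells.append(
            SyntheticCell(
                cell_id=f"cell_{i:04d}",
                volume_true=volume,
                length_true=2.0 * a,
                ring_diameter_true=d_true,
                cluster_diameter_true=(
                    config.cluster_prefactor * volume**config.cluster_exponent
                ),
                semi_axis_a=a,
                semi_axis_b=b,
                orientation=rng.uniform(-math.pi / 2.0, math.pi / 2.0),
                pixel_size=config.pixel_size,
                seed=_spawn_seed(child.spawn(1)[0]),
            )
        )
    return cells


def _cell_grid(cell: SyntheticCell, render: RenderConfig):
    """Pixel grid and rotated coordinates centered on the cell."""
    px = cell.pixel_size
    a_px = cell.semi_axis_a / px
    b_px = cell.semi_axis_b / px
    c, s = math.cos(cell.orientation), math.sin(cell.orientation)
    half_w = abs(a_px * c) + abs(b_px * s) + render.margin
    half_h = abs(a_px * s) + abs(b_px * c) + render.margin
    nx = 2 * int(math.ceil(half_w)) + 1
    ny = 2 * int(math.ceil(half_h)) + 1
    yy, xx = np.mgrid[0:ny, 0:nx]
    dx = xx - (nx - 1) / 2.0
    dy = yy - (ny - 1) / 2.0
    u = dx * c + dy * s  # along major axis, px
    v = -dx * s + dy * c
    return a_px, b_px, u, v, (ny, nx)


def cell_contour(
    cell: SyntheticCell, render: RenderConfig, n_vertices: int = 65
) -> np.ndarray:
    """Analytic spheroid-boundary contour in image coordinates (x, y px).

    Vertex 0 sits at the major-axis tip nearest the neck. Vertices are
    equally spaced in the ellipse parameter (nearly equal arc length for
    mild aspect ratios).
    """
    a_px = cell.semi_axis_a / cell.pixel_size
    b_px = cell.semi_axis_b / cell.pixel_size
    _, _, _, _, shape = _cell_grid(cell, render)
    t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    ex = a_px * np.cos(t)
    ey = b_px * np.sin(t)
    c, s = math.cos(cell.orientation), math.sin(cell.orientation)
    x = ex * c - ey * s + (shape[1] - 1) / 2.0
    y = ex * s + ey * c + (shape[0] - 1) / 2.0
    return np.column_stack([x, y])


def _spheroid_mask(cell: SyntheticCell, render: RenderConfig) -> np.ndarray:
    a_px, b_px, u, v, _ = _cell_grid(cell, render)
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


def _render_bar(
    cell: SyntheticCell,
    render: RenderConfig,
    u: np.ndarray,
    v: np.ndarray,
    a_px: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Edge-on ring: uniform bar of length d_true across the neck."""
    L = cell.ring_diameter_true / cell.pixel_size
    neck_u = 0.9 * a_px  # bar center sits near the major-axis tip (the neck)
    t_long = v  # bar long axis is perpendicular to the cell major axis
    t_perp = u - neck_u
    half_h = (shape[0] - 1) / 2.0
    half_w = (shape[1] - 1) / 2.0
    c, s = math.cos(cell.orientation), math.sin(cell.orientation)
    for sign in (-1.0, 1.0):
        ex = neck_u * c - sign * (L / 2.0) * s + half_w
        ey = neck_u * s + sign * (L / 2.0) * c + half_h
        if not (0 <= ex < shape[1] and 0 <= ey < shape[0]):
            raise RenderError("ring is wider than the rendered image")
    cover_long = np.clip(L / 2.0 - np.abs(t_long) + 0.5, 0.0, 1.0)
    cover_perp = np.clip(render.ring_bar_width / 2.0 - np.abs(t_perp) + 0.5, 0.0, 1.0)
    return render.ring_peak_intensity * cover_long * cover_perp


def render_cell_frame(
    cell: SyntheticCell,
    render: RenderConfig,
    frame: int = 0,
    with_ring: bool = True,
) -> tuple[np.ndarray, CellMask]:
    """Render one ring-channel frame and the matching ground-truth mask.

    The ring is a uniform-intensity bar of length ``ring_diameter_true``
    across the bud neck, convolved with a Gaussian PSF, on a constant
    background with optional Gaussian read noise. The mask is the
    rasterized spheroid projection (pixel-center test).
    """
    a_px, b_px, u, v, shape = _cell_grid(cell, render)
    img = np.zeros(shape)
    if with_ring:
        img += _render_bar(cell, render, u, v, a_px, shape)
    img = ndimage.gaussian_filter(img, render.psf_sigma)
    img += render.background_level
    if render.read_noise_sd > 0:
        rng = np.random.default_rng([cell.seed, 7919, frame])
        img += rng.normal(0.0, render.read_noise_sd, size=img.shape)
    mask = CellMask(
        pixels=(u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0,
        pixel_size=cell.pixel_size,
        frame=frame,
        cell_id=cell.cell_id,
    )
    return img, mask


def render_cell_zstack(cell: SyntheticCell, render: RenderConfig) -> np.ndarray:
    """Confocal-like stack of cytoplasmic signal through the spheroid.

    Slices are spaced ``z_step`` µm apart, sampled at slice centers, and
    cover the cell plus one empty slice of margin on each side.
    """
    if render.z_step <= 0:
        raise ConfigurationError("z_step must be positive")
    if cell.volume_true <= 0:
        raise ConfigurationError("cell has zero volume")
    a_px, b_px, u, v, shape = _cell_grid(cell, render)
    b = cell.semi_axis_b
    n_half = int(math.ceil(b / render.z_step)) + 1
    zs = np.arange(-n_half, n_half + 1) * render.z_step
    slices = []
    rng = np.random.default_rng([cell.seed, 104729])
    for z in zs:
        scale2 = 1.0 - (z / b) ** 2
        sl = np.zeros(shape)
        if scale2 > 0:
            inside = (u / (a_px * math.sqrt(scale2))) ** 2 + (
                v / (b_px * math.sqrt(scale2))
            ) ** 2 <= 1.0
            sl[inside] = render.cytoplasm_level
        sl = ndimage.gaussian_filter(sl, render.psf_sigma)
        sl += render.background_level
        if render.read_noise_sd > 0:
            sl += rng.normal(0.0, render.read_noise_sd, size=sl.shape)
        slices.append(sl)
    return np.stack(slices)


@dataclass(frozen=True)
class TimecourseFrame:
    """One frame of a polarization-to-budding timecourse."""

    frame: int
    ring_image: np.ndarray
    cluster_image: np.ndarray
    mask: CellMask
    ring_present: bool
    cluster_amplitude: float  # a.u., ground-truth spot amplitude


@dataclass(frozen=True)
class Timecourse:
    cell: SyntheticCell
    frames: tuple[TimecourseFrame, ...]
    cluster_peak_frame: int
    bud_emergence_frame: int

    @property
    def ground_truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": [f.frame for f in self.frames],
                "ring_present": [f.ring_present for f in self.frames],
                "cluster_amplitude": [f.cluster_amplitude for f in self.frames],
                "cluster_peak_frame": self.cluster_peak_frame,
                "bud_emergence_frame": self.bud_emergence_frame,
                "d_true_um": self.cell.ring_diameter_true,
                "cluster_d_true_um": self.cell.cluster_diameter_true,
            }
        )


def generate_timecourse(
    cell: SyntheticCell, render: RenderConfig, n_trailing: int = 2
) -> Timecourse:
    """Polarity cluster peaks, then the ring appears at bud emergence.

    The cluster channel carries a cortical Gaussian spot at the neck whose
    amplitude peaks at ``cluster_peak_frame`` (Gaussian time envelope); the
    ring channel carries the bar from ``bud_emergence_frame`` for
    ``frame_count_ring`` frames, followed by ``n_trailing`` background-only
    frames.
    """
    n_frames = render.bud_emergence_frame + render.frame_count_ring + n_trailing
    a_px, b_px, u, v, shape = _cell_grid(cell, render)
    px = cell.pixel_size
    sigma_spot = cell.cluster_diameter_true / px / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    neck_u = 0.9 * a_px
    spot = np.exp(-((u - neck_u) ** 2 + v**2) / (2.0 * sigma_spot**2))
    frames = []
    for t in range(n_frames):
        ring_on = render.bud_emergence_frame <= t < (
            render.bud_emergence_frame + render.frame_count_ring
        )
        ring_img, mask = render_cell_frame(cell, render, frame=t, with_ring=ring_on)
        amp = render.cluster_peak_intensity * math.exp(
            -((t - render.cluster_peak_frame) ** 2) / (2.0 * 1.5**2)
        )
        cluster_img = ndimage.gaussian_filter(amp * spot, render.psf_sigma)
        cluster_img += render.background_level
        if render.read_noise_sd > 0:
            rng = np.random.default_rng([cell.seed, 15485863, t])
            cluster_img += rng.normal(0.0, render.read_noise_sd, size=shape)
        frames.append(
            TimecourseFrame(
                frame=t,
                ring_image=ring_img,
                cluster_image=cluster_img,
                mask=mask,
                ring_present=bool(ring_on),
                cluster_amplitude=float(amp),
            )
        )
    return Timecourse(
        cell=cell,
        frames=tuple(frames),
        cluster_peak_frame=render.cluster_peak_frame,
        bud_emergence_frame=render.bud_emergence_frame,
    )


def generate_aging_track(
    base_cell: SyntheticCell,
    n_generations: int,
    beta: float = 0.15,
    volume_rule: Callable[[int], float] | None = None,
    noise_cv: float = 0.0,
) -> list[SyntheticCell]:
    """Replicative-aging track: mother volume grows per generation and the
    ring diameter follows ``d_norm = V_norm**beta`` (times optional noise).

    ``volume_rule(g)`` returns the normalized volume at generation g
    (generation 1 must map to 1); the default is 5% linear growth per
    generation, matching the steady volume increase of trapped mothers.
    """
    if n_generations < 1:
        raise ConfigurationError("n_generations must be >= 1")
    if volume_rule is None:
        volume_rule = lambda g: 1.0 + 0.05 * (g - 1)  # noqa: E731
    if abs(volume_rule(1) - 1.0) > 1e-12:
        raise ConfigurationError("volume_rule(1) must be 1 (normalization)")
    sigma_ln = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    rng = np.random.default_rng([base_cell.seed, 32452843])
    q = base_cell.semi_axis_a / base_cell.semi_axis_b
    track = []
    for g in range(1, n_generations + 1):
        v_norm = volume_rule(g)
        volume = base_cell.volume_true * v_norm
        noise = math.exp(rng.normal(0.0, sigma_ln)) if sigma_ln > 0 else 1.0
        d = base_cell.ring_diameter_true * v_norm**beta * noise
        b = (3.0 * volume / (4.0 * math.pi * q)) ** (1.0 / 3.0)
        track.append(
            replace(
                base_cell,
                cell_id=f"{base_cell.cell_id}_g{g:02d}",
                generation=g,
                volume_true=volume,
                ring_diameter_true=d,
                length_true=2.0 * q * b,
                semi_axis_a=q * b,
                semi_axis_b=b,
                seed=(base_cell.seed + 1009 * g) & 0x7FFFFFFF,
            )
        )
    return track


def population_table(cells: Sequence[SyntheticCell]) -> pd.DataFrame:
    """Ground-truth table, one row per cell."""
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "generation": [c.generation for c in cells],
            "volume_true_fL": [c.volume_true for c in cells],
            "length_true_um": [c.length_true for c in cells],
            "d_true_um": [c.ring_diameter_true for c in cells],
            "cluster_d_true_um": [c.cluster_diameter_true for c in cells],
        }
    )


def suggested_threshold(render: RenderConfig) -> float:
    """Detection threshold for scenes from this renderer: a quarter of the
    ring peak above background (well above read noise, below the plateau)."""
    return render.background_level + 0.25 * render.ring_peak_intensity


def write_scene(
    cells: Sequence[SyntheticCell],
    render: RenderConfig,
    out_dir: str | Path,
    config: PopulationConfig | None = None,
) -> Path:
    """Write a scene directory: per-cell multipage ring TIFFs, mask TIFFs,
    ground-truth CSV, and a scene.yaml with the measurement parameters."""
    out = Path(out_dir)
    (out / "cells").mkdir(parents=True, exist_ok=True)
    for cell in cells:
        pages = []
        mask = None
        for t in range(render.frame_count_ring):
            img, mask = render_cell_frame(cell, render, frame=t)
            pages.append(np.clip(np.round(img), 0, 65535).astype(np.uint16))
        tifffile.imwrite(out / "cells" / f"{cell.cell_id}_ring.tif", np.stack(pages))
        tifffile.imwrite(
            out / "cells" / f"{cell.cell_id}_mask.tif",
            mask.pixels.astype(np.uint8),
        )
    population_table(cells).to_csv(out / "ground_truth.csv", index=False)
    meta = {
        "pixel_size": cells[0].pixel_size if cells else 0.1,
        "threshold": float(suggested_threshold(render)),
        "min_area": 10,
        "half_length": 30,
        "avg_width": 10,
        "n_cells": len(cells),
        "frame_count_ring": render.frame_count_ring,
    }
    if config is not None:
        meta["population"] = {
            k: getattr(config, k) for k in PopulationConfig.__dataclass_fields__
        }
    with open(out / "scene.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return out
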