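"""Scene-level orchestration: measure a scene directory, fit the scaling law.

File contracts:

* a *scene directory* (as written by :func:`ringscale.synthetic.write_scene`
  or assembled from real data) holds ``scene.yaml`` (pixel_size, threshold,
  half_length, avg_width, min_area), ``cells/<id>_ring.tif`` multipage ring
  channel frames and ``cells/<id>_mask.tif`` binary masks;
* ``run_measure`` emits one CSV row per cell (rejected cells included, with
  an ``accepted`` flag) plus a plain-text log of rejection reasons;
* ``run_fit`` emits a JSON report: power/linear/log fits, bootstrap CI,
  SSR per model, winner, binned means, seed, and optional deviation ratios
  against a reference fit.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import InsufficientDataError
from .geometry import CellMask, measure_geometry
from .ring import measure_ring_frame
from .scaling import PowerLawFit, binned_means, compare_models, fit_power_law
from .tracks import CellTrack, aggregate_track

log = logging.getLogger("ringscale")

SUMMARY_COLUMNS = [
    "cell_id",
    "median_d_um",
    "median_volume_fL",
    "median_length_um",
    "elongation",
    "median_intensity_au",
    "n_ring_frames",
    "accepted",
]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one measure/fit run."""

    scene_dir: Path | str = "."
    threshold: float | None = None  # None: take from scene.yaml
    pixel_size: float | None = None
    min_area: int = 10
    half_length: int | None = None  # None: scene.yaml (30; 60 for large strains)
    avg_width: int = 10
    min_frames: int = 5
    n_boot: int = 50_000
    seed: int = 0
    n_bins: int = 8
    exclude: tuple[str, ...] = field(default_factory=tuple)


def _scene_meta(scene_dir: Path) -> dict:
    meta_path = scene_dir / "scene.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(f"no scene.yaml in {scene_dir}")
    with open(meta_path) as fh:
        return yaml.safe_load(fh)


def run_measure(config: RunConfig) -> pd.DataFrame:
    """Measure every cell of a scene: ring FWHM per frame, geometry from the
    mask, per-cell medians. Returns the summary table (one row per cell)."""
    scene = Path(config.scene_dir)
    cells_dir = scene / "cells"
    if not cells_dir.is_dir():
        raise FileNotFoundError(f"no cells/ directory under {scene}")
    meta = _scene_meta(scene)
    pixel_size = config.pixel_size or float(meta["pixel_size"])
    threshold = config.threshold or float(meta["threshold"])
    half_length = config.half_length or int(meta.get("half_length", 30))
    ring_files = sorted(cells_dir.glob("*_ring.tif"))
    if not ring_files:
        raise FileNotFoundError(f"no *_ring.tif files under {cells_dir}")
    rows = []
    for ring_path in ring_files:
        cell_id = ring_path.name[: -len("_ring.tif")]
        if cell_id in config.exclude:
            log.info("%s: excluded by user list", cell_id)
            continue
        mask_path = cells_dir / f"{cell_id}_mask.tif"
        if not mask_path.exists():
            raise FileNotFoundError(f"missing mask for {cell_id}: {mask_path}")
        stack = tifffile.imread(ring_path)
        if stack.ndim == 2:
            stack = stack[None]
        mask = CellMask(
            tifffile.imread(mask_path) > 0, pixel_size=pixel_size, cell_id=cell_id
        )
        geo = measure_geometry(mask)
        frames = tuple(
            (
                measure_ring_frame(
                    img,
                    threshold,
                    pixel_size,
                    min_area=config.min_area,
                    half_length=half_length,
                    avg_width=config.avg_width,
                    frame=t,
                ),
                geo,
            )
            for t, img in enumerate(stack)
        )
        summary = aggregate_track(
            CellTrack(cell_id, frames), min_frames=config.min_frames
        )
        if not summary.accepted:
            log.info(
                "%s: rejected (ring detected in %d < %d frames)",
                cell_id,
                summary.n_ring_frames,
                config.min_frames,
            )
        rows.append(
            {
                "cell_id": cell_id,
                "median_d_um": summary.median_diameter,
                "median_volume_fL": summary.median_volume,
                "median_length_um": summary.median_length,
                "elongation": geo.elongation,
                "median_intensity_au": summary.median_intensity,
                "n_ring_frames": summary.n_ring_frames,
                "accepted": summary.accepted,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def run_fit(
    summary: pd.DataFrame,
    config: RunConfig,
    reference: PowerLawFit | None = None,
) -> dict:
    """Fit the scaling models to accepted cells and assemble the report."""
    accepted = summary[summary["accepted"]]
    if len(accepted) < 3:
        raise InsufficientDataError(
            f"only {len(accepted)} accepted cells; need at least 3"
        )
    d = accepted["median_d_um"].to_numpy()
    V = accepted["median_volume_fL"].to_numpy()
    fit = fit_power_law(d, V, n_boot=config.n_boot, seed=config.seed)
    comparison = compare_models(d, V)
    edges = np.geomspace(V.min(), V.max() * (1 + 1e-9), config.n_bins + 1)
    bins = binned_means(V, d, edges)
    report = {
        "generated": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "n_cells": int(len(accepted)),
        "seed": config.seed,
        "n_boot": config.n_boot,
        "power": {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "prefactor": fit.prefactor,
            "ci95": list(fit.ci) if fit.ci else None,
            "ssr_linear_space": fit.ssr_linear,
            "ssr_log_space": fit.ssr_log,
        },
        "linear": {"offset": comparison.linear[0], "slope": comparison.linear[1]},
        "logarithmic": {
            "offset": comparison.logarithmic[0],
            "slope": comparison.logarithmic[1],
        },
        "ssr": comparison.ssr,
        "winner": comparison.winner,
        "binned_means": {
            "volume_fL": bins.mean_x.tolist(),
            "diameter_um": bins.mean_y.tolist(),
            "se_um": bins.se_y.tolist(),
            "n": bins.n.tolist(),
        },
    }
    if reference is not None:
        ratios = d / np.asarray(reference.predict(V), dtype=float)
        report["deviation"] = {
            "reference_slope": reference.slope,
            "reference_intercept": reference.intercept,
            "median_ratio": float(np.median(ratios)),
            "median_deviation_percent": float((np.median(ratios) - 1.0) * 100.0),
        }
    return report


def load_reference_fit(path: str | Path) -> PowerLawFit:
    """Load a reference fit from a report JSON (or a bare slope/intercept)."""
    with open(path) as fh:
        data = json.load(fh)
    if "power" in data:
        data = data["power"]
    return PowerLawFit(
        slope=float(data["slope"]), intercept=float(data["intercept"]), n=0
    )


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
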