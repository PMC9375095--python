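"""Image and table I/O plus QC overlays.

Images are multi-channel TIFF stacks with a declared channel map (channel
order ``nuclear, det_a, det_b`` for simulator output); tables are CSV with a
stable, documented column order so that a written table re-reads identically.
QC overlays follow the conventional pseudo-coloring: nuclei blue, detection A
magenta, detection B green, with spot markers color-coded by class.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .quantify import CELL_COLUMNS, SPOT_COLUMNS

__all__ = [
    "DEFAULT_CHANNEL_MAP",
    "read_image",
    "write_image",
    "write_tables",
    "read_tables",
    "write_sidecar",
    "save_overlay",
]

DEFAULT_CHANNEL_MAP = {"nuclear": 0, "det_a": 1, "det_b": 2}

_CLASS_COLORS = {"freeA": "magenta", "freeB": "lime", "complex": "white"}


def read_image(path: "Path | str", channel_map: "dict[str, int] | None" = None):
    """Read a TIFF stack and resolve channels through the channel map.

    Returns ``(stack, channel_map)`` with ``stack`` shaped (C, H, W); a 2-D
    image becomes a single-channel stack. Raises a clear error when the file
    is missing or the map names a channel the file does not have.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D TIFF, got shape {arr.shape}")
    if channel_map is None:
        channel_map = (
            dict(DEFAULT_CHANNEL_MAP) if arr.shape[0] >= 3 else {"signal": 0}
        )
    for name, idx in channel_map.items():
        if not 0 <= idx < arr.shape[0]:
            raise ValueError(
                f"channel {name!r} maps to index {idx} but the image has "
                f"{arr.shape[0]} channel(s)"
            )
    return arr, channel_map


def write_image(stack: np.ndarray, path: "Path | str") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        str(path),
        np.asarray(stack),
        photometric="minisblack",
        metadata={"channel_order": "nuclear,det_a,det_b"},
    )
    return path


def write_tables(
    spot_table: pd.DataFrame, cell_table: pd.DataFrame, outdir: "Path | str", prefix: str = ""
) -> dict[str, Path]:
    """Write the per-object and per-cell CSV exports with stable columns."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spot_path = outdir / f"{prefix}spots.csv"
    cell_path = outdir / f"{prefix}cells.csv"
    spots = spot_table.reindex(columns=[c for c in SPOT_COLUMNS if c in spot_table.columns])
    cells = cell_table.reindex(columns=[c for c in CELL_COLUMNS if c in cell_table.columns])
    spots.to_csv(spot_path, index=False)
    cells.to_csv(cell_path, index=False)
    return {"spots": spot_path, "cells": cell_path}


def read_tables(outdir: "Path | str", prefix: str = "") -> dict[str, pd.DataFrame]:
    outdir = Path(outdir)
    return {
        "spots": pd.read_csv(outdir / f"{prefix}spots.csv"),
        "cells": pd.read_csv(outdir / f"{prefix}cells.csv"),
    }


def write_sidecar(config_dict: dict, seed: int, outdir: "Path | str", name: str = "run.json") -> Path:
    """Echo the resolved configuration and seed next to a run's outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / name
    with open(path, "w") as fh:
        json.dump({"seed": seed, "config": config_dict}, fh, indent=2, default=str)
    return path


def _composite_rgb(stack: np.ndarray) -> np.ndarray:
    def norm(c):
        c = np.asarray(c, dtype=float)
        hi = np.percentile(c, 99.5)
        lo = c.min()
        return np.clip((c - lo) / max(hi - lo, 1e-9), 0, 1)

    nuclear, det_a, det_b = (norm(c) for c in stack[:3])
    rgb = np.zeros(stack.shape[1:] + (3,))
    rgb[..., 0] = det_a  # magenta = R + B
    rgb[..., 2] = np.clip(det_a + nuclear, 0, 1)  # blue nuclei
    rgb[..., 1] = det_b  # green
    return rgb


def save_overlay(
    stack: np.ndarray, spot_table: pd.DataFrame, path: "Path | str", dpi: int = 150
) -> Path:
    """Save a QC overlay: pseudo-colored composite with class-coded spots."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(_composite_rgb(stack))
    if not spot_table.empty and "rcp_class" in spot_table.columns:
        for cls, color in _CLASS_COLORS.items():
            sub = spot_table[spot_table["rcp_class"] == cls]
            ax.scatter(
                sub["x"], sub["y"], s=30, facecolors="none",
                edgecolors=color, linewidths=0.6, label=f"{cls} (n={len(sub)})",
            )
        ax.legend(loc="upper right", fontsize=7)
    ax.set_axis_off()
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return path
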