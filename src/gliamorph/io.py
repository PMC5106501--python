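"""Reading and writing of images, masks, ground truth and configs."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .errors import FormatError
from .synth import MicrogliaImage

__all__ = [
    "save_image",
    "load_raster",
    "save_mask_png",
    "load_mask_png",
    "save_region_json",
    "load_region_json",
    "save_ground_truth",
    "load_yaml_config",
]


def save_image(path: str | Path, raster: np.ndarray) -> None:
    """Write a raster as single-channel TIFF (8-/16-bit) or PNG by suffix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, raster)
    else:
        iio.imwrite(path, raster)


def load_raster(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG raster; rejects multichannel images."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path} is not a single-channel raster (shape {arr.shape})")
    return arr


def save_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def load_mask_png(path: str | Path) -> np.ndarray:
    """Read a 0/255 PNG mask as a boolean array."""
    return load_raster(path) > 127


def save_region_json(path: str | Path, polygon_xy: np.ndarray) -> None:
    """Write a region polygon as JSON ``{"polygon": [[x, y], ...]}``."""
    with open(path, "w") as fh:
        json.dump({"polygon": np.asarray(polygon_xy, float).tolist()}, fh)


def load_region_json(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        data = json.load(fh)
    return np.asarray(data["polygon"], dtype=float)


def save_ground_truth(out_dir: str | Path, image: MicrogliaImage, stem: str = "truth") -> None:
    """Write per-cell ground truth as JSON (cells array) and CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells = [
        {
            "cell_id": c.cell_id,
            "soma_xy_um": list(c.soma_xy_um),
            "endpoints_um": c.endpoints_um.tolist(),
            "true_domain_um2": c.true_domain_um2,
            "rendered_area_um2": c.rendered_area_um2,
            "fragmented": c.fragmented,
        }
        for c in image.ground_truth
    ]
    with open(out / f"{stem}.json", "w") as fh:
        json.dump(
            {
                "px_size_um": image.px_size_um,
                "true_coverage": image.true_coverage,
                "cells": cells,
            },
            fh,
        )
    image.to_dataframe().to_csv(out / f"{stem}.csv", index=False)


def load_region(path: str | Path, shape: tuple[int, int]) -> np.ndarray:
    """Load a region of interest as a boolean mask.

    Accepts a 0/255 PNG mask (must match ``shape``) or a polygon JSON
    written by :func:`save_region_json`, which is rasterised onto
    ``shape``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        from .synth import rasterize_polygon

        return rasterize_polygon(shape, load_region_json(path))
    mask = load_mask_png(path)
    if mask.shape != tuple(shape):
        raise FormatError(
            f"region mask {path} has shape {mask.shape}, expected {tuple(shape)}"
        )
    return mask


def load_yaml_config(path: str | Path) -> dict:
    """Read a YAML config file into a plain dict."""
    with open(path) as fh:
        return yaml.safe_load(fh)
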