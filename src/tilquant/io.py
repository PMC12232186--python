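"""Readers and writers for the pipeline's on-disk formats.

Coordinates are micrometres, origin top-left, y increasing downward.
Tiles: 8-bit RGB PNG/TIFF.  Regions: GeoJSON polygons (um coordinates,
pixel-size metadata in the top-level ``properties``).  Cell tables, score
matrices, survival tables, TIL panels: CSV with a header row.  Stain
models: JSON (see :class:`tilquant.stain.StainModel`).
"""
from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import shapely
import shapely.geometry
import tifffile

from .stain import StainModel

CELL_TABLE_REQUIRED = ("id", "x_um", "y_um")


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write a text file via a temp file + rename (no partial outputs)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_tile(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3 and img.shape[-1] == 4:
        img = img[..., :3]
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"{path}: expected an 8-bit RGB tile, got shape {img.shape}")
    if img.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit pixels, got {img.dtype}")
    return img


def write_tile(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3 or image.dtype != np.uint8:
        raise ValueError("tile must be 8-bit RGB")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image, photometric="rgb")
    else:
        iio.imwrite(path, image)


def read_region_geojson(path: str | Path):
    """Load a region annotation; returns (shapely geometry, properties dict)."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"{path}: malformed GeoJSON ({err})") from err
    props = doc.get("properties", {})
    if doc.get("type") == "FeatureCollection":
        geoms = []
        for i, feat in enumerate(doc.get("features", [])):
            if "geometry" not in feat:
                raise ValueError(f"{path}: feature {i} lacks a geometry")
            geoms.append(shapely.geometry.shape(feat["geometry"]))
        if not geoms:
            raise ValueError(f"{path}: empty FeatureCollection")
        geom = shapely.union_all(geoms)
    elif doc.get("type") == "Feature":
        geom = shapely.geometry.shape(doc["geometry"])
    else:
        geom = shapely.geometry.shape(doc)
    return geom, props


def write_region_geojson(
    path: str | Path,
    geometry,
    pixel_size_um: float | None = None,
    classification: str | None = None,
) -> None:
    props: dict = {}
    if pixel_size_um is not None:
        props["pixel_size_um"] = pixel_size_um
    feat_props = {}
    if classification is not None:
        feat_props["classification"] = classification
    geoms = getattr(geometry, "geoms", [geometry])
    doc = {
        "type": "FeatureCollection",
        "properties": props,
        "features": [
            {
                "type": "Feature",
                "properties": feat_props,
                "geometry": shapely.geometry.mapping(g),
            }
            for g in geoms
        ],
    }
    atomic_write_text(path, json.dumps(doc))


def read_cell_table(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as err:
        raise ValueError(f"{path}: malformed cell table ({err})") from err
    missing = [c for c in CELL_TABLE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cell table lacks columns {missing}")
    return df


def write_cell_table(path: str | Path, cells: pd.DataFrame) -> None:
    atomic_write_text(path, cells.to_csv(index=False))


def read_score_matrix(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as err:
        raise ValueError(f"{path}: malformed score matrix ({err})") from err
    if df.shape[1] < 1:
        raise ValueError(f"{path}: score matrix has no rater columns")
    return df


def write_score_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    atomic_write_text(path, matrix.to_csv())


def read_survival_table(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as err:
        raise ValueError(f"{path}: malformed survival table ({err})") from err
    for col in ("time_months", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: survival table lacks column {col!r}")
    return df


def write_survival_table(path: str | Path, table: pd.DataFrame) -> None:
    atomic_write_text(path, table.to_csv(index=False))


def read_stain_model(path: str | Path) -> StainModel:
    return StainModel.load(path)


def write_stain_model(path: str | Path, model: StainModel) -> None:
    atomic_write_text(path, json.dumps(model.to_dict(), indent=2))
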