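"""File formats: cell tables (CSV/Parquet), label masks and images
(TIFF), polygons (GeoJSON)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .segment import ImageGrid, LabelMask

__all__ = [
    "REQUIRED_COLUMNS",
    "read_cell_table",
    "write_cell_table",
    "write_image_tiff",
    "read_image_tiff",
    "write_label_mask",
    "read_label_mask",
    "polygons_to_geojson",
    "geojson_to_polygons",
]

REQUIRED_COLUMNS = ("cell_id", "roi_id", "case_id", "group", "x_um", "y_um")


def _validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in cells.columns:
            raise DataError(f"cell table missing mandatory column {col!r}")
    for col in ("x_um", "y_um"):
        coerced = pd.to_numeric(cells[col], errors="coerce")
        bad = coerced.isna() & cells[col].notna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(f"non-numeric {col!r} at row {idx}")
        if coerced.isna().any():
            idx = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise DataError(f"missing {col!r} at row {idx}")
        cells[col] = coerced.astype(float)
    return cells


def read_cell_table(path) -> pd.DataFrame:
    """Read a cell table from CSV or Parquet, validating the documented
    schema; unknown extra columns are preserved."""
    path = Path(path)
    if path.suffix.lower() == ".parquet":
        cells = pd.read_parquet(path)
    else:
        cells = pd.read_csv(path)
    return _validate_cell_table(cells)


def write_cell_table(cells: pd.DataFrame, path) -> None:
    _validate_cell_table(cells.copy())
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".parquet":
        cells.to_parquet(path, index=False)
    else:
        cells.to_csv(path, index=False)


def write_image_tiff(image: ImageGrid, path) -> None:
    """Multipage TIFF, one page per channel, channel names and pixel size
    recorded in the image description."""
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack([image.channels[name] for name in image.channel_names]).astype(np.float32)
    meta = {"channels": image.channel_names, "pixel_size_um": image.pixel_size}
    tifffile.imwrite(path, stack, description=json.dumps(meta))


def read_image_tiff(path) -> ImageGrid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc)
    if stack.ndim == 2:
        stack = stack[None]
    channels = {name: stack[i].astype(float) for i, name in enumerate(meta["channels"])}
    return ImageGrid(channels=channels, pixel_size=float(meta["pixel_size_um"]))


def write_label_mask(mask: LabelMask, path) -> None:
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dtype = np.uint16 if mask.labels.max() < 2**16 else np.uint32
    meta = {"seeds": {str(k): list(v) for k, v in mask.seeds.items()}}
    tifffile.imwrite(path, mask.labels.astype(dtype), description=json.dumps(meta))


def read_label_mask(path) -> LabelMask:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray().astype(np.int32)
        desc = tif.pages[0].description
    seeds = {}
    if desc:
        try:
            seeds = {
                int(k): tuple(v) for k, v in json.loads(desc).get("seeds", {}).items()
            }
        except (json.JSONDecodeError, AttributeError):
            seeds = {}
    return LabelMask(labels=arr, seeds=seeds)


def polygons_to_geojson(
    polygons: Sequence[np.ndarray] | Mapping[int, np.ndarray],
    path,
    properties: Sequence[Mapping] | None = None,
) -> None:
    """Write polygons (vertices in μm) as a GeoJSON FeatureCollection."""
    if isinstance(polygons, Mapping):
        items = [(k, v) for k, v in polygons.items()]
    else:
        items = list(enumerate(polygons))
    features = []
    for i, (key, poly) in enumerate(items):
        pts = np.asarray(poly, dtype=float)
        ring = pts.tolist()
        if ring[0] != ring[-1]:
            ring.append(ring[0])
        props = {"id": int(key)}
        if properties is not None:
            props.update(properties[i])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            }
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def geojson_to_polygons(path) -> dict[int, np.ndarray]:
    with open(path) as fh:
        payload = json.load(fh)
    out: dict[int, np.ndarray] = {}
    for feat in payload["features"]:
        ring = feat["geometry"]["coordinates"][0]
        pts = np.asarray(ring, dtype=float)
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        out[int(feat["properties"]["id"])] = pts
    return out
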