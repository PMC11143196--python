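"""Nuclear segmentation by maxima-seeded, radius-bounded region growing.

Seeds are strict local maxima of the Gaussian-smoothed nuclear channel;
each pixel within a fixed growth radius of a seed and above a per-seed
intensity floor is assigned to its nearest seed. Regions smaller than a
relative size cutoff (fraction of the median region area) are dropped.
Per-cell marker intensities are then quantified over the label mask,
with optional spillover compensation from mask-adjacent neighbors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError, DataError

__all__ = [
    "ImageGrid",
    "SegmentationParams",
    "LabelMask",
    "detect_maxima",
    "grow_regions",
    "quantify_cells",
    "compensate_spillover",
]


@dataclass
class ImageGrid:
    """Named 2-D channels on a common pixel grid (top-left origin,
    y increasing downward), with a physical pixel size in μm/px."""

    channels: dict[str, np.ndarray]
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise DataError(f"channel shapes disagree: {shapes}")
        for name, ch in self.channels.items():
            if ch.ndim != 2:
                raise DataError(f"channel {name!r} is not 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)


@dataclass
class SegmentationParams:
    smoothing_sigma: float = 1.0
    maxima_min_distance: int = 3
    maxima_min_intensity: float = 0.1  # fraction of (smoothed) channel max
    growth_radius: int = 5
    size_cutoff_factor: float = 0.1
    intensity_floor_frac: float = 0.1  # fraction of seed peak
    spillover_alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.growth_radius < 1:
            raise ConfigError("growth_radius must be >= 1")
        if not (0 <= self.size_cutoff_factor < 1):
            raise ConfigError("size_cutoff_factor must be in [0, 1)")
        if not (0 <= self.spillover_alpha <= 1):
            raise ConfigError("spillover_alpha must be in [0, 1]")
        if self.maxima_min_distance < 1:
            raise ConfigError("maxima_min_distance must be >= 1")
        if not (0 <= self.maxima_min_intensity <= 1):
            raise ConfigError("maxima_min_intensity must be in [0, 1]")
        if not (0 <= self.intensity_floor_frac < 1):
            raise ConfigError("intensity_floor_frac must be in [0, 1)")


@dataclass
class LabelMask:
    """Integer label raster (0 = background) plus label → seed map."""

    labels: np.ndarray
    seeds: dict[int, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise DataError("label mask must be 2-D")
        if (self.labels < 0).any():
            raise DataError("labels must be nonnegative")

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())


def _disc_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (xx**2 + yy**2) <= radius**2


def detect_maxima(nuclear: np.ndarray, params: SegmentationParams) -> list[tuple[int, int]]:
    """Strict local maxima of the smoothed nuclear channel.

    Returns (row, col) seed positions sorted by descending smoothed
    intensity, ties broken row-major. An all-zero raster yields no seeds.
    """
    nuclear = np.asarray(nuclear, dtype=float)
    if nuclear.size == 0:
        raise DataError("empty nuclear channel")
    smoothed = ndimage.gaussian_filter(nuclear, params.smoothing_sigma)
    peak = smoothed.max()
    if peak <= 0:
        return []
    fp = _disc_footprint(params.maxima_min_distance)
    fp[params.maxima_min_distance, params.maxima_min_distance] = False
    neighborhood_max = ndimage.maximum_filter(smoothed, footprint=fp, mode="constant", cval=-np.inf)
    strict = smoothed > neighborhood_max
    strict &= smoothed > params.maxima_min_intensity * peak
    rows, cols = np.nonzero(strict)
    if rows.size == 0:
        return []
    vals = smoothed[rows, cols]
    order = np.lexsort((cols, rows, -vals))
    return [(int(rows[i]), int(cols[i])) for i in order]


def grow_regions(
    nuclear: np.ndarray, seeds: list[tuple[int, int]], params: SegmentationParams
) -> LabelMask:
    """Grow a label region around each seed.

    A pixel joins a region iff it lies within ``growth_radius`` (Euclidean)
    of the seed and its smoothed intensity is at least
    ``intensity_floor_frac`` of the seed's peak. Contested pixels go to
    the nearest seed; exact distance ties go to the higher-intensity
    seed, then the lower label. Regions are trimmed to the 4-connected
    component containing their seed, then regions with area below
    ``size_cutoff_factor`` times the median region area are dropped and
    labels recompacted.
    """
    nuclear = np.asarray(nuclear, dtype=float)
    h, w = nuclear.shape
    labels = np.zeros((h, w), dtype=np.int32)
    if not seeds:
        return LabelMask(labels=labels, seeds={})
    smoothed = ndimage.gaussian_filter(nuclear, params.smoothing_sigma)
    r = params.growth_radius
    seed_vals = np.array([smoothed[p] for p in seeds])

    best_d2 = np.full((h, w), np.iinfo(np.int64).max, dtype=np.int64)
    best_val = np.full((h, w), -np.inf)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2_patch = (xx**2 + yy**2).astype(np.int64)
    in_disc = d2_patch <= r * r

    for i, (sr, sc) in enumerate(seeds):
        label = i + 1
        r0, r1 = max(sr - r, 0), min(sr + r + 1, h)
        c0, c1 = max(sc - r, 0), min(sc + r + 1, w)
        pr0, pr1 = r0 - (sr - r), r1 - (sr - r)
        pc0, pc1 = c0 - (sc - r), c1 - (sc - r)
        d2 = d2_patch[pr0:pr1, pc0:pc1]
        ok = in_disc[pr0:pr1, pc0:pc1] & (
            smoothed[r0:r1, c0:c1] >= params.intensity_floor_frac * seed_vals[i]
        )
        sub_d2 = best_d2[r0:r1, c0:c1]
        sub_val = best_val[r0:r1, c0:c1]
        closer = ok & (d2 < sub_d2)
        tied = ok & (d2 == sub_d2) & (seed_vals[i] > sub_val)
        take = closer | tied  # later (lower-priority) label never beats an equal one
        labels[r0:r1, c0:c1][take] = label
        sub_d2[take] = d2[take]
        sub_val[take] = seed_vals[i]
        best_d2[r0:r1, c0:c1] = sub_d2
        best_val[r0:r1, c0:c1] = sub_val

    # keep only the 4-connected component containing each seed
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for i, (sr, sc) in enumerate(seeds):
        label = i + 1
        region = labels == label
        if not region[sr, sc]:
            labels[region] = 0
            continue
        comp, _ = ndimage.label(region, structure=structure)
        labels[region & (comp != comp[sr, sc])] = 0

    areas = np.bincount(labels.ravel(), minlength=len(seeds) + 1)[1:]
    present = np.flatnonzero(areas > 0) + 1
    if present.size == 0:
        return LabelMask(labels=np.zeros((h, w), dtype=np.int32), seeds={})
    median_area = float(np.median(areas[present - 1]))
    keep = [
        int(l) for l in present if areas[l - 1] >= params.size_cutoff_factor * median_area
    ]
    remap = np.zeros(len(seeds) + 1, dtype=np.int32)
    seed_map: dict[int, tuple[int, int]] = {}
    for new, old in enumerate(keep, start=1):
        remap[old] = new
        seed_map[new] = seeds[old - 1]
    return LabelMask(labels=remap[labels], seeds=seed_map)


def quantify_cells(mask: LabelMask, image: ImageGrid) -> pd.DataFrame:
    """One record per label: centroid (μm), area (μm²) and per-channel
    mean intensity over the region."""
    if mask.labels.shape != image.shape:
        raise DataError(
            f"mask shape {mask.labels.shape} does not match image shape {image.shape}"
        )
    labels = mask.labels
    ids = np.arange(1, mask.n_regions + 1)
    ids = ids[np.isin(ids, labels)] if mask.n_regions else ids
    if len(ids) == 0:
        return pd.DataFrame(columns=["cell_id", "x_um", "y_um", "area_um2"])
    px = image.pixel_size
    counts = np.bincount(labels.ravel(), minlength=ids.max() + 1)
    coms = ndimage.center_of_mass(np.ones_like(labels), labels, ids)
    rows = {
        "cell_id": ids,
        "x_um": np.array([(c[1] + 0.5) * px for c in coms]),
        "y_um": np.array([(c[0] + 0.5) * px for c in coms]),
        "area_um2": counts[ids] * px * px,
    }
    for name, chan in image.channels.items():
        if name == "DNA":
            continue
        rows[name] = np.asarray(ndimage.mean(chan, labels, ids), dtype=float)
    return pd.DataFrame(rows)


def _mask_adjacency(labels: np.ndarray) -> dict[int, set[int]]:
    """Regions sharing a boundary pixel within a 1-px (8-neighborhood)
    dilation are adjacent."""
    adj: dict[int, set[int]] = {}
    shifts = [(0, 1), (1, 0), (1, 1), (1, -1)]
    for dr, dc in shifts:
        a = labels[max(dr, 0) : labels.shape[0] + min(dr, 0),
                   max(dc, 0) : labels.shape[1] + min(dc, 0)]
        b = labels[max(-dr, 0) : labels.shape[0] + min(-dr, 0),
                   max(-dc, 0) : labels.shape[1] + min(-dc, 0)]
        both = (a > 0) & (b > 0) & (a != b)
        for u, v in zip(a[both].ravel(), b[both].ravel()):
            adj.setdefault(int(u), set()).add(int(v))
            adj.setdefault(int(v), set()).add(int(u))
    return adj


def compensate_spillover(
    cells: pd.DataFrame,
    mask: LabelMask,
    alpha: float,
    markers: list[str] | None = None,
) -> pd.DataFrame:
    """Subtract ``alpha`` times the mean intensity of mask-adjacent
    neighbor cells from each cell, clipping at zero. Cells without
    neighbors (and the alpha=0 case) are unchanged."""
    if not (0 <= alpha <= 1):
        raise ConfigError("alpha must be in [0, 1]")
    out = cells.copy()
    if alpha == 0 or len(cells) == 0:
        return out
    if markers is None:
        skip = {"cell_id", "x_um", "y_um", "area_um2", "roi_id", "case_id", "group"}
        markers = [
            c for c in cells.columns
            if c not in skip and pd.api.types.is_numeric_dtype(cells[c])
        ]
    adj = _mask_adjacency(mask.labels)
    id_to_row = {int(cid): i for i, cid in enumerate(cells["cell_id"].to_numpy())}
    raw = cells[markers].to_numpy(dtype=float)
    corrected = raw.copy()
    for cid, row in id_to_row.items():
        neighbors = [id_to_row[n] for n in adj.get(cid, ()) if n in id_to_row]
        if not neighbors:
            continue
        corrected[row] = np.clip(raw[row] - alpha * raw[neighbors].mean(axis=0), 0, None)
    out[markers] = corrected
    return out
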