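"""Nuclear morphometry and positive-cell-fraction quantification."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import TestResult, rank_sum_test
from .errors import ConfigError, DataError
from .phenotype import ThresholdSet

__all__ = [
    "polygon_area_perimeter",
    "mask_to_polygons",
    "tumor_nuclear_morphometry",
    "positive_fraction",
]


def polygon_area_perimeter(polygon: np.ndarray) -> tuple[float, float]:
    """Shoelace area (absolute) and closed perimeter of a simple polygon.

    ``polygon`` is an (k, 2) array of ordered vertices; the closing edge
    back to the first vertex is implied (a repeated final vertex is
    tolerated). Self-intersecting polygons are rejected.
    """
    pts = np.asarray(polygon, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DataError("polygon must be a (k, 2) array of vertices")
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise DataError("polygon needs at least 3 distinct vertices")
    from shapely.geometry import LinearRing

    if not LinearRing(pts).is_simple:
        raise DataError("polygon is self-intersecting")
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    perimeter = float(np.sum(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)))
    return area, perimeter


def mask_to_polygons(labels: np.ndarray, pixel_size: float = 1.0) -> dict[int, np.ndarray]:
    """Trace each label's boundary (marching squares at the 0.5 level)
    into a polygon in μm. Entry point for mask-only pipelines."""
    from skimage import measure

    if pixel_size <= 0:
        raise ConfigError("pixel_size must be positive")
    out: dict[int, np.ndarray] = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        contours = measure.find_contours((labels == lab).astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)  # outer boundary
        # contour is (row, col); convert to (x, y) μm
        poly = np.column_stack([contour[:, 1], contour[:, 0]]) * pixel_size
        out[int(lab)] = poly
    return out


def tumor_nuclear_morphometry(
    cells: pd.DataFrame,
    polygons: Mapping[int, np.ndarray] | Sequence[np.ndarray],
    tumor_label: str = "Tumor B",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Area/perimeter of tumor-positive nuclei with per-group medians and
    pairwise rank-sum tests.

    Returns (per_nucleus, group_summary, pairwise_tests). Groups without
    tumor-positive nuclei appear in the summary with NaN medians and are
    excluded from testing.
    """
    for col in ("phenotype", "group", "cell_id"):
        if col not in cells.columns:
            raise DataError(f"cell table lacks column {col!r}")
    if not isinstance(polygons, Mapping):
        polygons = {int(cid): poly for cid, poly in zip(cells["cell_id"], polygons)}

    tumor = cells[cells["phenotype"] == tumor_label]
    records = []
    for _, row in tumor.iterrows():
        cid = int(row["cell_id"])
        key = cid if cid in polygons else row["cell_id"]
        if key not in polygons:
            continue
        area, perim = polygon_area_perimeter(polygons[key])
        records.append(
            {"cell_id": cid, "group": row["group"], "area_um2": area, "perimeter_um": perim}
        )
    per_nucleus = pd.DataFrame(records, columns=["cell_id", "group", "area_um2", "perimeter_um"])

    all_groups = list(pd.unique(cells["group"]))
    summary_rows = []
    for g in all_groups:
        sub = per_nucleus[per_nucleus["group"] == g]
        summary_rows.append(
            {
                "group": g,
                "n_nuclei": len(sub),
                "median_area_um2": sub["area_um2"].median() if len(sub) else np.nan,
                "median_perimeter_um": sub["perimeter_um"].median() if len(sub) else np.nan,
            }
        )
    summary = pd.DataFrame(summary_rows)

    testable = [g for g in all_groups if (per_nucleus["group"] == g).any()]
    test_rows = []
    for i in range(len(testable)):
        for j in range(i + 1, len(testable)):
            ga, gb = testable[i], testable[j]
            for metric in ("area_um2", "perimeter_um"):
                res = rank_sum_test(
                    per_nucleus.loc[per_nucleus["group"] == ga, metric],
                    per_nucleus.loc[per_nucleus["group"] == gb, metric],
                )
                test_rows.append(
                    {"group_a": ga, "group_b": gb, "metric": metric,
                     "statistic": res.statistic, "p": res.p, "method": res.method}
                )
    tests = pd.DataFrame(
        test_rows, columns=["group_a", "group_b", "metric", "statistic", "p", "method"]
    )
    return per_nucleus, summary, tests


def positive_fraction(
    cells: pd.DataFrame,
    marker: str,
    threshold: float | ThresholdSet,
    case_col: str = "case_id",
    core_col: str = "core_id",
    cofactor: float = 150.0,
) -> pd.DataFrame:
    """Per-core positive-cell fraction for one marker, with per-case
    medians.

    ``threshold`` is either a fitted :class:`ThresholdSet` or a float on
    the arcsinh-transformed scale (with ``cofactor``). Returns one row
    per core: case, core, marker, fraction, case_median_pct.
    """
    if marker not in cells.columns:
        raise DataError(f"marker column {marker!r} missing")
    for col in (case_col, core_col):
        if col not in cells.columns:
            raise DataError(f"grouping column {col!r} missing")
    if isinstance(threshold, ThresholdSet):
        pos = threshold.is_positive(cells, marker)
    else:
        pos = np.arcsinh(cells[marker].to_numpy(dtype=float) / cofactor) > float(threshold)

    tbl = cells[[case_col, core_col]].copy()
    tbl["pos"] = pos
    grouped = tbl.groupby([case_col, core_col], sort=True)["pos"]
    sizes = grouped.size()
    if (sizes == 0).any():
        empty = sizes.index[sizes == 0].tolist()
        raise DataError(f"empty core(s): {empty}")
    frac = grouped.mean().rename("fraction").reset_index()
    medians = frac.groupby(case_col)["fraction"].median() * 100.0
    frac["marker"] = marker
    frac["case_median_pct"] = frac[case_col].map(medians)
    return frac[[case_col, core_col, "marker", "fraction", "case_median_pct"]]
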