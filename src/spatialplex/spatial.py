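"""Annulus neighbor graphs, size-corrected interaction scores, and the
label-permutation chance null.

A pair of cells interacts when their centroid distance lies in the
closed range [d_min, d_max] μm (default 3–30). Pair counts E_ij between
populations are corrected for the number of cells involved:
S_ij = E_ij / (n_i + n_j) off-diagonal and E_ii / (2 n_i) on the
diagonal. Enrichment against chance shuffles labels within each ROI
with positions (and hence the graph) fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigError, DataError

__all__ = [
    "NeighborGraph",
    "InteractionMatrix",
    "EnrichmentResult",
    "build_neighbor_graph",
    "interaction_scores",
    "permutation_enrichment",
    "voronoi_export",
]


@dataclass
class NeighborGraph:
    """Undirected annulus-range adjacency over cells, per ROI.

    ``edges`` has columns roi_id, cell_a, cell_b, distance_um with
    cell_a < cell_b positions referring to ``cell_ids`` order per ROI.
    """

    edges: pd.DataFrame
    cell_ids: dict[str, np.ndarray]  # roi_id -> cell ids in table order
    d_min: float
    d_max: float

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def roi_edge_indices(self, roi_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as positional indices into this ROI's cell_ids."""
        sub = self.edges[self.edges["roi_id"] == roi_id]
        ids = self.cell_ids[roi_id]
        pos = {cid: i for i, cid in enumerate(ids)}
        a = np.array([pos[c] for c in sub["cell_a"]], dtype=np.intp)
        b = np.array([pos[c] for c in sub["cell_b"]], dtype=np.intp)
        return a, b


@dataclass
class InteractionMatrix:
    """Symmetric size-corrected interaction scores for one ROI (NaN where
    a population is absent, mirroring a "not assessable" entry)."""

    S: pd.DataFrame
    E: pd.DataFrame
    n: pd.Series


@dataclass
class EnrichmentResult:
    observed: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    ratio: pd.DataFrame
    p_enrich: pd.DataFrame
    p_deplete: pd.DataFrame
    n_perm: int
    seed: int


def build_neighbor_graph(
    cells: pd.DataFrame, d_min: float = 3.0, d_max: float = 30.0
) -> NeighborGraph:
    """All cell pairs with d_min <= centroid distance <= d_max, computed
    independently within each ROI (no cross-ROI edges)."""
    if not (0 <= d_min < d_max):
        raise ConfigError("need 0 <= d_min < d_max")
    for col in ("cell_id", "roi_id", "x_um", "y_um"):
        if col not in cells.columns:
            raise DataError(f"cell table lacks column {col!r}")
    frames = []
    cell_ids: dict[str, np.ndarray] = {}
    for roi, sub in cells.groupby("roi_id", sort=True):
        ids = sub["cell_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise DataError(f"duplicate cell ids in ROI {roi!r}")
        cell_ids[roi] = ids
        pts = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        pairs = cKDTree(pts).query_pairs(r=d_max, output_type="ndarray")
        if len(pairs) == 0:
            continue
        d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        keep = d >= d_min
        pairs, d = pairs[keep], d[keep]
        a = np.minimum(ids[pairs[:, 0]], ids[pairs[:, 1]])
        b = np.maximum(ids[pairs[:, 0]], ids[pairs[:, 1]])
        frames.append(
            pd.DataFrame({"roi_id": roi, "cell_a": a, "cell_b": b, "distance_um": d})
        )
    edges = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["roi_id", "cell_a", "cell_b", "distance_um"])
    )
    return NeighborGraph(edges=edges, cell_ids=cell_ids, d_min=d_min, d_max=d_max)


def _pair_counts(
    codes_a: np.ndarray, codes_b: np.ndarray, n_pop: int
) -> np.ndarray:
    """Symmetric KxK edge-count matrix from endpoint label codes."""
    lo = np.minimum(codes_a, codes_b)
    hi = np.maximum(codes_a, codes_b)
    flat = np.bincount(lo * n_pop + hi, minlength=n_pop * n_pop)
    upper = flat.reshape(n_pop, n_pop)
    return upper + np.triu(upper, 1).T


def _scores_from_counts(E: np.ndarray, n: np.ndarray) -> np.ndarray:
    denom = n[:, None] + n[None, :]
    np.fill_diagonal(denom, 2 * n)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(denom > 0, E / np.where(denom > 0, denom, 1), np.nan)
    # pairs involving an absent population are not assessable
    absent = n == 0
    S[absent, :] = np.nan
    S[:, absent] = np.nan
    return S


def _labels_to_codes(
    labels: pd.Series, populations: list[str] | None
) -> tuple[np.ndarray, list[str]]:
    if populations is None:
        populations = sorted(pd.unique(labels.astype(str)))
    cat = pd.Categorical(labels.astype(str), categories=populations)
    if cat.isna().any():
        extra = sorted(set(labels.astype(str)) - set(populations))
        raise DataError(f"labels outside the population list: {extra}")
    return cat.codes.astype(np.intp), list(populations)


def interaction_scores(
    graph: NeighborGraph,
    labels: pd.Series,
    populations: list[str] | None = None,
) -> InteractionMatrix:
    """Size-corrected pairwise interaction scores pooled over the graph's
    ROIs (typically one). ``labels`` is indexed by cell_id."""
    all_ids = np.concatenate(list(graph.cell_ids.values())) if graph.cell_ids else np.array([])
    missing = set(all_ids) - set(labels.index)
    if missing:
        raise DataError(f"{len(missing)} graph cell(s) have no label")
    codes_by_roi = {}
    pops: list[str] | None = populations
    # establish a common category order first
    joint = labels.loc[all_ids] if len(all_ids) else labels.iloc[:0]
    codes_all, pops = _labels_to_codes(joint, populations)
    k = len(pops)
    offset = 0
    n = np.zeros(k, dtype=np.int64)
    E = np.zeros((k, k), dtype=np.int64)
    for roi, ids in graph.cell_ids.items():
        codes = codes_all[offset : offset + len(ids)]
        offset += len(ids)
        n += np.bincount(codes, minlength=k)
        a, b = graph.roi_edge_indices(roi)
        if len(a):
            E += _pair_counts(codes[a], codes[b], k)
    S = _scores_from_counts(E.astype(float), n)
    return InteractionMatrix(
        S=pd.DataFrame(S, index=pops, columns=pops),
        E=pd.DataFrame(E, index=pops, columns=pops),
        n=pd.Series(n, index=pops),
    )


def permutation_enrichment(
    graph: NeighborGraph,
    labels: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    populations: list[str] | None = None,
) -> EnrichmentResult:
    """Calibrate interaction scores against a within-ROI label-permutation
    null (positions and graph fixed).

    p_enrich = (1 + #{S_perm >= S_obs}) / (n_perm + 1), and symmetrically
    for depletion. Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    if graph.n_edges == 0:
        raise DataError("neighbor graph has no edges")
    rng = np.random.default_rng(seed)

    all_ids = np.concatenate(list(graph.cell_ids.values()))
    codes_all, pops = _labels_to_codes(labels.loc[all_ids], populations)
    k = len(pops)

    roi_slices: list[tuple[slice, np.ndarray, np.ndarray]] = []
    offset = 0
    n = np.zeros(k, dtype=np.int64)
    E_obs = np.zeros((k, k), dtype=np.int64)
    for roi, ids in graph.cell_ids.items():
        sl = slice(offset, offset + len(ids))
        offset += len(ids)
        codes = codes_all[sl]
        n += np.bincount(codes, minlength=k)
        a, b = graph.roi_edge_indices(roi)
        roi_slices.append((sl, a, b))
        if len(a):
            E_obs += _pair_counts(codes[a], codes[b], k)
    S_obs = _scores_from_counts(E_obs.astype(float), n)

    sum_s = np.zeros((k, k))
    sum_s2 = np.zeros((k, k))
    ge = np.zeros((k, k), dtype=np.int64)
    le = np.zeros((k, k), dtype=np.int64)
    for _ in range(n_perm):
        E = np.zeros((k, k), dtype=np.int64)
        for sl, a, b in roi_slices:
            perm = rng.permutation(codes_all[sl])
            if len(a):
                E += _pair_counts(perm[a], perm[b], k)
        S = _scores_from_counts(E.astype(float), n)
        sum_s += np.nan_to_num(S)
        sum_s2 += np.nan_to_num(S) ** 2
        with np.errstate(invalid="ignore"):
            ge += S >= S_obs
            le += S <= S_obs

    null_mean = sum_s / n_perm
    null_var = np.clip(sum_s2 / n_perm - null_mean**2, 0, None)
    null_sd = np.sqrt(null_var)
    absent = ~np.isfinite(S_obs)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(null_mean > 0, S_obs / null_mean, np.nan)
    p_enrich = (1.0 + ge) / (n_perm + 1.0)
    p_deplete = (1.0 + le) / (n_perm + 1.0)
    for arr in (null_mean, null_sd, ratio, p_enrich, p_deplete):
        arr[absent] = np.nan

    def df(a: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(a, index=pops, columns=pops)

    return EnrichmentResult(
        observed=df(S_obs),
        null_mean=df(null_mean),
        null_sd=df(null_sd),
        ratio=df(ratio),
        p_enrich=df(p_enrich),
        p_deplete=df(p_deplete),
        n_perm=n_perm,
        seed=seed,
    )


def voronoi_export(
    cells: pd.DataFrame,
    roi_bounds: tuple[float, float, float, float],
) -> list[dict]:
    """Voronoi tessellation of cell centroids clipped to the ROI rectangle.

    ``roi_bounds`` is (xmin, ymin, xmax, ymax) in μm. Returns one record
    per cell: {cell_id, phenotype, polygon (shapely Polygon)}. The
    mirror-point construction guarantees every cell's region is finite,
    so the clipped polygons tile the rectangle.
    """
    from scipy.spatial import Voronoi, QhullError
    from shapely.geometry import Polygon, box

    if len(cells) < 3:
        raise DataError("voronoi_export needs at least 3 cells")
    xmin, ymin, xmax, ymax = roi_bounds
    pts = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise DataError("degenerate input: cell positions are collinear")
    # reflect across all four edges so every original region is bounded
    mirrored = [
        pts,
        np.column_stack([2 * xmin - pts[:, 0], pts[:, 1]]),
        np.column_stack([2 * xmax - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymin - pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymax - pts[:, 1]]),
    ]
    try:
        vor = Voronoi(np.vstack(mirrored))
    except (QhullError, ValueError) as exc:
        raise DataError(f"degenerate (e.g. collinear) cell positions: {exc}") from exc
    clip = box(xmin, ymin, xmax, ymax)
    out: list[dict] = []
    phen = cells["phenotype"] if "phenotype" in cells.columns else None
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise DataError("unbounded Voronoi region; degenerate input")
        poly = Polygon(vor.vertices[region]).intersection(clip)
        out.append(
            {
                "cell_id": cells["cell_id"].iloc[i],
                "phenotype": None if phen is None else phen.iloc[i],
                "polygon": poly,
            }
        )
    return out
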