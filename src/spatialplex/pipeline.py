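"""Stage orchestration: simulate/segment → phenotype → abundance →
spatial → morphometry, with a reproducible manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import abundance as ab
from . import io as spio
from . import morphometry as morph
from . import phenotype as ph
from . import simulate as sim
from . import spatial as sp
from .config import RunConfig
from .errors import ConfigError, DataError
from .segment import SegmentationParams, detect_maxima, grow_regions, quantify_cells, compensate_spillover

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _simulate_cohort(config: RunConfig):
    """Generate the demo cohort: cases × ROIs for each preset group."""
    frames = []
    polygons: dict[int, np.ndarray] = {}
    labels_true: dict[int, str] = {}
    offset = 0
    roi_index = 0
    for group in config.groups:
        for c in range(config.cases_per_group):
            case_id = f"{group}_case{c}"
            for r in range(config.rois_per_case):
                preset = sim.make_group_presets(
                    group, n_cells=config.n_cells, seed=config.seed
                )
                cells, truth = sim.simulate_tissue(
                    preset,
                    roi_index=roi_index,
                    roi_id=f"{case_id}_roi{r}",
                    case_id=case_id,
                    group=group,
                )
                cells = cells.copy()
                cells["cell_id"] = cells["cell_id"] + offset
                for i, poly in enumerate(truth.polygons):
                    polygons[offset + i] = poly
                    labels_true[offset + i] = str(truth.labels[i])
                offset += len(cells)
                roi_index += 1
                frames.append(cells)
    table = pd.concat(frames, ignore_index=True)
    return table, polygons, labels_true


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and write all products plus a manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    Deterministic for a fixed seed.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "mode": config.mode,
        "stages": list(config.stages),
        "versions": {
            "spatialplex": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "parameters": {
            "d_min": config.d_min,
            "d_max": config.d_max,
            "n_perm": config.n_perm,
            "threshold_method": config.threshold_method,
            "floor_fraction": config.floor_fraction,
            "floor_count": config.floor_count,
        },
        "row_counts": {},
        "outputs": {},
    }
    outputs: list[Path] = []
    polygons: dict[int, np.ndarray] | None = None

    # ---- input stage ---------------------------------------------------
    if config.mode == "simulate" and "simulate" in config.stages:
        cells, polygons, _ = _simulate_cohort(config)
        spio.write_cell_table(cells, outdir / "cells.csv")
        spio.polygons_to_geojson(polygons, outdir / "nuclei.geojson")
        outputs += [outdir / "cells.csv", outdir / "nuclei.geojson"]
    elif config.mode == "cell_table":
        cells = spio.read_cell_table(config.cell_table_path)
    elif config.mode == "image" and "segment" in config.stages:
        image = spio.read_image_tiff(config.image_path)
        if "DNA" not in image.channels:
            raise DataError("image lacks a 'DNA' nuclear channel")
        params = SegmentationParams(**config.segmentation)
        seeds = detect_maxima(image.channels["DNA"], params)
        mask = grow_regions(image.channels["DNA"], seeds, params)
        cells = quantify_cells(mask, image)
        if params.spillover_alpha > 0:
            cells = compensate_spillover(cells, mask, params.spillover_alpha)
        cells["roi_id"] = "roi0"
        cells["case_id"] = "case0"
        cells["group"] = ""
        spio.write_label_mask(mask, outdir / "mask.tiff")
        spio.write_cell_table(cells, outdir / "cells.csv")
        outputs += [outdir / "mask.tiff", outdir / "cells.csv"]
        polygons = morph.mask_to_polygons(mask.labels, image.pixel_size)
    else:
        raise ConfigError(f"no input stage enabled for mode {config.mode!r}")
    manifest["row_counts"]["cells"] = len(cells)

    # ---- phenotype -----------------------------------------------------
    if "phenotype" in config.stages:
        schema = ph.default_schema()
        thresholds = ph.fit_marker_thresholds(
            cells,
            method=config.threshold_method,
            cofactor=config.arcsinh_cofactor,
            seed=config.seed,
        )
        thresholds.to_yaml(outdir / "thresholds.yaml")
        cells = ph.assign_phenotypes(cells, schema, thresholds)
        spio.write_cell_table(cells, outdir / "cells_phenotyped.csv")
        outputs += [outdir / "thresholds.yaml", outdir / "cells_phenotyped.csv"]
        manifest["row_counts"]["phenotyped"] = len(cells)

    # ---- abundance -----------------------------------------------------
    if "abundance" in config.stages:
        comp = ab.roi_composition(cells)
        zmat = ab.zscore_matrix(comp)
        comp.fractions.to_csv(outdir / "composition.csv")
        zmat.z.to_csv(outdir / "zscores.csv")
        zmat.group_means.to_csv(outdir / "group_zscores.csv")
        outputs += [
            outdir / "composition.csv",
            outdir / "zscores.csv",
            outdir / "group_zscores.csv",
        ]
        manifest["row_counts"]["rois"] = len(comp.fractions)

    # ---- spatial -------------------------------------------------------
    if "spatial" in config.stages:
        graph = sp.build_neighbor_graph(cells, d_min=config.d_min, d_max=config.d_max)
        graph.edges.to_csv(outdir / "edges.csv", index=False)
        outputs.append(outdir / "edges.csv")
        manifest["row_counts"]["edges"] = graph.n_edges
        pops = list(ph.default_schema().names) + [ph.OTHER_LABEL]
        groups = sorted(cells["group"].unique()) if "group" in cells.columns else [""]
        for group in groups:
            sub = cells[cells["group"] == group] if group != "" else cells
            if len(sub) == 0:
                continue
            gsub = sp.build_neighbor_graph(sub, d_min=config.d_min, d_max=config.d_max)
            labels = pd.Series(
                sub["phenotype"].to_numpy(), index=sub["cell_id"].to_numpy()
            )
            tag = group if group != "" else "all"
            mat = sp.interaction_scores(gsub, labels, populations=pops)
            mat.S.to_csv(outdir / f"interactions_{tag}.csv")
            outputs.append(outdir / f"interactions_{tag}.csv")
            if gsub.n_edges > 0:
                enr = sp.permutation_enrichment(
                    gsub, labels, n_perm=config.n_perm, seed=config.seed,
                    populations=pops,
                )
                enr.ratio.to_csv(outdir / f"enrichment_ratio_{tag}.csv")
                enr.p_enrich.to_csv(outdir / f"enrichment_p_{tag}.csv")
                outputs += [
                    outdir / f"enrichment_ratio_{tag}.csv",
                    outdir / f"enrichment_p_{tag}.csv",
                ]
            # one Voronoi export per group, first ROI
            roi0 = sub["roi_id"].iloc[0]
            rsub = sub[sub["roi_id"] == roi0]
            if len(rsub) >= 3:
                bounds = (
                    float(rsub["x_um"].min()), float(rsub["y_um"].min()),
                    float(rsub["x_um"].max()), float(rsub["y_um"].max()),
                )
                try:
                    vor = sp.voronoi_export(rsub, bounds)
                except DataError:
                    vor = []
                if vor:
                    polys = {
                        int(rec["cell_id"]): np.asarray(
                            rec["polygon"].exterior.coords
                        )
                        for rec in vor
                        if not rec["polygon"].is_empty
                    }
                    props = [
                        {"phenotype": rec["phenotype"]}
                        for rec in vor
                        if not rec["polygon"].is_empty
                    ]
                    spio.polygons_to_geojson(
                        polys, outdir / f"voronoi_{tag}.geojson", properties=props
                    )
                    outputs.append(outdir / f"voronoi_{tag}.geojson")

    # ---- morphometry ---------------------------------------------------
    if "morphometry" in config.stages and polygons is not None:
        per_nucleus, summary, tests = morph.tumor_nuclear_morphometry(cells, polygons)
        per_nucleus.to_csv(outdir / "tumor_morphometry.csv", index=False)
        summary.to_csv(outdir / "tumor_morphometry_summary.csv", index=False)
        tests.to_csv(outdir / "tumor_morphometry_tests.csv", index=False)
        outputs += [
            outdir / "tumor_morphometry.csv",
            outdir / "tumor_morphometry_summary.csv",
            outdir / "tumor_morphometry_tests.csv",
        ]
        manifest["row_counts"]["tumor_nuclei"] = len(per_nucleus)

    manifest["outputs"] = {p.name: _sha256(p) for p in outputs}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
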