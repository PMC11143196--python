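import numpy as np
import pandas as pd
import pytest

from spatialplex.phenotype import assign_phenotypes, default_schema, fit_marker_thresholds
from spatialplex.simulate import make_group_presets, simulate_tissue


@pytest.fixture(scope="session")
def group1_tissue():
    """One group1 ROI (nodular, planted rosettes) with ground truth."""
    config = make_group_presets("group1", n_cells=2000, seed=11)
    cells, truth = simulate_tissue(config, roi_index=0, group="group1")
    return config, cells, truth


@pytest.fixture(scope="session")
def phenotyped_cohort():
    """Small 4-group cohort with fitted thresholds and assigned phenotypes."""
    frames = []
    truths = {}
    offset = 0
    for gi, group in enumerate(("group1", "group2", "group3", "thrlbcl")):
        for c in range(2):
            for r in range(2):
                config = make_group_presets(group, n_cells=700, seed=3)
                roi_id = f"{group}_case{c}_roi{r}"
                cells, truth = simulate_tissue(
                    config,
                    roi_index=gi * 4 + c * 2 + r,
                    roi_id=roi_id,
                    case_id=f"{group}_case{c}",
                    group=group,
                )
                cells = cells.copy()
                cells["cell_id"] = cells["cell_id"] + offset
                truths[roi_id] = truth
                offset += len(cells)
                frames.append(cells)
    table = pd.concat(frames, ignore_index=True)
    thresholds = fit_marker_thresholds(table, seed=0)
    phenotyped = assign_phenotypes(table, default_schema(), thresholds)
    return phenotyped, truths


@pytest.fixture
def rng():
    return np.random.default_rng(42)
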