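"""Marker-gating phenotype assignment.

Cells are assigned to named populations by boolean co-expression rules:
a cell matches a rule iff all *required* markers are positive and all
*forbidden* markers are negative. Among matching rules the one with the
largest required set wins; ties are broken by rule priority. Cells that
match no rule are labeled ``"other"``.

Marker positivity is decided on arcsinh-transformed intensities against
per-marker thresholds fitted either by a two-component Gaussian mixture
or by an upper quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError

__all__ = [
    "MARKER_PANEL",
    "POPULATIONS",
    "OTHER_LABEL",
    "POPULATION_PROFILES",
    "PhenotypeRule",
    "PhenotypeSchema",
    "ThresholdSet",
    "default_schema",
    "fit_marker_thresholds",
    "assign_phenotypes",
    "detect_population",
]

#: The 21-marker panel carried by synthetic cell tables.
MARKER_PANEL: tuple[str, ...] = (
    "CD20", "BCL6", "IgD", "CD3", "CD4", "CD8", "PD1", "LAG3", "CD69",
    "FOXP3", "CD68", "MPO", "CD14", "CD163", "PU1", "CD45", "CD30",
    "CD15", "CD11c", "CD56", "Ki67",
)

OTHER_LABEL = "other"


@dataclass(frozen=True)
class PhenotypeRule:
    """One gating rule: name + required/forbidden marker sets.

    ``priority`` breaks ties between rules with equally many required
    markers; lower numbers win.
    """

    name: str
    required: frozenset[str]
    forbidden: frozenset[str] = frozenset()
    priority: int = 0

    def __post_init__(self) -> None:
        if not self.required:
            raise ConfigError(f"rule {self.name!r} has an empty required set")
        if self.required & self.forbidden:
            raise ConfigError(
                f"rule {self.name!r}: markers {sorted(self.required & self.forbidden)} "
                "are both required and forbidden"
            )


@dataclass
class PhenotypeSchema:
    """Ordered collection of gating rules with unique names and priorities."""

    rules: list[PhenotypeRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.rules]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate rule names in schema")
        priorities = [r.priority for r in self.rules]
        if len(set(priorities)) != len(priorities):
            raise ConfigError("rule priorities must be strictly ordered (unique)")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rules]

    @property
    def markers(self) -> set[str]:
        out: set[str] = set()
        for r in self.rules:
            out |= r.required | r.forbidden
        return out

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def to_yaml(self, path) -> None:
        payload = [
            {
                "name": r.name,
                "required": sorted(r.required),
                "forbidden": sorted(r.forbidden),
                "priority": r.priority,
            }
            for r in self.rules
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhenotypeSchema":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        rules = [
            PhenotypeRule(
                name=item["name"],
                required=frozenset(item["required"]),
                forbidden=frozenset(item.get("forbidden", ())),
                priority=int(item["priority"]),
            )
            for item in payload
        ]
        return cls(rules)


def default_schema() -> PhenotypeSchema:
    """The 12-population gating schema used throughout the pipeline.

    B-cell rules forbid CD3; T-cell rules forbid CD20 and CD68; plain
    Helper T additionally forbids the markers that would promote a cell
    into one of its activated/specialized subsets; Cytotoxic T forbids
    CD4 except for the double-positive population, which requires both.
    """
    b_forbid = frozenset({"CD3"})
    t_forbid = frozenset({"CD20", "CD68"})
    rules = [
        PhenotypeRule("Tumor B", frozenset({"CD20", "BCL6"}), b_forbid, 1),
        PhenotypeRule("TME B", frozenset({"CD20", "IgD"}), b_forbid, 2),
        PhenotypeRule(
            "Helper T", frozenset({"CD3", "CD4"}),
            t_forbid | {"CD8", "FOXP3", "PD1", "LAG3", "CD69"}, 3,
        ),
        PhenotypeRule(
            "Activated Helper T", frozenset({"CD3", "CD4", "LAG3", "CD69"}),
            t_forbid | {"CD8", "FOXP3", "PD1"}, 4,
        ),
        PhenotypeRule(
            "TFH", frozenset({"CD3", "CD4", "PD1", "BCL6"}),
            t_forbid | {"CD8", "FOXP3"}, 5,
        ),
        PhenotypeRule(
            "aTFH", frozenset({"CD3", "CD4", "PD1", "BCL6", "LAG3", "CD69"}),
            t_forbid | {"CD8", "FOXP3"}, 6,
        ),
        PhenotypeRule(
            "Cytotoxic T", frozenset({"CD3", "CD8"}), t_forbid | {"CD4"}, 7,
        ),
        PhenotypeRule(
            "Activated Cytotoxic T", frozenset({"CD3", "CD8", "LAG3", "CD69"}),
            t_forbid | {"CD4"}, 8,
        ),
        PhenotypeRule(
            "T-reg", frozenset({"CD3", "CD4", "FOXP3"}), t_forbid | {"CD8"}, 9,
        ),
        PhenotypeRule("DPT", frozenset({"CD3", "CD4", "CD8"}), t_forbid, 10),
        PhenotypeRule("Macrophage", frozenset({"CD68"}), frozenset({"CD3", "CD20"}), 11),
        PhenotypeRule(
            "Monocyte", frozenset({"CD68", "MPO", "CD14"}), frozenset({"CD3", "CD20"}), 12,
        ),
    ]
    return PhenotypeSchema(rules)


#: Population names in schema order (without "other").
POPULATIONS: tuple[str, ...] = tuple(r.name for r in default_schema().rules)

#: Which panel markers each population truly expresses; used by the tissue
#: simulator to draw intensities. Profiles are consistent with
#: :func:`default_schema` (required markers present, forbidden absent).
POPULATION_PROFILES: dict[str, frozenset[str]] = {
    "Tumor B": frozenset({"CD20", "BCL6", "CD45", "Ki67"}),
    "TME B": frozenset({"CD20", "IgD", "CD45"}),
    "Helper T": frozenset({"CD3", "CD4", "CD45"}),
    "Activated Helper T": frozenset({"CD3", "CD4", "LAG3", "CD69", "CD45"}),
    "TFH": frozenset({"CD3", "CD4", "PD1", "BCL6", "CD45"}),
    "aTFH": frozenset({"CD3", "CD4", "PD1", "BCL6", "LAG3", "CD69", "CD45"}),
    "Cytotoxic T": frozenset({"CD3", "CD8", "CD45"}),
    "Activated Cytotoxic T": frozenset({"CD3", "CD8", "LAG3", "CD69", "CD45"}),
    "T-reg": frozenset({"CD3", "CD4", "FOXP3", "CD45"}),
    "DPT": frozenset({"CD3", "CD4", "CD8", "CD45"}),
    "Macrophage": frozenset({"CD68", "CD163", "PU1", "CD11c", "CD45"}),
    "Monocyte": frozenset({"CD68", "MPO", "CD14", "PU1", "CD45"}),
    OTHER_LABEL: frozenset(),
}


@dataclass
class ThresholdSet:
    """Per-marker positivity thresholds on the arcsinh-transformed scale."""

    thresholds: dict[str, float]
    cofactor: float = 150.0

    def __post_init__(self) -> None:
        if self.cofactor <= 0:
            raise ConfigError("arcsinh cofactor must be positive")
        for marker, t in self.thresholds.items():
            if not np.isfinite(t):
                raise ConfigError(f"threshold for {marker!r} is not finite")

    def transform(self, x: np.ndarray) -> np.ndarray:
        return np.arcsinh(np.asarray(x, dtype=float) / self.cofactor)

    def is_positive(self, cells: pd.DataFrame, marker: str) -> np.ndarray:
        if marker not in cells.columns:
            raise DataError(f"marker column {marker!r} missing from cell table")
        return self.transform(cells[marker].to_numpy()) > self.thresholds[marker]

    def to_yaml(self, path) -> None:
        payload = {
            "cofactor": float(self.cofactor),
            "thresholds": {k: float(v) for k, v in self.thresholds.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ThresholdSet":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(thresholds=dict(payload["thresholds"]), cofactor=float(payload["cofactor"]))


def fit_marker_thresholds(
    cells: pd.DataFrame,
    method: str = "gmm2",
    markers: Sequence[str] | None = None,
    cofactor: float = 150.0,
    quantile: float = 0.9,
    seed: int = 0,
) -> ThresholdSet:
    """Fit per-marker positivity thresholds.

    ``gmm2`` fits a two-component 1-D Gaussian mixture to the arcsinh
    intensities and puts the threshold at the midpoint of the component
    means. ``quantile`` uses the configured upper quantile. Markers with
    (near-)constant intensity get a threshold above their maximum so no
    cell is called positive, with a warning.
    """
    if method not in ("gmm2", "quantile"):
        raise ConfigError(f"unknown threshold method {method!r}")
    if markers is None:
        markers = [m for m in MARKER_PANEL if m in cells.columns]
    if not markers:
        raise DataError("no marker columns found in cell table")

    thresholds: dict[str, float] = {}
    for marker in markers:
        if marker not in cells.columns:
            raise DataError(f"marker column {marker!r} missing from cell table")
        values = np.arcsinh(cells[marker].to_numpy(dtype=float) / cofactor)
        if not np.all(np.isfinite(values)):
            raise DataError(f"non-finite intensities for marker {marker!r}")
        if np.ptp(values) < 1e-12:
            warnings.warn(
                f"marker {marker!r} is (near-)constant; no cell will be positive",
                stacklevel=2,
            )
            thresholds[marker] = float(values.max() + 1.0)
            continue
        if method == "quantile":
            thresholds[marker] = float(np.quantile(values, quantile))
        else:
            from sklearn.mixture import GaussianMixture

            gm = GaussianMixture(
                n_components=2, n_init=3, random_state=seed, covariance_type="full"
            ).fit(values.reshape(-1, 1))
            means = np.sort(gm.means_.ravel())
            thresholds[marker] = float(means.mean())
    return ThresholdSet(thresholds=thresholds, cofactor=cofactor)


def _marker_state_matrix(
    cells: pd.DataFrame, schema: PhenotypeSchema, thresholds: ThresholdSet
) -> pd.DataFrame:
    markers = sorted(schema.markers)
    missing = [m for m in markers if m not in cells.columns]
    if missing:
        raise DataError(f"marker column(s) missing from cell table: {missing}")
    missing_thr = [m for m in markers if m not in thresholds.thresholds]
    if missing_thr:
        raise DataError(f"no fitted threshold for marker(s): {missing_thr}")
    state = {m: thresholds.is_positive(cells, m) for m in markers}
    return pd.DataFrame(state, index=cells.index)


def assign_phenotypes(
    cells: pd.DataFrame,
    schema: PhenotypeSchema | None = None,
    thresholds: ThresholdSet | None = None,
    marker_states: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign each cell the most specific matching population.

    Returns a copy of ``cells`` with a ``phenotype`` column and one
    ``<marker>_pos`` boolean column per schema marker. ``marker_states``
    may be supplied directly (bypassing thresholds), e.g. in tests.
    """
    if schema is None:
        schema = default_schema()
    if marker_states is None:
        if thresholds is None:
            raise ConfigError("either thresholds or marker_states must be given")
        marker_states = _marker_state_matrix(cells, schema, thresholds)
    else:
        missing = [m for m in sorted(schema.markers) if m not in marker_states.columns]
        if missing:
            raise DataError(f"marker state column(s) missing: {missing}")

    n = len(cells)
    # score = number of required markers of the matched rule; ties by priority
    best_score = np.full(n, -1, dtype=int)
    best_prio = np.full(n, np.iinfo(int).max, dtype=int)
    assigned = np.full(n, OTHER_LABEL, dtype=object)
    for rule in schema:
        match = np.ones(n, dtype=bool)
        for m in rule.required:
            match &= marker_states[m].to_numpy()
        for m in rule.forbidden:
            match &= ~marker_states[m].to_numpy()
        score = len(rule.required)
        take = match & (
            (score > best_score) | ((score == best_score) & (rule.priority < best_prio))
        )
        assigned[take] = rule.name
        best_score[take] = score
        best_prio[take] = rule.priority

    out = cells.copy()
    out["phenotype"] = assigned
    for m in sorted(schema.markers):
        out[f"{m}_pos"] = marker_states[m].to_numpy()
    return out


def detect_population(
    case_cells: pd.DataFrame,
    name: str,
    floor_fraction: float = 0.001,
    floor_count: int = 20,
    schema: PhenotypeSchema | None = None,
) -> bool:
    """Decide whether a population is detected in one case.

    True iff the population's fraction of all pooled cells for the case
    is at least ``floor_fraction`` and its count at least ``floor_count``.
    """
    if schema is None:
        schema = default_schema()
    known = set(schema.names) | {OTHER_LABEL}
    if name not in known:
        raise ConfigError(f"unknown population name {name!r}")
    if "phenotype" not in case_cells.columns:
        raise DataError("cell table has no 'phenotype' column; run assign_phenotypes first")
    total = len(case_cells)
    if total == 0:
        raise DataError("case has no cells")
    count = int((case_cells["phenotype"] == name).sum())
    return count >= floor_count and (count / total) >= floor_fraction
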