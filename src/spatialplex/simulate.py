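"""Synthetic tissue generator.

Produces per-ROI cell tables with known ground truth for every
downstream stage: cell positions (nodular or diffuse point patterns
with a minimum center-to-center spacing), population labels drawn from
a configurable composition, planted TFH rosettes around tumor anchors,
log-normal marker intensities, and noisy elliptical nucleus polygons.
Optionally renders a multichannel raster image of the ROI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .phenotype import MARKER_PANEL, OTHER_LABEL, POPULATION_PROFILES, POPULATIONS
from .segment import ImageGrid

__all__ = [
    "RosetteSpec",
    "TissueConfig",
    "GroundTruth",
    "GROUPS",
    "make_group_presets",
    "simulate_tissue",
    "render_image",
]

GROUPS = ("group1", "group2", "group3", "thrlbcl")

# log-normal intensity levels (log-mean, log-sd) on the raw scale
_POS_LEVEL = (math.log(600.0), 0.30)
_NEG_LEVEL = (math.log(10.0), 0.45)

_ROSETTE_ANCHOR = "Tumor B"
_ROSETTE_MEMBER = "TFH"


@dataclass(frozen=True)
class RosetteSpec:
    """Planted rosette geometry: TFH members per tumor anchor and the
    annulus (in μm) they are placed in."""

    tfh_per_lp: int
    r_lo: float
    r_hi: float

    def __post_init__(self) -> None:
        if self.tfh_per_lp < 1:
            raise ConfigError("tfh_per_lp must be >= 1")
        if not (0 <= self.r_lo < self.r_hi):
            raise ConfigError("rosette annulus requires 0 <= r_lo < r_hi")


@dataclass
class TissueConfig:
    """Full generative specification for one synthetic ROI."""

    architecture: str  # "nodular" | "diffuse"
    roi_size_um: tuple[float, float]
    n_cells: int
    composition: dict[str, float]
    nodule_count: int = 0
    nodule_radius_um: float = 0.0
    rosette_spec: RosetteSpec | None = None
    intensity_model: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    nuclear_size_model: dict[str, tuple[float, float]] = field(default_factory=dict)
    min_spacing_um: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.architecture not in ("nodular", "diffuse"):
            raise ConfigError(f"unknown architecture {self.architecture!r}")
        w, h = self.roi_size_um
        if w <= 0 or h <= 0:
            raise ConfigError("roi dimensions must be positive")
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        fracs = np.array(list(self.composition.values()), dtype=float)
        if (fracs < 0).any():
            raise ConfigError("composition fractions must be nonnegative")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ConfigError(f"composition must sum to 1 (got {fracs.sum():.12f})")
        if self.architecture == "nodular":
            if self.nodule_count < 1 or self.nodule_radius_um <= 0:
                raise ConfigError("nodular architecture needs nodule_count>=1 and radius>0")
        if self.min_spacing_um < 0:
            raise ConfigError("min_spacing_um must be nonnegative")

    # -- YAML round trip ------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "architecture": self.architecture,
            "roi_size_um": list(self.roi_size_um),
            "n_cells": self.n_cells,
            "composition": {k: float(v) for k, v in self.composition.items()},
            "nodule_count": self.nodule_count,
            "nodule_radius_um": self.nodule_radius_um,
            "rosette_spec": (
                None
                if self.rosette_spec is None
                else {
                    "tfh_per_lp": self.rosette_spec.tfh_per_lp,
                    "r_lo": self.rosette_spec.r_lo,
                    "r_hi": self.rosette_spec.r_hi,
                }
            ),
            "intensity_model": {
                pop: {m: [float(a), float(b)] for m, (a, b) in model.items()}
                for pop, model in self.intensity_model.items()
            },
            "nuclear_size_model": {
                pop: [float(a), float(b)] for pop, (a, b) in self.nuclear_size_model.items()
            },
            "min_spacing_um": self.min_spacing_um,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TissueConfig":
        with open(path) as fh:
            p = yaml.safe_load(fh)
        ros = p.get("rosette_spec")
        return cls(
            architecture=p["architecture"],
            roi_size_um=tuple(p["roi_size_um"]),
            n_cells=int(p["n_cells"]),
            composition={k: float(v) for k, v in p["composition"].items()},
            nodule_count=int(p.get("nodule_count", 0)),
            nodule_radius_um=float(p.get("nodule_radius_um", 0.0)),
            rosette_spec=None if ros is None else RosetteSpec(**ros),
            intensity_model={
                pop: {m: tuple(v) for m, v in model.items()}
                for pop, model in p.get("intensity_model", {}).items()
            },
            nuclear_size_model={
                pop: tuple(v) for pop, v in p.get("nuclear_size_model", {}).items()
            },
            min_spacing_um=float(p.get("min_spacing_um", 4.0)),
            seed=int(p.get("seed", 0)),
        )


@dataclass
class GroundTruth:
    """True per-cell labels, nucleus polygons and planted structure."""

    labels: np.ndarray  # object array of population names
    polygons: list[np.ndarray]  # each (k, 2) vertices in μm, open ring
    composition: dict[str, float]  # realized label fractions
    rosettes: list[tuple[int, tuple[int, ...]]]  # (anchor index, member indices)


def default_intensity_model() -> dict[str, dict[str, tuple[float, float]]]:
    """Log-normal (log-mean, log-sd) per population and marker, derived
    from the population expression profiles."""
    model: dict[str, dict[str, tuple[float, float]]] = {}
    for pop, positives in POPULATION_PROFILES.items():
        model[pop] = {
            m: (_POS_LEVEL if m in positives else _NEG_LEVEL) for m in MARKER_PANEL
        }
    return model


def _nuclear_sizes(tumor_mean: float) -> dict[str, tuple[float, float]]:
    sizes = {pop: (16.0, 2.5) for pop in POPULATIONS}
    sizes[OTHER_LABEL] = (16.0, 2.5)
    sizes["Macrophage"] = (24.0, 3.0)
    sizes["Monocyte"] = (20.0, 2.5)
    sizes["Tumor B"] = (tumor_mean, 3.0)
    return sizes


# Composition vectors chosen to respect the qualitative cross-group
# orderings (tumor-B increasing toward THRLBCL, TME-B decreasing,
# macrophage/monocyte maximal in THRLBCL); the absolute values are
# implementation choices, not published quantities.
_PRESET_COMPOSITION: dict[str, dict[str, float]] = {
    "group1": {
        "Tumor B": 0.02, "TME B": 0.30, "Helper T": 0.20, "Activated Helper T": 0.02,
        "TFH": 0.08, "aTFH": 0.01, "Cytotoxic T": 0.08, "Activated Cytotoxic T": 0.02,
        "T-reg": 0.02, "DPT": 0.02, "Macrophage": 0.04, "Monocyte": 0.02,
    },
    "group2": {
        "Tumor B": 0.045, "TME B": 0.22, "Helper T": 0.17, "Activated Helper T": 0.035,
        "TFH": 0.065, "aTFH": 0.02, "Cytotoxic T": 0.09, "Activated Cytotoxic T": 0.03,
        "T-reg": 0.03, "DPT": 0.02, "Macrophage": 0.045, "Monocyte": 0.03,
    },
    "group3": {
        "Tumor B": 0.07, "TME B": 0.12, "Helper T": 0.10, "Activated Helper T": 0.06,
        "TFH": 0.06, "aTFH": 0.04, "Cytotoxic T": 0.10, "Activated Cytotoxic T": 0.04,
        "T-reg": 0.035, "DPT": 0.015, "Macrophage": 0.06, "Monocyte": 0.04,
    },
    "thrlbcl": {
        "Tumor B": 0.10, "TME B": 0.02, "Helper T": 0.07, "Activated Helper T": 0.02,
        "TFH": 0.03, "aTFH": 0.06, "Cytotoxic T": 0.14, "Activated Cytotoxic T": 0.06,
        "T-reg": 0.04, "DPT": 0.004, "Macrophage": 0.15, "Monocyte": 0.065,
    },
}

# tumor nuclear mean area (μm²): group1 < group2 < thrlbcl < group3
_PRESET_TUMOR_AREA = {"group1": 22.0, "group2": 28.0, "group3": 40.0, "thrlbcl": 34.0}


def make_group_presets(
    group: str, n_cells: int = 2000, roi_size_um: tuple[float, float] = (400.0, 400.0),
    seed: int = 0,
) -> TissueConfig:
    """Return the generative preset for one of the four analysis groups.

    group1/group2 are nodular (group1 with planted TFH rosettes),
    group3/thrlbcl diffuse.
    """
    if group not in GROUPS:
        raise ConfigError(f"unknown group {group!r}; expected one of {GROUPS}")
    comp = dict(_PRESET_COMPOSITION[group])
    comp[OTHER_LABEL] = 1.0 - sum(comp.values())
    nodular = group in ("group1", "group2")
    return TissueConfig(
        architecture="nodular" if nodular else "diffuse",
        roi_size_um=roi_size_um,
        n_cells=n_cells,
        composition=comp,
        nodule_count=3 if nodular else 0,
        nodule_radius_um=min(roi_size_um) * 0.22 if nodular else 0.0,
        rosette_spec=RosetteSpec(tfh_per_lp=3, r_lo=4.0, r_hi=12.0)
        if group == "group1"
        else None,
        intensity_model=default_intensity_model(),
        nuclear_size_model=_nuclear_sizes(_PRESET_TUMOR_AREA[group]),
        min_spacing_um=4.0,
        seed=seed,
    )


class _SpacingGrid:
    """Uniform hash grid for minimum-distance rejection sampling."""

    def __init__(self, spacing: float):
        self.spacing = spacing
        self.cell = max(spacing, 1e-9)
        self.buckets: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return (int(x // self.cell), int(y // self.cell))

    def ok(self, x: float, y: float) -> bool:
        if self.spacing <= 0:
            return True
        kx, ky = self._key(x, y)
        s2 = self.spacing * self.spacing
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for px, py in self.buckets.get((kx + dx, ky + dy), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < s2:
                        return False
        return True

    def add(self, x: float, y: float) -> None:
        self.buckets.setdefault(self._key(x, y), []).append((x, y))

    def remove(self, x: float, y: float) -> None:
        self.buckets[self._key(x, y)].remove((x, y))


def _sample_label_counts(
    composition: Mapping[str, float],
    n: int,
    rng: np.random.Generator,
    rosette_spec: RosetteSpec | None,
) -> dict[str, int]:
    """Multinomial draw of per-population counts.

    When rosettes are requested the draw is topped up (from the largest
    uninvolved population) so every anchor can receive its members; the
    adjustment is small relative to binomial sampling noise.
    """
    names = list(composition)
    probs = np.array([composition[k] for k in names], dtype=float)
    counts = dict(zip(names, rng.multinomial(n, probs / probs.sum()).tolist()))
    if rosette_spec is not None:
        need = rosette_spec.tfh_per_lp * counts.get(_ROSETTE_ANCHOR, 0)
        shortfall = need - counts.get(_ROSETTE_MEMBER, 0)
        while shortfall > 0:
            donor = max(
                (k for k in names if k not in (_ROSETTE_ANCHOR, _ROSETTE_MEMBER)),
                key=lambda k: counts[k],
                default=None,
            )
            if donor is None or counts[donor] == 0:
                raise ConfigError(
                    "composition cannot support the requested rosettes"
                )
            counts[donor] -= 1
            counts[_ROSETTE_MEMBER] = counts.get(_ROSETTE_MEMBER, 0) + 1
            shortfall -= 1
    return counts


class _PositionSampler:
    """Dart-throwing sampler with the configured architecture proposal
    and minimum-spacing rejection."""

    def __init__(self, config: TissueConfig, rng: np.random.Generator, max_tries: int = 2000):
        self.config = config
        self.rng = rng
        self.max_tries = max_tries
        self.grid = _SpacingGrid(config.min_spacing_um)
        self.points: list[tuple[float, float]] = []
        w, h = config.roi_size_um
        if config.architecture == "nodular":
            margin = min(config.nodule_radius_um, min(w, h) / 2)
            self.centers = np.column_stack(
                [
                    rng.uniform(margin, w - margin, size=config.nodule_count),
                    rng.uniform(margin, h - margin, size=config.nodule_count),
                ]
            )
        else:
            self.centers = None

    def _propose(self) -> tuple[float, float] | None:
        w, h = self.config.roi_size_um
        if self.centers is not None and self.rng.uniform() < 0.85:
            c = self.centers[self.rng.integers(len(self.centers))]
            r = self.config.nodule_radius_um * math.sqrt(self.rng.uniform())
            theta = self.rng.uniform(0, 2 * math.pi)
            x, y = c[0] + r * math.cos(theta), c[1] + r * math.sin(theta)
            if not (0 <= x <= w and 0 <= y <= h):
                return None
        else:
            x, y = self.rng.uniform(0, w), self.rng.uniform(0, h)
        return x, y

    def place(self, n: int) -> list[int]:
        """Place ``n`` points; returns their indices."""
        out = []
        for _ in range(n):
            for _ in range(self.max_tries):
                xy = self._propose()
                if xy is not None and self.grid.ok(*xy):
                    self.grid.add(*xy)
                    self.points.append(xy)
                    out.append(len(self.points) - 1)
                    break
            else:
                w, h = self.config.roi_size_um
                raise ConfigError(
                    f"infeasible packing: placed {len(self.points)} of "
                    f"{self.config.n_cells} cells in {w:.0f}x{h:.0f} μm at "
                    f"spacing {self.config.min_spacing_um} μm"
                )
        return out

    def place_in_annulus(self, cx: float, cy: float, r_lo: float, r_hi: float) -> int:
        w, h = self.config.roi_size_um
        for _ in range(self.max_tries):
            r = math.sqrt(self.rng.uniform(r_lo**2, r_hi**2))
            theta = self.rng.uniform(0, 2 * math.pi)
            x, y = cx + r * math.cos(theta), cy + r * math.sin(theta)
            if 0 <= x <= w and 0 <= y <= h and self.grid.ok(x, y):
                self.grid.add(x, y)
                self.points.append((x, y))
                return len(self.points) - 1
        raise ConfigError("infeasible rosette placement at the spacing constraint")


def _make_polygon(
    cx: float, cy: float, area: float, rng: np.random.Generator, n_vertices: int = 14
) -> np.ndarray:
    """Noisy rotated ellipse with the requested area (star-shaped, hence simple)."""
    aspect = rng.uniform(0.7, 1.0)
    phi = rng.uniform(0, math.pi)
    theta = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    wobble = 1.0 + rng.normal(0, 0.05, size=n_vertices)
    a = 1.0
    b = aspect
    x = a * np.cos(theta) * wobble
    y = b * np.sin(theta) * wobble
    xr = x * math.cos(phi) - y * math.sin(phi)
    yr = x * math.sin(phi) + y * math.cos(phi)
    poly = np.column_stack([xr, yr])
    # rescale to the target area via the shoelace formula
    x0, y0 = poly[:, 0], poly[:, 1]
    raw_area = 0.5 * abs(np.dot(x0, np.roll(y0, -1)) - np.dot(y0, np.roll(x0, -1)))
    scale = math.sqrt(area / raw_area)
    poly *= scale
    poly[:, 0] += cx
    poly[:, 1] += cy
    return poly


def simulate_tissue(
    config: TissueConfig,
    roi_index: int = 0,
    roi_id: str | None = None,
    case_id: str = "case0",
    group: str | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one synthetic ROI.

    Deterministic given ``(config.seed, roi_index)``: a single RNG stream
    seeded from that pair drives positions, labels, rosettes, intensities
    and polygons.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, roi_index])
    if roi_id is None:
        roi_id = f"roi{roi_index}"

    counts = _sample_label_counts(
        config.composition, config.n_cells, rng, config.rosette_spec
    )
    sampler = _PositionSampler(config, rng)
    labels = np.empty(config.n_cells, dtype=object)
    rosettes: list[tuple[int, tuple[int, ...]]] = []

    if config.rosette_spec is not None:
        # plant anchors and rosette members first, while the ROI is sparse
        spec = config.rosette_spec
        n_anchor = counts.get(_ROSETTE_ANCHOR, 0)
        need = spec.tfh_per_lp * n_anchor
        if counts.get(_ROSETTE_MEMBER, 0) < need:
            raise ConfigError(
                f"rosette spec needs {need} {_ROSETTE_MEMBER} cells but composition "
                f"yields only {counts.get(_ROSETTE_MEMBER, 0)}"
            )
        anchor_idx = sampler.place(n_anchor)
        for a in anchor_idx:
            ax, ay = sampler.points[a]
            members = tuple(
                sampler.place_in_annulus(ax, ay, spec.r_lo, spec.r_hi)
                for _ in range(spec.tfh_per_lp)
            )
            for m in members:
                labels[m] = _ROSETTE_MEMBER
            labels[a] = _ROSETTE_ANCHOR
            rosettes.append((int(a), members))
        remaining = dict(counts)
        remaining[_ROSETTE_ANCHOR] -= n_anchor
        remaining[_ROSETTE_MEMBER] -= need
    else:
        remaining = dict(counts)

    n_placed = len(sampler.points)
    rest_idx = sampler.place(config.n_cells - n_placed)
    rest_labels = np.concatenate(
        [np.full(c, name, dtype=object) for name, c in remaining.items()]
    )
    rng.shuffle(rest_labels)
    labels[rest_idx] = rest_labels
    positions = np.asarray(sampler.points, dtype=float)

    intensity_model = config.intensity_model or default_intensity_model()
    n = config.n_cells
    data: dict[str, np.ndarray] = {}
    for marker in MARKER_PANEL:
        col = np.empty(n, dtype=float)
        for pop in list(config.composition):
            idx = np.flatnonzero(labels == pop)
            if idx.size == 0:
                continue
            model = intensity_model.get(pop, {})
            log_mean, log_sd = model.get(marker, _NEG_LEVEL)
            col[idx] = rng.lognormal(log_mean, log_sd, size=idx.size)
        data[marker] = col

    size_model = config.nuclear_size_model or _nuclear_sizes(25.0)
    polygons: list[np.ndarray] = []
    for i in range(n):
        mean, sd = size_model.get(str(labels[i]), (16.0, 2.5))
        area = max(rng.normal(mean, sd), 5.0)
        polygons.append(_make_polygon(positions[i, 0], positions[i, 1], area, rng))

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "roi_id": roi_id,
            "case_id": case_id,
            "group": group if group is not None else "",
            "x_um": positions[:, 0],
            "y_um": positions[:, 1],
            **data,
        }
    )
    truth = GroundTruth(
        labels=labels,
        polygons=polygons,
        composition={k: counts[k] / n for k in counts},
        rosettes=rosettes,
    )
    return cells, truth


def render_image(
    cells: pd.DataFrame,
    truth: GroundTruth,
    pixel_size: float,
    roi_size_um: tuple[float, float] | None = None,
    noise_sd: float = 2.0,
    rng: np.random.Generator | None = None,
) -> ImageGrid:
    """Render a multichannel raster of an ROI.

    The nuclear channel ("DNA") is a sum of per-nucleus Gaussian blobs
    whose amplitude and width scale with nucleus polygon area; each
    marker channel paints the per-cell intensity over its nucleus mask
    plus Gaussian read noise.
    """
    if pixel_size <= 0:
        raise ConfigError("pixel_size must be positive")
    if len(cells) == 0:
        raise DataError("cannot render an empty cell table")
    if rng is None:
        rng = np.random.default_rng(0)

    from skimage.draw import polygon as draw_polygon

    if roi_size_um is None:
        allv = np.vstack(truth.polygons)
        roi_size_um = (float(allv[:, 0].max()) + 2.0, float(allv[:, 1].max()) + 2.0)
    width = max(int(round(roi_size_um[0] / pixel_size)), 1)
    height = max(int(round(roi_size_um[1] / pixel_size)), 1)

    xs = cells["x_um"].to_numpy() / pixel_size
    ys = cells["y_um"].to_numpy() / pixel_size

    dna = np.zeros((height, width), dtype=float)
    areas = np.array(
        [_shoelace_area(p) for p in truth.polygons]
    )
    for i in range(len(cells)):
        sigma_px = math.sqrt(areas[i] / math.pi) / 2.0 / pixel_size
        sigma_px = max(sigma_px, 0.5)
        amp = areas[i]
        half = int(math.ceil(4 * sigma_px))
        cx, cy = xs[i], ys[i]
        r0, r1 = max(int(cy) - half, 0), min(int(cy) + half + 1, height)
        c0, c1 = max(int(cx) - half, 0), min(int(cx) + half + 1, width)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dna[r0:r1, c0:c1] += amp * np.exp(
            -(((xx + 0.5) - cx) ** 2 + ((yy + 0.5) - cy) ** 2) / (2 * sigma_px**2)
        )

    channels: dict[str, np.ndarray] = {"DNA": dna}
    masks: list[tuple[np.ndarray, np.ndarray]] = []
    for poly in truth.polygons:
        rr, cc = draw_polygon(poly[:, 1] / pixel_size, poly[:, 0] / pixel_size,
                              shape=(height, width))
        masks.append((rr, cc))
    for marker in MARKER_PANEL:
        if marker not in cells.columns:
            continue
        chan = np.zeros((height, width), dtype=float)
        vals = cells[marker].to_numpy()
        for i, (rr, cc) in enumerate(masks):
            chan[rr, cc] = vals[i]
        if noise_sd > 0:
            chan += rng.normal(0, noise_sd, size=chan.shape)
        channels[marker] = np.clip(chan, 0, None)
    return ImageGrid(channels=channels, pixel_size=pixel_size)


def _shoelace_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
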