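"""Composition, Z-score and rank-sum statistics over phenotyped ROIs."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .phenotype import OTHER_LABEL, default_schema, detect_population

__all__ = [
    "CompositionTable",
    "ZScoreMatrix",
    "TestResult",
    "roi_composition",
    "zscore_matrix",
    "rank_sum_test",
    "detection_rate",
    "group_compare",
]

_EXACT_MAX_MIN_N = 10


@dataclass
class CompositionTable:
    """Per-ROI population fractions (rows = ROI, columns = populations
    including "other") plus ROI → case → group metadata."""

    fractions: pd.DataFrame
    counts: pd.DataFrame
    meta: pd.DataFrame  # index roi_id, columns case_id, group

    def __post_init__(self) -> None:
        sums = self.fractions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise DataError("composition rows must sum to 1")


@dataclass
class ZScoreMatrix:
    """Cross-ROI standardized abundances (rows = population, columns =
    ROI) and case-consolidated group means."""

    z: pd.DataFrame
    group_means: pd.DataFrame  # rows = population, columns = group
    meta: pd.DataFrame


@dataclass
class TestResult:
    statistic: float  # rank sum of the first sample
    p: float
    n1: int
    n2: int
    method: str  # "exact" | "normal_tie_corrected"
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1):
            raise DataError(f"p-value out of range: {self.p}")


def roi_composition(
    cells: pd.DataFrame,
    populations: Sequence[str] | None = None,
    roi_ids: Sequence[str] | None = None,
) -> CompositionTable:
    """Per-ROI fraction of each population (including "other")."""
    if "phenotype" not in cells.columns:
        raise DataError("cell table has no 'phenotype' column")
    if "roi_id" not in cells.columns:
        raise DataError("cell table has no 'roi_id' column")
    if populations is None:
        populations = list(default_schema().names) + [OTHER_LABEL]
    observed = set(cells["phenotype"].unique())
    unknown = observed - set(populations)
    if unknown:
        raise DataError(f"phenotype labels outside the population set: {sorted(unknown)}")

    counts = (
        cells.groupby("roi_id", sort=True)["phenotype"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=populations, fill_value=0)
    )
    if roi_ids is not None:
        missing = [r for r in roi_ids if r not in counts.index]
        if missing:
            raise DataError(f"empty ROI(s): {missing}")
        counts = counts.loc[list(roi_ids)]
    fractions = counts.div(counts.sum(axis=1), axis=0)

    meta_cols = [c for c in ("case_id", "group") if c in cells.columns]
    meta = cells.groupby("roi_id", sort=True)[meta_cols].first().reindex(counts.index)
    return CompositionTable(fractions=fractions, counts=counts, meta=meta)


def zscore_matrix(comp: CompositionTable) -> ZScoreMatrix:
    """Standardize each population's per-ROI fractions to mean 0 / SD 1
    across all ROIs pooled, then consolidate case means and group means.

    Zero-variance populations are emitted as all-zero rows with a warning.
    """
    if len(comp.fractions) < 2:
        raise DataError("zscore_matrix requires at least 2 ROIs")
    x = comp.fractions.T  # rows = population, columns = roi
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=0)
    degenerate = sd <= 0
    if degenerate.any():
        warnings.warn(
            f"zero-variance population row(s) set to 0: {list(x.index[degenerate])}",
            stacklevel=2,
        )
    safe_sd = sd.where(~degenerate, 1.0)
    z = x.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[degenerate] = 0.0

    # case means first, then group means of case values
    meta = comp.meta
    if {"case_id", "group"}.issubset(meta.columns):
        case_group = meta.groupby("case_id")["group"].first()
        case_means = z.T.groupby(meta["case_id"]).mean()  # rows = case
        group_means = case_means.groupby(case_group).mean().T  # rows = population
    else:
        group_means = pd.DataFrame(index=z.index)
    return ZScoreMatrix(z=z, group_means=group_means, meta=meta)


def _exact_rank_sum_p(ranks: np.ndarray, n1: int, alternative: str) -> tuple[float, float]:
    """Exact conditional null by enumerating all C(N, n1) labelings of
    the pooled mid-ranks. Returns (observed statistic, p)."""
    n = len(ranks)
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (ranks.sum() / n)
    eps = 1e-9
    total = 0
    hits = 0
    for idx in combinations(range(n), n1):
        w = float(ranks[list(idx)].sum())
        total += 1
        if alternative == "two-sided":
            hits += abs(w - mu) >= abs(w_obs - mu) - eps
        elif alternative == "less":
            hits += w <= w_obs + eps
        else:
            hits += w >= w_obs - eps
    return w_obs, hits / total


def rank_sum_test(
    x: Iterable[float], y: Iterable[float], alternative: str = "two-sided"
) -> TestResult:
    """Wilcoxon rank-sum (Mann–Whitney) test with mid-ranks for ties.

    Exact by enumeration of all group labelings whenever
    ``min(n1, n2) <= 10``; otherwise a tie-corrected normal
    approximation (with continuity correction).
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ConfigError(f"unknown alternative {alternative!r}")
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise DataError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:n1].sum())
    if np.ptp(pooled) == 0:
        return TestResult(w_obs, 1.0, n1, n2, "exact", alternative)
    if min(n1, n2) <= _EXACT_MAX_MIN_N and math.comb(n1 + n2, n1) <= 2_000_000:
        w_obs, p = _exact_rank_sum_p(ranks, n1, alternative)
        return TestResult(w_obs, min(p, 1.0), n1, n2, "exact", alternative)
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return TestResult(w_obs, float(res.pvalue), n1, n2, "normal_tie_corrected", alternative)


def detection_rate(
    cases: Sequence[tuple[str, pd.DataFrame]],
    population: str,
    floor_fraction: float = 0.001,
    floor_count: int = 20,
) -> float:
    """Percentage of cases in which the population is detected, rounded
    to one decimal (e.g. 7 of 8 → 87.5)."""
    if len(cases) == 0:
        raise DataError("at least one case required")
    detected = sum(
        detect_population(tbl, population, floor_fraction, floor_count)
        for _, tbl in cases
    )
    return round(100.0 * detected / len(cases), 1)


def group_compare(
    comp: CompositionTable,
    population: str,
    group_a: str,
    group_b: str,
    alternative: str = "two-sided",
) -> TestResult:
    """Rank-sum test on a population's per-ROI fractions between two groups."""
    if population not in comp.fractions.columns:
        raise ConfigError(f"unknown population {population!r}")
    if "group" not in comp.meta.columns:
        raise DataError("composition metadata lacks a 'group' column")
    groups = comp.meta["group"]
    for g in (group_a, group_b):
        if g not in set(groups):
            raise ConfigError(f"unknown group {g!r}")
    a = comp.fractions.loc[groups == group_a, population].to_numpy()
    b = comp.fractions.loc[groups == group_b, population].to_numpy()
    return rank_sum_test(a, b, alternative=alternative)
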