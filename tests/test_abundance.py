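import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spatialplex.abundance import (
    CompositionTable,
    detection_rate,
    group_compare,
    rank_sum_test,
    roi_composition,
    zscore_matrix,
)
from spatialplex.errors import ConfigError, DataError
from spatialplex.phenotype import OTHER_LABEL


def make_cells(roi_labels, case=None, group=None):
    """roi_labels: dict roi -> list of phenotype labels."""
    rows = []
    cid = 0
    for roi, labels in roi_labels.items():
        for lab in labels:
            rows.append(
                {
                    "cell_id": cid,
                    "roi_id": roi,
                    "case_id": (case or {}).get(roi, f"case_{roi}"),
                    "group": (group or {}).get(roi, "g"),
                    "phenotype": lab,
                }
            )
            cid += 1
    return pd.DataFrame(rows)


class TestComposition:
    def test_simple_fraction(self):
        cells = make_cells({"r1": ["Macrophage"] * 4 + [OTHER_LABEL] * 6})
        comp = roi_composition(cells)
        assert comp.fractions.loc["r1", "Macrophage"] == pytest.approx(0.4)

    def test_rows_sum_to_one(self):
        cells = make_cells(
            {"r1": ["Macrophage", "TFH", OTHER_LABEL], "r2": ["DPT"] * 5}
        )
        comp = roi_composition(cells)
        assert np.allclose(comp.fractions.sum(axis=1), 1.0, atol=1e-9)

    def test_pooled_fraction_is_weighted_mean(self):
        labels1 = ["Macrophage"] * 3 + [OTHER_LABEL] * 7
        labels2 = ["Macrophage"] * 8 + [OTHER_LABEL] * 12
        cells = make_cells({"r1": labels1, "r2": labels2})
        comp = roi_composition(cells)
        pooled = (
            cells["phenotype"].eq("Macrophage").sum() / len(cells)
        )
        weights = comp.counts.sum(axis=1)
        weighted = (comp.fractions["Macrophage"] * weights).sum() / weights.sum()
        assert pooled == pytest.approx(weighted)

    def test_empty_roi_rejected_by_name(self):
        cells = make_cells({"r1": ["DPT"] * 3})
        with pytest.raises(DataError, match="r9"):
            roi_composition(cells, roi_ids=["r1", "r9"])

    def test_missing_phenotype_rejected(self):
        with pytest.raises(DataError):
            roi_composition(pd.DataFrame({"roi_id": ["r1"]}))


class TestZScores:
    def _comp(self, values, populations=("Macrophage",)):
        n_roi = len(values)
        fractions = pd.DataFrame(
            {p: values for p in populations},
            index=[f"r{i}" for i in range(n_roi)],
        )
        fractions[OTHER_LABEL] = 1.0 - fractions.sum(axis=1)
        counts = (fractions * 100).astype(int)
        meta = pd.DataFrame(
            {
                "case_id": [f"c{i // 2}" for i in range(n_roi)],
                "group": ["gA" if i < n_roi / 2 else "gB" for i in range(n_roi)],
            },
            index=fractions.index,
        )
        return CompositionTable(fractions=fractions, counts=counts, meta=meta)

    def test_closed_form_three_rois(self):
        comp = self._comp([0.1, 0.2, 0.3])
        z = zscore_matrix(comp).z
        expected = (np.array([0.1, 0.2, 0.3]) - 0.2) / np.sqrt(2 / 3) / 0.1
        np.testing.assert_allclose(z.loc["Macrophage"].to_numpy(), expected, atol=1e-9)
        assert z.loc["Macrophage"].iloc[0] == pytest.approx(-1.2247, abs=1e-4)

    def test_constant_row_all_zeros_with_warning(self):
        comp = self._comp([0.2, 0.2, 0.2, 0.2])
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore_matrix(comp).z
        assert (z.loc["Macrophage"] == 0).all()

    def test_rows_mean_zero_sd_one(self, rng):
        comp = self._comp(list(rng.uniform(0.05, 0.4, size=8)))
        z = zscore_matrix(comp).z
        row = z.loc["Macrophage"]
        assert abs(row.mean()) < 1e-9
        assert abs(row.std(ddof=0) - 1.0) < 1e-9

    def test_group_means_consolidate_cases_first(self):
        # 2 cases per group, 2 ROIs per case; case means first, then group
        comp = self._comp([0.1, 0.3, 0.2, 0.2, 0.25, 0.35, 0.15, 0.45])
        zm = zscore_matrix(comp)
        z = zm.z.loc["Macrophage"]
        case_means = z.groupby(comp.meta["case_id"]).mean()
        group_of_case = comp.meta.groupby("case_id")["group"].first()
        expected = case_means.groupby(group_of_case).mean()
        for g in ("gA", "gB"):
            assert zm.group_means.loc["Macrophage", g] == pytest.approx(expected[g])

    def test_fewer_than_two_rois_rejected(self):
        comp = self._comp([0.1, 0.2])
        comp.fractions = comp.fractions.iloc[:1]
        with pytest.raises(DataError):
            zscore_matrix(comp)


class TestRankSum:
    def test_small_example_exact(self):
        res = rank_sum_test([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p == pytest.approx(2 / 6)

    def test_identical_samples_p_one(self):
        res = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert res.p == 1.0

    def test_all_tied_p_one(self):
        assert rank_sum_test([5, 5], [5, 5, 5]).p == 1.0

    def test_exact_matches_product_enumeration_oracle(self, rng):
        for n1, n2, tied in [(2, 3, False), (3, 3, True), (4, 2, True), (2, 5, False)]:
            x = rng.integers(0, 4, n1).astype(float) if tied else rng.normal(size=n1)
            y = rng.integers(0, 4, n2).astype(float) if tied else rng.normal(size=n2)
            res = rank_sum_test(x, y)
            # oracle: enumerate binary label vectors via itertools.product
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            n = n1 + n2
            mu = n1 * (n + 1) / 2
            w_obs = ranks[:n1].sum()
            hits = total = 0
            for lab in itertools.product([0, 1], repeat=n):
                if sum(lab) != n1:
                    continue
                total += 1
                w = sum(r for r, l in zip(ranks, lab) if l)
                if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
                    hits += 1
            assert res.p == pytest.approx(hits / total)

    def test_exact_close_to_normal_approximation(self, rng):
        diffs = []
        for _ in range(20):
            x = rng.normal(size=10)
            y = rng.normal(0.5, size=10)
            exact = rank_sum_test(x, y).p
            approx = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            diffs.append(abs(exact - approx))
        assert max(diffs) < 0.02

    def test_one_sided_alternatives(self):
        low = rank_sum_test([1, 2], [3, 4], alternative="less").p
        high = rank_sum_test([1, 2], [3, 4], alternative="greater").p
        assert low < high

    def test_large_samples_use_normal(self, rng):
        res = rank_sum_test(rng.normal(size=30), rng.normal(size=30))
        assert res.method == "normal_tie_corrected"
        assert 0 <= res.p <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError):
            rank_sum_test([], [1.0])


class TestDetectionRate:
    def _cases(self, outcomes):
        cases = []
        for i, det in enumerate(outcomes):
            n_dpt = 25 if det else 0
            labels = ["DPT"] * n_dpt + [OTHER_LABEL] * (20_000 - n_dpt)
            cases.append((f"case{i}", pd.DataFrame({"phenotype": labels})))
        return cases

    def test_seven_of_eight(self):
        assert detection_rate(self._cases([True] * 7 + [False]), "DPT") == 87.5

    def test_one_of_four(self):
        assert detection_rate(self._cases([True, False, False, False]), "DPT") == 25.0

    def test_zero_of_n(self):
        assert detection_rate(self._cases([False] * 5), "DPT") == 0.0

    def test_order_invariance(self, rng):
        outcomes = [True, False, True, True, False]
        cases = self._cases(outcomes)
        rates = set()
        for _ in range(5):
            rng.shuffle(cases)
            rates.add(detection_rate(cases, "DPT"))
        assert len(rates) == 1

    def test_roi_partition_invariance(self):
        # splitting a case's cells across ROIs does not change pooled detection
        labels = ["DPT"] * 25 + [OTHER_LABEL] * (20_000 - 25)
        whole = pd.DataFrame({"phenotype": labels, "roi_id": "r1"})
        halves = whole.copy()
        halves.loc[halves.index[: len(halves) // 2], "roi_id"] = "r2"
        r1 = detection_rate([("c", whole)], "DPT")
        r2 = detection_rate([("c", halves)], "DPT")
        assert r1 == r2 == 100.0

    def test_no_cases_rejected(self):
        with pytest.raises(DataError):
            detection_rate([], "DPT")


class TestGroupCompare:
    def _comp(self):
        cells = make_cells(
            {
                "r1": ["Macrophage"] * 2 + [OTHER_LABEL] * 8,
                "r2": ["Macrophage"] * 3 + [OTHER_LABEL] * 7,
                "r3": ["Macrophage"] * 6 + [OTHER_LABEL] * 4,
                "r4": ["Macrophage"] * 7 + [OTHER_LABEL] * 3,
            },
            group={"r1": "gA", "r2": "gA", "r3": "gB", "r4": "gB"},
        )
        return roi_composition(cells)

    def test_symmetry(self):
        comp = self._comp()
        a = group_compare(comp, "Macrophage", "gA", "gB")
        b = group_compare(comp, "Macrophage", "gB", "gA")
        assert a.p == pytest.approx(b.p)

    def test_identical_groups_p_one(self):
        cells = make_cells(
            {"r1": ["DPT"] * 5, "r2": ["DPT"] * 5},
            group={"r1": "gA", "r2": "gB"},
        )
        comp = roi_composition(cells)
        assert group_compare(comp, "DPT", "gA", "gB").p == 1.0

    def test_unknown_group_rejected(self):
        with pytest.raises(ConfigError, match="unknown group"):
            group_compare(self._comp(), "Macrophage", "gA", "gZ")

    def test_unknown_population_rejected(self):
        with pytest.raises(ConfigError):
            group_compare(self._comp(), "NK", "gA", "gB")
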