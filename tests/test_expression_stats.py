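"""CPM, percentile summaries, high-expressor ANOVA and the dot-plot matrix."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats

from troplip import expression_stats as es
from troplip.errors import DataError
from troplip.io_formats import CellDataset


def _dataset(counts, clusters=None, conditions=None):
    counts = np.asarray(counts)
    g, n = counts.shape
    meta = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "sample_id": ["s1"] * n,
        "cluster": clusters or ["SCT"] * n,
        "condition": conditions or ["Ctrl"] * n,
    })
    return CellDataset(sp.csr_matrix(counts), [f"g{i}" for i in range(g)], meta)


class TestCpm:
    def test_forced_by_definition(self):
        ds = _dataset(np.array([[1], [1], [2]]))
        cpm = es.compute_cpm(ds)
        assert np.allclose(cpm.ravel(), [250_000, 250_000, 500_000])

    def test_equal_counts_give_uniform_cpm(self):
        ds = _dataset(np.full((8, 3), 5))
        assert np.allclose(es.compute_cpm(ds), 1e6 / 8)

    def test_per_cell_sums_conserved(self):
        rng = np.random.default_rng(0)
        ds = _dataset(rng.integers(0, 20, size=(50, 20)) + (np.arange(20) == 0))
        cpm = es.compute_cpm(ds)
        assert np.allclose(cpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_total_cell_rejected_by_id(self):
        ds = _dataset(np.array([[1, 0], [2, 0]]))
        with pytest.raises(DataError, match="c1"):
            es.compute_cpm(ds)


class TestSummaries:
    def test_constant_gene_median_equals_p95(self):
        ds = _dataset(np.array([[2, 2, 2], [2, 2, 2]]))
        cpm = es.compute_cpm(ds)
        summ = es.summarize_cluster_groups(ds, cpm).table
        assert np.allclose(summ["median_cpm"], summ["p95_cpm"])

    def test_p95_linear_interpolation_convention(self):
        # CPM values 0..99 in one stratum -> p95 = 94.05
        counts = np.zeros((2, 100), dtype=int)
        counts[0] = np.arange(100)
        counts[1] = 1000 - np.arange(100)   # keeps totals constant at 1000
        ds = _dataset(counts)
        cpm = es.compute_cpm(ds)
        summ = es.summarize_cluster_groups(ds, cpm).table
        row = summ[(summ["gene"] == "g0")].iloc[0]
        assert row["p95_cpm"] == pytest.approx(94.05 / 1000 * 1e6)

    def test_detect_frac_counts_nonzero_cells(self):
        counts = np.zeros((1, 20), dtype=int)
        counts[0, :7] = 3
        ds = _dataset(np.vstack([counts, np.ones((1, 20), dtype=int)]))
        cpm = es.compute_cpm(ds)
        summ = es.summarize_cluster_groups(ds, cpm).table
        assert summ[summ["gene"] == "g0"]["detect_frac"].iloc[0] == 0.35

    def test_p95_at_least_median(self, spiked_sc):
        _, cells, _, _ = spiked_sc
        cpm = es.compute_cpm(cells)
        summ = es.summarize_cluster_groups(cells, cpm).table
        assert (summ["p95_cpm"] >= summ["median_cpm"] - 1e-9).all()
        assert (summ["n_cells"] == summ.groupby(
            ["cluster", "condition"]
        )["n_cells"].transform("first")).all()


class TestHighExpressors:
    def _graded(self):
        counts = np.zeros((2, 100), dtype=int)
        counts[0] = np.arange(100)
        counts[1] = 1000 - np.arange(100)
        conds = ["Ctrl"] * 50 + ["PE"] * 50
        return _dataset(counts, conditions=conds)

    def test_strictly_above_pooled_p95(self):
        ds = self._graded()
        cpm = es.compute_cpm(ds)
        threshold, subset = es.select_high_expressors(ds, cpm, "g0", "SCT")
        assert threshold == pytest.approx(94.05 / 1000 * 1e6)
        assert len(subset) == 5                      # values 95..99
        assert (subset["cpm"] > threshold).all()

    def test_constant_gene_selects_nothing(self):
        ds = _dataset(np.array([[2, 2, 2, 2], [1, 1, 1, 1]]))
        cpm = es.compute_cpm(ds)
        _, subset = es.select_high_expressors(ds, cpm, "g0", "SCT")
        assert subset.empty

    def test_threshold_invariant_to_condition_labels(self):
        ds = self._graded()
        cpm = es.compute_cpm(ds)
        t1, s1 = es.select_high_expressors(ds, cpm, "g0", "SCT")
        shuffled = ds.cell_meta.copy()
        rng = np.random.default_rng(5)
        shuffled["condition"] = rng.permutation(
            shuffled["condition"].to_numpy()
        )
        ds2 = CellDataset(ds.counts, ds.gene_ids, shuffled)
        t2, s2 = es.select_high_expressors(ds2, cpm, "g0", "SCT")
        assert t1 == t2
        assert list(s1["cell_id"]) == list(s2["cell_id"])


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        f, p = es.anova_high_expressors(
            np.array([1.0, 2, 3, 1, 2, 3]),
            np.array(["a", "a", "a", "b", "b", "b"]),
        )
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_f(self):
        # [1,2,3] vs [4,5,6]: between SS = 13.5, within MS = 1 -> F = 13.5
        f, p = es.anova_high_expressors(
            np.array([1.0, 2, 3, 4, 5, 6]),
            np.array(["a", "a", "a", "b", "b", "b"]),
        )
        grand = 3.5
        ss_between = 3 * ((2 - grand) ** 2 + (5 - grand) ** 2)
        ms_within = (2 + 2) / 4
        assert f == pytest.approx(ss_between / ms_within)
        assert p == pytest.approx(scipy.stats.f.sf(f, 1, 4))

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
        f, p_f = es.anova_high_expressors(
            np.concatenate([x, y]),
            np.array(["a"] * 12 + ["b"] * 9),
        )
        t, p_t = scipy.stats.ttest_ind(x, y)
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_untestable_stratum_flagged_not_raised(self):
        f, p = es.anova_high_expressors(np.array([1.0, 2]), np.array(["a", "a"]))
        assert np.isnan(f) and np.isnan(p)


class TestDotplot:
    def _summary(self, ctrl_p95, case_p95):
        rows = []
        for cond, p95 in (("Ctrl", ctrl_p95), ("PE", case_p95)):
            rows.append({
                "gene": "LDLR_LIKE", "cluster": "SCT", "condition": cond,
                "n_cells": 10, "detect_frac": 1.0, "median_cpm": 1.0,
                "p95_cpm": p95,
            })
        return es.ClusterGroupSummary(pd.DataFrame(rows))

    def test_equal_p95_gives_zero(self):
        dot = es.dotplot_log2fc(self._summary(100.0, 100.0), "PE", "Ctrl")
        assert dot.log2fc.loc["LDLR_LIKE", "SCT"] == 0.0

    def test_printed_percentile_pair(self):
        # control 608.6 vs case 462.1 -> log2(462.1/608.6) ~ -0.397
        dot = es.dotplot_log2fc(self._summary(608.6, 462.1), "PE", "Ctrl")
        assert dot.log2fc.loc["LDLR_LIKE", "SCT"] == pytest.approx(
            np.log2(462.1 / 608.6)
        )
        assert dot.log2fc.loc["LDLR_LIKE", "SCT"] == pytest.approx(-0.397,
                                                                   abs=5e-4)
        assert dot.control_p95.loc["LDLR_LIKE", "SCT"] == 608.6

    def test_doubling_gives_plus_one(self):
        dot = es.dotplot_log2fc(self._summary(50.0, 100.0), "PE", "Ctrl")
        assert dot.log2fc.loc["LDLR_LIKE", "SCT"] == 1.0

    def test_zero_p95_flagged_missing(self):
        dot = es.dotplot_log2fc(self._summary(0.0, 100.0), "PE", "Ctrl")
        assert np.isnan(dot.log2fc.loc["LDLR_LIKE", "SCT"])

    def test_spiked_set_entries_negative(self, spiked_sc):
        _, cells, truth, _ = spiked_sc
        cpm = es.compute_cpm(cells)
        summ = es.summarize_cluster_groups(cells, cpm)
        dot = es.dotplot_log2fc(summ, "PE", "Ctrl")
        vals = dot.log2fc.loc[truth.set_members["CHOL_BIOSYNTH"], "SCT"]
        assert (vals.dropna() < 0).mean() >= 0.95
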