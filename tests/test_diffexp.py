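"""Differential expression: MWU, pseudobulk NB-Wald, BH, TMM, FPKM filter."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from troplip import diffexp
from troplip.errors import DataError
from troplip.io_formats import BulkDataset, CellDataset


def _bh_quadratic(p):
    """Reference BH: literal step-up definition, O(n^2)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    out = np.empty(m)
    for i, pi in enumerate(p):
        rank = np.sum(p <= pi)
        # adjusted p_i = min over all p_j >= p_i of p_j * m / rank(p_j)
        candidates = [
            pj * m / np.sum(p <= pj) for pj in p if pj >= pi
        ]
        out[i] = min(1.0, min(candidates))
    return out


class TestBenjaminiHochberg:
    def test_hand_step_up(self):
        assert np.allclose(
            diffexp.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
            [0.04, 0.04, 0.04, 0.04],
        )

    def test_single_and_degenerate(self):
        assert diffexp.benjamini_hochberg([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(diffexp.benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            diffexp.benjamini_hochberg([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_quadratic_reference(self, p):
        got = diffexp.benjamini_hochberg(p)
        ref = _bh_quadratic(p)
        assert np.allclose(got, ref)
        assert (got >= np.asarray(p) - 1e-12).all()
        assert (got <= 1.0).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 200)
        _, ref, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(diffexp.benjamini_hochberg(p), ref)


def _mwu_dataset(case_vals, ctrl_vals):
    vals = np.array([case_vals + ctrl_vals], dtype=int)
    ds = CellDataset(
        sp.csr_matrix(vals),
        ["g0"],
        pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(vals.shape[1])],
            "sample_id": "s1",
            "cluster": "SCT",
            "condition": ["PE"] * len(case_vals) + ["Ctrl"] * len(ctrl_vals),
        }),
    )
    return ds, vals.astype(float)


class TestMannWhitney:
    def test_exact_enumeration_small_groups(self):
        # [1,2,3] vs [4,5,6]: U = 0, exact two-sided p = 2/20 = 0.1
        ds, cpm = _mwu_dataset([1, 2, 3], [4, 5, 6])
        res = diffexp.mannwhitney_de(ds, cpm, "SCT", "PE", "Ctrl")
        assert res.loc["g0", "stat"] == 0
        assert res.loc["g0", "p"] == pytest.approx(0.1)

    def test_identical_groups_null(self):
        ds, cpm = _mwu_dataset([5, 6, 7], [5, 6, 7])
        res = diffexp.mannwhitney_de(ds, cpm, "SCT", "PE", "Ctrl")
        assert res.loc["g0", "p"] == pytest.approx(1.0)
        assert res.loc["g0", "log2fc"] == pytest.approx(0.0)

    def test_all_tied_degenerate(self):
        ds, cpm = _mwu_dataset([3, 3, 3], [3, 3, 3])
        res = diffexp.mannwhitney_de(ds, cpm, "SCT", "PE", "Ctrl")
        assert res.loc["g0", "p"] == 1.0

    def test_label_swap_negates_log2fc_keeps_p(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 30, size=(20, 60)) + 1
        meta = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(60)],
            "sample_id": "s1", "cluster": "SCT",
            "condition": ["PE"] * 30 + ["Ctrl"] * 30,
        })
        ds = CellDataset(sp.csr_matrix(counts), [f"g{i}" for i in range(20)],
                         meta)
        cpm = counts / counts.sum(0) * 1e6
        fwd = diffexp.mannwhitney_de(ds, cpm, "SCT", "PE", "Ctrl")
        rev = diffexp.mannwhitney_de(ds, cpm, "SCT", "Ctrl", "PE")
        assert np.allclose(fwd["p"], rev["p"])
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])


class TestPseudobulk:
    def test_single_group_equals_row_sums(self, toy_cells):
        meta = toy_cells.cell_meta.copy()
        meta["sample_id"] = "s1"
        ds = CellDataset(toy_cells.counts, toy_cells.gene_ids, meta)
        pb = diffexp.aggregate_pseudobulk(ds)
        assert pb.counts.shape[1] == 1
        assert np.array_equal(
            pb.counts.iloc[:, 0].to_numpy(),
            np.asarray(ds.counts.sum(axis=1)).ravel(),
        )

    def test_split_and_merge_additivity(self, spiked_sc):
        _, cells, _, _ = spiked_sc
        pb = diffexp.aggregate_pseudobulk(cells)
        # re-merging pseudo-samples per (sample, cluster) recovers totals
        merged = pb.counts.T.groupby(
            pb.col_meta.set_index("column")["cluster"]
        ).sum().T
        by_cluster = {
            cl: np.asarray(
                cells.counts[:, (cells.cell_meta["cluster"] == cl).to_numpy()]
                .sum(axis=1)
            ).ravel()
            for cl in merged.columns
        }
        for cl in merged.columns:
            assert np.array_equal(merged[cl].to_numpy(), by_cluster[cl])

    def test_total_count_conservation(self, spiked_sc):
        _, cells, _, _ = spiked_sc
        pb = diffexp.aggregate_pseudobulk(cells)
        assert pb.counts.to_numpy().sum() == cells.counts.sum()


class TestSizeFactors:
    def test_identical_samples(self):
        counts = pd.DataFrame({"a": [5, 10, 3], "b": [5, 10, 3]})
        assert np.allclose(diffexp.estimate_size_factors(counts), 1.0)

    def test_doubled_library(self):
        counts = pd.DataFrame({"a": [5, 10, 3], "b": [10, 20, 6]})
        f = diffexp.estimate_size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 100, (50, 4)))
        f1 = diffexp.estimate_size_factors(counts)
        f2 = diffexp.estimate_size_factors(counts.iloc[::-1])
        assert np.allclose(f1, f2)

    def test_requires_all_positive_gene(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(DataError, match="filter"):
            diffexp.estimate_size_factors(counts)


class TestNbWald:
    def test_label_swap_negates_statistics(self, spiked_bulk):
        _, bulk, _, _, _ = spiked_bulk
        cond = bulk.sample_meta.set_index("sample_id")["condition"]
        fwd, _ = diffexp.fit_nb_wald_de(bulk.counts, cond, "PE", "Ctrl")
        rev, _ = diffexp.fit_nb_wald_de(bulk.counts, cond, "Ctrl", "PE")
        tested = fwd["stat"].notna()
        assert np.allclose(fwd.loc[tested, "log2fc"],
                           -rev.loc[tested, "log2fc"], atol=1e-6)
        assert np.allclose(fwd.loc[tested, "stat"],
                           -rev.loc[tested, "stat"], atol=1e-6)

    def test_matches_statsmodels_glm(self, spiked_bulk):
        import statsmodels.api as sm

        _, bulk, _, _, _ = spiked_bulk
        cond = bulk.sample_meta.set_index("sample_id")["condition"]
        de, _ = diffexp.fit_nb_wald_de(bulk.counts, cond, "PE", "Ctrl")
        sf = diffexp.estimate_size_factors(bulk.counts)
        x = sm.add_constant((cond == "PE").astype(float).to_numpy())
        offset = np.log(sf.to_numpy())
        rng = np.random.default_rng(0)
        genes = rng.choice(de.index[de["stat"].notna()], 15, replace=False)
        for gene in genes:
            phi = de.loc[gene, "dispersion"]
            fit = sm.GLM(
                bulk.counts.loc[gene].to_numpy(), x,
                family=sm.families.NegativeBinomial(alpha=phi),
                offset=offset,
            ).fit()
            assert de.loc[gene, "log2fc"] == pytest.approx(
                fit.params[1] / np.log(2), abs=1e-4
            )
            assert de.loc[gene, "stat"] == pytest.approx(
                fit.params[1] / fit.bse[1], rel=1e-3
            )

    def test_ranked_list_is_sorted_permutation(self, spiked_bulk):
        _, bulk, _, _, _ = spiked_bulk
        cond = bulk.sample_meta.set_index("sample_id")["condition"]
        de, ranked = diffexp.fit_nb_wald_de(bulk.counts, cond, "PE", "Ctrl")
        tested = set(de.index[de["stat"].notna()])
        assert set(ranked["gene"]) == tested
        scores = ranked["score"].to_numpy()
        assert (np.diff(scores) <= 1e-12).all()

    def test_spiked_genes_rank_at_extremes(self, spiked_bulk):
        _, bulk, truth, _, _ = spiked_bulk
        cond = bulk.sample_meta.set_index("sample_id")["condition"]
        de, ranked = diffexp.fit_nb_wald_de(bulk.counts, cond, "PE", "Ctrl")
        up = truth.set_members["UP_SET"]
        top = set(ranked["gene"].head(len(up) * 2))
        assert len(set(up) & top) >= len(up) * 0.8


class TestTmm:
    def test_identical_libraries(self):
        counts = pd.DataFrame(np.tile([[10], [20], [5]], (1, 3)),
                              columns=list("abc"))
        assert np.allclose(diffexp.tmm_factors(counts), 1.0)

    def test_pure_depth_change_absorbed(self):
        rng = np.random.default_rng(3)
        base = rng.integers(10, 1000, 200)
        counts = pd.DataFrame({"a": base, "b": base * 2, "c": base})
        f = diffexp.tmm_factors(counts)
        assert np.allclose(f, 1.0, atol=1e-9)

    def test_geometric_mean_one(self, spiked_bulk):
        _, bulk, _, _, _ = spiked_bulk
        f = diffexp.tmm_factors(bulk.counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)
        assert (f > 0).all()


class TestFpkmAndFilter:
    def test_unit_case(self):
        counts = pd.DataFrame({"s1": [10, 999_990], "s2": [10, 999_990]},
                              index=["g1", "g2"])
        samples = pd.DataFrame({"sample_id": ["s1", "s2"],
                                "condition": ["a", "b"]})
        lengths = pd.Series([1000.0, 1000.0], index=["g1", "g2"])
        ds = BulkDataset(counts, samples, lengths)
        ones = pd.Series([1.0, 1.0], index=["s1", "s2"])
        fpkm = diffexp.compute_fpkm(ds, factors=ones)
        assert fpkm.loc["g1", "s1"] == pytest.approx(10.0)

    def test_bottom_quartile_in_one_group_retained(self):
        # gene "low_a" is bottom-quartile in group a only -> retained
        fpkm = pd.DataFrame({
            "a1": [0.1, 10, 20, 30, 40, 50, 60, 70],
            "a2": [0.1, 10, 20, 30, 40, 50, 60, 70],
            "b1": [99, 10, 20, 30, 0.1, 50, 60, 70],
            "b2": [99, 10, 20, 30, 0.1, 50, 60, 70],
        }, index=[f"g{i}" for i in range(8)])
        groups = ["a", "a", "b", "b"]
        kept = diffexp.filter_low_expressed(fpkm, groups)
        assert "g0" in kept and "g4" in kept

    def test_retained_fraction_at_least_three_quarters(self):
        rng = np.random.default_rng(9)
        fpkm = pd.DataFrame(rng.gamma(2, 10, (200, 6)))
        groups = ["a"] * 3 + ["b"] * 3
        kept = diffexp.filter_low_expressed(fpkm, groups)
        assert len(kept) >= 150

    def test_any_group_flag_is_stricter(self):
        rng = np.random.default_rng(10)
        fpkm = pd.DataFrame(rng.gamma(2, 10, (100, 4)))
        groups = ["a", "a", "b", "b"]
        every = diffexp.filter_low_expressed(fpkm, groups)
        any_ = diffexp.filter_low_expressed(fpkm, groups,
                                            require_all_groups=False)
        assert set(any_) <= set(every)
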