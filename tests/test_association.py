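"""Proliferation classes, fold-change bands, per-row tests, CGC enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circlandscape.association import (
    cgc_enrichment,
    classify_fast_slow,
    contrast_groups,
    differential_tests,
    group_fold_change,
    proliferation_correlation,
)
from circlandscape.formats import CountMatrix, ValidationError


def meta_with_folds(folds):
    lines = [f"CL{i:02d}" for i in range(len(folds))]
    return pd.DataFrame(
        {
            "sample_id": [f"{c}_r1" for c in lines],
            "cell_line": lines,
            "proliferation_fold_72h": folds,
        }
    ).set_index("sample_id", drop=False)


def cm(values, index, columns):
    return CountMatrix(
        pd.DataFrame(values, index=index, columns=columns), "gene", "per_million"
    )


class TestProliferationClasses:
    def test_inclusive_boundaries(self):
        classes = classify_fast_slow(meta_with_folds([5.0, 3.0, 4.0]))
        assert classes.labels.tolist() == ["fast", "slow", "intermediate"]

    def test_planted_class_sizes_recovered(self, small_sim):
        classes = classify_fast_slow(small_sim.meta)
        assert (len(classes.fast), len(classes.slow)) == (11, 21)

    def test_invalid_cuts(self):
        with pytest.raises(ValidationError):
            classify_fast_slow(meta_with_folds([4.0]), fast_cut=3.0, slow_cut=5.0)


class TestProliferationCorrelation:
    def test_proportional_feature_perfect(self):
        meta = meta_with_folds([1.0, 2.0, 3.0, 4.0])
        lines = meta["cell_line"].tolist()
        m = cm([[2.0, 4.0, 6.0, 8.0], [1.0, 1.0, 1.0, 1.0]], ["up", "flat"], lines)
        corr, n_excl = proliferation_correlation(m, meta)
        assert corr["up"] == pytest.approx(1.0)
        assert "flat" not in corr.index and n_excl == 1

    def test_agrees_with_textbook(self):
        rng = np.random.default_rng(0)
        meta = meta_with_folds(rng.uniform(1, 8, 20))
        lines = meta["cell_line"].tolist()
        vals = rng.gamma(2, 1, size=(30, 20))
        m = cm(vals, [f"g{i}" for i in range(30)], lines)
        corr, _ = proliferation_correlation(m, meta)
        folds = meta.set_index("cell_line")["proliferation_fold_72h"].loc[lines]
        for i in range(30):
            assert corr[f"g{i}"] == pytest.approx(
                np.corrcoef(vals[i], folds)[0, 1], abs=1e-12
            )

    def test_planted_effects_rank_to_top(self):
        rng = np.random.default_rng(1)
        n_feat, n_lines = 2000, 40
        meta = meta_with_folds(rng.uniform(1, 8, n_lines))
        lines = meta["cell_line"].tolist()
        folds = meta["proliferation_fold_72h"].to_numpy()
        z = (folds - folds.mean()) / folds.std()
        vals = rng.lognormal(0, 0.5, size=(n_feat, n_lines))
        beta = 0.8
        vals[:20] *= np.exp(beta * z)[None, :]
        m = cm(vals, [f"g{i:04d}" for i in range(n_feat)], lines)
        corr, _ = proliferation_correlation(m, meta)
        top = set(corr.sort_values(ascending=False).index[:20])
        recall = len(top & {f"g{i:04d}" for i in range(20)}) / 20
        assert recall >= 0.9


class TestFoldChangeClasses:
    def test_band_boundary_and_exclusives(self):
        m = cm(
            [[2.0, 2.0, 1.0, 1.0],  # FC 2.0 -> band (inclusive)
             [3.0, 3.0, 0.0, 0.0],  # only_fast
             [0.0, 0.0, 1.0, 1.0],  # only_slow
             [9.0, 9.0, 1.0, 1.0],  # other
             [0.0, 0.0, 0.0, 0.0]],  # dropped
            ["band", "of", "os", "other", "zero"],
            ["f1", "f2", "s1", "s2"],
        )
        out = group_fold_change(m, ["f1", "f2"], ["s1", "s2"])
        assert out.loc["band", "fc_class"] == "band"
        assert out.loc["of", "fc_class"] == "only_fast"
        assert out.loc["os", "fc_class"] == "only_slow"
        assert out.loc["other", "fc_class"] == "other"
        assert "zero" not in out.index

    def test_classes_partition_expressed_features(self, small_dataset):
        ds = small_dataset
        cols = list(ds.gene_cell_line.samples)
        half = len(cols) // 2
        out = group_fold_change(ds.gene_cell_line, cols[:half], cols[half:])
        expressed = (ds.gene_cell_line.values[cols].sum(axis=1) > 0).sum()
        assert out["fc_class"].isin(["only_slow", "only_fast", "band", "other"]).all()
        assert len(out) == expressed

    def test_band_fraction_rises_with_occurrence_cut(self):
        # under the null, broadly expressed features concentrate near FC 1
        from circlandscape.quantify import filter_min_cell_lines

        rng = np.random.default_rng(2)
        n, m_lines = 2000, 40
        vals = rng.lognormal(0, 1.0, size=(n, m_lines))
        mask = rng.random((n, m_lines)) < rng.uniform(0.05, 1.0, n)[:, None]
        vals = vals * mask
        mat = cm(vals, [f"g{i}" for i in range(n)], [f"c{k}" for k in range(m_lines)])
        a = [f"c{k}" for k in range(20)]
        b = [f"c{k}" for k in range(20, 40)]
        frac_all = (group_fold_change(mat, a, b)["fc_class"] == "band").mean()
        kept = filter_min_cell_lines(mat, k=20)
        frac_kept = (group_fold_change(kept, a, b)["fc_class"] == "band").mean()
        assert frac_kept > frac_all


class TestDifferentialTests:
    def test_zero_mean_group_excluded(self):
        m = cm(
            [[1.0, 2.0, 0.0, 0.0], [1.0, 2.0, 2.0, 1.0]],
            ["excl", "kept"],
            ["a1", "a2", "b1", "b2"],
        )
        res = differential_tests(m, ["a1", "a2"], ["b1", "b2"])
        assert res.n_excluded == 1
        assert list(res.table.index) == ["kept"]
        assert res.bonferroni_threshold == pytest.approx(0.05)

    def test_matches_scipy_row_by_row(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(0, 0.5, size=(50, 16))
        m = cm(vals, [f"g{i}" for i in range(50)], [f"c{k}" for k in range(16)])
        a, b = [f"c{k}" for k in range(8)], [f"c{k}" for k in range(8, 16)]
        res = differential_tests(m, a, b)
        for i in range(50):
            x, y = vals[i, :8], vals[i, 8:]
            f = x.var(ddof=1) / y.var(ddof=1)
            fp = 2 * min(stats.f.cdf(f, 7, 7), stats.f.sf(f, 7, 7))
            expected = stats.ttest_ind(x, y, equal_var=fp >= 0.05)
            assert res.table["p"].iloc[i] == pytest.approx(expected.pvalue, abs=1e-12)

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(0, 0.5, size=(500, 20))
        m = cm(vals, [f"g{i}" for i in range(500)], [f"c{k}" for k in range(20)])
        res = differential_tests(m, [f"c{k}" for k in range(10)],
                                 [f"c{k}" for k in range(10, 20)])
        assert res.significant_features == []

    def test_group_size_guard(self):
        m = cm([[1.0, 1.0, 1.0]], ["g"], ["a1", "b1", "b2"])
        with pytest.raises(ValidationError):
            differential_tests(m, ["a1"], ["b1", "b2"])


class TestContrastsAndCgc:
    def test_contrast_resolution(self, small_sim):
        meta = small_sim.meta
        a, b, label = contrast_groups(meta, "transformed")
        assert len(a) + len(b) == meta["cell_line"].nunique()
        assert label == "tumor_vs_non_transformed"
        a, b, _ = contrast_groups(meta, "TP53")
        per_line = meta.groupby("cell_line").first()
        assert all(per_line.loc[c, "TP53"] == "mut" for c in a)
        assert all(per_line.loc[c, "TP53"] == "wt" for c in b)

    def test_disjoint_cgc_fraction_zero(self):
        m = cm([[1.0], [2.0]], ["gA", "gB"], ["c1"])
        jg = pd.Series({"j1": "gA", "j2": "gB"})
        with pytest.warns(UserWarning):
            enr = cgc_enrichment(m, jg, {"gZ"})
        assert enr.fraction_genes_cgc == 0.0
        assert enr.fraction_junctions_cgc == 0.0

    def test_all_genes_cgc_symmetric(self):
        m = cm([[1.0], [2.0]], ["gA", "gB"], ["c1"])
        jg = pd.Series({"j1": "gA", "j2": "gB"})
        enr = cgc_enrichment(m, jg, {"gA", "gB"})
        assert enr.fraction_genes_cgc == 1.0
        assert enr.fraction_junctions_cgc == 1.0
        assert np.isnan(enr.fold_change) or enr.fold_change > 0

    def test_planted_fold_recovered(self):
        # designed experiment: a large planted cancer subset with tame
        # dispersion so the fold estimate is tight
        from circlandscape import SimulationConfig, build_dataset, simulate_landscape

        cfg = SimulationConfig(
            seed=9, n_genes=400, n_cell_lines=20, n_fast=4, n_slow=8,
            cgc_fraction=0.25, cgc_multiplier=2.1,
            circ_per_gene_log_sd=0.5, circ_rate_log_sd=0.5, sparsity=0.0,
        )
        sim = simulate_landscape(cfg)
        ds = build_dataset(sim.junctions_by_sample, sim.meta, sim.linear_fpkm)
        enr = cgc_enrichment(
            ds.gene_cell_line, ds.junction_gene, set(sim.truth["cgc_genes"])
        )
        assert 1.7 <= enr.fold_change <= 2.4
        assert enr.p_value < 0.05
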