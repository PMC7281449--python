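"""Normalization, replicate averaging, aggregation and summaries."""

import numpy as np
import pandas as pd
import pytest

from circlandscape.formats import BacksplicedJunction, CountMatrix, ValidationError
from circlandscape.quantify import (
    aggregate_gene_level,
    average_replicates,
    backsplice_sites_per_gene,
    build_backsplice_matrix,
    filter_min_cell_lines,
    merge_junctions,
    normalize_per_million,
    occurrence,
    replicate_concordance,
    top_expressed,
)


def meta_frame(samples, lines, libs):
    return pd.DataFrame(
        {"sample_id": samples, "cell_line": lines, "library_size": libs},
    ).set_index("sample_id", drop=False)


def cm(values: dict, level="backsplice", normalization="raw", index=None):
    df = pd.DataFrame(values, index=index)
    return CountMatrix(df, level, normalization)


class TestNormalization:
    def test_per_million_arithmetic(self):
        m = cm({"s1": [10.0]}, index=["j1"])
        meta = meta_frame(["s1"], ["CL1"], [20_000_000])
        out = normalize_per_million(m, meta)
        assert out.values.loc["j1", "s1"] == 0.5
        assert out.normalization == "per_million"

    def test_all_zero_feature_stays_zero(self):
        m = cm({"s1": [0.0], "s2": [0.0]}, index=["j1"])
        meta = meta_frame(["s1", "s2"], ["a", "b"], [1e6, 2e6])
        assert (normalize_per_million(m, meta).values.to_numpy() == 0).all()

    def test_missing_library_size_names_sample(self):
        m = cm({"s1": [1.0], "sX": [1.0]}, index=["j1"])
        meta = meta_frame(["s1"], ["a"], [1e6])
        with pytest.raises(ValidationError, match="sX"):
            normalize_per_million(m, meta)

    def test_column_sums_match_hand_computation(self):
        m = cm({"s1": [3.0, 7.0]}, index=["j1", "j2"])
        meta = meta_frame(["s1"], ["a"], [5_000_000])
        out = normalize_per_million(m, meta)
        assert out.values["s1"].sum() == pytest.approx(1e6 * 10 / 5_000_000)


class TestReplicateAveraging:
    def test_mean_of_replicates(self):
        m = cm({"a_r1": [2.0], "a_r2": [4.0], "b_r1": [1.0], "b_r2": [2.0], "b_r3": [6.0]},
               index=["j1"], normalization="per_million")
        meta = meta_frame(
            ["a_r1", "a_r2", "b_r1", "b_r2", "b_r3"],
            ["a", "a", "b", "b", "b"],
            [1e6] * 5,
        )
        out = average_replicates(m, meta)
        assert out.values.loc["j1", "a"] == 3.0
        assert out.values.loc["j1", "b"] == 3.0

    def test_single_replicate_identity(self):
        m = cm({"a_r1": [5.0]}, index=["j1"], normalization="per_million")
        out = average_replicates(m, meta_frame(["a_r1"], ["a"], [1e6]))
        assert out.values.loc["j1", "a"] == 5.0


class TestAggregation:
    def test_sum_over_junctions(self):
        m = cm({"cl": [3.0, 7.0, 4.0]}, index=["j1", "j2", "j3"],
               normalization="per_million")
        out = aggregate_gene_level(m, {"j1": "gA", "j2": "gA", "j3": "gB"})
        assert out.values.loc["gA", "cl"] == 10.0
        assert out.values.loc["gB", "cl"] == 4.0
        assert out.level == "gene"

    def test_unmapped_junction_rejected(self):
        m = cm({"cl": [1.0]}, index=["j1"])
        with pytest.raises(ValidationError, match="j1"):
            aggregate_gene_level(m, {"jX": "gA"})

    def test_conservation_on_random_fixture(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(1.0, 2.0, size=(50, 8))
        idx = [f"j{i}" for i in range(50)]
        genes = {f"j{i}": f"g{i % 7}" for i in range(50)}
        m = cm({f"c{k}": vals[:, k] for k in range(8)}, index=idx,
               normalization="per_million")
        out = aggregate_gene_level(m, genes)
        # independent sequential accumulation oracle, bitwise identical
        acc: dict[str, np.ndarray] = {}
        for i, j in enumerate(idx):
            g = genes[j]
            if g not in acc:
                acc[g] = np.zeros(8)
            acc[g] += vals[i]
        for g, row in acc.items():
            assert (out.values.loc[g].to_numpy() == row).all()

    def test_normalize_aggregate_commute(self):
        rng = np.random.default_rng(1)
        vals = np.round(rng.gamma(1.0, 20.0, size=(30, 4)))
        idx = [f"j{i}" for i in range(30)]
        genes = {f"j{i}": f"g{i % 5}" for i in range(30)}
        samples = [f"s{k}" for k in range(4)]
        meta = meta_frame(samples, list("abcd"), [2e6, 3e6, 4e6, 5e6])
        raw = cm({s: vals[:, k] for k, s in enumerate(samples)}, index=idx)
        path1 = aggregate_gene_level(normalize_per_million(raw, meta), genes)
        agg_raw = aggregate_gene_level(raw, genes)
        path2 = normalize_per_million(agg_raw, meta)
        assert np.allclose(path1.values.to_numpy(), path2.values.to_numpy(),
                           rtol=1e-12, atol=0)


class TestOccurrenceAndFilters:
    def test_occurrence_counts_and_histogram(self):
        m = cm({"c1": [1.0, 0.0], "c2": [0.0, 0.0], "c3": [2.0, 0.0]},
               index=["j1", "j2"], normalization="per_million")
        occ, hist = occurrence(m)
        assert occ["j1"] == 2 and occ["j2"] == 0
        assert hist[0] == 1 and hist[2] == 1 and hist.sum() == 2

    def test_filter_boundary_inclusive(self):
        vals = np.zeros((2, 40))
        vals[0, :30] = 1.0  # occurrence 30
        vals[1, :29] = 1.0  # occurrence 29
        m = cm({f"c{k}": vals[:, k] for k in range(40)}, index=["keep", "drop"],
               normalization="per_million")
        out = filter_min_cell_lines(m, k=30)
        assert list(out.values.index) == ["keep"]

    def test_filter_k_above_panel_warns_empty(self):
        m = cm({"c1": [1.0]}, index=["j1"], normalization="per_million")
        with pytest.warns(UserWarning):
            out = filter_min_cell_lines(m, k=5)
        assert out.values.empty

    def test_gene_occurrence_dominates_junctions(self, small_dataset):
        ds = small_dataset
        occ_j, _ = occurrence(ds.backsplice_cell_line)
        occ_g, _ = occurrence(ds.gene_cell_line)
        for jid, gene in ds.junction_gene.items():
            assert occ_g[gene] >= occ_j[jid]


class TestSitesAndRanking:
    def test_sites_per_gene(self):
        j1 = BacksplicedJunction("c", 0, 10, "+", "gA", {"s": 1}, 1, 2)
        j2 = BacksplicedJunction("c", 0, 20, "+", "gA", {"s": 1}, 1, 3)
        j3 = BacksplicedJunction("c", 5, 20, "+", "gB", {"s": 1}, 2, 3)
        counts, summary = backsplice_sites_per_gene([j1, j2, j3])
        assert counts["gA"] == 2 and counts["gB"] == 1
        assert summary["max"] == 2 and summary["min"] == 1

    def test_top_expressed_order_and_ties(self):
        m = cm({"c1": [5.0, 1.0, 3.0, 3.0]}, index=["a", "d", "c", "b"],
               normalization="per_million")
        assert top_expressed(m, 4) == ["a", "b", "c", "d"]
        assert top_expressed(m, 100) == ["a", "b", "c", "d"]  # n beyond count

    def test_top_matches_brute_force_on_fixture(self):
        rng = np.random.default_rng(3)
        vals = rng.gamma(1.0, 1.0, size=(500, 6))
        idx = [f"f{i:04d}" for i in range(500)]
        m = cm({f"c{k}": vals[:, k] for k in range(6)}, index=idx,
               normalization="per_million")
        got = top_expressed(m, 100)
        sums = {f: vals[i].sum() for i, f in enumerate(idx)}
        expected = sorted(idx, key=lambda f: (-sums[f], f))[:100]
        assert got == expected


class TestReplicateConcordance:
    def test_identical_replicates_score_one(self):
        rng = np.random.default_rng(4)
        col = rng.random(20)
        m = cm({"a_r1": col, "a_r2": col.copy()}, index=[f"j{i}" for i in range(20)],
               normalization="per_million")
        meta = meta_frame(["a_r1", "a_r2"], ["a", "a"], [1e6, 1e6])
        scores, flagged = replicate_concordance(m, meta)
        assert scores["a"] == pytest.approx(1.0)
        assert flagged == []

    def test_swapped_replicate_flagged(self):
        rng = np.random.default_rng(5)
        pa, pb = rng.random(30), rng.random(30)
        m = cm(
            {"a_r1": pa, "a_r2": pb + rng.normal(0, 0.01, 30) ** 2,
             "b_r1": pb, "b_r2": pb + rng.normal(0, 0.01, 30) ** 2},
            index=[f"j{i}" for i in range(30)], normalization="per_million",
        )
        meta = meta_frame(["a_r1", "a_r2", "b_r1", "b_r2"],
                          ["a", "a", "b", "b"], [1e6] * 4)
        _, flagged = replicate_concordance(m, meta)
        assert "a_r2" in flagged

    def test_concordance_decreases_with_noise(self):
        rng = np.random.default_rng(6)
        base = rng.gamma(2.0, 1.0, 200)
        scores = []
        for sd in (0.01, 0.2, 1.0):
            m = cm(
                {"a_r1": base + rng.normal(0, sd, 200) ** 2,
                 "a_r2": base + rng.normal(0, sd, 200) ** 2},
                index=[f"j{i}" for i in range(200)], normalization="per_million",
            )
            meta = meta_frame(["a_r1", "a_r2"], ["a", "a"], [1e6, 1e6])
            s, _ = replicate_concordance(m, meta)
            scores.append(s["a"])
        assert scores[0] > scores[1] > scores[2]


class TestMergeAndConservation:
    def test_same_junction_two_samples_merged(self):
        j = dict(chrom="c", start=0, end=10, strand="+", gene="gA",
                 acceptor_exon=1, donor_exon=2)
        per_sample = {
            "s1": [BacksplicedJunction(reads={"s1": 3}, **j)],
            "s2": [BacksplicedJunction(reads={"s2": 5}, **j)],
        }
        merged = merge_junctions(per_sample)
        assert len(merged) == 1
        assert merged[0].reads == {"s1": 3, "s2": 5}
        m = build_backsplice_matrix(merged, ["s1", "s2"])
        assert m.values.iloc[0].tolist() == [3.0, 5.0]

    def test_dataset_conservation_exact(self, small_dataset):
        ds = small_dataset
        b = ds.backsplice_cell_line.values
        g = ds.gene_cell_line.values
        acc: dict[str, np.ndarray] = {}
        for jid in b.index:
            gene = ds.junction_gene[jid]
            if gene not in acc:
                acc[gene] = np.zeros(b.shape[1])
            acc[gene] += b.loc[jid].to_numpy()
        for gene, row in acc.items():
            assert (g.loc[gene].to_numpy() == row).all()
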