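import math

import numpy as np
import pandas as pd
import pytest

from sweepscan import (
    DivergentRegion,
    GeneModel,
    ScanConfig,
    assign_genes,
    call_outlier_windows,
    evaluate_recovery,
    make_windows,
    merge_regions,
    rank_top_genes,
    scan_windows,
)
from sweepscan.synthetic_data import SimConfig, simulate_two_pop


def stats_frame(fst, pi_ratio, contig="chr1", start0=1, step=10_000, size=40_000):
    """A windows table with the given statistics (all retained)."""
    n = len(fst)
    starts = start0 + np.arange(n) * step
    return pd.DataFrame(
        {
            "contig": [contig] * n,
            "start": starts,
            "end": starts + size - 1,
            "n_snps": [50] * n,
            "fst": fst,
            "pi_a": [1e-4] * n,
            "pi_b": [1e-4] * n,
            "pi_ratio": pi_ratio,
            "ratio_defined": [True] * n,
            "excluded": [False] * n,
        }
    )


class TestMakeWindows:
    def test_grid_arithmetic(self):
        cfg = ScanConfig()
        w = make_windows({"c": 100_000}, cfg)
        assert len(w) == 7
        assert w[0] == ("c", 1, 40_000)
        assert w[-1] == ("c", 60_001, 100_000)

    def test_exact_fit_single_window(self):
        w = make_windows({"c": 40_000}, ScanConfig())
        assert w == [("c", 1, 40_000)]

    def test_short_contig_truncated(self):
        w = make_windows({"c": 25_000}, ScanConfig())
        assert w == [("c", 1, 25_000)]

    def test_step_exceeding_window_rejected(self):
        with pytest.raises(ValueError):
            ScanConfig(window_size_bp=10_000, step_bp=20_000)


class TestCallOutliers:
    def test_concordant_rankings_select_top_five(self):
        vals = np.arange(1, 101) / 100.0
        out = call_outlier_windows(stats_frame(vals, vals), ScanConfig())
        assert out["selected"].sum() == 5
        assert set(out.loc[out["selected"], "fst"]) == {0.96, 0.97, 0.98, 0.99, 1.0}

    def test_opposed_rankings_select_nothing(self):
        vals = np.arange(1, 101) / 100.0
        out = call_outlier_windows(stats_frame(vals, vals[::-1]), ScanConfig())
        assert out["selected"].sum() == 0

    def test_all_tied_selects_all(self):
        out = call_outlier_windows(
            stats_frame([0.5] * 100, [2.0] * 100), ScanConfig()
        )
        assert out["selected"].all()

    def test_infinite_ratio_ranks_maximal(self):
        vals = np.arange(1, 101) / 100.0
        ratios = vals.copy().astype(object)
        df = stats_frame(vals, vals)
        df.loc[99, "pi_ratio"] = np.inf
        df.loc[99, "ratio_defined"] = False
        out = call_outlier_windows(df, ScanConfig())
        assert bool(out.loc[99, "selected"])

    def test_excluded_windows_dropped_before_thresholding(self):
        vals = np.arange(1, 101) / 100.0
        df = stats_frame(vals, vals)
        df.loc[95:, "excluded"] = True  # remove the top windows
        out = call_outlier_windows(df, ScanConfig())
        assert len(out) == 95
        assert out.loc[out["selected"], "fst"].min() >= 0.91

    def test_selection_count_bounded(self):
        rng = np.random.default_rng(11)
        fst = rng.uniform(0, 1, 500)
        ratio = rng.uniform(0.5, 5, 500)
        out = call_outlier_windows(stats_frame(fst, ratio), ScanConfig())
        assert out["selected"].sum() <= math.ceil(0.05 * 500)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        fst = rng.uniform(0, 1, 200)
        ratio = rng.uniform(0.5, 5, 200)
        base = call_outlier_windows(stats_frame(fst, ratio), ScanConfig())
        warped = call_outlier_windows(
            stats_frame(fst**3, np.exp(ratio)), ScanConfig()
        )
        np.testing.assert_array_equal(
            base["selected"].to_numpy(), warped["selected"].to_numpy()
        )

    def test_high_quantile_selects_at_most_one(self):
        vals = np.arange(1, 101) / 100.0
        out = call_outlier_windows(
            stats_frame(vals, vals), ScanConfig(outlier_quantile=0.999)
        )
        assert out["selected"].sum() <= 1


class TestMergeRegions:
    def test_overlapping_windows_merge(self):
        df = stats_frame([0.5, 0.6], [2, 3])
        df["selected"] = True
        (r,) = merge_regions(df)
        assert (r.start, r.end, r.n_windows) == (1, 50_000, 2)
        assert r.peak_fst == 0.6 and r.peak_pi_ratio == 3

    def test_different_contigs_never_merge(self):
        a = stats_frame([0.5], [2], contig="c1")
        b = stats_frame([0.5], [2], contig="c2")
        df = pd.concat([a, b], ignore_index=True)
        df["selected"] = True
        assert len(merge_regions(df)) == 2

    def test_chained_windows_count(self):
        df = stats_frame([0.4, 0.5, 0.6], [2, 2, 2])
        df["selected"] = True
        (r,) = merge_regions(df)
        assert r.n_windows == 3

    def test_book_ended_windows_merge(self):
        df = stats_frame([0.5, 0.5], [2, 2], step=40_000)
        df["selected"] = True
        assert len(merge_regions(df)) == 1

    def test_gapped_windows_stay_separate(self):
        df = stats_frame([0.5, 0.5], [2, 2], step=50_000)
        df["selected"] = True
        assert len(merge_regions(df)) == 2


class TestAssignGenes:
    def test_one_bp_overlap_suffices(self):
        r = DivergentRegion("c", 52_001, 96_000, 2, 0.5, 3.0)
        genes = [GeneModel("gA", "c", 90_000, 120_000)]
        assign_genes([r], genes)
        assert r.genes == ["gA"]

    def test_adjacent_gene_not_assigned(self):
        r = DivergentRegion("c", 52_001, 96_000, 2, 0.5, 3.0)
        genes = [GeneModel("gB", "c", 40_000, 52_000)]
        assign_genes([r], genes)
        assert r.genes == []

    def test_gene_spanning_two_regions_counted_once_in_union(self):
        r1 = DivergentRegion("c", 1, 40_000, 1, 0.5, 2.0)
        r2 = DivergentRegion("c", 100_000, 140_000, 1, 0.5, 2.0)
        genes = [GeneModel("gC", "c", 30_000, 110_000)]
        assign_genes([r1, r2], genes)
        assert r1.genes == ["gC"] and r2.genes == ["gC"]
        assert len({g for r in (r1, r2) for g in r.genes}) == 1


class TestRankTopGenes:
    def _selected(self, n):
        df = stats_frame(
            np.linspace(0.9, 0.1, n), np.linspace(5, 1, n), step=50_000
        )
        df["selected"] = True
        return df

    def test_exclusion_logic(self):
        df = self._selected(3)
        starts = df["start"].to_numpy()
        genes = [
            GeneModel(f"g{i + 1}", "chr1", int(s), int(s) + 100)
            for i, s in enumerate(starts)
        ]
        out = rank_top_genes(df, genes, n_fst=2, n_pi=1)
        assert [e.gene_name for e in out] == ["g1", "g2", "g3"]
        assert [e.selected_by for e in out] == ["fst", "fst", "pi_ratio"]

    def test_gene_top_in_both_metrics_appears_once_as_fst(self):
        df = self._selected(3)
        starts = df["start"].to_numpy()
        genes = [
            GeneModel(f"g{i + 1}", "chr1", int(s), int(s) + 100)
            for i, s in enumerate(starts)
        ]
        out = rank_top_genes(df, genes, n_fst=1, n_pi=2)
        names = [e.gene_name for e in out]
        assert names.count("g1") == 1
        assert out[0].selected_by == "fst"

    def test_120_genes_yield_exactly_100(self):
        df = self._selected(120)
        starts = df["start"].to_numpy()
        genes = [
            GeneModel(f"g{i:03d}", "chr1", int(s), int(s) + 100)
            for i, s in enumerate(starts)
        ]
        out = rank_top_genes(df, genes, n_fst=50, n_pi=50)
        assert len(out) == 100
        assert sum(e.selected_by == "fst" for e in out) == 50
        assert sum(e.selected_by == "pi_ratio" for e in out) == 50
        assert len({e.gene_name for e in out}) == 100

    def test_shortfall_returns_all(self):
        df = self._selected(3)
        genes = [GeneModel("only", "chr1", 1, 100)]
        out = rank_top_genes(df, genes, n_fst=50, n_pi=50)
        assert len(out) == 1


class TestEvaluateRecovery:
    def test_perfect_calls(self):
        truth = [("c", 1, 1000), ("c", 5000, 6000)]
        regions = [DivergentRegion(c, s, e, 1, 0.5, 2.0) for c, s, e in truth]
        assert evaluate_recovery(regions, truth) == (1.0, 1.0)

    def test_no_calls(self):
        recall, precision = evaluate_recovery([], [("c", 1, 1000)])
        assert recall == 0.0 and math.isnan(precision)

    def test_half_overlapping_region(self):
        truth = [("c", 1, 1000)]
        regions = [DivergentRegion("c", 501, 1500, 1, 0.5, 2.0)]
        recall, precision = evaluate_recovery(regions, truth)
        assert recall == 1.0 and precision == pytest.approx(0.5)

    def test_empty_truth_recall_undefined(self):
        regions = [DivergentRegion("c", 1, 100, 1, 0.5, 2.0)]
        recall, _ = evaluate_recovery(regions, [])
        assert math.isnan(recall)


class TestNullScatter:
    def test_neutral_scan_selects_no_contig_disproportionately(self):
        """Without sweeps, joint outliers are few and spread across contigs."""
        hits = {f"contig_{i + 1}": 0 for i in range(5)}
        total = 0
        for seed in range(20):
            sim = simulate_two_pop(
                SimConfig(seed=seed, n_contigs=5, contig_length_bp=400_000,
                          n_sweeps=0, n_causal_phenotype_snps=0)
            )
            out = call_outlier_windows(
                scan_windows(sim.table, sim.contrast, ScanConfig()), ScanConfig()
            )
            sel = out.loc[out["selected"]]
            for contig in sel["contig"]:
                hits[contig] += 1
                total += 1
        if total:
            share = 1 / 5
            for contig, k in hits.items():
                assert k <= max(3 * share * total, 3)
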