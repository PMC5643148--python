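"""Weighted-level arithmetic, tiling, feature pooling, correlation, contexts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oometh import methylation_summary as ms
from tests.conftest import make_records


def records_from_counts(counts, context="CG", chrom="chr1", start_pos=100, step=10):
    rows = [
        (chrom, start_pos + i * step, "+", m, u, context,
         {"CG": "CGA", "CHG": "CAG", "CHH": "CAT"}[context])
        for i, (m, u) in enumerate(counts)
    ]
    return make_records(rows)


class TestWeightedLevel:
    def test_hand_summation(self):
        records = records_from_counts([(3, 1), (0, 4), (2, 2)])
        assert ms.weighted_level(records) == pytest.approx(5 / 12)

    def test_fully_methylated(self):
        records = records_from_counts([(5, 0), (5, 0)])
        assert ms.weighted_level(records) == 1.0

    def test_no_covered_sites_is_undefined_not_zero(self):
        records = records_from_counts([(0, 0), (0, 0)])
        assert math.isnan(ms.weighted_level(records))

    def test_context_filter(self, simple_records):
        assert ms.weighted_level(simple_records, "CG") == pytest.approx(5 / 12)
        assert ms.weighted_level(simple_records, "nonCG") == pytest.approx(1 / 9)
        assert ms.weighted_level(simple_records, None) == pytest.approx(6 / 21)

    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 50), st.integers(0, 50)), min_size=2, max_size=20
        ).filter(lambda c: sum(m + u for m, u in c) > 0),
        split=st.integers(1, 19),
    )
    @settings(max_examples=50, deadline=None)
    def test_pooling_invariant_under_splitting(self, counts, split):
        """Splitting the stream and pooling counts gives the same level."""
        records = records_from_counts(counts)
        whole = ms.weighted_level(records)
        split = min(split, len(records) - 1)
        parts = [records.iloc[:split], records.iloc[split:]]
        meth = sum(p["count_methylated"].sum() for p in parts)
        total = meth + sum(p["count_unmethylated"].sum() for p in parts)
        assert whole == pytest.approx(meth / total)

    def test_uniform_depth_equals_unweighted_mean(self):
        counts = [(3, 7), (8, 2), (5, 5)]
        records = records_from_counts(counts)
        per_site = [m / (m + u) for m, u in counts]
        assert ms.weighted_level(records) == pytest.approx(np.mean(per_site))


class TestTileWindows:
    GENOME = [("chr1", 25_000)]

    def test_partial_last_tile(self):
        windows = ms.tile_windows(records_from_counts([(1, 1)]), 10_000, self.GENOME)
        assert list(zip(windows["start"], windows["end"])) == [
            (0, 10_000), (10_000, 20_000), (20_000, 25_000)
        ]

    def test_one_based_boundary_site(self):
        # 1-based pos 10000 is 0-based 9999 -> first tile
        records = make_records([("chr1", 10_000, "+", 4, 0, "CG", "CGA")])
        windows = ms.tile_windows(records, 10_000, self.GENOME, min_sites=1)
        assert windows.loc[0, "n_sites_covered"] == 1
        assert windows.loc[1, "n_sites_covered"] == 0

    def test_pooling_matches_brute_force(self, small_fgo):
        _, records, truth = small_fgo
        cfg = truth.config
        genome = records.loc[records["chrom"] != "lambda"]
        windows = ms.tile_windows(genome, cfg.window_size, list(cfg.genome_spec))
        cg = genome.loc[genome["context"] == "CG"]
        for row in windows.sample(n=8, random_state=0).itertuples():
            inside = cg.loc[
                (cg["chrom"] == row.chrom)
                & (cg["pos"] - 1 >= row.start)
                & (cg["pos"] - 1 < row.end)
            ]
            assert row.pooled_methylated == inside["count_methylated"].sum()
            assert row.pooled_unmethylated == inside["count_unmethylated"].sum()

    def test_each_site_in_exactly_one_tile(self, small_fgo):
        _, records, truth = small_fgo
        cfg = truth.config
        genome = records.loc[records["chrom"] != "lambda"]
        windows = ms.tile_windows(genome, cfg.window_size, list(cfg.genome_spec))
        n_cg_sites = int((genome["context"] == "CG").sum())
        assert windows["n_sites_covered"].sum() == n_cg_sites

    def test_global_level_bounded_by_window_levels(self, small_fgo):
        _, records, truth = small_fgo
        cfg = truth.config
        genome = records.loc[records["chrom"] != "lambda"]
        windows = ms.tile_windows(genome, cfg.window_size, list(cfg.genome_spec))
        levels = windows["level"].dropna()
        global_level = ms.weighted_level(genome, "CG")
        assert levels.min() <= global_level <= levels.max()

    def test_unknown_chromosome_policy(self):
        records = records_from_counts([(1, 1)], chrom="chrUn")
        windows = ms.tile_windows(records, 10_000, self.GENOME)
        assert windows["n_sites_covered"].sum() == 0
        with pytest.raises(ValueError, match="unknown"):
            ms.tile_windows(records, 10_000, self.GENOME, on_unknown_chrom="error")


class TestFeatureLevels:
    def test_single_covering_feature_equals_global(self, simple_records):
        features = pd.DataFrame(
            [{"chrom": "chr1", "start": 0, "end": 10_000, "name": "all", "feature_class": "genic"}]
        )
        _, per_class = ms.feature_levels(simple_records, features)
        assert per_class.loc[0, "level"] == pytest.approx(
            ms.weighted_level(simple_records, "CG")
        )

    def test_partition_conserves_counts(self, simple_records):
        features = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 0, "end": 1200, "name": "a", "feature_class": "A"},
                {"chrom": "chr1", "start": 1200, "end": 10_000, "name": "b", "feature_class": "B"},
            ]
        )
        _, per_class = ms.feature_levels(simple_records, features)
        pooled_m = per_class["pooled_methylated"].sum()
        pooled_u = per_class["pooled_unmethylated"].sum()
        cg = simple_records.loc[simple_records["context"] == "CG"]
        assert pooled_m == cg["count_methylated"].sum()
        assert pooled_u == cg["count_unmethylated"].sum()

    def test_nested_features_count_site_twice(self, small_fgo):
        _, records, _ = small_fgo
        genome = records.loc[records["chrom"] != "lambda"]
        features = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 0, "end": 50_000, "name": "outer", "feature_class": "X"},
                {"chrom": "chr1", "start": 10_000, "end": 20_000, "name": "inner", "feature_class": "Y"},
            ]
        )
        per_feature, _ = ms.feature_levels(genome, features)
        # brute-force oracle: scan every CG site against every interval
        cg = genome.loc[genome["context"] == "CG"]
        for row in per_feature.itertuples():
            inside = cg.loc[
                (cg["chrom"] == row.chrom)
                & (cg["pos"] - 1 >= row.start)
                & (cg["pos"] - 1 < row.end)
            ]
            assert row.pooled_methylated == inside["count_methylated"].sum()
            assert row.n_sites_covered == len(inside)


class TestConversionRate:
    def test_perfect_conversion(self):
        records = records_from_counts([(0, 20)], chrom="lambda")
        assert ms.conversion_rate(records) == 1.0

    def test_pooled_arithmetic(self):
        records = records_from_counts([(1, 99)], chrom="lambda")
        assert ms.conversion_rate(records) == pytest.approx(0.99)

    def test_missing_spikein_is_undefined(self, simple_records):
        assert math.isnan(ms.conversion_rate(simple_records))

    def test_all_contexts_pooled(self):
        records = make_records(
            [
                ("lambda", 10, "+", 1, 9, "CG", "CGA"),
                ("lambda", 20, "+", 0, 10, "CHH", "CTT"),
            ]
        )
        assert ms.conversion_rate(records) == pytest.approx(1 - 1 / 20)


class TestSampleCorrelation:
    def _windows(self, levels):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(len(levels)) * 10_000,
                "end": (np.arange(len(levels)) + 1) * 10_000,
                "level": levels,
            }
        )

    def test_identity_is_one(self):
        a = self._windows([0.1, 0.5, 0.9, 0.3])
        assert ms.sample_correlation(a, a) == (pytest.approx(1.0), 4)

    def test_anticorrelation(self):
        a = self._windows([0.1, 0.5, 0.9])
        b = self._windows([0.9, 0.5, 0.1])
        r, _ = ms.sample_correlation(a, b)
        assert r == pytest.approx(-1.0)

    def test_undefined_below_two_windows(self):
        a = self._windows([0.1, math.nan])
        r, n = ms.sample_correlation(a, a)
        assert math.isnan(r) and n == 1

    def test_replicate_simulations_correlate(self):
        import dataclasses
        from oometh import synthetic_methylome as sm
        from tests.conftest import SMALL_GENOME

        cfg1 = sm.control_fgo_config(seed=21, genome_spec=SMALL_GENOME, noncg_density=0.0)
        cfg2 = dataclasses.replace(cfg1, seed=22)
        rec1, _ = sm.simulate_oocyte_methylome(cfg1, "FGO")
        rec2, _ = sm.simulate_oocyte_methylome(cfg2, "FGO")
        spec = list(cfg1.genome_spec)
        w1 = ms.tile_windows(rec1.loc[rec1["chrom"] != "lambda"], 10_000, spec)
        w2 = ms.tile_windows(rec2.loc[rec2["chrom"] != "lambda"], 10_000, spec)
        r, n = ms.sample_correlation(w1, w2)
        assert n == 30
        assert r > 0.9  # window-class structure is shared between replicates


class TestContextSplit:
    def test_equal_counts_give_equal_shares(self):
        records = make_records(
            [
                ("chr1", 10, "+", 5, 5, "CG", "CGA"),
                ("chr1", 20, "+", 5, 5, "CHG", "CAG"),
                ("chr1", 30, "+", 5, 5, "CHH", "CAT"),
            ]
        )
        split = ms.context_split(records)
        assert split["share_of_5mc"].tolist() == pytest.approx([1 / 3] * 3)

    def test_shares_match_truth_counting(self, small_fgo):
        _, records, _ = small_fgo
        genome = records.loc[records["chrom"] != "lambda"]
        split = ms.context_split(genome).set_index("context")
        total = genome["count_methylated"].sum()
        for context in ("CG", "CHG", "CHH"):
            expected = genome.loc[
                genome["context"] == context, "count_methylated"
            ].sum() / total
            assert split.loc[context, "share_of_5mc"] == pytest.approx(expected)
        assert split["share_of_5mc"].sum() == pytest.approx(1.0)


def test_summarize_sample_bundles_levels(small_fgo):
    _, records, truth = small_fgo
    summary = ms.summarize_sample(records, sample_id="s1")
    genome = records.loc[records["chrom"] != "lambda"]
    assert summary.global_cg_level == pytest.approx(ms.weighted_level(genome, "CG"))
    assert summary.conversion_rate == pytest.approx(
        1 - truth.config.error_rate, abs=0.01
    )
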