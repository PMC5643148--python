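"""Allele splitting, conservation, ICR concordance, and the genotype chi²."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2

from oometh import allele_methylation as am
from oometh import methylation_summary as ms


def read_table(rows):
    """Rows of (pos, methylated, allele) at one CG site per pos."""
    return pd.DataFrame(
        [
            {"chrom": "chr1", "pos": pos, "strand": "+", "context": "CG",
             "methylated": m, "allele": allele}
            for pos, m, allele in rows
        ]
    )


class TestSplitByAllele:
    def test_bookkeeping(self):
        reads = read_table(
            [(100, 1, "maternal")] * 3
            + [(100, 1, "paternal")]
            + [(100, 0, "unassigned")] * 2
        )
        tagged = am.split_by_allele(reads)
        row = tagged.iloc[0]
        assert (row["maternal_methylated"], row["maternal_unmethylated"]) == (3, 0)
        assert (row["paternal_methylated"], row["paternal_unmethylated"]) == (1, 0)
        assert (row["unassigned_methylated"], row["unassigned_unmethylated"]) == (0, 2)

    def test_all_unassigned_when_no_snps(self):
        reads = read_table([(100, 1, "unassigned"), (110, 0, "unassigned")])
        tagged = am.split_by_allele(reads)
        assert (tagged[["maternal_methylated", "paternal_methylated"]] == 0).all().all()

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError, match="unknown allele"):
            am.split_by_allele(read_table([(100, 1, "grandmaternal")]))

    @given(
        reads=st.lists(
            st.tuples(
                st.integers(100, 105),
                st.integers(0, 1),
                st.sampled_from(am.ALLELES),
            ),
            min_size=1,
            max_size=60,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_conservation_is_exact(self, reads):
        table = read_table(reads)
        tagged = am.split_by_allele(table)
        totals = am.tagged_totals(tagged)
        assert totals["count_methylated"].sum() == table["methylated"].sum()
        assert (
            totals["count_methylated"] + totals["count_unmethylated"]
        ).sum() == len(table)
        # per-site conservation
        per_site = table.groupby("pos")["methylated"].agg(["sum", "size"])
        merged = totals.set_index("pos").join(per_site)
        assert (merged["count_methylated"] == merged["sum"]).all()


class TestAlleleGlobalLevels:
    def test_weighted_levels_per_allele(self):
        tagged = pd.DataFrame(
            [
                {"chrom": "chr1", "pos": 100, "strand": "+", "context": "CG",
                 "maternal_methylated": 143, "maternal_unmethylated": 857,
                 "paternal_methylated": 166, "paternal_unmethylated": 834,
                 "unassigned_methylated": 0, "unassigned_unmethylated": 0}
            ]
        )
        mat, pat = am.allele_global_levels(tagged)
        assert mat == pytest.approx(0.143)
        assert pat == pytest.approx(0.166)

    def test_unassigned_only_is_undefined(self):
        tagged = pd.DataFrame(
            [
                {"chrom": "chr1", "pos": 100, "strand": "+", "context": "CG",
                 "maternal_methylated": 0, "maternal_unmethylated": 0,
                 "paternal_methylated": 0, "paternal_unmethylated": 0,
                 "unassigned_methylated": 3, "unassigned_unmethylated": 5}
            ]
        )
        mat, pat = am.allele_global_levels(tagged)
        assert math.isnan(mat) and math.isnan(pat)

    def test_overall_level_decomposes_by_allele_exactly(self):
        """Depth-weighted allele levels plus the unassigned part reproduce the
        overall weighted level (arithmetic identity)."""
        rng = np.random.default_rng(3)
        n = 50
        tagged = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(n) * 10 + 1,
                "strand": "+",
                "context": "CG",
                "maternal_methylated": rng.integers(0, 10, n),
                "maternal_unmethylated": rng.integers(0, 10, n),
                "paternal_methylated": rng.integers(0, 10, n),
                "paternal_unmethylated": rng.integers(0, 10, n),
                "unassigned_methylated": rng.integers(0, 10, n),
                "unassigned_unmethylated": rng.integers(0, 10, n),
            }
        )
        overall = ms.weighted_level(am.tagged_totals(tagged), "CG")
        parts = 0.0
        depth_total = 0
        for allele in am.ALLELES:
            meth = tagged[f"{allele}_methylated"].sum()
            depth = meth + tagged[f"{allele}_unmethylated"].sum()
            level = meth / depth
            parts += level * depth
            depth_total += depth
        assert overall == pytest.approx(parts / depth_total, abs=1e-12)


class TestIcrAlleleTable:
    ICRS = pd.DataFrame(
        [
            {"chrom": "chr1", "start": 0, "end": 1000, "name": "SnrpnLike",
             "methylated_parent": "maternal"},
        ]
    )

    def _tagged(self, mat_level, pat_level, depth=100):
        mat_m = int(round(mat_level * depth))
        pat_m = int(round(pat_level * depth))
        return pd.DataFrame(
            [
                {"chrom": "chr1", "pos": 500, "strand": "+", "context": "CG",
                 "maternal_methylated": mat_m, "maternal_unmethylated": depth - mat_m,
                 "paternal_methylated": pat_m, "paternal_unmethylated": depth - pat_m,
                 "unassigned_methylated": 0, "unassigned_unmethylated": 0}
            ]
        )

    def test_expected_parent_dominant_is_concordant(self):
        table = am.icr_allele_table(self._tagged(0.9, 0.05), self.ICRS)
        assert table.loc[0, "status"] == "concordant"

    def test_biallelic_is_discordant(self):
        table = am.icr_allele_table(self._tagged(0.5, 0.5), self.ICRS)
        assert table.loc[0, "status"] == "discordant"

    def test_uncovered_region_is_no_data(self):
        empty = self._tagged(0.9, 0.05)
        empty["pos"] = 5000  # outside the ICR
        table = am.icr_allele_table(empty, self.ICRS)
        assert table.loc[0, "status"] == "no_data"


class TestIcrGenotypeTest:
    def test_hand_computed_statistic(self):
        # margins 100/100 and 140/60 -> expected 70/30 per row
        cmp = am.icr_genotype_test((90, 10), (50, 50), region="demo")
        expected = 2 * (20**2 / 70 + 20**2 / 30)
        assert cmp.statistic == pytest.approx(expected, rel=1e-9)
        assert cmp.p_value == pytest.approx(chi2.sf(expected, df=1), rel=1e-6)
        assert cmp.p_value < 1e-8

    def test_identical_counts_null(self):
        cmp = am.icr_genotype_test((40, 60), (40, 60))
        assert cmp.statistic == 0.0 and cmp.p_value == 1.0

    def test_symmetric_in_genotype_order(self):
        ab = am.icr_genotype_test((90, 10), (50, 50))
        ba = am.icr_genotype_test((50, 50), (90, 10))
        assert ab.statistic == pytest.approx(ba.statistic)

    def test_zero_margin_undefined(self):
        cmp = am.icr_genotype_test((0, 0), (10, 10))
        assert math.isnan(cmp.statistic) and math.isnan(cmp.p_value)

    @given(
        a_m=st.integers(0, 1000), a_u=st.integers(0, 1000),
        b_m=st.integers(0, 1000), b_u=st.integers(0, 1000),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_expected_counts(self, a_m, a_u, b_m, b_u):
        """Statistic equals the direct sum over (obs-exp)^2/exp."""
        table = np.array([[a_m, a_u], [b_m, b_u]], dtype=float)
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            return
        cmp = am.icr_genotype_test((a_m, a_u), (b_m, b_u))
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        stat = ((table - expected) ** 2 / expected).sum()
        assert cmp.statistic == pytest.approx(stat, abs=1e-9)


class TestSimulationRecovery:
    def test_per_allele_levels_match_truth(self):
        from oometh import synthetic_methylome as sm
        from tests.conftest import SMALL_GENOME

        _, tagged, truth = sm.simulate_blastocyst(
            "control", seed=31, genome_spec=SMALL_GENOME, noncg_density=0.0
        )
        mat, pat = am.allele_global_levels(tagged)
        err = truth.config.error_rate
        for measured, allele in ((mat, "maternal"), (pat, "paternal")):
            true_level = truth.true_allele_cg_level(allele)
            expected_obs = true_level * (1 - 2 * err) + err
            # assigned sites are SNP-biased toward transcribed windows, so
            # allow a broad band around the genome-wide truth
            assert measured == pytest.approx(expected_obs, abs=0.03)

    def test_conservation_against_merged_records(self):
        from oometh import synthetic_methylome as sm
        from tests.conftest import SMALL_GENOME

        records, tagged, _ = sm.simulate_blastocyst(
            "control", seed=31, genome_spec=SMALL_GENOME, noncg_density=0.0
        )
        totals = am.tagged_totals(tagged)
        merged = records.merge(
            totals, on=["chrom", "pos", "strand", "context"], suffixes=("", "_tagged")
        )
        assert len(merged) == len(records)
        assert (merged["count_methylated"] == merged["count_methylated_tagged"]).all()
        assert (
            merged["count_unmethylated"] == merged["count_unmethylated_tagged"]
        ).all()
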