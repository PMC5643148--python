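"""Allele-resolved methylation: parental-genome levels and ICR tests.

Reads overlapping an informative SNP can be assigned to the maternal or the
paternal genome; reads without a nearby SNP stay unassigned.  This module
consumes pre-tagged input — either per-site counts already partitioned by
allele, or read-level (site, methylation state, allele) tuples — and
summarizes per-allele weighted levels genome-wide and at imprinting control
regions (ICRs), plus a chi-squared test for per-region genotype differences.
Read alignment, SNP calling and phasing are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

ALLELES = ("maternal", "paternal", "unassigned")

TAGGED_COLUMNS = (
    "chrom",
    "pos",
    "strand",
    "context",
    "maternal_methylated",
    "maternal_unmethylated",
    "paternal_methylated",
    "paternal_unmethylated",
    "unassigned_methylated",
    "unassigned_unmethylated",
)


@dataclass
class IcrComparison:
    """Chi-squared comparison of one region's pooled counts between genotypes."""

    region: str
    a_methylated: int
    a_unmethylated: int
    b_methylated: int
    b_unmethylated: int
    statistic: float
    p_value: float


def split_by_allele(reads: pd.DataFrame) -> pd.DataFrame:
    """Aggregate read-level tuples into per-site allele-tagged counts.

    ``reads`` columns: chrom, pos (1-based), strand, context, methylated
    (0/1 or bool), allele in {maternal, paternal, unassigned}.  Returns one
    row per site with the six allele count columns; maternal + paternal +
    unassigned totals equal the untagged totals exactly by construction.
    """
    bad = ~reads["allele"].isin(ALLELES)
    if bad.any():
        raise ValueError(
            f"unknown allele tag(s): {sorted(reads.loc[bad, 'allele'].unique())}"
        )
    work = reads.copy()
    work["methylated"] = work["methylated"].astype(int)
    if not work["methylated"].isin([0, 1]).all():
        raise ValueError("methylated must be 0/1")
    work["unmethylated"] = 1 - work["methylated"]

    pivot = work.pivot_table(
        index=["chrom", "pos", "strand", "context"],
        columns="allele",
        values=["methylated", "unmethylated"],
        aggfunc="sum",
        fill_value=0,
    )
    out = pd.DataFrame(index=pivot.index)
    for allele in ALLELES:
        for state in ("methylated", "unmethylated"):
            col = (state, allele)
            out[f"{allele}_{state}"] = (
                pivot[col].astype("int64") if col in pivot.columns else 0
            )
    return out.reset_index()[list(TAGGED_COLUMNS)]


def tagged_totals(tagged: pd.DataFrame) -> pd.DataFrame:
    """Collapse allele-tagged counts back to untagged per-site totals."""
    out = tagged[["chrom", "pos", "strand", "context"]].copy()
    out["count_methylated"] = (
        tagged["maternal_methylated"]
        + tagged["paternal_methylated"]
        + tagged["unassigned_methylated"]
    )
    out["count_unmethylated"] = (
        tagged["maternal_unmethylated"]
        + tagged["paternal_unmethylated"]
        + tagged["unassigned_unmethylated"]
    )
    return out


def _context_mask(tagged: pd.DataFrame, context: str | None) -> pd.Series:
    if context is None or context == "all":
        return pd.Series(True, index=tagged.index)
    if context == "nonCG":
        return tagged["context"].isin(["CHG", "CHH"])
    return tagged["context"] == context


def _allele_level(sub: pd.DataFrame, allele: str) -> float:
    meth = int(sub[f"{allele}_methylated"].sum())
    total = meth + int(sub[f"{allele}_unmethylated"].sum())
    return meth / total if total else math.nan


def allele_global_levels(
    tagged: pd.DataFrame, context: str | None = "CG"
) -> tuple[float, float]:
    """Weighted (maternal, paternal) levels over assigned counts only.

    An allele with zero assigned depth gets NaN.
    """
    sub = tagged.loc[_context_mask(tagged, context)]
    return _allele_level(sub, "maternal"), _allele_level(sub, "paternal")


def icr_allele_table(
    tagged: pd.DataFrame,
    icrs: pd.DataFrame,
    margin: float = 0.3,
    context: str | None = "CG",
) -> pd.DataFrame:
    """Per-ICR parental levels and a concordance call.

    ``icrs`` columns: chrom, start, end (0-based half-open), name,
    methylated_parent in {maternal, paternal}.  An ICR is *concordant* when
    the expected parent's weighted level exceeds the other parent's by at
    least ``margin``; regions with no assigned counts are reported as
    ``no_data`` rather than discordant.
    """
    sub = tagged.loc[_context_mask(tagged, context)]
    rows = []
    for icr in icrs.itertuples(index=False):
        expected = icr.methylated_parent
        if expected not in ("maternal", "paternal"):
            raise ValueError(f"ICR {icr.name}: bad methylated_parent {expected!r}")
        pos0 = sub["pos"] - 1
        inside = sub.loc[
            (sub["chrom"] == icr.chrom) & (pos0 >= icr.start) & (pos0 < icr.end)
        ]
        mat = _allele_level(inside, "maternal")
        pat = _allele_level(inside, "paternal")
        if math.isnan(mat) or math.isnan(pat):
            status = "no_data"
        else:
            expected_level = mat if expected == "maternal" else pat
            other_level = pat if expected == "maternal" else mat
            status = (
                "concordant" if expected_level - other_level >= margin else "discordant"
            )
        n_assigned = int(
            inside[
                [
                    "maternal_methylated",
                    "maternal_unmethylated",
                    "paternal_methylated",
                    "paternal_unmethylated",
                ]
            ]
            .to_numpy()
            .sum()
        )
        rows.append(
            {
                "name": icr.name,
                "methylated_parent": expected,
                "maternal_level": mat,
                "paternal_level": pat,
                "n_assigned_reads": n_assigned,
                "status": status,
            }
        )
    return pd.DataFrame(rows)


def icr_genotype_test(
    a_counts: tuple[int, int],
    b_counts: tuple[int, int],
    region: str = "",
) -> IcrComparison:
    """Pearson chi-squared (no continuity correction) on a 2x2 pooled table.

    ``a_counts`` and ``b_counts`` are (methylated, unmethylated) pooled read
    counts for one region in the two genotypes.  Zero margins make the test
    undefined and yield NaN statistic/p.
    """
    a_m, a_u = (int(x) for x in a_counts)
    b_m, b_u = (int(x) for x in b_counts)
    table = np.array([[a_m, a_u], [b_m, b_u]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        stat, p = math.nan, math.nan
    elif a_m * b_u == a_u * b_m:  # identical proportions -> exactly 0
        stat, p = 0.0, 1.0
    else:
        stat, p, _, _ = chi2_contingency(table, correction=False)
    return IcrComparison(
        region=region,
        a_methylated=a_m,
        a_unmethylated=a_u,
        b_methylated=b_m,
        b_unmethylated=b_u,
        statistic=float(stat),
        p_value=float(p),
    )
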