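"""Hemimethylated CpG-dyad calling from strand-resolved counts.

A CG site is palindromic: the plus-strand C at 0-based position p pairs with
the minus-strand C at p+1.  A dyad is hemimethylated when one strand is
methylated and the other is not.  Following the field's standard recipe, the
caller selects candidate dyads that are highly methylated (level >= 70% on
either strand) with read depth >= 10, tests the 2x2 strand-by-methylation
table with Fisher's exact test, and calls dyads with p < 0.05
hemimethylated.  The headline statistic is the proportion of hemimethylated
sites among the highly methylated candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.proportion import proportions_chisquare

DYAD_COLUMNS = (
    "chrom",
    "dyad_start",
    "plus_methylated",
    "plus_unmethylated",
    "minus_methylated",
    "minus_unmethylated",
)


@dataclass(frozen=True)
class CpGDyad:
    """Paired plus/minus strand counts at one CG dyad (0-based plus-strand C)."""

    chrom: str
    dyad_start: int
    plus_methylated: int
    plus_unmethylated: int
    minus_methylated: int
    minus_unmethylated: int


@dataclass
class HemiSummary:
    """Candidate and hemimethylated dyad counts, and their ratio."""

    n_candidates: int
    n_hemimethylated: int

    @property
    def proportion(self) -> float:
        if self.n_candidates == 0:
            return math.nan
        return self.n_hemimethylated / self.n_candidates


@dataclass
class HemiComparison:
    """Difference in hemimethylation proportions with a two-proportion test."""

    proportion_a: float
    proportion_b: float
    difference: float
    statistic: float
    p_value: float


class DuplicateSiteError(ValueError):
    """Two records for the same (chrom, pos, strand) in one sample."""


def pair_dyads(records: pd.DataFrame) -> pd.DataFrame:
    """Pair strand-resolved CG records into dyads.

    Input records may contain any context; only CG records are used.  A
    plus-strand C at 1-based pos p sits at 0-based p-1 = dyad_start; its
    partner is the minus-strand C at 0-based p (1-based p+1).  Unpaired
    strands yield dyads with zero counts on the missing strand.
    """
    cg = records.loc[records["context"] == "CG"]
    dup = cg.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        first = cg.loc[dup].iloc[0]
        raise DuplicateSiteError(
            f"duplicate CG record at {first['chrom']}:{first['pos']} ({first['strand']})"
        )

    plus = cg.loc[cg["strand"] == "+", ["chrom", "pos", "count_methylated", "count_unmethylated"]].copy()
    plus["dyad_start"] = plus["pos"] - 1
    minus = cg.loc[cg["strand"] == "-", ["chrom", "pos", "count_methylated", "count_unmethylated"]].copy()
    minus["dyad_start"] = minus["pos"] - 2

    merged = plus.merge(
        minus,
        on=["chrom", "dyad_start"],
        how="outer",
        suffixes=("_plus", "_minus"),
    )
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "dyad_start": merged["dyad_start"].astype("int64"),
            "plus_methylated": merged["count_methylated_plus"].fillna(0).astype("int64"),
            "plus_unmethylated": merged["count_unmethylated_plus"].fillna(0).astype("int64"),
            "minus_methylated": merged["count_methylated_minus"].fillna(0).astype("int64"),
            "minus_unmethylated": merged["count_unmethylated_minus"].fillna(0).astype("int64"),
        }
    )
    return out.sort_values(["chrom", "dyad_start"], ignore_index=True)


def _fisher_pvalues(tables: np.ndarray) -> np.ndarray:
    """Two-sided Fisher exact p for each (a, b, c, d) row, deduplicated.

    Sequencing depths repeat heavily, so unique tables are tested once and
    results broadcast back.
    """
    if len(tables) == 0:
        return np.empty(0)
    unique, inverse = np.unique(tables, axis=0, return_inverse=True)
    pvals = np.empty(len(unique))
    for i, (a, b, c, d) in enumerate(unique):
        pvals[i] = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    return pvals[inverse]


def call_hemimethylation(
    dyads: pd.DataFrame,
    min_depth: int = 10,
    level_threshold: float = 0.7,
    alpha: float = 0.05,
    depth_rule: str = "per_strand",
) -> tuple[pd.DataFrame, HemiSummary]:
    """Call hemimethylated dyads and summarize their frequency.

    A dyad is a *candidate* when it passes the depth rule and at least one
    strand has methylation level >= ``level_threshold``.  ``depth_rule``:

    - ``"per_strand"`` (default): each strand independently needs depth >=
      ``min_depth`` — the exact test is powerless on a near-empty strand;
    - ``"combined"``: plus+minus total depth >= ``min_depth``.

    Candidates are tested with a two-sided Fisher exact test on the table
    [[plus_meth, plus_unmeth], [minus_meth, minus_unmeth]]; a candidate with
    p < ``alpha`` is called hemimethylated.  No multiple-testing correction
    is applied (the cutoff is a raw p threshold by design).  Non-candidates
    get NaN p-values.
    """
    if not (0 < level_threshold <= 1) or not (0 < alpha < 1) or min_depth < 1:
        raise ValueError("thresholds out of range")

    calls = dyads.copy().reset_index(drop=True)
    plus_depth = calls["plus_methylated"] + calls["plus_unmethylated"]
    minus_depth = calls["minus_methylated"] + calls["minus_unmethylated"]
    with np.errstate(invalid="ignore"):
        calls["plus_level"] = np.where(
            plus_depth > 0, calls["plus_methylated"] / np.maximum(plus_depth, 1), np.nan
        )
        calls["minus_level"] = np.where(
            minus_depth > 0, calls["minus_methylated"] / np.maximum(minus_depth, 1), np.nan
        )

    if depth_rule == "per_strand":
        depth_ok = (plus_depth >= min_depth) & (minus_depth >= min_depth)
    elif depth_rule == "combined":
        depth_ok = (plus_depth + minus_depth) >= min_depth
    else:
        raise ValueError(f"unknown depth_rule {depth_rule!r}")
    level_ok = (calls["plus_level"] >= level_threshold) | (
        calls["minus_level"] >= level_threshold
    )
    calls["is_candidate"] = (depth_ok & level_ok.fillna(False)).to_numpy()

    calls["p_value"] = np.nan
    cand_idx = np.flatnonzero(calls["is_candidate"].to_numpy())
    tables = calls.loc[
        calls["is_candidate"],
        ["plus_methylated", "plus_unmethylated", "minus_methylated", "minus_unmethylated"],
    ].to_numpy()
    calls.loc[calls.index[cand_idx], "p_value"] = _fisher_pvalues(tables)
    calls["is_hemimethylated"] = calls["is_candidate"] & (calls["p_value"] < alpha)

    summary = HemiSummary(
        n_candidates=int(calls["is_candidate"].sum()),
        n_hemimethylated=int(calls["is_hemimethylated"].sum()),
    )
    return calls, summary


def compare_hemi_proportions(a: HemiSummary, b: HemiSummary) -> HemiComparison:
    """Difference a − b in hemimethylation proportions, two-proportion chi²."""
    if a.n_candidates == 0 or b.n_candidates == 0:
        raise ValueError("both summaries need candidates to compare")
    stat, p, _ = proportions_chisquare(
        count=[a.n_hemimethylated, b.n_hemimethylated],
        nobs=[a.n_candidates, b.n_candidates],
    )
    if a.proportion == b.proportion:
        stat, p = 0.0, 1.0  # degenerate identical proportions
    return HemiComparison(
        proportion_a=a.proportion,
        proportion_b=b.proportion,
        difference=a.proportion - b.proportion,
        statistic=float(stat),
        p_value=float(p),
    )
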