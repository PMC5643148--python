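"""Depth-weighted methylation summaries.

Throughout this package the "global" methylation level of a set of cytosines
is the weighted level: total methylated read counts divided by total read
counts over the covered sites.  This takes sequencing depth into account and
is invariant under arbitrary splitting or merging of the record stream,
unlike an unweighted mean of per-site levels.  An undefined level (empty
denominator) is signalled with NaN, which is distinct from a measured 0.0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import GenomicInterval

logger = logging.getLogger(__name__)

#: Context filters accepted by the summary operations.  "nonCG" pools CHG+CHH;
#: None (or "all") pools every context.
CONTEXT_FILTERS = ("CG", "CHG", "CHH", "nonCG", "all")

WINDOW_COLUMNS = (
    "chrom",
    "start",
    "end",
    "context",
    "pooled_methylated",
    "pooled_unmethylated",
    "n_sites_covered",
    "level",
    "excluded",
)


@dataclass(frozen=True)
class WindowMethylation:
    """A genomic interval with pooled counts and a depth-weighted level."""

    interval: GenomicInterval
    context: str
    pooled_methylated: int
    pooled_unmethylated: int
    n_sites_covered: int

    @property
    def level(self) -> float:
        depth = self.pooled_methylated + self.pooled_unmethylated
        if depth == 0:
            return math.nan
        return self.pooled_methylated / depth


@dataclass
class SampleSummary:
    """Headline numbers for one sample: global levels and feature-class levels."""

    sample_id: str
    labels: dict = field(default_factory=dict)
    global_levels: dict = field(default_factory=dict)  # context -> level
    feature_class_levels: dict = field(default_factory=dict)  # class -> level
    conversion_rate: float = math.nan

    @property
    def global_cg_level(self) -> float:
        return self.global_levels.get("CG", math.nan)


def _context_mask(records: pd.DataFrame, context: str | None) -> pd.Series:
    if context is None or context == "all":
        return pd.Series(True, index=records.index)
    if context == "nonCG":
        return records["context"].isin(["CHG", "CHH"]).astype(bool)
    if context not in ("CG", "CHG", "CHH"):
        raise ValueError(f"unknown context filter {context!r}")
    return (records["context"] == context).astype(bool)


def weighted_level(records: pd.DataFrame, context: str | None = "CG") -> float:
    """Depth-weighted methylation level of the filtered sites.

    Returns ``sum(count_methylated) / sum(count_methylated + count_unmethylated)``,
    or NaN when the filtered stream has zero total depth.
    """
    sub = records.loc[_context_mask(records, context)]
    meth = int(sub["count_methylated"].sum())
    total = meth + int(sub["count_unmethylated"].sum())
    if total == 0:
        return math.nan
    return meth / total


def tile_windows(
    records: pd.DataFrame,
    window_size: int,
    genome_spec: list[tuple[str, int]],
    context: str | None = "CG",
    min_sites: int = 5,
    min_site_depth: int = 1,
    on_unknown_chrom: str = "warn",
) -> pd.DataFrame:
    """Pool counts into non-overlapping tiles anchored at 0 per chromosome.

    Tiles are half-open and the last partial tile is retained.  Sites with
    depth >= ``min_site_depth`` contribute; windows with fewer than
    ``min_sites`` covered context-matching sites are flagged ``excluded``
    (they are still listed, with their level, so callers decide).

    Records on chromosomes absent from ``genome_spec`` are skipped with a
    warning, or raise when ``on_unknown_chrom="error"``.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    lengths = dict(genome_spec)
    if len(lengths) != len(genome_spec):
        raise ValueError("duplicate chromosome in genome_spec")

    sub = records.loc[_context_mask(records, context)].copy()
    depth = sub["count_methylated"] + sub["count_unmethylated"]
    sub = sub.loc[depth >= min_site_depth]

    unknown = ~sub["chrom"].isin(lengths)
    if unknown.any():
        n_unknown = int(unknown.sum())
        if on_unknown_chrom == "error":
            raise ValueError(
                f"{n_unknown} records on unknown chromosomes (not in genome_spec)"
            )
        logger.warning("skipping %d records on unknown chromosomes", n_unknown)
        sub = sub.loc[~unknown]

    # 1-based disk position -> 0-based, then integer tile index.
    sub["window_index"] = (sub["pos"] - 1) // window_size
    grouped = sub.groupby(["chrom", "window_index"], sort=False).agg(
        pooled_methylated=("count_methylated", "sum"),
        pooled_unmethylated=("count_unmethylated", "sum"),
        n_sites_covered=("pos", "size"),
    )

    rows = []
    for chrom, length in genome_spec:
        n_windows = max(1, -(-length // window_size))
        for widx in range(n_windows):
            start = widx * window_size
            end = min(start + window_size, length)
            key = (chrom, widx)
            if key in grouped.index:
                meth, unmeth, n_sites = (int(v) for v in grouped.loc[key])
            else:
                meth = unmeth = n_sites = 0
            total = meth + unmeth
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "context": context if context is not None else "all",
                    "pooled_methylated": meth,
                    "pooled_unmethylated": unmeth,
                    "n_sites_covered": n_sites,
                    "level": meth / total if total else math.nan,
                    "excluded": n_sites < min_sites,
                }
            )
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def feature_levels(
    records: pd.DataFrame,
    features: pd.DataFrame,
    context: str | None = "CG",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool counts over annotated features and feature classes.

    ``features`` needs columns chrom/start/end/name/feature_class (see
    ``io_formats.intervals_to_frame``).  A site overlapping k features
    contributes its counts to each of the k features, so per-class levels of
    overlapping annotations are not additive by construction.

    Returns ``(per_feature, per_class)`` tables with pooled counts and
    weighted levels.
    """
    sub = records.loc[_context_mask(records, context)]
    trees: dict[str, IntervalTree] = {}
    for idx, row in features.reset_index(drop=True).iterrows():
        if row["start"] >= row["end"]:
            raise ValueError(f"feature {row['name']} has start >= end")
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            int(row["start"]), int(row["end"]), idx
        )

    n_features = len(features)
    meth = np.zeros(n_features, dtype=np.int64)
    unmeth = np.zeros(n_features, dtype=np.int64)
    n_sites = np.zeros(n_features, dtype=np.int64)
    for chrom, chrom_records in sub.groupby("chrom", sort=False):
        tree = trees.get(chrom)
        if tree is None:
            continue
        pos0 = chrom_records["pos"].to_numpy() - 1
        cm = chrom_records["count_methylated"].to_numpy()
        cu = chrom_records["count_unmethylated"].to_numpy()
        for p, m, u in zip(pos0, cm, cu):
            for hit in tree.at(int(p)):
                fi = hit.data
                meth[fi] += m
                unmeth[fi] += u
                n_sites[fi] += 1

    per_feature = features.reset_index(drop=True).copy()
    per_feature["pooled_methylated"] = meth
    per_feature["pooled_unmethylated"] = unmeth
    per_feature["n_sites_covered"] = n_sites
    total = meth + unmeth
    with np.errstate(invalid="ignore"):
        per_feature["level"] = np.where(total > 0, meth / np.maximum(total, 1), np.nan)

    per_class = (
        per_feature.groupby("feature_class", sort=False)
        .agg(
            pooled_methylated=("pooled_methylated", "sum"),
            pooled_unmethylated=("pooled_unmethylated", "sum"),
            n_sites_covered=("n_sites_covered", "sum"),
        )
        .reset_index()
    )
    ctotal = per_class["pooled_methylated"] + per_class["pooled_unmethylated"]
    with np.errstate(invalid="ignore"):
        per_class["level"] = np.where(
            ctotal > 0, per_class["pooled_methylated"] / np.maximum(ctotal, 1), np.nan
        )
    return per_feature, per_class


def conversion_rate(
    records: pd.DataFrame, spikein_chrom: str = "lambda"
) -> float:
    """Bisulfite conversion rate from an unmethylated spike-in chromosome.

    1 minus the weighted apparent methylation over *all* cytosine contexts of
    the spike-in.  NaN when the spike-in chromosome is absent or uncovered.
    """
    sub = records.loc[records["chrom"] == spikein_chrom]
    if sub.empty:
        return math.nan
    level = weighted_level(sub, context=None)
    return math.nan if math.isnan(level) else 1.0 - level


def sample_correlation(
    a: pd.DataFrame, b: pd.DataFrame, method: str = "pearson"
) -> tuple[float, int]:
    """Correlation of window levels between two samples.

    Windows are matched on identical (chrom, start, end); only windows with a
    defined level in both samples enter.  Returns ``(r, n_windows_used)``;
    ``r`` is NaN with fewer than 2 shared windows.
    """
    merged = a.merge(
        b, on=["chrom", "start", "end"], suffixes=("_a", "_b"), how="inner"
    ).dropna(subset=["level_a", "level_b"])
    n = len(merged)
    if n < 2:
        return math.nan, n
    if method == "pearson":
        r = stats.pearsonr(merged["level_a"], merged["level_b"]).statistic
    elif method == "spearman":
        r = stats.spearmanr(merged["level_a"], merged["level_b"]).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), n


def context_split(records: pd.DataFrame) -> pd.DataFrame:
    """Per-context weighted levels and each context's share of all 5mC.

    The share is the fraction of total methylated read counts attributable
    to each context (so e.g. a non-CG 5mC share near 0.65 even though the
    per-site non-CG level is low, because non-CG sites vastly outnumber CG
    sites).
    """
    rows = []
    total_meth = int(records["count_methylated"].sum())
    for context in ("CG", "CHG", "CHH"):
        sub = records.loc[records["context"] == context]
        meth = int(sub["count_methylated"].sum())
        depth = meth + int(sub["count_unmethylated"].sum())
        rows.append(
            {
                "context": context,
                "level": meth / depth if depth else math.nan,
                "methylated_counts": meth,
                "share_of_5mc": meth / total_meth if total_meth else math.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_sample(
    records: pd.DataFrame,
    sample_id: str,
    labels: dict | None = None,
    features: pd.DataFrame | None = None,
    spikein_chrom: str | None = "lambda",
) -> SampleSummary:
    """Bundle the per-sample headline numbers into a :class:`SampleSummary`."""
    genome = records
    if spikein_chrom is not None:
        genome = records.loc[records["chrom"] != spikein_chrom]
    summary = SampleSummary(sample_id=sample_id, labels=dict(labels or {}))
    for context in ("CG", "CHG", "CHH", "nonCG"):
        summary.global_levels[context] = weighted_level(genome, context)
    if features is not None and not features.empty:
        _, per_class = feature_levels(genome, features)
        summary.feature_class_levels = dict(
            zip(per_class["feature_class"], per_class["level"])
        )
    if spikein_chrom is not None:
        summary.conversion_rate = conversion_rate(records, spikein_chrom)
    return summary
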