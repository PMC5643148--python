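"""Methylation-dynamics classification of tiling windows.

Windows that are at least moderately methylated (>= 40%) in the control
sample are split four ways by their control band and their response to the
knockout:

- Group 1: moderate (40-80%) control level, decrease < 20 percentage points;
- Group 2: moderate control level, decrease >= 20 points ("affected");
- Group 3: high (>= 80%) control level, decrease < 20 points;
- Group 4: high control level, decrease >= 20 points.

Windows below 40% in the control are Unclassified.  The decrease is the
absolute difference of levels (percentage points); a relative mode is
available behind a flag.  The moderate band is half-open [0.40, 0.80) so the
two bands partition everything >= 40%, and windows that *gain* methylation
count as unaffected.  The module also overlays transcription (RPKM) and
H3K36me3 enrichment on the groups and resolves methylation gain across the
oocyte growth stages (NGO -> P12 -> P15 -> FGO).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

logger = logging.getLogger(__name__)

GROUPS = ("Group1", "Group2", "Group3", "Group4")
LABELS = GROUPS + ("Unclassified",)

STAGES = ("ngo", "p12", "p15", "fgo")


@dataclass(frozen=True)
class FeatureExpression:
    """A feature's read count and its RPKM."""

    feature: str
    length: int
    count: int
    rpkm: float


def classify_windows(
    control: pd.DataFrame,
    ko: pd.DataFrame,
    moderate: tuple[float, float] = (0.40, 0.80),
    high: float = 0.80,
    affected_delta: float = 0.20,
    relative: bool = False,
) -> pd.DataFrame:
    """Label matched windows Group1-4 / Unclassified from control and KO levels.

    ``control`` and ``ko`` are window tables (chrom/start/end/level); windows
    are matched on identical intervals and those undefined in either sample
    are dropped (count logged and stored in ``result.attrs["n_excluded"]``).
    Boundary policy: control exactly at ``high`` is high; decrease exactly at
    ``affected_delta`` is affected.  With ``relative=True`` the decrease is
    (control - ko) / control instead of percentage points.
    """
    lo, hi = moderate
    if not (0 <= lo < hi <= high):
        raise ValueError("thresholds must satisfy 0 <= lo < hi <= high")
    merged = control.merge(
        ko, on=["chrom", "start", "end"], suffixes=("_control", "_ko"), how="inner"
    )
    n_total = max(len(control), len(ko))
    defined = merged.dropna(subset=["level_control", "level_ko"]).copy()
    n_excluded = n_total - len(defined)
    if n_excluded:
        logger.info("excluded %d windows unmatched or undefined in one sample", n_excluded)

    ctrl = defined["level_control"].to_numpy()
    kol = defined["level_ko"].to_numpy()
    decrease = ctrl - kol
    if relative:
        with np.errstate(divide="ignore", invalid="ignore"):
            decrease = np.where(ctrl > 0, decrease / ctrl, 0.0)
    # a difference of two levels carries float representation error, so a
    # window sitting exactly on the threshold (e.g. 0.60 - 0.40) counts as
    # affected despite landing at 0.19999...
    affected = decrease >= affected_delta - 1e-12
    is_moderate = (ctrl >= lo) & (ctrl < hi)
    is_high = ctrl >= high

    label = np.full(len(defined), "Unclassified", dtype=object)
    label[is_moderate & ~affected] = "Group1"
    label[is_moderate & affected] = "Group2"
    label[is_high & ~affected] = "Group3"
    label[is_high & affected] = "Group4"

    out = defined[["chrom", "start", "end", "level_control", "level_ko"]].copy()
    out["decrease"] = decrease
    out["label"] = label
    out = out.reset_index(drop=True)
    out.attrs["n_excluded"] = n_excluded
    return out


def group_affected_fractions(labels: pd.DataFrame) -> dict:
    """Fractions of moderate and high windows that the KO affected.

    Returns ``moderate_affected`` = |Group2| / (|Group1|+|Group2|) and
    ``high_affected`` = |Group4| / (|Group3|+|Group4|), with the per-group
    counts; an empty denominator yields NaN for that fraction.
    """
    counts = {g: int((labels["label"] == g).sum()) for g in LABELS}
    n_moderate = counts["Group1"] + counts["Group2"]
    n_high = counts["Group3"] + counts["Group4"]
    return {
        "counts": counts,
        "moderate_affected": counts["Group2"] / n_moderate if n_moderate else float("nan"),
        "high_affected": counts["Group4"] / n_high if n_high else float("nan"),
    }


def rpkm(counts: pd.DataFrame, total_mapped: int) -> pd.DataFrame:
    """Reads per kb of feature per million mapped reads.

    ``counts`` needs feature/length/count columns; RPKM =
    count / ((length/1000) * (total_mapped/1e6)).
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if (counts["length"] <= 0).any():
        raise ValueError("feature lengths must be positive")
    out = counts.copy()
    out["rpkm"] = out["count"] / (
        (out["length"] / 1000.0) * (total_mapped / 1e6)
    )
    return out


def overlay_groups(
    labels: pd.DataFrame,
    covariates: pd.DataFrame,
    value_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribution of per-window covariates (RPKM, H3K36me3, ...) per group.

    ``covariates`` carries chrom/start/end plus one column per covariate
    (default: every non-coordinate column); windows are matched on
    intervals.  Returns a per-group summary (n, median, quartiles) and the
    pairwise two-sided Mann-Whitney U tests between groups; groups with
    fewer than 2 windows are summarized but not tested.
    """
    merged = labels.merge(covariates, on=["chrom", "start", "end"], how="inner")
    if value_columns is None:
        value_columns = [
            c
            for c in covariates.columns
            if c not in ("chrom", "start", "end") and pd.api.types.is_numeric_dtype(covariates[c])
        ]

    summary_rows = []
    test_rows = []
    for col in value_columns:
        by_group = {
            g: merged.loc[merged["label"] == g, col].dropna().to_numpy()
            for g in LABELS
        }
        for g, values in by_group.items():
            if len(values) == 0:
                continue
            summary_rows.append(
                {
                    "covariate": col,
                    "group": g,
                    "n": len(values),
                    "median": float(np.median(values)),
                    "q1": float(np.quantile(values, 0.25)),
                    "q3": float(np.quantile(values, 0.75)),
                }
            )
        for g1, g2 in itertools.combinations(GROUPS, 2):
            v1, v2 = by_group[g1], by_group[g2]
            if len(v1) < 2 or len(v2) < 2:
                continue
            if np.ptp(np.concatenate([v1, v2])) == 0:
                stat, p = len(v1) * len(v2) / 2.0, 1.0  # all values tied
            else:
                stat, p = mannwhitneyu(v1, v2, alternative="two-sided")
            test_rows.append(
                {
                    "covariate": col,
                    "group_a": g1,
                    "group_b": g2,
                    "statistic": float(stat),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(summary_rows), pd.DataFrame(test_rows)


def stage_gains(
    stage_levels: pd.DataFrame,
    labels: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-window methylation gains across the three phases of oocyte growth.

    ``stage_levels`` carries chrom/start/end and level columns ``ngo``,
    ``p12``, ``p15``, ``fgo``.  Gains: early = P12 - NGO, mid = P15 - P12,
    late = FGO - P15; they telescope so early + mid + late = FGO - NGO
    exactly for every window.  Windows missing any stage are excluded (count
    logged).  With ``labels``, per-group mean gains are also returned.
    """
    missing = [s for s in STAGES if s not in stage_levels.columns]
    if missing:
        raise ValueError(f"stage_levels missing columns: {missing}")
    profiles = stage_levels.dropna(subset=list(STAGES)).copy()
    n_excluded = len(stage_levels) - len(profiles)
    if n_excluded:
        logger.info("excluded %d windows missing a stage level", n_excluded)
    profiles["early_gain"] = profiles["p12"] - profiles["ngo"]
    profiles["mid_gain"] = profiles["p15"] - profiles["p12"]
    profiles["late_gain"] = profiles["fgo"] - profiles["p15"]
    profiles = profiles.reset_index(drop=True)
    profiles.attrs["n_excluded"] = n_excluded

    if labels is None:
        return profiles, None
    merged = profiles.merge(
        labels[["chrom", "start", "end", "label"]],
        on=["chrom", "start", "end"],
        how="inner",
    )
    per_group = (
        merged.groupby("label")[["early_gain", "mid_gain", "late_gain"]]
        .mean()
        .reset_index()
    )
    return profiles, per_group
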