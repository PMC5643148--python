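"""Synthetic strand-resolved, allele-tagged methylome generator.

Every downstream stage of the pipeline is exercised on data from this
module, so its defaults encode the study conditions the analysis targets:
mouse-like CpG density (~10 dyads/kb), a fully grown oocyte (FGO) global CG
level of 38.7% in the control genotype and 30.8% in the *Uhrf1*-KO
genotype, per-site non-CG methylation of 3.2% (control) spread over a
non-CG cytosine density high enough that roughly two-thirds of all 5mC
falls at non-CG sites, and replication-coupled dilution of the maternal
genome to x0.37 of its FGO level by the blastocyst stage (x0.10 in the
maternal KO).

Model structure
---------------
The genome is tiled into fixed windows, each assigned one *window class*
(quota-exact, spatially shuffled) that carries a CG-level trajectory across
the oocyte stages (NGO, P12, P15, FGO), a transcription category, and
target RPKM / H3K36me3 scalars.  Highly methylated windows correspond to
transcribed units, and the KO genotype's class table plants the structure
the window-dynamics module is meant to recover: a moderately methylated,
untranscribed, late-methylating class that loses most of its methylation in
the KO.

Each CG dyad in a window with target level p is drawn *methylated* with
probability q = p / (1 - h/2), where h is ``hemi_fraction``; a methylated
dyad becomes hemimethylated (one strand only, chosen at random) with
probability h, otherwise both strands are methylated.  The q adjustment
keeps the expected level exactly p.  Hemimethylation is injected into every
dyad drawn methylated — exactly the dyads whose site-level methylation is
high, i.e. the selection domain of the hemimethylation caller — so the
injected fraction is the caller's estimand.  Class targets are rescaled
once (monotone root-find) so the expected genome-wide weighted CG level
equals ``global_cg_level`` exactly for the realized window layout.

Read counts are Poisson per strand (standard minimal model for shotgun
coverage); each read reports methylation with a small symmetric error
(bisulfite non-conversion / sequencing error, default 0.5%), which is what
the lambda spike-in conversion-rate estimate measures.  Non-CG sites are
independent single-strand sites at uniform density (non-CG methylation is
strand-asymmetric by nature).  SNPs are placed preferentially in
transcribed windows (mirroring the genic enrichment of informative SNPs in
real crosses); a site is allele-taggable when a SNP lies within one read
length.

Layout (window classes, site positions, SNPs) is governed by
``layout_seed`` and the stochastic draws by ``seed``, so samples simulated
with different seeds share a genome and can be compared window by window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import REPORT_COLUMNS

STAGES = ("NGO", "P12", "P15", "FGO")
_STREAMS = {"NGO": 1, "P12": 2, "P15": 3, "FGO": 4, "blastocyst": 5, "expression": 6}

#: Length of the unmethylated lambda-phage-like spike-in chromosome (bp).
SPIKEIN_LENGTH = 48_502

#: Aggregate survival of maternal-genome methylation across preimplantation
#: cleavage in the two genotypes (blastocyst maternal level / FGO level):
#: 14.3/38.7 in the control and 3.1/30.8 in the maternal KO.
CONTROL_PREIMPLANTATION_SURVIVAL = 14.3 / 38.7
UHRF1_KO_PREIMPLANTATION_SURVIVAL = 3.1 / 30.8


@dataclass(frozen=True)
class WindowClassSpec:
    """One window class: genome fraction, stage trajectory, transcription."""

    name: str
    fraction: float
    stage_levels: dict  # stage -> target CG level in [0, 1]
    transcription: str  # untranscribed / low / mid / high
    rpkm: float
    k36: float


def control_classes() -> tuple[WindowClassSpec, ...]:
    """Control-genotype FGO window classes.

    Half the genome is a lowly methylated untranscribed background;
    transcribed windows carry moderate-to-high methylation gained mostly
    early in oocyte growth; one moderately methylated *untranscribed* class
    gains its methylation late.  Mixture means: FGO ~0.387, NGO ~0.023.
    """
    return (
        WindowClassSpec(
            "background", 0.52,
            {"NGO": 0.018, "P12": 0.035, "P15": 0.055, "FGO": 0.08},
            "untranscribed", 0.05, 0.2,
        ),
        WindowClassSpec(
            "moderate_transcribed", 0.195,
            {"NGO": 0.025, "P12": 0.35, "P15": 0.48, "FGO": 0.60},
            "mid", 6.0, 1.5,
        ),
        WindowClassSpec(
            "moderate_untranscribed_late", 0.105,
            {"NGO": 0.02, "P12": 0.10, "P15": 0.20, "FGO": 0.60},
            "untranscribed", 0.05, 0.25,
        ),
        WindowClassSpec(
            "high_transcribed", 0.1638,
            {"NGO": 0.04, "P12": 0.55, "P15": 0.75, "FGO": 0.92},
            "high", 40.0, 3.0,
        ),
        WindowClassSpec(
            "high_late", 0.0162,
            {"NGO": 0.03, "P12": 0.20, "P15": 0.40, "FGO": 0.92},
            "low", 1.0, 0.8,
        ),
    )


def uhrf1_ko_classes() -> tuple[WindowClassSpec, ...]:
    """KO-genotype FGO classes: late-methylating untranscribed windows lose
    most of their methylation; transcribed windows are only slightly
    affected.  Mixture FGO mean ~0.313 (calibrated to 0.308)."""
    ko_fgo = {
        "background": 0.05,
        "moderate_transcribed": 0.55,
        "moderate_untranscribed_late": 0.25,
        "high_transcribed": 0.88,
        "high_late": 0.60,
    }
    out = []
    for spec in control_classes():
        levels = dict(spec.stage_levels)
        levels["FGO"] = ko_fgo[spec.name]
        out.append(dataclasses.replace(spec, stage_levels=levels))
    return tuple(out)


def dnmt1_ko_classes() -> tuple[WindowClassSpec, ...]:
    """Dnmt1-KO FGO classes: a mild uniform deficit (global 36.0% vs 38.7%)."""
    out = []
    for spec in control_classes():
        levels = dict(spec.stage_levels)
        levels["FGO"] = spec.stage_levels["FGO"] * (36.0 / 38.7)
        out.append(dataclasses.replace(spec, stage_levels=levels))
    return tuple(out)


def sperm_like_classes(level: float = 0.166 / CONTROL_PREIMPLANTATION_SURVIVAL) -> tuple[WindowClassSpec, ...]:
    """A uniform paternal gamete genome.

    Default level 0.449 is chosen so that after control preimplantation
    dilution (x0.37) the paternal blastocyst genome sits at 16.6%.
    """
    return (
        WindowClassSpec(
            "paternal_uniform", 1.0,
            {stage: level for stage in STAGES},
            "untranscribed", 0.0, 0.2,
        ),
    )


@dataclass
class SimulationConfig:
    """Parameters of one simulated sample; defaults are the control FGO.

    ``global_cg_level`` is the *true* genome-wide weighted CG level the
    class mixture is calibrated to at ``calibration_stage`` (the observed
    level additionally carries the read error rate); set it to None to use
    the class stage levels as-is.  ``dilution_survival`` is the per-cell-
    cycle maintenance probability used by the blastocyst simulation.
    """

    genome_spec: tuple = (("chr1", 3_000_000), ("chr2", 2_000_000))
    window_size: int = 10_000
    cg_density: float = 10.0  # CG dyads per kb
    noncg_density: float = 450.0  # non-CG cytosines per kb (both strands pooled)
    global_cg_level: float | None = 0.387
    global_noncg_level: float = 0.032
    hemi_fraction: float = 0.04
    depth_mean: float = 20.0  # mean read depth per strand
    error_rate: float = 0.005  # bisulfite non-conversion / sequencing error
    classes: tuple = field(default_factory=control_classes)
    calibration_stage: str = "FGO"
    spikein_chrom: str | None = "lambda"
    snp_density: float = 2.0  # SNPs per kb
    snp_transcribed_bias: float = 1.2
    read_length: int = 96
    dilution_survival: float = CONTROL_PREIMPLANTATION_SURVIVAL ** (1 / 5)
    total_mapped_reads: int = 2_000_000
    seed: int = 0
    layout_seed: int = 0

    @property
    def transcribed_fraction(self) -> float:
        return sum(c.fraction for c in self.classes if c.transcription != "untranscribed")

    @property
    def level_by_transcription(self) -> dict:
        """FGO target level per transcription category (depth-weighted mean)."""
        levels: dict[str, list] = {}
        for c in self.classes:
            levels.setdefault(c.transcription, []).append(
                (c.fraction, c.stage_levels["FGO"])
            )
        return {
            k: sum(f * l for f, l in v) / sum(f for f, _ in v)
            for k, v in levels.items()
        }

    def validate(self) -> None:
        if not self.genome_spec or any(length <= 0 for _, length in self.genome_spec):
            raise ValueError("genome_spec must list chromosomes with positive length")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.window_size <= 0 or self.cg_density <= 0:
            raise ValueError("window_size and cg_density must be positive")
        probs = [self.global_noncg_level, self.hemi_fraction, self.error_rate]
        if self.global_cg_level is not None:
            probs.append(self.global_cg_level)
        for c in self.classes:
            probs.extend(c.stage_levels.values())
            probs.append(c.fraction)
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(c.fraction for c in self.classes) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if not (0 <= self.dilution_survival <= 1):
            raise ValueError("dilution_survival must lie in [0, 1]")


def control_fgo_config(seed: int = 0, **overrides) -> SimulationConfig:
    return dataclasses.replace(SimulationConfig(seed=seed), **overrides)


def uhrf1_ko_fgo_config(seed: int = 0, **overrides) -> SimulationConfig:
    base = SimulationConfig(
        seed=seed,
        classes=uhrf1_ko_classes(),
        global_cg_level=0.308,
        global_noncg_level=0.026,  # 85% of the control per-site non-CG level
        hemi_fraction=0.129,
        dilution_survival=UHRF1_KO_PREIMPLANTATION_SURVIVAL ** (1 / 5),
    )
    return dataclasses.replace(base, **overrides)


def dnmt1_ko_fgo_config(seed: int = 0, **overrides) -> SimulationConfig:
    base = SimulationConfig(
        seed=seed,
        classes=dnmt1_ko_classes(),
        global_cg_level=0.360,
        global_noncg_level=0.035,
        hemi_fraction=0.068,
    )
    return dataclasses.replace(base, **overrides)


def sperm_config(seed: int = 0, **overrides) -> SimulationConfig:
    base = SimulationConfig(
        seed=seed,
        classes=sperm_like_classes(),
        global_cg_level=None,
        global_noncg_level=0.002,
        hemi_fraction=0.0,
    )
    return dataclasses.replace(base, **overrides)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated gamete-stage sample.

    ``dyads`` has one row per CG dyad (chrom, dyad_start, window_index,
    class_name, plus_state, minus_state, is_hemi, taggable); spike-in dyads
    carry window_index -1 and class_name "spikein".  ``windows`` carries the
    per-window class and calibrated stage targets; ``noncg`` the single-
    strand non-CG sites; ``snps`` the parental SNP table.
    """

    stage: str
    config: SimulationConfig
    windows: pd.DataFrame
    dyads: pd.DataFrame
    noncg: pd.DataFrame
    snps: pd.DataFrame

    def genome_dyads(self) -> pd.DataFrame:
        return self.dyads.loc[self.dyads["window_index"] >= 0]

    def true_cg_level(self) -> float:
        d = self.genome_dyads()
        return float((d["plus_state"].to_numpy() + d["minus_state"].to_numpy()).mean() / 2)

    def true_hemi_fraction(self) -> float:
        """Fraction hemimethylated among dyads with any methylation."""
        d = self.genome_dyads()
        meth = (d["plus_state"] | d["minus_state"]).to_numpy(bool)
        if meth.sum() == 0:
            return float("nan")
        return float(d.loc[meth, "is_hemi"].mean())


@dataclass
class BlastocystTruth:
    """Ground truth of a simulated blastocyst (per-allele dyad states)."""

    config: SimulationConfig
    n_cycles: int
    maintenance_prob: float
    windows: pd.DataFrame
    dyads: pd.DataFrame  # maternal_/paternal_ x plus_/minus_state + taggable
    noncg: pd.DataFrame
    snps: pd.DataFrame

    def true_allele_cg_level(self, allele: str) -> float:
        d = self.dyads.loc[self.dyads["window_index"] >= 0]
        plus = d[f"{allele}_plus_state"].to_numpy()
        minus = d[f"{allele}_minus_state"].to_numpy()
        return float((plus + minus).mean() / 2)


# ---------------------------------------------------------------------------
# layout


def _layout_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.layout_seed))


def _draw_rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((config.seed, _STREAMS[stream]))
    )


def _build_windows(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    index = 0
    for chrom, length in config.genome_spec:
        start = 0
        while start < length:
            rows.append(
                {"chrom": chrom, "start": start, "end": min(start + config.window_size, length), "window_index": index}
            )
            index += 1
            start += config.window_size
    windows = pd.DataFrame(rows)
    n = len(windows)

    # quota-exact class counts (largest remainder), spatially shuffled
    fractions = np.array([c.fraction for c in config.classes])
    ideal = fractions * n
    counts = np.floor(ideal).astype(int)
    remainder = n - counts.sum()
    if remainder:
        order = np.argsort(-(ideal - counts))
        counts[order[:remainder]] += 1
    assignment = np.repeat(np.arange(len(config.classes)), counts)
    rng.shuffle(assignment)

    windows["class_name"] = [config.classes[i].name for i in assignment]
    windows["transcription"] = [config.classes[i].transcription for i in assignment]
    windows["rpkm_target"] = [config.classes[i].rpkm for i in assignment]
    windows["k36_target"] = [config.classes[i].k36 for i in assignment]
    for stage in STAGES:
        windows[f"raw_{stage}"] = [config.classes[i].stage_levels[stage] for i in assignment]
    return windows


def _place_dyads(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """CG dyad positions: distinct even 0-based starts, so dyads never overlap."""
    frames = []
    for chrom, length in config.genome_spec:
        n = int(round(length * config.cg_density / 1000.0))
        n_slots = (length - 1) // 2
        if n > n_slots:
            raise ValueError(f"cg_density too high for chromosome {chrom}")
        starts = np.sort(rng.choice(n_slots, size=n, replace=False)) * 2
        frames.append(pd.DataFrame({"chrom": chrom, "dyad_start": starts}))
    return pd.concat(frames, ignore_index=True)


def _place_noncg(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    frames = []
    for chrom, length in config.genome_spec:
        n = int(round(length * config.noncg_density / 1000.0))
        if n == 0:
            continue
        pos0 = np.sort(rng.choice(length, size=min(n, length), replace=False))
        strand = np.where(rng.random(len(pos0)) < 0.5, "+", "-")
        is_chg = rng.random(len(pos0)) < 0.25
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos0": pos0, "strand": strand, "is_chg": is_chg}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos0", "strand", "is_chg"])
    return pd.concat(frames, ignore_index=True)


def _place_snps(
    config: SimulationConfig, windows: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    bases = np.array(list("ACGT"))
    for chrom, length in config.genome_spec:
        n = int(round(length * config.snp_density / 1000.0))
        if n == 0:
            continue
        chrom_windows = windows.loc[windows["chrom"] == chrom]
        weights = np.where(
            chrom_windows["transcription"].to_numpy() != "untranscribed",
            config.snp_transcribed_bias,
            1.0,
        )
        weights = weights / weights.sum()
        chosen = rng.choice(len(chrom_windows), size=n, p=weights)
        starts = chrom_windows["start"].to_numpy()[chosen]
        ends = chrom_windows["end"].to_numpy()[chosen]
        pos0 = starts + (rng.random(n) * (ends - starts)).astype(int)
        mat_idx = rng.integers(0, 4, size=n)
        pat_idx = (mat_idx + rng.integers(1, 4, size=n)) % 4
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.sort(pos0) + 1,  # 1-based on disk
                    "maternal_base": bases[mat_idx],
                    "paternal_base": bases[pat_idx],
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos", "maternal_base", "paternal_base"])
    return pd.concat(rows, ignore_index=True)


def _taggable(
    positions: np.ndarray, chroms: np.ndarray, snps: pd.DataFrame, read_length: int
) -> np.ndarray:
    """True where a SNP lies within one read length of the site (0-based pos)."""
    out = np.zeros(len(positions), dtype=bool)
    for chrom, sub in snps.groupby("chrom", sort=False):
        mask = chroms == chrom
        if not mask.any():
            continue
        snp_pos0 = np.sort(sub["pos"].to_numpy() - 1)
        pos = positions[mask]
        idx = np.searchsorted(snp_pos0, pos)
        left = np.where(idx > 0, pos - snp_pos0[np.maximum(idx - 1, 0)], np.iinfo(np.int64).max)
        right = np.where(
            idx < len(snp_pos0), snp_pos0[np.minimum(idx, len(snp_pos0) - 1)] - pos, np.iinfo(np.int64).max
        )
        out[mask] = np.minimum(left, right) <= read_length
    return out


def _calibrate_targets(
    config: SimulationConfig, windows: pd.DataFrame, dyads_per_window: np.ndarray, stage: str
) -> np.ndarray:
    """Per-window target levels, rescaled so the dyad-weighted mean hits the
    configured global level exactly at the calibration stage."""
    raw = windows[f"raw_{stage}"].to_numpy(float)
    cap = 1.0 - config.hemi_fraction / 2.0
    target = config.global_cg_level
    if target is None or stage != config.calibration_stage:
        return np.minimum(raw, cap)
    weights = dyads_per_window / max(dyads_per_window.sum(), 1)

    def realized(scale: float) -> float:
        return float(np.sum(weights * np.minimum(scale * raw, cap))) - target

    max_level = float(np.sum(weights * np.where(raw > 0, cap, 0.0)))
    if target > max_level + 1e-12:
        raise ValueError(
            f"global_cg_level {target} unreachable with this class mixture (max {max_level:.3f})"
        )
    if target == 0:
        return np.zeros_like(raw)
    if target >= max_level - 1e-12:  # saturate every window with a nonzero class level
        return np.where(raw > 0, cap, 0.0)
    scale = brentq(realized, 0.0, cap / max(raw[raw > 0].min(), 1e-12))
    return np.minimum(scale * raw, cap)


# ---------------------------------------------------------------------------
# samplers

_CG_TRIS = np.array(["CGA", "CGC", "CGG", "CGT"])
_CHG_TRIS = np.array(["CAG", "CCG", "CTG"])
_CHH_TRIS = np.array(
    ["CAA", "CAC", "CAT", "CCA", "CCC", "CCT", "CTA", "CTC", "CTT"]
)


def _observed_counts(
    states: np.ndarray, depth_mean: float, error_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson depth per site, binomial methylated counts around the state."""
    depth = rng.poisson(depth_mean, size=len(states))
    p = np.where(states > 0, 1.0 - error_rate, error_rate)
    meth = rng.binomial(depth, p)
    return meth, depth - meth


def _strand_records(
    chrom: np.ndarray,
    pos: np.ndarray,
    strand: str,
    meth: np.ndarray,
    unmeth: np.ndarray,
    context: np.ndarray | str,
    tri: np.ndarray,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "strand": strand,
            "count_methylated": meth,
            "count_unmethylated": unmeth,
            "context": context,
            "trinucleotide": tri,
        }
    )


def simulate_oocyte_methylome(
    config: SimulationConfig, stage: str = "FGO"
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate one gamete-stage sample; returns (records, truth).

    ``records`` is a per-cytosine report DataFrame (1-based positions, both
    strands of every CG dyad, single-strand non-CG sites, and an
    unmethylated spike-in chromosome when configured).
    """
    config.validate()
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    layout = _layout_rng(config)
    rng = _draw_rng(config, stage)

    windows = _build_windows(config, layout)
    dyads = _place_dyads(config, layout)
    noncg = _place_noncg(config, layout)
    snps = _place_snps(config, windows, layout)

    # map dyads onto windows (tiles are anchored at 0, so integer division)
    chrom_offsets = {}
    for chrom in dict(config.genome_spec):
        sub = windows.loc[windows["chrom"] == chrom, "window_index"]
        chrom_offsets[chrom] = int(sub.min())
    widx = (
        dyads["chrom"].map(chrom_offsets).to_numpy()
        + dyads["dyad_start"].to_numpy() // config.window_size
    )
    dyads["window_index"] = widx
    dyads_per_window = np.bincount(widx, minlength=len(windows))

    targets = _calibrate_targets(config, windows, dyads_per_window, stage)
    for st in STAGES:
        # store calibrated trajectory for the simulated stage, raw for others
        col = targets if st == stage else np.minimum(
            windows[f"raw_{st}"].to_numpy(float), 1.0 - config.hemi_fraction / 2.0
        )
        windows[f"level_{st}"] = col
    windows["target_level"] = targets
    dyads["class_name"] = windows["class_name"].to_numpy()[widx]

    # true dyad states
    h = config.hemi_fraction
    p_dyad = targets[widx]
    q = p_dyad / (1.0 - h / 2.0)
    meth_event = rng.random(len(dyads)) < q
    hemi = meth_event & (rng.random(len(dyads)) < h)
    hemi_on_plus = rng.random(len(dyads)) < 0.5
    plus_state = meth_event & (~hemi | hemi_on_plus)
    minus_state = meth_event & (~hemi | ~hemi_on_plus)
    dyads["plus_state"] = plus_state.astype(np.int8)
    dyads["minus_state"] = minus_state.astype(np.int8)
    dyads["is_hemi"] = hemi

    # spike-in: fully unmethylated extra chromosome
    if config.spikein_chrom is not None:
        n_spike = int(round(SPIKEIN_LENGTH * config.cg_density / 1000.0))
        spike_starts = np.sort(layout.choice((SPIKEIN_LENGTH - 1) // 2, n_spike, replace=False)) * 2
        spike = pd.DataFrame(
            {
                "chrom": config.spikein_chrom,
                "dyad_start": spike_starts,
                "window_index": -1,
                "class_name": "spikein",
                "plus_state": np.int8(0),
                "minus_state": np.int8(0),
                "is_hemi": False,
            }
        )
        dyads = pd.concat([dyads, spike], ignore_index=True)

    dyads["taggable"] = _taggable(
        dyads["dyad_start"].to_numpy(),
        dyads["chrom"].to_numpy(),
        snps,
        config.read_length,
    )

    # non-CG true states (independent, single strand)
    noncg = noncg.copy()
    noncg["state"] = (rng.random(len(noncg)) < config.global_noncg_level).astype(np.int8)
    if config.spikein_chrom is not None and config.noncg_density > 0:
        n_spike_nc = int(round(SPIKEIN_LENGTH * config.noncg_density / 1000.0))
        pos0 = np.sort(layout.choice(SPIKEIN_LENGTH, n_spike_nc, replace=False))
        spike_nc = pd.DataFrame(
            {
                "chrom": config.spikein_chrom,
                "pos0": pos0,
                "strand": np.where(layout.random(n_spike_nc) < 0.5, "+", "-"),
                "is_chg": layout.random(n_spike_nc) < 0.25,
                "state": np.int8(0),
            }
        )
        noncg = pd.concat([noncg, spike_nc], ignore_index=True)
    noncg["taggable"] = _taggable(
        noncg["pos0"].to_numpy(), noncg["chrom"].to_numpy(), snps, config.read_length
    )

    records = _records_from_states(
        dyads,
        noncg,
        {"plus": dyads["plus_state"].to_numpy(), "minus": dyads["minus_state"].to_numpy()},
        noncg["state"].to_numpy(),
        config.depth_mean,
        config,
        rng,
    )
    truth = SyntheticTruth(
        stage=stage, config=config, windows=windows, dyads=dyads, noncg=noncg, snps=snps
    )
    return records, truth


def _records_from_states(
    dyads: pd.DataFrame,
    noncg: pd.DataFrame,
    dyad_states: dict,
    noncg_states: np.ndarray,
    depth_mean: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    chrom = dyads["chrom"].to_numpy()
    start = dyads["dyad_start"].to_numpy()
    plus_m, plus_u = _observed_counts(dyad_states["plus"], depth_mean, config.error_rate, rng)
    minus_m, minus_u = _observed_counts(dyad_states["minus"], depth_mean, config.error_rate, rng)
    cg_tri = lambda n: _CG_TRIS[rng.integers(0, len(_CG_TRIS), n)]
    frames = [
        _strand_records(chrom, start + 1, "+", plus_m, plus_u, "CG", cg_tri(len(dyads))),
        _strand_records(chrom, start + 2, "-", minus_m, minus_u, "CG", cg_tri(len(dyads))),
    ]
    if len(noncg):
        nc_m, nc_u = _observed_counts(noncg_states, depth_mean, config.error_rate, rng)
        is_chg = noncg["is_chg"].to_numpy()
        tri = np.where(
            is_chg,
            _CHG_TRIS[rng.integers(0, len(_CHG_TRIS), len(noncg))],
            _CHH_TRIS[rng.integers(0, len(_CHH_TRIS), len(noncg))],
        )
        frames.append(
            _strand_records(
                noncg["chrom"].to_numpy(),
                noncg["pos0"].to_numpy() + 1,
                None,  # placeholder, replaced below
                nc_m,
                nc_u,
                np.where(is_chg, "CHG", "CHH"),
                tri,
            ).assign(strand=noncg["strand"].to_numpy())
        )
    records = pd.concat(frames, ignore_index=True)
    records = records.sort_values(["chrom", "pos", "strand"], ignore_index=True)
    return records[list(REPORT_COLUMNS)]


def simulate_blastocyst_from_gametes(
    maternal: SyntheticTruth,
    paternal: SyntheticTruth,
    n_cycles: int = 5,
    maintenance_prob: float | None = None,
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, BlastocystTruth]:
    """Replication-coupled dilution of two gamete genomes into a blastocyst.

    Each methylated strand survives each of ``n_cycles`` cleavage cycles
    independently with probability ``maintenance_prob`` (default: the
    maternal config's ``dilution_survival``), so the expected final level is
    the initial level times ``maintenance_prob ** n_cycles``.  Reads are
    drawn per allele at half the configured per-strand depth; sites within
    one read length of a SNP yield allele-assigned counts, the rest are
    unassigned.

    Returns ``(records, tagged, truth)``: a merged untagged per-cytosine
    report, the per-site allele-tagged count table, and the ground truth.
    """
    config = config if config is not None else maternal.config
    if maintenance_prob is None:
        maintenance_prob = config.dilution_survival
    if n_cycles < 0 or not (0 <= maintenance_prob <= 1):
        raise ValueError("n_cycles must be >= 0 and maintenance_prob in [0, 1]")
    m_dyads = maternal.dyads.reset_index(drop=True)
    p_dyads = paternal.dyads.reset_index(drop=True)
    if not (
        m_dyads["chrom"].equals(p_dyads["chrom"])
        and m_dyads["dyad_start"].equals(p_dyads["dyad_start"])
    ):
        raise ValueError(
            "maternal and paternal truths must share a genome layout "
            "(simulate both with the same layout_seed)"
        )
    rng = _draw_rng(config, "blastocyst")
    survival = maintenance_prob**n_cycles
    n = len(m_dyads)

    def dilute(states: pd.Series) -> np.ndarray:
        keep = rng.random(n) < survival
        return (states.to_numpy(bool) & keep).astype(np.int8)

    dyads = m_dyads[["chrom", "dyad_start", "window_index", "class_name", "taggable"]].copy()
    for allele, source in (("maternal", m_dyads), ("paternal", p_dyads)):
        for strand in ("plus", "minus"):
            dyads[f"{allele}_{strand}_state"] = dilute(source[f"{strand}_state"])

    m_noncg = maternal.noncg.reset_index(drop=True)
    p_noncg = paternal.noncg.reset_index(drop=True)
    shared_noncg = len(m_noncg) == len(p_noncg) and m_noncg["pos0"].equals(p_noncg["pos0"])
    noncg = m_noncg[["chrom", "pos0", "strand", "is_chg", "taggable"]].copy()
    keep_m = rng.random(len(noncg)) < survival
    noncg["maternal_state"] = (m_noncg["state"].to_numpy(bool) & keep_m).astype(np.int8)
    if shared_noncg:
        keep_p = rng.random(len(noncg)) < survival
        noncg["paternal_state"] = (p_noncg["state"].to_numpy(bool) & keep_p).astype(np.int8)
    else:
        noncg["paternal_state"] = np.int8(0)

    half_depth = config.depth_mean / 2.0
    err = config.error_rate

    def allele_counts(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return _observed_counts(states, half_depth, err, rng)

    # per-strand site rows: CG plus, CG minus, then non-CG
    site_frames = []
    for strand, pos_off in (("plus", 1), ("minus", 2)):
        frame = pd.DataFrame(
            {
                "chrom": dyads["chrom"],
                "pos": dyads["dyad_start"] + pos_off,
                "strand": "+" if strand == "plus" else "-",
                "context": "CG",
                "taggable": dyads["taggable"],
            }
        )
        for allele in ("maternal", "paternal"):
            meth, unmeth = allele_counts(dyads[f"{allele}_{strand}_state"].to_numpy())
            frame[f"{allele}_meth"] = meth
            frame[f"{allele}_unmeth"] = unmeth
        site_frames.append(frame)
    if len(noncg):
        frame = pd.DataFrame(
            {
                "chrom": noncg["chrom"],
                "pos": noncg["pos0"] + 1,
                "strand": noncg["strand"],
                "context": np.where(noncg["is_chg"], "CHG", "CHH"),
                "taggable": noncg["taggable"],
            }
        )
        for allele in ("maternal", "paternal"):
            meth, unmeth = allele_counts(noncg[f"{allele}_state"].to_numpy())
            frame[f"{allele}_meth"] = meth
            frame[f"{allele}_unmeth"] = unmeth
        site_frames.append(frame)
    sites = pd.concat(site_frames, ignore_index=True)

    taggable = sites["taggable"].to_numpy(bool)
    tagged = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"].astype("int64"),
            "strand": sites["strand"],
            "context": sites["context"],
            "maternal_methylated": np.where(taggable, sites["maternal_meth"], 0),
            "maternal_unmethylated": np.where(taggable, sites["maternal_unmeth"], 0),
            "paternal_methylated": np.where(taggable, sites["paternal_meth"], 0),
            "paternal_unmethylated": np.where(taggable, sites["paternal_unmeth"], 0),
            "unassigned_methylated": np.where(
                ~taggable, sites["maternal_meth"] + sites["paternal_meth"], 0
            ),
            "unassigned_unmethylated": np.where(
                ~taggable, sites["maternal_unmeth"] + sites["paternal_unmeth"], 0
            ),
        }
    ).sort_values(["chrom", "pos", "strand"], ignore_index=True)

    records = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"].astype("int64"),
            "strand": sites["strand"],
            "count_methylated": sites["maternal_meth"] + sites["paternal_meth"],
            "count_unmethylated": sites["maternal_unmeth"] + sites["paternal_unmeth"],
            "context": sites["context"],
        }
    )
    tri = np.empty(len(records), dtype=object)
    cg = records["context"].to_numpy() == "CG"
    chg = records["context"].to_numpy() == "CHG"
    chh = ~cg & ~chg
    tri[cg] = _CG_TRIS[rng.integers(0, len(_CG_TRIS), int(cg.sum()))]
    tri[chg] = _CHG_TRIS[rng.integers(0, len(_CHG_TRIS), int(chg.sum()))]
    tri[chh] = _CHH_TRIS[rng.integers(0, len(_CHH_TRIS), int(chh.sum()))]
    records["trinucleotide"] = tri
    records = records.sort_values(["chrom", "pos", "strand"], ignore_index=True)[
        list(REPORT_COLUMNS)
    ]

    truth = BlastocystTruth(
        config=config,
        n_cycles=n_cycles,
        maintenance_prob=maintenance_prob,
        windows=maternal.windows,
        dyads=dyads,
        noncg=noncg,
        snps=maternal.snps,
    )
    return records, tagged, truth


def simulate_blastocyst(
    genotype: str = "control", seed: int = 0, n_cycles: int = 5, **overrides
) -> tuple[pd.DataFrame, pd.DataFrame, BlastocystTruth]:
    """Convenience wrapper: gametes plus dilution for one genotype.

    ``genotype`` "control" pairs a control FGO with wild-type sperm under
    normal maintenance; "uhrf1_ko" pairs a KO FGO with the same sperm under
    the reduced maternal-KO maintenance.  Gamete draw seeds are derived from
    ``seed``; both gametes share the layout so dyads align.
    """
    if genotype == "control":
        ocfg = control_fgo_config(seed=seed, **overrides)
    elif genotype == "uhrf1_ko":
        ocfg = uhrf1_ko_fgo_config(seed=seed, **overrides)
    else:
        raise ValueError(f"unknown genotype {genotype!r}")
    scfg = sperm_config(
        seed=seed + 1,
        genome_spec=ocfg.genome_spec,
        window_size=ocfg.window_size,
        cg_density=ocfg.cg_density,
        noncg_density=ocfg.noncg_density,
        depth_mean=ocfg.depth_mean,
        error_rate=ocfg.error_rate,
        spikein_chrom=ocfg.spikein_chrom,
        snp_density=ocfg.snp_density,
        layout_seed=ocfg.layout_seed,
    )
    _, maternal = simulate_oocyte_methylome(ocfg, "FGO")
    _, paternal = simulate_oocyte_methylome(scfg, "FGO")
    return simulate_blastocyst_from_gametes(
        maternal, paternal, n_cycles=n_cycles, maintenance_prob=ocfg.dilution_survival, config=ocfg
    )


def simulate_expression_table(
    config: SimulationConfig,
    truth: SyntheticTruth,
    transcribed_fraction: float | None = None,
) -> tuple[pd.DataFrame, int]:
    """Per-window read counts, lengths and H3K36me3 enrichment.

    Counts are Poisson around each window's target RPKM (with lognormal
    window-to-window dispersion), so windows of more highly transcribed
    classes receive stochastically larger RPKM.  ``transcribed_fraction=0``
    silences every window.  Returns ``(features, total_mapped_reads)``.
    """
    rng = _draw_rng(config, "expression")
    windows = truth.windows
    length = (windows["end"] - windows["start"]).to_numpy()
    rpkm_target = windows["rpkm_target"].to_numpy(float).copy()
    if transcribed_fraction is not None:
        if transcribed_fraction == 0:
            rpkm_target[:] = 0.0
        else:
            base = config.transcribed_fraction
            if base > 0:
                rpkm_target *= transcribed_fraction / base
    dispersion = rng.lognormal(mean=0.0, sigma=0.5, size=len(windows))
    expected = rpkm_target * (length / 1000.0) * (config.total_mapped_reads / 1e6) * dispersion
    counts = rng.poisson(expected)
    k36 = windows["k36_target"].to_numpy(float) * rng.lognormal(0.0, 0.3, size=len(windows))
    features = pd.DataFrame(
        {
            "feature": [f"w{w}" for w in windows["window_index"]],
            "chrom": windows["chrom"],
            "start": windows["start"],
            "end": windows["end"],
            "length": length,
            "count": counts,
            "k36_enrichment": k36,
        }
    )
    return features, int(config.total_mapped_reads)
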