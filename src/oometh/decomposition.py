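"""De novo vs maintenance decomposition of maternal-genome methylation loss.

During oocyte growth the maternal genome gains methylation de novo (no DNA
replication occurs); after fertilization, maintenance failure causes
replication-coupled dilution across preimplantation cell cycles.  A
knockout restricted to the oocyte can therefore reduce blastocyst
maternal-genome methylation through two routes: a smaller de novo endowment
at fertilization, and weaker maintenance in the embryo.  The model
separates the two with four measured levels:

- ``L_fgo_ctrl``, ``L_fgo_ko``: global CG level of control / KO fully grown
  oocytes — the maternal genome's state at fertilization;
- ``L_blast_mat_ctrl``, ``L_blast_mat_ko``: maternal-allele CG level of
  control / KO blastocysts.

The control dilution factor ``f = L_blast_mat_ctrl / L_fgo_ctrl`` summarizes
normal preimplantation loss.  Applying it to the KO oocyte level gives the
level expected from the oocyte defect alone, ``E = L_fgo_ko * f``; the part
of the total loss ``T = L_blast_mat_ctrl - L_blast_mat_ko`` not explained by
it, ``D = L_blast_mat_ctrl - E``, is the de novo component, and the
remainder ``M = T - D`` is the embryonic maintenance component.  The model
assumes a uniform maternal dilution factor and attributes all
paternal-genome loss to maintenance.

Two rounding modes are provided: ``full_precision`` (default) rounds nothing
until reporting, while ``printed`` rounds f to 2 decimals and each level to
1 decimal (percent scale) before the next step, reproducing table-style
chained arithmetic bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal


@dataclass(frozen=True)
class DecompositionInputs:
    """The four measured CG levels, in percent or as fractions.

    Units are auto-detected (any value > 1.5 means percent) unless ``units``
    is given explicitly; results are always reported in percent.
    """

    fgo_control: float
    blastocyst_maternal_control: float
    fgo_ko: float
    blastocyst_maternal_ko: float
    units: str | None = None  # "percent", "fraction", or None = auto

    def as_percent(self) -> "DecompositionInputs":
        values = (
            self.fgo_control,
            self.blastocyst_maternal_control,
            self.fgo_ko,
            self.blastocyst_maternal_ko,
        )
        if any(not (0 <= v <= 100) for v in values):
            raise ValueError(f"levels out of range: {values}")
        units = self.units
        if units is None:
            units = "percent" if any(v > 1.5 for v in values) else "fraction"
        if units == "percent":
            scaled = values
        elif units == "fraction":
            if any(v > 1 for v in values):
                raise ValueError("fraction units but a level exceeds 1")
            scaled = tuple(100.0 * v for v in values)
        else:
            raise ValueError(f"unknown units {units!r}")
        if scaled[0] == 0:
            raise ValueError("control FGO level must be positive")
        return DecompositionInputs(*scaled, units="percent")


@dataclass(frozen=True)
class DecompositionResult:
    """Dilution factor and the de novo / maintenance partition, in percent.

    ``de_novo + maintenance == total_loss`` holds exactly in both rounding
    modes because maintenance is defined as the remainder.
    """

    dilution_factor: float
    expected_ko_level: float
    total_loss: float
    de_novo: float
    maintenance: float
    mode: str


def _round_half_up(x: float, ndigits: int) -> float:
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def decompose(
    inputs: DecompositionInputs, mode: str = "full_precision"
) -> DecompositionResult:
    """Partition the maternal-genome methylation loss (see module docstring)."""
    if mode not in ("full_precision", "printed"):
        raise ValueError(f"unknown mode {mode!r}")
    pct = inputs.as_percent()
    l_fgo_c = pct.fgo_control
    l_bl_c = pct.blastocyst_maternal_control
    l_fgo_k = pct.fgo_ko
    l_bl_k = pct.blastocyst_maternal_ko

    f = l_bl_c / l_fgo_c
    if mode == "printed":
        f = _round_half_up(f, 2)
    expected = l_fgo_k * f
    if mode == "printed":
        expected = _round_half_up(expected, 1)
    total_loss = l_bl_c - l_bl_k
    if mode == "printed":
        total_loss = _round_half_up(total_loss, 1)
    de_novo = l_bl_c - expected
    if mode == "printed":
        de_novo = _round_half_up(de_novo, 1)
    maintenance = total_loss - de_novo
    if mode == "printed":
        maintenance = _round_half_up(maintenance, 1)
    return DecompositionResult(
        dilution_factor=f,
        expected_ko_level=expected,
        total_loss=total_loss,
        de_novo=de_novo,
        maintenance=maintenance,
        mode=mode,
    )


def decompose_from_summaries(
    fgo_control_summary,
    blastocyst_control_tagged,
    fgo_ko_summary,
    blastocyst_ko_tagged,
    mode: str = "full_precision",
) -> DecompositionResult:
    """Extract the four inputs from pipeline outputs and decompose.

    FGO global CG levels come from ``methylation_summary.SampleSummary``
    objects; blastocyst maternal levels from allele-tagged count tables
    (``allele_methylation.TAGGED_COLUMNS``).  A missing maternal level
    raises, naming the sample.
    """
    from .allele_methylation import allele_global_levels

    levels = {}
    for name, summary in (
        ("fgo_control", fgo_control_summary),
        ("fgo_ko", fgo_ko_summary),
    ):
        level = summary.global_cg_level
        if math.isnan(level):
            raise ValueError(f"undefined global CG level in sample {name}")
        levels[name] = level
    for name, tagged in (
        ("blastocyst_control", blastocyst_control_tagged),
        ("blastocyst_ko", blastocyst_ko_tagged),
    ):
        maternal, _ = allele_global_levels(tagged, context="CG")
        if math.isnan(maternal):
            raise ValueError(f"undefined maternal-allele CG level in sample {name}")
        levels[name] = maternal

    inputs = DecompositionInputs(
        fgo_control=levels["fgo_control"],
        blastocyst_maternal_control=levels["blastocyst_control"],
        fgo_ko=levels["fgo_ko"],
        blastocyst_maternal_ko=levels["blastocyst_ko"],
    )
    return decompose(inputs, mode=mode)
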