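"""Readers and writers for the text formats the methylome pipeline touches.

Disk conventions follow the tools that produce the files: per-cytosine
reports (Bismark CX dialect) store 1-based positions, BED and bedGraph are
0-based half-open.  All internal arithmetic in this package is 0-based
half-open; the conversion happens here and only here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple

import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")

#: Column order of the on-disk per-cytosine report and of the DataFrames
#: produced by :func:`read_cytosine_report`.
REPORT_COLUMNS = (
    "chrom",
    "pos",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "trinucleotide",
)


class CytosineReportParseError(ValueError):
    """A malformed line in a per-cytosine report, with its line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class CytosineReportRecord(NamedTuple):
    """One strand-resolved cytosine with methylated/unmethylated read counts.

    ``pos`` is the 1-based position as stored on disk.
    """

    chrom: str
    pos: int
    strand: str
    count_methylated: int
    count_unmethylated: int
    context: str
    trinucleotide: str

    @property
    def depth(self) -> int:
        return self.count_methylated + self.count_unmethylated


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValueError(f"start >= end: {self}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP distinguishing the parental genomes (1-based pos)."""

    chrom: str
    pos: int
    maternal_base: str
    paternal_base: str

    def __post_init__(self):
        for base in (self.maternal_base, self.paternal_base):
            if base not in "ACGT" or len(base) != 1:
                raise ValueError(f"invalid base {base!r}")
        if self.maternal_base == self.paternal_base:
            raise ValueError(f"uninformative SNP at {self.chrom}:{self.pos}")


def to_zero_based(pos: int) -> int:
    """Convert a 1-based disk position to the internal 0-based convention."""
    return pos - 1


def to_one_based(pos0: int) -> int:
    """Convert an internal 0-based position back to the 1-based disk form."""
    return pos0 + 1


def context_of_trinucleotide(trinucleotide: str) -> str | None:
    """Classify a cytosine trinucleotide as CG/CHG/CHH; None if ambiguous.

    The trinucleotide is read 5'→3' on the cytosine's own strand, so the
    first base is the C itself.  Any N makes the context ambiguous.
    """
    tri = trinucleotide.upper()
    if len(tri) != 3 or any(b not in "ACGTN" for b in tri):
        raise ValueError(f"invalid trinucleotide {trinucleotide!r}")
    if "N" in tri:
        return None
    if tri[1] == "G":
        return "CG"
    if tri[2] == "G":
        return "CHG"
    return "CHH"


def _parse_report_line(
    line: str, line_number: int, aliases: Mapping[str, str] | None
) -> CytosineReportRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 7:
        raise CytosineReportParseError(
            line_number, f"expected 7 tab-separated columns, got {len(fields)}"
        )
    chrom, pos_s, strand, meth_s, unmeth_s, context, tri = fields
    if aliases:
        chrom = aliases.get(chrom, chrom)
    if strand not in ("+", "-"):
        raise CytosineReportParseError(line_number, f"bad strand {strand!r}")
    if context not in CONTEXTS:
        raise CytosineReportParseError(line_number, f"unknown context {context!r}")
    try:
        pos = int(pos_s)
        meth = int(meth_s)
        unmeth = int(unmeth_s)
    except ValueError as exc:
        raise CytosineReportParseError(line_number, str(exc)) from None
    if pos < 1 or meth < 0 or unmeth < 0:
        raise CytosineReportParseError(line_number, "negative count or position < 1")
    expected = context_of_trinucleotide(tri)
    if expected is not None and expected != context:
        raise CytosineReportParseError(
            line_number, f"context {context} inconsistent with trinucleotide {tri}"
        )
    return CytosineReportRecord(chrom, pos, strand, meth, unmeth, context, tri)


def iter_cytosine_report(
    path: str | Path, chrom_aliases: Mapping[str, str] | None = None
) -> Iterator[CytosineReportRecord]:
    """Stream a Bismark-style CX report line by line.

    Zero-depth lines are retained; filtering is an analysis decision, not an
    I/O one.  ``chrom_aliases`` optionally renames chromosomes on read
    (matching is otherwise exact string equality).
    """
    with open(path) as handle:
        for line_number, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            yield _parse_report_line(line, line_number, chrom_aliases)


def read_cytosine_report(
    path: str | Path, chrom_aliases: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a per-cytosine report into a DataFrame with :data:`REPORT_COLUMNS`."""
    records = list(iter_cytosine_report(path, chrom_aliases))
    return records_to_frame(records)


def records_to_frame(records: Iterable[CytosineReportRecord]) -> pd.DataFrame:
    frame = pd.DataFrame(list(records), columns=REPORT_COLUMNS)
    frame["pos"] = frame["pos"].astype("int64")
    frame["count_methylated"] = frame["count_methylated"].astype("int64")
    frame["count_unmethylated"] = frame["count_unmethylated"].astype("int64")
    return frame


def write_cytosine_report(
    records: pd.DataFrame | Iterable[CytosineReportRecord], path: str | Path
) -> None:
    """Write records back in the 7-column tab-separated disk dialect."""
    if isinstance(records, pd.DataFrame):
        records[list(REPORT_COLUMNS)].to_csv(
            path, sep="\t", header=False, index=False
        )
        return
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for rec in records:
            writer.writerow(rec)


def read_bed(
    path: str | Path, chrom_aliases: Mapping[str, str] | None = None
) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals, sorted per chromosome.

    Overlapping intervals are legal (annotations overlap); start >= end is
    not and raises ``ValueError``.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {line_number}: fewer than 3 BED columns")
            chrom = fields[0]
            if chrom_aliases:
                chrom = chrom_aliases.get(chrom, chrom)
            start, end = int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, strand))
            except ValueError as exc:
                raise ValueError(f"line {line_number}: {exc}") from None
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.strand is not None:
                fields += ["0", iv.strand]
            handle.write("\t".join(fields) + "\n")


def intervals_to_frame(
    intervals: Iterable[GenomicInterval], feature_class: str | None = None
) -> pd.DataFrame:
    """Tabulate intervals for the summary operations.

    ``feature_class`` labels every interval with one annotation class (e.g.
    "CGI", "ICR"); when omitted each interval's own name is used.
    """
    rows = []
    for iv in intervals:
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "name": iv.name if iv.name is not None else f"{iv.chrom}:{iv.start}-{iv.end}",
                "feature_class": feature_class if feature_class is not None else (iv.name or "feature"),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "feature_class"])


def write_bedgraph(windows: pd.DataFrame, path: str | Path) -> None:
    """Write window methylation as bedGraph, levels in percent (2 decimals).

    Expects the window table produced by ``methylation_summary.tile_windows``
    (columns chrom/start/end/level/n_sites_covered).  Windows with no covered
    sites are omitted.
    """
    with open(path, "w") as handle:
        for row in windows.itertuples(index=False):
            if row.n_sites_covered == 0 or pd.isna(row.level):
                continue
            handle.write(
                f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{100.0 * row.level:.2f}\n"
            )


SNP_COLUMNS = ("chrom", "pos", "maternal_base", "paternal_base")


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated SNP table (chrom, 1-based pos, maternal, paternal)."""
    frame = pd.read_csv(path, sep="\t", header=0)
    missing = set(SNP_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"SNP table missing columns: {sorted(missing)}")
    for rec in frame.itertuples(index=False):
        SnpRecord(rec.chrom, int(rec.pos), rec.maternal_base, rec.paternal_base)
    return frame[list(SNP_COLUMNS)]


def write_snp_table(snps: pd.DataFrame, path: str | Path) -> None:
    snps[list(SNP_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """Read a per-feature read-count table (feature, length, count [, ...])."""
    frame = pd.read_csv(path, sep="\t", header=0)
    required = {"feature", "length", "count"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return frame
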