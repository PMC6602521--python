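"""Readers and writers for the formats the pipeline consumes and emits.

Inputs are plain text: BED/narrowPeak peak files, a TSS annotation table,
a DESeq2-style differential-expression table, GMT gene-set files and a
two-column baseline table.  All genomic coordinates are 0-based; BED
intervals are half-open per the BED standard.  Every reader returns plain
domain objects plus a :class:`ParseReport` accounting for dropped or
collapsed records, so that kept + dropped always equals the number of data
lines in the input.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger("cistromego")

_SKIP_PREFIXES = ("track", "browser", "#")


class ParseError(ValueError):
    """Raised on malformed input files; the message names the offending line."""


@dataclass(frozen=True)
class Peak:
    """One ChIP-seq interval; the unit of binding evidence.

    ``score`` is the peak caller's -log10(p-value) when available.  The peak
    center, used for all distance computations, is the floor of the interval
    midpoint.
    """

    chrom: str
    start: int
    end: int
    score: Optional[float] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.score is not None and self.score < 0:
            raise ValueError(f"negative peak score {self.score}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene id anchored at one TSS.  Genes with several isoform TSSs appear
    as several records sharing ``gene_id``; downstream scoring applies a
    per-gene policy over them."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self):
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")


@dataclass(frozen=True)
class DGERecord:
    gene_id: str
    log2fc: float
    pvalue: float
    padj: Optional[float] = None

    def __post_init__(self):
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"p-value out of (0,1] for {self.gene_id}: {self.pvalue}")


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"empty gene set {self.set_id}")


@dataclass
class ParseReport:
    """Per-file accounting: data lines seen, records kept, records dropped
    or collapsed, with reasons."""

    data_lines: int = 0
    kept: int = 0
    dropped: dict = field(default_factory=dict)

    def drop(self, reason: str, n: int = 1) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + n

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


def _data_lines(path):
    """Yield (1-based line number, stripped line) skipping headers/comments."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


def read_peaks(path, dialect: str = "bed", with_report: bool = False):
    """Read a BED3+/BED5 or narrowPeak file into a list of :class:`Peak`.

    BED column 5 is used as the significance score only when numeric and
    strictly positive (0 is the conventional placeholder and means "no
    score"); narrowPeak column 8 (-log10 p-value) is authoritative for that
    dialect.  Lines starting with ``track``/``browser``/``#`` are skipped.
    """
    if dialect not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    peaks: list[Peak] = []
    report = ParseReport()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
        report.data_lines += 1
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: non-integer coordinates "
                f"{fields[1]!r}/{fields[2]!r}"
            ) from None
        if start >= end or start < 0:
            raise ParseError(f"{path}: line {lineno}: invalid interval {start}-{end}")
        score = None
        if dialect == "narrowPeak":
            if len(fields) >= 8:
                try:
                    score = float(fields[7])
                except ValueError:
                    score = None
        else:
            if len(fields) >= 5:
                try:
                    s = float(fields[4])
                except ValueError:
                    s = None
                if s is not None and s > 0:
                    score = s
        peaks.append(Peak(chrom, start, end, score))
        report.kept += 1
    if not peaks:
        raise ParseError(f"{path}: no peaks found (empty file)")
    return (peaks, report) if with_report else peaks


def write_peaks_bed(peaks: Iterable[Peak], path) -> None:
    """Write peaks as BED5 (name '.', score 0 when absent); round-trips
    through :func:`read_peaks`."""
    with open(path, "w") as fh:
        for p in peaks:
            score = 0 if p.score is None else p.score
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t.\t{score:g}\n")


def read_annotation(path, with_report: bool = False):
    """Read the TSS table (tab-separated, header gene_id/chrom/tss/strand).

    Duplicate gene_id rows are retained as isoform TSSs; the multi-TSS
    policy (max RP over TSSs) is applied by the scoring module.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty annotation file") from None
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing annotation columns {sorted(missing)}")
    if df.empty:
        raise ParseError(f"{path}: annotation has no data rows")
    try:
        tss = df["tss"].astype(int)
    except (ValueError, TypeError):
        raise ParseError(f"{path}: non-integer tss values") from None
    report = ParseReport(data_lines=len(df), kept=len(df))
    records = [
        GeneAnnotation(str(g), str(c), int(t), str(s))
        for g, c, t, s in zip(df["gene_id"], df["chrom"], tss, df["strand"])
    ]
    n_multi = len(df) - df["gene_id"].nunique()
    if n_multi:
        logger.info("annotation: %d extra isoform TSS rows retained", n_multi)
    return (records, report) if with_report else records


def write_annotation(genes: Iterable[GeneAnnotation], path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss, g.strand) for g in genes],
        columns=["gene_id", "chrom", "tss", "strand"],
    )
    df.to_csv(path, sep="\t", index=False)


_DGE_DEFAULT_COLS = {
    "gene_id": "gene_id",
    "log2fc": "log2FoldChange",
    "pvalue": "pvalue",
    "padj": "padj",
}


def read_dge(path, column_map: Optional[dict] = None, with_report: bool = False):
    """Read a DESeq2-style DGE table.

    ``column_map`` remaps the logical names gene_id/log2fc/pvalue/padj to the
    file's column headers.  Rows with missing p-values are dropped (counted);
    p-values of exactly 0 are clamped to the smallest positive float;
    duplicate gene ids keep the row with the smallest p-value.
    """
    cols = dict(_DGE_DEFAULT_COLS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t")
    for logical in ("gene_id", "log2fc", "pvalue"):
        if cols[logical] not in df.columns:
            raise ParseError(
                f"{path}: required column {cols[logical]!r} (for {logical}) not found"
            )
    has_padj = cols["padj"] in df.columns
    report = ParseReport(data_lines=len(df))

    pv = pd.to_numeric(df[cols["pvalue"]], errors="coerce")
    missing = pv.isna()
    if missing.any():
        report.drop("missing_pvalue", int(missing.sum()))
        logger.info("dge: dropped %d rows with missing p-value", int(missing.sum()))
    df = df[~missing].copy()
    pv = pv[~missing]
    n_zero = int((pv == 0).sum())
    if n_zero:
        logger.info("dge: %d zero p-values clamped to float minimum", n_zero)
    pv = pv.astype(float).clip(lower=sys.float_info.min)
    df["_pv"] = pv.values

    # duplicate gene ids: keep smallest p-value
    df = df.sort_values("_pv", kind="stable")
    dup = df.duplicated(subset=cols["gene_id"], keep="first")
    if dup.any():
        report.drop("duplicate_gene_id", int(dup.sum()))
        logger.info("dge: %d duplicate gene ids collapsed (kept smallest p)", int(dup.sum()))
    df = df[~dup]

    records = []
    for _, row in df.iterrows():
        padj = None
        if has_padj:
            pa = pd.to_numeric(pd.Series([row[cols["padj"]]]), errors="coerce").iloc[0]
            padj = None if pd.isna(pa) else float(max(pa, sys.float_info.min))
        records.append(
            DGERecord(str(row[cols["gene_id"]]), float(row[cols["log2fc"]]),
                      float(row["_pv"]), padj)
        )
    report.kept = len(records)
    return (records, report) if with_report else records


def read_gmt(path, with_report: bool = False):
    """Read a GMT file: ``set_id TAB description TAB gene TAB gene...``.

    Duplicate member genes within a line are deduplicated; lines with no
    member genes are dropped with a warning; a repeated set_id is an error.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    report = ParseReport()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        report.data_lines += 1
        if len(fields) < 3:
            if len(fields) == 2:
                report.drop("empty_set")
                logger.warning("gmt: line %d: set %r has no members, dropped",
                               lineno, fields[0])
                continue
            raise ParseError(f"{path}: line {lineno}: fewer than 3 fields")
        set_id, name = fields[0], fields[1]
        if set_id in seen:
            raise ParseError(f"{path}: line {lineno}: duplicate set id {set_id!r}")
        seen.add(set_id)
        members = frozenset(g for g in fields[2:] if g)
        if not members:
            report.drop("empty_set")
            continue
        sets.append(GeneSet(set_id, name, members))
        report.kept += 1
    return (sets, report) if with_report else sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.members)]) + "\n")


def read_baseline(path) -> dict:
    """Read the two-column baseline table (gene_id, baseline in [0,1])."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: baseline table needs two columns")
    gene_col, val_col = df.columns[:2]
    values = pd.to_numeric(df[val_col], errors="raise")
    if ((values < 0) | (values > 1)).any():
        raise ParseError(f"{path}: baseline values outside [0, 1]")
    return dict(zip(df[gene_col].astype(str), values.astype(float)))


def write_baseline(baseline: dict, path) -> None:
    df = pd.DataFrame(sorted(baseline.items()), columns=["gene_id", "baseline"])
    df.to_csv(path, sep="\t", index=False)


def check_chromosome_overlap(peaks: Iterable[Peak], genes: Iterable[GeneAnnotation]):
    """Warn about chromosomes present in only one of the two inputs; matching
    is exact string comparison."""
    pc = {p.chrom for p in peaks}
    gc = {g.chrom for g in genes}
    only_peaks, only_genes = sorted(pc - gc), sorted(gc - pc)
    if only_peaks:
        logger.warning("chromosomes only in peaks: %s", ",".join(only_peaks))
    if only_genes:
        logger.warning("chromosomes only in annotation: %s", ",".join(only_genes))
    return only_peaks, only_genes
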