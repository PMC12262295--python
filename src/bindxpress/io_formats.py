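"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open (BED convention). GTF input,
which is 1-based inclusive, is converted at the parser boundary. Gene
identifiers are matched as exact strings; no symbol aliasing is attempted.

Formats handled: narrowPeak (BED6+4), GTF / BED12 transcript annotation,
FASTA genomes, GMT gene-set collections, tab-separated differential
expression and microarray tables, and plain one-gene-per-line lists.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """A file violated its format contract; message names the line if known."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

VALID_SEQUENCE_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class PeakRecord:
    """One narrowPeak interval; the unit of ChIP-seq binding evidence.

    ``start``/``end`` are 0-based half-open. ``p_value_log``/``q_value_log``
    hold -log10 values with -1 as the absent sentinel; ``summit_offset`` is
    the peak-summit offset from ``start`` or -1 when not called.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: int = 0
    strand: str = "."
    signal_value: float = 0.0
    p_value_log: float = -1.0
    q_value_log: float = -1.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if not self.chrom:
            raise FormatError("peak chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"peak interval must satisfy 0 <= start < end, got "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")
        if self.signal_value < 0:
            raise FormatError("signal_value must be non-negative")


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript interval with its parent gene; strand is mandatory."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"transcript {self.transcript_id} has unstranded/invalid "
                f"strand {self.strand!r}"
            )
        if not self.start < self.end:
            raise FormatError(
                f"transcript {self.transcript_id}: start must be < end"
            )


@dataclass(frozen=True)
class GeneTss:
    """Strand-aware 5'-most transcription start site of a gene."""

    gene_id: str
    chrom: str
    strand: str
    tss: int


@dataclass(frozen=True)
class DiffExprRecord:
    """Per-gene, per-tissue mutant-vs-wild-type differential expression.

    ``log_fc`` is the log fold change of mutant relative to wild-type
    (negative = down in the mutant); ``pct_wt``/``pct_mut`` are the percent
    of cells of that tissue expressing the gene, in [0, 100].
    """

    gene_id: str
    tissue: str
    log_fc: float
    p_value: float
    pct_wt: float
    pct_mut: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise FormatError(
                f"{self.gene_id}/{self.tissue}: p_value must be in (0,1], "
                f"got {self.p_value}"
            )
        for label, pct in (("pct_wt", self.pct_wt), ("pct_mut", self.pct_mut)):
            if not (0.0 <= pct <= 100.0):
                raise FormatError(
                    f"{self.gene_id}/{self.tissue}: {label} must be in "
                    f"[0,100], got {pct}"
                )


@dataclass(frozen=True)
class MicroarrayRecord:
    """Whole-embryo microarray fold change (signed linear scale)."""

    gene_id: str
    fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        if self.fold_change == 0:
            raise FormatError(f"{self.gene_id}: fold_change must be nonzero")
        if not (0.0 < self.p_value <= 1.0):
            raise FormatError(
                f"{self.gene_id}: p_value must be in (0,1], got {self.p_value}"
            )


class GeneSetCollection(dict):
    """Mapping of set name -> frozenset of gene identifiers."""

    def __setitem__(self, name: str, genes) -> None:
        super().__setitem__(name, frozenset(genes))


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------

def read_narrowpeak(path) -> list[PeakRecord]:
    """Parse a 10-column narrowPeak (BED6+4) file, preserving line order."""
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(
                    f"{path}:{lineno}: expected 10 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                records.append(
                    PeakRecord(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        name=fields[3],
                        score=int(fields[4]),
                        strand=fields[5],
                        signal_value=float(fields[6]),
                        p_value_log=float(fields[7]),
                        q_value_log=float(fields[8]),
                        summit_offset=int(fields[9]),
                    )
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_narrowpeak(records: Iterable[PeakRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t"
                f"{r.strand}\t{r.signal_value:g}\t{r.p_value_log:g}\t"
                f"{r.q_value_log:g}\t{r.summit_offset}\n"
            )


# ---------------------------------------------------------------------------
# annotation (GTF / BED12) and the TSS table
# ---------------------------------------------------------------------------

def read_gtf_transcripts(path) -> list[TranscriptModel]:
    """Read transcript features from a GTF; coordinates converted to 0-based
    half-open at this boundary (GTF itself is 1-based inclusive)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    out: list[TranscriptModel] = []
    for feat in db.features_of_type("transcript", order_by=("seqid", "start")):
        try:
            gene_id = feat.attributes["gene_id"][0]
            transcript_id = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise FormatError(
                f"{path}: transcript at {feat.seqid}:{feat.start} missing "
                f"attribute {exc}"
            ) from exc
        out.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=transcript_id,
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start - 1,
                end=feat.end,
            )
        )
    if not out:
        raise FormatError(f"{path}: no transcript features found")
    return out


def write_gtf_transcripts(transcripts: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            )
            fh.write(
                f"{t.chrom}\tbindxpress\ttranscript\t{t.start + 1}\t{t.end}\t"
                f".\t{t.strand}\t.\t{attrs}\n"
            )


def read_bed12_transcripts(path) -> list[TranscriptModel]:
    """Read transcripts from BED12. The name field carries the identity;
    ``gene:transcript`` names are split, a bare name serves as both ids."""
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}"
                )
            name = fields[3]
            gene_id, _, transcript_id = name.partition(":")
            try:
                out.append(
                    TranscriptModel(
                        gene_id=gene_id,
                        transcript_id=transcript_id or name,
                        chrom=fields[0],
                        strand=fields[5],
                        start=int(fields[1]),
                        end=int(fields[2]),
                    )
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def gene_tss_table(transcripts: Sequence[TranscriptModel]) -> list[GeneTss]:
    """Collapse transcripts to one strand-aware 5'-most TSS per gene.

    On the + strand the TSS is the minimum transcript start; on the - strand
    it is the maximum transcript end minus one (the 5'-most base in 0-based
    coordinates). Genes whose transcripts disagree on chromosome or strand
    are rejected.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    order: list[str] = []
    for t in transcripts:
        if t.gene_id not in by_gene:
            order.append(t.gene_id)
        by_gene.setdefault(t.gene_id, []).append(t)

    out: list[GeneTss] = []
    for gene_id in order:
        ts = by_gene[gene_id]
        chroms = {t.chrom for t in ts}
        strands = {t.strand for t in ts}
        if len(chroms) > 1 or len(strands) > 1:
            raise FormatError(
                f"gene {gene_id}: transcripts span multiple chromosomes or "
                f"strands ({sorted(chroms)}, {sorted(strands)})"
            )
        strand = ts[0].strand
        if strand == "+":
            tss = min(t.start for t in ts)
        else:
            tss = max(t.end for t in ts) - 1
        out.append(GeneTss(gene_id=gene_id, chrom=ts[0].chrom,
                           strand=strand, tss=tss))
    return out


# ---------------------------------------------------------------------------
# DE / microarray tables
# ---------------------------------------------------------------------------

DE_COLUMNS = ["gene_id", "tissue", "log_fc", "p_value", "pct_wt", "pct_mut"]
MICROARRAY_COLUMNS = ["gene_id", "fold_change", "p_value"]


def read_de_table(path) -> list[DiffExprRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing DE columns {sorted(missing)}")
    dup = df.duplicated(subset=["gene_id", "tissue"])
    if dup.any():
        first = df.loc[dup, ["gene_id", "tissue"]].iloc[0]
        raise FormatError(
            f"{path}: duplicate (gene, tissue) pair "
            f"({first.gene_id}, {first.tissue})"
        )
    try:
        return [
            DiffExprRecord(
                gene_id=str(row.gene_id),
                tissue=str(row.tissue),
                log_fc=float(row.log_fc),
                p_value=float(row.p_value),
                pct_wt=float(row.pct_wt),
                pct_mut=float(row.pct_mut),
            )
            for row in df.itertuples(index=False)
        ]
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_de_table(records: Iterable[DiffExprRecord], path) -> None:
    df = pd.DataFrame(
        [(r.gene_id, r.tissue, r.log_fc, r.p_value, r.pct_wt, r.pct_mut)
         for r in records],
        columns=DE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_microarray_table(path) -> list[MicroarrayRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(MICROARRAY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    try:
        return [
            MicroarrayRecord(
                gene_id=str(row.gene_id),
                fold_change=float(row.fold_change),
                p_value=float(row.p_value),
            )
            for row in df.itertuples(index=False)
        ]
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_microarray_table(records: Iterable[MicroarrayRecord], path) -> None:
    df = pd.DataFrame(
        [(r.gene_id, r.fold_change, r.p_value) for r in records],
        columns=MICROARRAY_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Parse GMT ``name<TAB>description<TAB>gene...`` lines. Empty sets are
    retained at load; size filtering happens downstream."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name and description"
                )
            name = fields[0]
            if name in coll:
                raise FormatError(f"{path}:{lineno}: duplicate set {name!r}")
            coll[name] = [g for g in fields[2:] if g]
    return coll


def write_gmt(collection: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Load a genome FASTA into a chrom -> uppercase sequence mapping.

    Characters outside ACGTN are rejected.
    """
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_SEQUENCE_CHARS
        if bad:
            raise FormatError(
                f"{path}: sequence {rec.id} contains invalid characters "
                f"{sorted(bad)}"
            )
        if rec.id in genome:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        genome[rec.id] = seq
    return genome


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# plain gene lists
# ---------------------------------------------------------------------------

def read_gene_list(path) -> list[str]:
    """One gene per line; blank lines and '#' comments ignored."""
    out: list[str] = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            gene = line.strip()
            if not gene or gene.startswith("#"):
                continue
            if gene not in seen:
                seen.add(gene)
                out.append(gene)
    return out


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
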