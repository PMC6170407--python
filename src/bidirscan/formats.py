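"""On-disk formats and the core interval/annotation types.

Conventions used throughout the package:

* all coordinates are 0-based, half-open (BED dialect);
* the TSS of a minus-strand gene is its *larger* coordinate;
* the BED6 score column carries the ``unique`` mapping flag (1/0);
* readers reject invalid records (with a line number) instead of repairing them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-")


class FormatError(ValueError):
    """Raised for malformed on-disk records."""


@dataclass(frozen=True)
class ReadInterval:
    """A strand-bearing aligned-read interval (0-based, half-open)."""

    contig: str
    start: int
    end: int
    strand: str
    read_id: str = ""
    unique: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """Position of the 5' end: start on '+', end-1 on '-'."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class GeneAnnotation:
    """A transcription unit with oriented TSS/TES.

    For a plus-strand gene ``tss < tes``; for a minus-strand gene
    ``tss > tes`` (the TSS is the larger coordinate).
    """

    gene_id: str
    contig: str
    strand: str
    tss: int
    tes: int
    expression_weight: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise FormatError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if self.tss == self.tes:
            raise FormatError(f"gene {self.gene_id}: tss == tes")
        if self.strand == "+" and not self.tss < self.tes:
            raise FormatError(f"gene {self.gene_id}: '+' gene requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise FormatError(f"gene {self.gene_id}: '-' gene requires tss > tes")
        if self.expression_weight is not None and self.expression_weight < 0:
            raise FormatError(f"gene {self.gene_id}: negative expression weight")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint as a half-open interval, strand-agnostic."""
        lo, hi = sorted((self.tss, self.tes))
        return lo, hi + (1 if self.strand == "-" else 0)

    @property
    def length(self) -> int:
        lo, hi = self.span
        return hi - lo


@dataclass(frozen=True)
class IntervalScore:
    """A scored half-open interval (bedGraph-style carrier)."""

    contig: str
    start: int
    end: int
    strand: str
    value: float


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{contig: sequence}`` map.

    Sequences are uppercased on read; duplicate headers are an error.
    """
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"duplicate FASTA header {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED6


def read_bed6(path: str | Path) -> list[ReadInterval]:
    """Read 6-column BED into ReadIntervals; score column is the unique flag."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["contig", "start", "end", "name", "score", "strand"],
            dtype={"contig": str, "name": str, "strand": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 6:
        raise FormatError(f"{path}: expected 6 BED columns")
    reads: list[ReadInterval] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.strand not in STRANDS:
            raise FormatError(f"{path}: line {i}: invalid strand {row.strand!r}")
        if not (0 <= int(row.start) < int(row.end)):
            raise FormatError(
                f"{path}: line {i}: start must satisfy 0 <= start < end"
            )
        reads.append(
            ReadInterval(
                contig=row.contig,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                read_id=str(row.name),
                unique=bool(int(row.score)),
            )
        )
    return reads


def write_bed6(reads: Iterable[ReadInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.read_id}\t{int(r.unique)}\t{r.strand}\n"
            )


# ---------------------------------------------------------------------------
# Gene table (TSV)

_GENE_COLS = ["gene_id", "contig", "strand", "tss", "tes"]


def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    """Read the TSV gene table (gene_id/contig/strand/tss/tes[/weight])."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig": str, "strand": str})
    if df.empty and all(c in df.columns for c in _GENE_COLS):
        return []
    missing = [c for c in _GENE_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing gene-table columns {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    has_weight = "weight" in df.columns
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneAnnotation(
                gene_id=row.gene_id,
                contig=row.contig,
                strand=row.strand,
                tss=int(row.tss),
                tes=int(row.tes),
                expression_weight=float(row.weight) if has_weight else None,
            )
        )
    return genes


def write_gene_table(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    genes = list(genes)
    rows = {
        "gene_id": [g.gene_id for g in genes],
        "contig": [g.contig for g in genes],
        "strand": [g.strand for g in genes],
        "tss": [g.tss for g in genes],
        "tes": [g.tes for g in genes],
    }
    if any(g.expression_weight is not None for g in genes):
        rows["weight"] = [
            g.expression_weight if g.expression_weight is not None else 1.0
            for g in genes
        ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bedGraph export and JSON sidecars


def write_bedgraph(scores: Iterable[IntervalScore], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in scores:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.value:g}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
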