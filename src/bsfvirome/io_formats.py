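"""Readers and writers for the external formats the pipeline touches.

Sequences travel as lightweight :class:`SequenceRecord` objects (Biopython's
``SeqIO`` does the actual parsing); genomic locations are 0-based half-open
:class:`GenomicInterval` objects; externally produced translated-homology hits
enter through the 12-column tabular dialect (BLAST/DIAMOND ``outfmt 6``).

A note on the printed coordinate dialect (``SEQID:START-END``) used in EVE
summary tables: the printed pair is interpreted so that the element's span is
exactly ``END - START`` nucleotides. This is the only reading under which the
table's own extreme spans (148 and 3750 nt) match the printed coordinates, so
the pair is stored verbatim as a half-open interval.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "ParseError",
    "CoordinateDialectError",
    "SequenceRecord",
    "GenomicInterval",
    "TabularHitRow",
    "read_sequences",
    "write_sequences",
    "parse_coordinate_string",
    "format_coordinate_string",
    "read_tabular_hits",
    "write_tabular_hits",
]

FASTA_WRAP = 80  # fixed output wrap for determinism


class ParseError(ValueError):
    """A file did not conform to its declared format."""


class CoordinateDialectError(ParseError):
    """A printed coordinate string violates the START < END dialect."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence.

    Sequences are upper-cased on construction; ambiguity codes (N, X) and,
    in alignment contexts, the gap character ``-`` are permitted.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")

    def span(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


_TABULAR_COLUMNS = (
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
)


@dataclass(frozen=True)
class TabularHitRow:
    """One row of the 12-column tabular homology-hit dialect.

    Coordinates are 1-based inclusive, as emitted by BLAST/DIAMOND.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of [0,100]: {self.pct_identity}")
        if self.aln_length < 1:
            raise ValueError(f"aln_length must be >= 1, got {self.aln_length}")
        if self.evalue < 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")


def read_sequences(path: str | Path, format: str = "fasta") -> list[SequenceRecord]:
    """Read FASTA or FASTQ (Sanger/Phred+33) into :class:`SequenceRecord` s.

    An empty file yields an empty list. Malformed records raise
    :class:`ParseError`. FASTQ quality strings are length-checked against
    their sequences by the underlying parser.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt not in {"fasta", "fastq"}:
        raise ValueError(f"unsupported format {format!r}")
    records: list[SequenceRecord] = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            records.append(
                SequenceRecord(id=rec.id, seq=str(rec.seq), description=rec.description)
            )
    except ValueError as exc:  # Biopython signals format violations as ValueError
        raise ParseError(
            f"{path}: malformed {fmt} near record {len(records) + 1}: {exc}"
        ) from exc
    if fmt == "fasta" and not records:
        # SeqIO silently returns nothing for a non-empty file with no '>' header
        text = path.read_text()
        if text.strip() and not text.lstrip().startswith(">"):
            lineno = 1 + text[: len(text) - len(text.lstrip())].count("\n")
            raise ParseError(f"{path}: line {lineno}: expected '>' FASTA header")
    return records


def write_sequences(
    records: Iterable[SequenceRecord],
    path: str | Path,
    format: str = "fasta",
    qualities: int = 40,
) -> Path:
    """Write records as FASTA (80-column wrap) or FASTQ (constant quality)."""
    path = Path(path)
    fmt = format.lower()
    bio_records = []
    for rec in records:
        br = _BioSeqRecord(Seq(rec.seq), id=rec.id, description=rec.description)
        if fmt == "fastq":
            br.letter_annotations["phred_quality"] = [qualities] * len(rec.seq)
        bio_records.append(br)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "fasta":
        with path.open("w") as handle:
            writer = SeqIO.FastaIO.FastaWriter(handle, wrap=FASTA_WRAP)
            writer.write_file(bio_records)
    elif fmt == "fastq":
        SeqIO.write(bio_records, str(path), "fastq")
    else:
        raise ValueError(f"unsupported format {format!r}")
    return path


_COORD_RE = re.compile(r"^(?P<seq_id>[^:\s]+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_coordinate_string(text: str) -> GenomicInterval:
    """Parse a printed ``SEQID:START-END`` coordinate string.

    The printed pair is stored verbatim as a half-open interval so that
    ``span() == END - START`` (see module docstring). Strand is unknown (``.``).
    """
    m = _COORD_RE.match(text.strip())
    if m is None:
        raise ParseError(f"unparseable coordinate string {text!r}")
    start, end = int(m.group("start")), int(m.group("end"))
    if end <= start:
        raise CoordinateDialectError(
            f"coordinate string {text!r}: END ({end}) must exceed START ({start})"
        )
    return GenomicInterval(seq_id=m.group("seq_id"), start=start, end=end, strand=".")


def format_coordinate_string(interval: GenomicInterval) -> str:
    return f"{interval.seq_id}:{interval.start}-{interval.end}"


def read_tabular_hits(path: str | Path) -> list[TabularHitRow]:
    """Read a 12-column tab-separated homology hit file (``outfmt 6``)."""
    path = Path(path)
    rows: list[TabularHitRow] = []
    with path.open(newline="") as handle:
        for i, fields in enumerate(csv.reader(handle, delimiter="\t")):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue
            if len(fields) != 12:
                raise ParseError(
                    f"{path}: row {i}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                rows.append(
                    TabularHitRow(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: row {i}: {exc}") from exc
    return rows


def write_tabular_hits(rows: Iterable[TabularHitRow], path: str | Path) -> Path:
    """Write hits in the 12-column tabular dialect (read_tabular_hits inverse)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for row in rows:
            writer.writerow(
                [
                    row.query_id,
                    row.subject_id,
                    repr(row.pct_identity),  # repr round-trips floats exactly
                    row.aln_length,
                    row.mismatches,
                    row.gap_opens,
                    row.q_start,
                    row.q_end,
                    row.s_start,
                    row.s_end,
                    repr(row.evalue),
                    repr(row.bitscore),
                ]
            )
    return path
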