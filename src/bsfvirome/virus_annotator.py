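"""Annotation and triage of candidate exogenous viral contigs.

Totivirus-like genomes (double-stranded RNA, ~4.6-8.8 kb) carry two long
ORFs: GAG (capsid) followed by POL (the RNA-dependent RNA polymerase). A
transcriptome contig is triaged as a near-complete genome when it is longer
than 5 kb and shows that two-ORF layout; everything else is a partial
fragment. The module also prepares protein alignments for external tree
inference: occupancy-based column trimming and partition-aware
concatenation. Alignment inference itself (and tree building) is out of
scope — alignments come in as aligned FASTA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import GenomicInterval, SequenceRecord, read_sequences, write_sequences
from .homology_search import six_frame_translate

__all__ = [
    "Orf",
    "OrfAnnotation",
    "Alignment",
    "find_orfs",
    "orient_contig",
    "triage_viral_contigs",
    "trim_alignment",
    "concat_alignments",
    "pairwise_identity",
    "read_alignment",
    "write_alignment",
    "write_phylip",
    "write_partition_sets",
    "orfs_to_gff3",
]

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass(frozen=True)
class Orf:
    """One open reading frame: ATG to stop, coordinates on the forward strand.

    ``interval`` includes the stop codon (a codon-multiple span);
    ``length_aa`` counts codons excluding the stop.
    """

    interval: GenomicInterval
    frame: int
    length_aa: int
    label: str = "other"

    def __post_init__(self) -> None:
        if self.interval.span() % 3 != 0:
            raise ValueError("ORF interval must be a codon-multiple span")


@dataclass(frozen=True)
class OrfAnnotation:
    contig_id: str
    genome_len_nt: int
    orfs: tuple[Orf, ...]

    def labelled(self, label: str) -> Orf | None:
        for orf in self.orfs:
            if orf.label == label:
                return orf
        return None


def find_orfs(contig: SequenceRecord, min_len_aa: int) -> OrfAnnotation:
    """Annotate ATG->stop ORFs of at least ``min_len_aa`` codons on 6 frames.

    ORFs start at the first ATG following the previous stop in that frame and
    end at (and include) the next stop codon; ORFs running off the contig end
    without a stop are not reported. The two longest non-identical ORFs are
    labelled GAG (the 5'-most of the two on the plus strand) and POL (the
    3'-most), mirroring totivirus genome organisation; a length tie keeps the
    positional labelling and logs a warning.
    """
    seq_len = len(contig.seq)
    frames = six_frame_translate(contig.seq)
    orfs: list[Orf] = []
    for frame, aa in frames.items():
        start_codon = None
        for i, ch in enumerate(aa):
            if ch == "M" and start_codon is None:
                start_codon = i
            elif ch == "*":
                if start_codon is not None:
                    length_aa = i - start_codon
                    if length_aa >= min_len_aa:
                        lo, hi = _codons_to_genome(frame, start_codon, i + 1, seq_len)
                        orfs.append(
                            Orf(
                                interval=GenomicInterval(
                                    seq_id=contig.id,
                                    start=lo,
                                    end=hi,
                                    strand="+" if frame > 0 else "-",
                                ),
                                frame=frame,
                                length_aa=length_aa,
                            )
                        )
                start_codon = None
    orfs.sort(key=lambda o: (o.interval.start, o.interval.end))
    orfs = _label_gag_pol(orfs)
    return OrfAnnotation(contig_id=contig.id, genome_len_nt=seq_len, orfs=tuple(orfs))


def _codons_to_genome(frame: int, aa_start: int, aa_end: int, seq_len: int) -> tuple[int, int]:
    offset = abs(frame) - 1
    nt_lo = offset + 3 * aa_start
    nt_hi = offset + 3 * aa_end
    if frame > 0:
        return nt_lo, nt_hi
    return seq_len - nt_hi, seq_len - nt_lo


def _label_gag_pol(orfs: list[Orf]) -> list[Orf]:
    if len(orfs) < 2:
        return orfs
    ranked = sorted(orfs, key=lambda o: (-o.length_aa, o.interval.start))
    top_two = ranked[:2]
    if top_two[0].length_aa == top_two[1].length_aa:
        logger.warning(
            "GAG/POL labelling ambiguous: two longest ORFs have equal length "
            "(%d aa); labelling by coordinate only", top_two[0].length_aa
        )
    five_prime, three_prime = sorted(top_two, key=lambda o: o.interval.start)
    out = []
    for orf in orfs:
        if orf is five_prime:
            out.append(Orf(orf.interval, orf.frame, orf.length_aa, label="GAG"))
        elif orf is three_prime:
            out.append(Orf(orf.interval, orf.frame, orf.length_aa, label="POL"))
        else:
            out.append(orf)
    return out


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def orient_contig(contig: SequenceRecord, min_len_aa: int) -> SequenceRecord:
    """Reverse-complement a contig if its longest ORF lies 5' of the second.

    Totivirus convention puts the longer (POL/RdRP) ORF 3' on the plus
    strand; orientation-normalising first makes GAG/POL labels positional.
    """
    ann = find_orfs(contig, min_len_aa)
    if len(ann.orfs) < 2:
        return contig
    ranked = sorted(ann.orfs, key=lambda o: (-o.length_aa, o.interval.start))
    longest, second = ranked[0], ranked[1]
    if longest.interval.start < second.interval.start:
        return SequenceRecord(
            id=contig.id, seq=_revcomp(contig.seq), description=contig.description
        )
    return contig


def triage_viral_contigs(
    contigs: Sequence[SequenceRecord],
    near_complete_min_nt: int = 5000,
    orf_min_len_aa: int = 150,
) -> dict[str, list[OrfAnnotation]]:
    """Partition contigs into near-complete genomes and partial fragments.

    A contig is near-complete iff it is strictly longer than
    ``near_complete_min_nt`` AND carries both a GAG and a POL ORF after
    orientation normalisation. The returned annotations retain lengths and
    ORF layout for reporting.
    """
    partition: dict[str, list[OrfAnnotation]] = {"near_complete": [], "partial": []}
    for contig in contigs:
        oriented = orient_contig(contig, orf_min_len_aa)
        ann = find_orfs(oriented, orf_min_len_aa)
        complete = (
            ann.genome_len_nt > near_complete_min_nt
            and ann.labelled("GAG") is not None
            and ann.labelled("POL") is not None
        )
        partition["near_complete" if complete else "partial"].append(ann)
    return partition


@dataclass(frozen=True)
class Alignment:
    """A protein multiple alignment: equal-length gapped rows keyed by taxon."""

    rows: tuple[tuple[str, str], ...]
    # half-open column ranges of the source parts after concatenation
    partitions: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.rows:
            widths = {len(seq) for _, seq in self.rows}
            if len(widths) > 1:
                raise ValueError(f"ragged alignment: row widths {sorted(widths)}")
        taxa = [t for t, _ in self.rows]
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon ids in alignment")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def taxa(self) -> list[str]:
        return [t for t, _ in self.rows]

    def matrix(self) -> np.ndarray:
        return np.array([list(seq) for _, seq in self.rows], dtype="U1")


def trim_alignment(aln: Alignment, min_occupancy: float = 0.10,
                   end_trim_occupancy: float = 0.50) -> Alignment:
    """Occupancy-trim an alignment: end trim, then column filter.

    The alignment is first restricted to the span between the first and last
    columns whose occupancy (non-gap fraction) reaches
    ``end_trim_occupancy``; inside that span a column is kept iff its
    occupancy is at least ``min_occupancy`` (so with 10 rows a single residue
    exactly meets the default 10% bar). Removing every column yields an empty
    alignment, which is valid and logged.
    """
    if aln.n_rows == 0:
        return aln
    mat = aln.matrix()
    occupancy = (mat != GAP).sum(axis=0) / aln.n_rows
    ends = np.flatnonzero(occupancy >= end_trim_occupancy)
    if ends.size == 0:
        logger.info("end trimming removed every column")
        return Alignment(rows=tuple((t, "") for t, _ in aln.rows))
    lo, hi = int(ends[0]), int(ends[-1]) + 1
    keep = [c for c in range(lo, hi) if occupancy[c] >= min_occupancy]
    if not keep:
        logger.info("occupancy filter removed every column")
    rows = tuple(
        (taxon, "".join(seq[c] for c in keep)) for taxon, seq in aln.rows
    )
    return Alignment(rows=rows)


def concat_alignments(parts: Sequence[Alignment]) -> Alignment:
    """Concatenate alignments row-wise, keyed by taxon (input order kept).

    All parts must cover exactly the same taxon set; offenders are listed in
    the error. Column provenance of each part is retained in ``partitions``
    for building partition files.
    """
    if not parts:
        return Alignment(rows=())
    reference_taxa = list(parts[0].taxa())
    ref_set = set(reference_taxa)
    for i, part in enumerate(parts[1:], start=2):
        part_set = set(part.taxa())
        if part_set != ref_set:
            missing = sorted(ref_set - part_set)
            extra = sorted(part_set - ref_set)
            raise ValueError(
                f"part {i} taxon mismatch: missing {missing}, unexpected {extra}"
            )
    joined = {taxon: [] for taxon in reference_taxa}
    partitions = []
    offset = 0
    for i, part in enumerate(parts, start=1):
        lookup = dict(part.rows)
        for taxon in reference_taxa:
            joined[taxon].append(lookup[taxon])
        partitions.append((f"part{i}", offset, offset + part.n_cols))
        offset += part.n_cols
    rows = tuple((taxon, "".join(joined[taxon])) for taxon in reference_taxa)
    return Alignment(rows=rows, partitions=tuple(partitions))


def pairwise_identity(aln: Alignment) -> np.ndarray:
    """Pairwise % identity over co-occupied columns; diagonal 100.

    Entries for pairs with zero co-occupied columns are NaN (reported
    missing rather than fabricated).
    """
    if aln.n_rows < 2:
        raise ValueError("pairwise identity needs at least 2 rows")
    mat = aln.matrix()
    non_gap = mat != GAP
    n = aln.n_rows
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            both = non_gap[i] & non_gap[j]
            denom = int(both.sum())
            if denom == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            matches = int((mat[i][both] == mat[j][both]).sum())
            out[i, j] = out[j, i] = 100.0 * matches / denom
    return out


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    records = read_sequences(path, format="fasta")
    return Alignment(rows=tuple((r.id, r.seq) for r in records))


def write_alignment(aln: Alignment, path: str | Path) -> Path:
    return write_sequences(
        [SequenceRecord(id=t, seq=s) for t, s in aln.rows], path, format="fasta"
    )


def write_phylip(aln: Alignment, path: str | Path) -> Path:
    """Write relaxed (long-name) sequential PHYLIP."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as handle:
        handle.write(f"{aln.n_rows} {aln.n_cols}\n")
        for taxon, seq in aln.rows:
            handle.write(f"{taxon}  {seq}\n")
    return path


def write_partition_sets(aln: Alignment, path: str | Path) -> Path:
    """Write the concatenation partitions as a NEXUS ``sets`` block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as handle:
        handle.write("#nexus\nbegin sets;\n")
        for name, lo, hi in aln.partitions:
            handle.write(f"    charset {name} = {lo + 1}-{hi};\n")
        handle.write("end;\n")
    return path


def orfs_to_gff3(annotations: Iterable[OrfAnnotation], path: str | Path) -> Path:
    """Write ORF annotations as GFF3 (1-based inclusive coordinates)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as handle:
        handle.write("##gff-version 3\n")
        for ann in annotations:
            for i, orf in enumerate(ann.orfs, start=1):
                attrs = f"ID=orf{i};label={orf.label};frame={orf.frame}"
                handle.write(
                    f"{ann.contig_id}\tbsfvirome\tCDS\t{orf.interval.start + 1}\t"
                    f"{orf.interval.end}\t.\t{orf.interval.strand}\t0\t{attrs}\n"
                )
    return path
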