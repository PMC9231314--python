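"""Cross-assembly placement of EVEs by flanking-sequence identity.

Two integrations in different assemblies are the same locus (orthologous,
i.e. inherited from a common ancestor rather than acquired independently)
when the EVE sequences themselves are near-identical AND they sit inside the
same host sequence: both flanks of the candidate must be recognisably the
same stretch of host genome as the flanks of the reference copy. A 20 kb
window around each EVE is used as the flank context, a 98% nucleotide
identity bar on the EVE pair, and at least 50 nt of flank match per side.

Loci are labelled systematically per family in reference-assembly coordinate
order (T1, T2, ... for Totiviridae and so on); curated labels from published
tables can of course differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .eve_caller import NO_POSITION, EveRecord, FAMILY_SHORT_CODES
from .io_formats import GenomicInterval, SequenceRecord

__all__ = [
    "LOCUS_CODES",
    "OrthologyParams",
    "LocusAssignment",
    "extract_flank_region",
    "assign_loci",
    "orthology_summary",
    "presence_from_records",
]

# Locus label prefixes per family (systematic counterparts of curated names).
LOCUS_CODES: dict[str, str] = {
    "Partitiviridae": "PT",
    "Parvoviridae": "PR",
    "Rhabdoviridae": "Rh",
    "Totiviridae": "T",
    "Xinmoviridae": "Xi",
}


@dataclass(frozen=True)
class OrthologyParams:
    """Thresholds of the orthology test.

    min_identity_pct:   global nucleotide identity required between the two
                        EVE sequences (98, the bar under which same-family
                        copies are treated as independent integrations).
    min_flank_match_nt: an exact shared substring of at least this many
                        nucleotides must exist between each candidate flank
                        and the reference 20 kb window.
    window_nt:          width of the flank-context window around each EVE.
    """

    min_identity_pct: float = 98.0
    min_flank_match_nt: int = 50
    window_nt: int = 20_000


@dataclass
class LocusAssignment:
    """A named orthologous insertion site and its member EVEs."""

    locus_label: str
    family: str
    members: list[tuple[str, EveRecord]]
    reference_assembly: str
    # pairwise % identity between member EVE sequences, diagonal 100
    identity_matrix: np.ndarray | None = None

    def assemblies(self) -> set[str]:
        return {assembly for assembly, _ in self.members}


def extract_flank_region(
    contigs: Sequence[SequenceRecord],
    eve: EveRecord,
    window_nt: int = 20_000,
) -> SequenceRecord:
    """Extract the window of host sequence centred on an EVE, clipped at edges.

    The record id encodes assembly, contig and window coordinates so dumped
    windows remain traceable.
    """
    by_id = {c.id: c for c in contigs}
    contig = by_id.get(eve.interval.seq_id)
    if contig is None:
        raise KeyError(f"EVE references unknown contig {eve.interval.seq_id!r}")
    centre = (eve.interval.start + eve.interval.end) // 2
    half = window_nt // 2
    # clipping shortens the window rather than re-anchoring it, so the EVE
    # stays centred whenever the contig allows
    lo = max(0, centre - half)
    hi = min(len(contig.seq), centre - half + window_nt)
    return SequenceRecord(
        id=f"{eve.assembly}|{contig.id}|{lo}-{hi}",
        seq=contig.seq[lo:hi],
        description=f"flank window of {eve.name} {eve.locus_label}",
    )


def _global_identity_pct(a: str, b: str) -> float:
    """Global-alignment identity (match +1, mismatch -1, gap -2), in percent.

    Identity is matched columns over total alignment columns. A deterministic
    global aligner stands in for interactive read-mapping tools.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(a.upper(), b.upper())[0]
    counts = aln.counts()
    n_cols = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / n_cols if n_cols else 0.0


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _flank_matches(
    flank: str, reference_window_kmers: set[str], min_match_nt: int
) -> bool:
    """True if the flank shares an exact substring >= min_match_nt with the window."""
    if len(flank) < min_match_nt:
        return False
    k = min_match_nt
    return any(
        flank[i : i + k] in reference_window_kmers for i in range(len(flank) - k + 1)
    )


def _eve_seq(assemblies: Mapping[str, Sequence[SequenceRecord]], eve: EveRecord) -> str:
    for contig in assemblies[eve.assembly]:
        if contig.id == eve.interval.seq_id:
            return contig.seq[eve.interval.start : eve.interval.end]
    raise KeyError(f"unknown contig {eve.interval.seq_id!r} in {eve.assembly!r}")


def assign_loci(
    eves_by_assembly: Mapping[str, Sequence[EveRecord]],
    assemblies: Mapping[str, Sequence[SequenceRecord]],
    params: OrthologyParams | None = None,
    reference_assembly: str | None = None,
    locus_codes: Mapping[str, str] | None = None,
) -> tuple[list[LocusAssignment], list[EveRecord]]:
    """Group EVEs into orthologous loci anchored on a reference assembly.

    Every EVE of the reference assembly seeds a locus, numbered per family in
    (contig, start) order. An EVE from another assembly joins a same-family
    reference locus iff (a) the two EVE sequences align globally at
    ``min_identity_pct`` nucleotide identity or better, and (b) both of its
    flanks share an exact match of at least ``min_flank_match_nt`` with the
    reference locus window. EVEs that fail placement are returned with label
    ``np``. Returns (loci, updated records for all input EVEs).
    """
    params = params or OrthologyParams()
    codes = dict(LOCUS_CODES)
    if locus_codes:
        codes.update(locus_codes)
    names = sorted(eves_by_assembly)
    if reference_assembly is None:
        reference_assembly = names[0]
    if reference_assembly not in eves_by_assembly:
        raise KeyError(f"reference assembly {reference_assembly!r} has no EVE list")

    # seed loci from the reference assembly, numbered per family
    ref_eves = sorted(
        eves_by_assembly[reference_assembly],
        key=lambda e: (e.family, e.interval.seq_id, e.interval.start),
    )
    loci: list[LocusAssignment] = []
    per_family_counter: dict[str, int] = {}
    ref_context: list[tuple[str, set[str], str]] = []  # (eve_seq, window kmers, label)
    updated: list[EveRecord] = []
    for eve in ref_eves:
        n = per_family_counter.get(eve.family, 0) + 1
        per_family_counter[eve.family] = n
        label = f"{codes.get(eve.family, eve.family[:2])}{n}"
        placed = EveRecord(**{**eve.__dict__, "locus_label": label})
        window = extract_flank_region(
            assemblies[reference_assembly], eve, params.window_nt
        )
        loci.append(
            LocusAssignment(
                locus_label=label,
                family=eve.family,
                members=[(reference_assembly, placed)],
                reference_assembly=reference_assembly,
            )
        )
        ref_context.append(
            (
                _eve_seq(assemblies, eve),
                _kmer_set(window.seq, params.min_flank_match_nt),
                label,
            )
        )
        updated.append(placed)

    # place the non-reference EVEs (assembly order is irrelevant by construction)
    for assembly in names:
        if assembly == reference_assembly:
            continue
        for eve in eves_by_assembly[assembly]:
            best_locus = None
            best_identity = -1.0
            cand_seq = _eve_seq(assemblies, eve)
            contig = next(
                c for c in assemblies[assembly] if c.id == eve.interval.seq_id
            )
            left_flank = contig.seq[: eve.interval.start]
            right_flank = contig.seq[eve.interval.end :]
            for locus, (ref_seq, window_kmers, _label) in zip(loci, ref_context):
                if locus.family != eve.family:
                    continue
                identity = _global_identity_pct(cand_seq, ref_seq)
                if identity < params.min_identity_pct:
                    continue
                if not (
                    _flank_matches(left_flank, window_kmers, params.min_flank_match_nt)
                    and _flank_matches(
                        right_flank, window_kmers, params.min_flank_match_nt
                    )
                ):
                    continue
                if identity > best_identity:
                    best_identity = identity
                    best_locus = locus
            if best_locus is not None:
                placed = EveRecord(**{**eve.__dict__, "locus_label": best_locus.locus_label})
                best_locus.members.append((assembly, placed))
                updated.append(placed)
            else:
                updated.append(EveRecord(**{**eve.__dict__, "locus_label": NO_POSITION}))

    for locus in loci:
        locus.identity_matrix = _member_identity_matrix(locus, assemblies)
    return loci, updated


def _member_identity_matrix(
    locus: LocusAssignment, assemblies: Mapping[str, Sequence[SequenceRecord]]
) -> np.ndarray:
    seqs = [_eve_seq(assemblies, eve) for _, eve in locus.members]
    n = len(seqs)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _global_identity_pct(seqs[i], seqs[j])
    return mat


def orthology_summary(loci: Sequence[LocusAssignment]) -> pd.DataFrame:
    """Locus x assembly boolean presence matrix with member counts.

    The ``n_members`` column counts EVEs in the locus (one locus can hold
    more than one copy per assembly); ``n_assemblies`` counts assemblies.
    """
    if not loci:
        return pd.DataFrame()
    all_assemblies = sorted({a for locus in loci for a in locus.assemblies()})
    rows = {}
    for locus in loci:
        present = locus.assemblies()
        rows[locus.locus_label] = {
            "family": locus.family,
            **{a: a in present for a in all_assemblies},
            "n_members": len(locus.members),
            "n_assemblies": len(present),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def presence_from_records(records: Sequence[EveRecord]) -> pd.DataFrame:
    """Presence matrix built from already-labelled EVE records (e.g. a table).

    Rows are non-``np`` locus labels, columns assemblies, entries booleans;
    the ``n_assemblies`` column tallies assemblies per locus.
    """
    labelled = [r for r in records if r.locus_label != NO_POSITION]
    if not labelled:
        return pd.DataFrame()
    all_assemblies = sorted({r.assembly for r in labelled})
    rows: dict[str, dict] = {}
    for rec in labelled:
        row = rows.setdefault(
            rec.locus_label,
            {"family": rec.family, **{a: False for a in all_assemblies}},
        )
        row[rec.assembly] = True
    df = pd.DataFrame.from_dict(rows, orient="index")
    df["n_assemblies"] = df[all_assemblies].sum(axis=1)
    return df
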