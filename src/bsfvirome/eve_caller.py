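"""Turn screened translated hits into endogenous viral element (EVE) calls.

The calling logic mirrors how genome-scale EVE screens are curated by hand:
hits to proteins of the same viral family that land close together on a
contig are one integration event, not many; candidates on contigs with no
host sequence on either side are sequencing contamination, not integrations
(the classic give-away of carried-over reads from an unrelated organism);
and candidates resembling a host protein more than a viral one are host
genes picked up by a permissive search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .homology_search import (
    ProteinRecord,
    SearchParams,
    TranslatedHit,
    hit_sort_key,
    host_protein_screen,
    translated_search,
)
from .io_formats import GenomicInterval, SequenceRecord

__all__ = [
    "FAMILY_SHORT_CODES",
    "EveRecord",
    "MergedCandidate",
    "merge_hits",
    "contamination_filter",
    "call_eves",
    "summarize_eves",
    "EveSummary",
    "eves_to_tsv",
    "eves_to_bed",
]

logger = logging.getLogger(__name__)

# Family short codes used in EVE names; extensible via the config layer.
FAMILY_SHORT_CODES: dict[str, str] = {
    "Partitiviridae": "Partiti",
    "Parvoviridae": "Parvo",
    "Rhabdoviridae": "Rhabdo",
    "Totiviridae": "Toti",
    "Xinmoviridae": "Xinmo",
}

NO_POSITION = "np"  # locus label of an EVE that could not be placed


@dataclass(frozen=True)
class EveRecord:
    """One called EVE: a merged, screened viral insertion in a host assembly."""

    name: str
    assembly: str
    interval: GenomicInterval
    family: str
    best_hit_subject: str
    best_hit_pct_identity: float
    protein_class: str
    locus_label: str = NO_POSITION

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("family must be non-empty")


@dataclass(frozen=True)
class MergedCandidate:
    """A cluster of nearby same-family hits, pre-screening."""

    interval: GenomicInterval
    family: str
    hits: tuple[TranslatedHit, ...]

    @property
    def best_hit(self) -> TranslatedHit:
        return min(self.hits, key=hit_sort_key)


def merge_hits(
    hits: Sequence[TranslatedHit], max_gap_nt: int = 50
) -> list[MergedCandidate]:
    """Merge same-family hits closer than ``max_gap_nt`` into candidates.

    Within each (contig, family) group, hits are sorted by start and merged
    transitively whenever the gap to the growing candidate (next start minus
    current end) is strictly less than ``max_gap_nt``; overlapping hits
    (negative gap) always merge. Merging is strand- and frame-agnostic since
    EVE decay scrambles reading frames. Families never merge with each other.
    """
    groups: dict[tuple[str, str], list[TranslatedHit]] = {}
    for hit in hits:
        groups.setdefault(
            (hit.genome_interval.seq_id, hit.subject_family), []
        ).append(hit)
    candidates: list[MergedCandidate] = []
    for (seq_id, family), group in groups.items():
        group = sorted(group, key=lambda h: (h.genome_interval.start, h.genome_interval.end))
        cluster: list[TranslatedHit] = []
        cluster_end = None
        for hit in group:
            if cluster and hit.genome_interval.start - cluster_end >= max_gap_nt:
                candidates.append(_make_candidate(seq_id, family, cluster))
                cluster = []
                cluster_end = None
            cluster.append(hit)
            end = hit.genome_interval.end
            cluster_end = end if cluster_end is None else max(cluster_end, end)
        if cluster:
            candidates.append(_make_candidate(seq_id, family, cluster))
    candidates.sort(key=lambda c: (c.interval.seq_id, c.interval.start, c.family))
    return candidates


def _make_candidate(
    seq_id: str, family: str, cluster: list[TranslatedHit]
) -> MergedCandidate:
    start = min(h.genome_interval.start for h in cluster)
    end = max(h.genome_interval.end for h in cluster)
    return MergedCandidate(
        interval=GenomicInterval(seq_id=seq_id, start=start, end=end, strand="."),
        family=family,
        hits=tuple(sorted(cluster, key=hit_sort_key)),
    )


def contamination_filter(
    candidates: Sequence[MergedCandidate],
    contigs: Sequence[SequenceRecord],
    min_flank_nt: int = 50,
) -> tuple[list[MergedCandidate], list[tuple[MergedCandidate, str]]]:
    """Discard candidates with no host flank on either side.

    A genuine integration sits inside host sequence; a candidate with fewer
    than ``min_flank_nt`` nucleotides of contig on BOTH sides occupies
    essentially its whole contig and is treated as contamination.
    Returns (retained, discarded-with-reason).
    """
    lengths = {c.id: len(c.seq) for c in contigs}
    retained: list[MergedCandidate] = []
    discarded: list[tuple[MergedCandidate, str]] = []
    for cand in candidates:
        if cand.interval.seq_id not in lengths:
            raise KeyError(f"candidate references unknown contig {cand.interval.seq_id!r}")
        contig_len = lengths[cand.interval.seq_id]
        left = cand.interval.start
        right = contig_len - cand.interval.end
        if left < min_flank_nt and right < min_flank_nt:
            discarded.append((cand, "no host flank"))
            logger.info(
                "discarding %s:%d-%d (%s): no host flank (left=%d, right=%d nt)",
                cand.interval.seq_id, cand.interval.start, cand.interval.end,
                cand.family, left, right,
            )
        else:
            retained.append(cand)
    return retained, discarded


def call_eves(
    assemblies: Mapping[str, Sequence[SequenceRecord]],
    viral_proteome: Sequence[ProteinRecord],
    host_proteome: Sequence[ProteinRecord] = (),
    params: SearchParams | None = None,
    max_gap_nt: int = 50,
    min_flank_nt: int = 50,
    family_codes: Mapping[str, str] | None = None,
    host_screen: bool = True,
) -> list[EveRecord]:
    """Full EVE-calling pipeline over one or more assemblies.

    Stages: translated search -> same-family hit merging -> host-proteome
    false-positive screen -> host-flank contamination filter. Locus labels
    are left as ``np``; cross-assembly placement is a separate step
    (:mod:`bsfvirome.orthology_mapper`).
    """
    params = params or SearchParams()
    codes = dict(FAMILY_SHORT_CODES)
    if family_codes:
        codes.update(family_codes)
    records: list[EveRecord] = []
    for assembly, contigs in assemblies.items():
        seq_by_id = {c.id: c.seq for c in contigs}
        hits = translated_search(contigs, viral_proteome, params)
        candidates = merge_hits(hits, max_gap_nt=max_gap_nt)
        if host_screen and host_proteome:
            pairs = [
                (seq_by_id[c.interval.seq_id][c.interval.start : c.interval.end], c)
                for c in candidates
            ]
            candidates = [c for _, c in host_protein_screen(pairs, host_proteome, params)]
        candidates, _discarded = contamination_filter(
            candidates, contigs, min_flank_nt=min_flank_nt
        )
        for cand in candidates:
            best = cand.best_hit
            short = codes.get(cand.family, cand.family)
            records.append(
                EveRecord(
                    name=f"{short}EVE",
                    assembly=assembly,
                    interval=cand.interval,
                    family=cand.family,
                    best_hit_subject=best.subject_id,
                    best_hit_pct_identity=best.pct_identity,
                    protein_class=best.subject_protein_class,
                )
            )
    return records


@dataclass(frozen=True)
class EveSummary:
    """Table-level summary of a set of EVE calls."""

    total: int
    per_family: dict[str, int]
    span_min: int
    span_max: int
    n_loci: int
    n_contigs_in_assembly: int
    assembly_of_interest: str


def summarize_eves(
    records: Sequence[EveRecord], assembly_of_interest: str
) -> EveSummary:
    """Summarise EVE calls the way a discovery screen is reported.

    Reports total count, per-family counts, the minimum and maximum EVE span,
    the number of distinct placed (non-``np``) loci, and the number of
    distinct contigs/chromosomes bearing at least one EVE in the named
    assembly. Empty input yields an all-zero summary.
    """
    if not records:
        return EveSummary(0, {}, 0, 0, 0, 0, assembly_of_interest)
    per_family: dict[str, int] = {}
    for rec in records:
        per_family[rec.family] = per_family.get(rec.family, 0) + 1
    spans = [rec.interval.span() for rec in records]
    loci = {rec.locus_label for rec in records if rec.locus_label != NO_POSITION}
    contigs = {
        rec.interval.seq_id
        for rec in records
        if rec.assembly == assembly_of_interest
    }
    return EveSummary(
        total=len(records),
        per_family=per_family,
        span_min=min(spans),
        span_max=max(spans),
        n_loci=len(loci),
        n_contigs_in_assembly=len(contigs),
        assembly_of_interest=assembly_of_interest,
    )


def eves_to_tsv(records: Sequence[EveRecord], path: str | Path) -> Path:
    """Write EVE calls as a TSV mirroring the summary-table columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "family": [r.family for r in records],
            "eve_name": [r.name for r in records],
            "locus_label": [r.locus_label for r in records],
            "assembly": [r.assembly for r in records],
            "best_hit": [r.best_hit_subject for r in records],
            "aa_pct": [r.best_hit_pct_identity for r in records],
            "protein_class": [r.protein_class for r in records],
            "contig": [r.interval.seq_id for r in records],
            "start": [r.interval.start for r in records],
            "end": [r.interval.end for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def eves_to_bed(records: Sequence[EveRecord], path: str | Path) -> Path:
    """Write EVE calls as BED (0-based half-open) for genome-browser use."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as handle:
        for r in records:
            name = f"{r.name}_{r.locus_label}" if r.locus_label != NO_POSITION else r.name
            handle.write(
                f"{r.interval.seq_id}\t{r.interval.start}\t{r.interval.end}"
                f"\t{name}\t{r.best_hit_pct_identity:.1f}\t{r.interval.strand}\n"
            )
    return path
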