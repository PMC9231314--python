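"""Built-in translated homology search (nucleotide genome vs protein database).

This is a deliberately small stand-in for a BLASTx/DIAMOND-style search:
six-frame translation, exact amino-acid k-mer seeding, and ungapped X-drop
extension under BLOSUM62. It exists so the downstream EVE-calling logic can be
exercised end to end with no external binaries; externally produced tabular
hits (``outfmt 6``) can be converted to the same :class:`TranslatedHit` type
and are drop-in replacements.

No E-value statistics are computed: hits are ranked and thresholded on raw
substitution score and alignment length. Defaults are calibrated so that
planted viral fragments down to ~40% amino-acid identity remain detectable
while random sequence of the scales used here yields essentially no hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io_formats import GenomicInterval, SequenceRecord, TabularHitRow

__all__ = [
    "ProteinRecord",
    "TranslatedHit",
    "SearchParams",
    "six_frame_translate",
    "translated_search",
    "host_protein_screen",
    "hits_from_tabular",
]

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its taxonomic family and protein-class label."""

    id: str
    seq: str
    family: str = ""
    protein_class: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())


@dataclass(frozen=True)
class TranslatedHit:
    """One translated-search match, located on the genome's forward strand."""

    genome_interval: GenomicInterval
    frame: int
    subject_id: str
    subject_family: str
    subject_protein_class: str
    pct_identity: float
    score: float
    aln_len_aa: int

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise ValueError(f"frame must be in {FRAMES}, got {self.frame}")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of [0,100]: {self.pct_identity}")


@dataclass(frozen=True)
class SearchParams:
    """Knobs of the translated search.

    kmer_k:          exact amino-acid seed length. 3 keeps seed sensitivity
                     adequate for fragments near 30-40% AA identity.
    min_score:       minimum BLOSUM62 sum for a reported hit. 75 keeps the
                     expected number of random hits per ~100 kb x 10-protein
                     search well below one.
    min_aln_len_aa:  minimum extended alignment length in residues.
    xdrop:           extension stops once the running score falls this far
                     below the best score seen (per direction). 40 lets the
                     extension bridge the score dips a ~35% AA identity
                     alignment routinely contains; it does not change which
                     random scores exist, only how completely they are found.
    """

    kmer_k: int = 3
    min_score: float = 75.0
    min_aln_len_aa: int = 20
    xdrop: float = 40.0


_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHABET = _BLOSUM.alphabet


def _blosum_dict() -> dict[tuple[str, str], float]:
    table: dict[tuple[str, str], float] = {}
    for a in _ALPHABET:
        for b in _ALPHABET:
            table[(a, b)] = float(_BLOSUM[a, b])
    return table


_SCORE: dict[tuple[str, str], float] = _blosum_dict()
_UNKNOWN_SCORE = -4.0  # characters outside the matrix alphabet


def _pair_score(a: str, b: str) -> float:
    return _SCORE.get((a, b), _UNKNOWN_SCORE)


def six_frame_translate(seq: str) -> dict[int, str]:
    """Translate all six reading frames of ``seq`` (standard code, stops '*').

    Frames +1..+3 read the forward strand offset by 0..2; frames -1..-3 read
    the reverse complement with the same offsets. Trailing partial codons are
    dropped. Sequences shorter than 3 yield six empty frames.
    """
    seq = seq.upper()
    out: dict[int, str] = {}
    fwd = Seq(seq)
    rev = fwd.reverse_complement()
    for f in (1, 2, 3):
        for strand_seq, frame in ((fwd, f), (rev, -f)):
            sub = strand_seq[f - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            out[frame] = str(sub.translate(table=1)) if len(sub) else ""
    return out


def _frame_to_genome(frame: int, aa_start: int, aa_end: int, seq_len: int) -> tuple[int, int]:
    """Map an AA slice [aa_start, aa_end) of a frame to forward-strand nt coords."""
    offset = abs(frame) - 1
    nt_lo = offset + 3 * aa_start
    nt_hi = offset + 3 * aa_end
    if frame > 0:
        return nt_lo, nt_hi
    return seq_len - nt_hi, seq_len - nt_lo


def _extend(
    qs: str, ps: str, qi: int, pj: int, k: int, xdrop: float
) -> tuple[int, int, float, int]:
    """Ungapped X-drop extension of a k-length seed at (qi, pj).

    Returns (q_start, q_end) of the best-scoring extension in query AA
    coordinates together with its score and match count.
    """
    score = 0.0
    matches = 0
    for t in range(k):
        score += _pair_score(qs[qi + t], ps[pj + t])
        if qs[qi + t] == ps[pj + t]:
            matches += 1
    # right extension
    best, best_right, run = score, 0, score
    run_matches = best_matches_r = 0
    m = 0
    i, j = qi + k, pj + k
    while i < len(qs) and j < len(ps):
        run += _pair_score(qs[i], ps[j])
        if qs[i] == ps[j]:
            m += 1
        if run > best:
            best, best_right, best_matches_r = run, i - (qi + k) + 1, m
        elif run < best - xdrop:
            break
        i += 1
        j += 1
    # left extension
    run = best
    best_left = 0
    m = 0
    best_matches_l = 0
    i, j = qi - 1, pj - 1
    while i >= 0 and j >= 0:
        run += _pair_score(qs[i], ps[j])
        if qs[i] == ps[j]:
            m += 1
        if run > best:
            best, best_left, best_matches_l = run, qi - i, m
        elif run < best - xdrop:
            break
        i -= 1
        j -= 1
    q_start = qi - best_left
    q_end = qi + k + best_right
    total_matches = matches + best_matches_r + best_matches_l
    return q_start, q_end, best, total_matches


def _index_proteins(
    proteins: Sequence[ProteinRecord], k: int
) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for p_idx, prot in enumerate(proteins):
        s = prot.seq
        for j in range(len(s) - k + 1):
            index.setdefault(s[j : j + k], []).append((p_idx, j))
    return index


def hit_sort_key(hit: TranslatedHit) -> tuple:
    """Best-hit ordering: higher score, then higher identity, then subject id."""
    return (-hit.score, -hit.pct_identity, hit.subject_id)


def translated_search(
    genome: Sequence[SequenceRecord],
    proteins: Sequence[ProteinRecord],
    params: SearchParams | None = None,
) -> list[TranslatedHit]:
    """Search genome contigs against a protein database in all six frames.

    For each seed k-mer shared between a translated frame and a protein the
    seed is extended ungapped in both directions under BLOSUM62 with X-drop
    termination. Hits below ``min_score`` or ``min_aln_len_aa`` are dropped;
    per (contig, subject) only the best-scoring hit of any set of mutually
    overlapping hits is kept. Coordinates are reported on the forward strand.
    """
    params = params or SearchParams()
    if not proteins:
        return []
    k = params.kmer_k
    index = _index_proteins(proteins, k)
    raw: list[TranslatedHit] = []
    for contig in genome:
        seq_len = len(contig.seq)
        frames = six_frame_translate(contig.seq)
        for frame in FRAMES:
            qs = frames[frame]
            if len(qs) < k:
                continue
            # per (protein, diagonal): right edge of the last extension, so
            # seeds inside an already-extended region are skipped
            seen_until: dict[tuple[int, int], int] = {}
            for qi in range(len(qs) - k + 1):
                for p_idx, pj in index.get(qs[qi : qi + k], ()):
                    diag = qi - pj
                    if seen_until.get((p_idx, diag), -1) >= qi:
                        continue
                    prot = proteins[p_idx]
                    q_start, q_end, score, matches = _extend(
                        qs, prot.seq, qi, pj, k, params.xdrop
                    )
                    seen_until[(p_idx, diag)] = q_end - k
                    aln_len = q_end - q_start
                    if score < params.min_score or aln_len < params.min_aln_len_aa:
                        continue
                    nt_lo, nt_hi = _frame_to_genome(frame, q_start, q_end, seq_len)
                    raw.append(
                        TranslatedHit(
                            genome_interval=GenomicInterval(
                                seq_id=contig.id,
                                start=nt_lo,
                                end=nt_hi,
                                strand="+" if frame > 0 else "-",
                            ),
                            frame=frame,
                            subject_id=prot.id,
                            subject_family=prot.family,
                            subject_protein_class=prot.protein_class,
                            pct_identity=100.0 * matches / aln_len,
                            score=score,
                            aln_len_aa=aln_len,
                        )
                    )
    return _best_per_region(raw)


def _best_per_region(hits: list[TranslatedHit]) -> list[TranslatedHit]:
    """Per (contig, subject), keep the best hit of each overlapping cluster."""
    kept: list[TranslatedHit] = []
    by_key: dict[tuple[str, str], list[TranslatedHit]] = {}
    for hit in hits:
        by_key.setdefault((hit.genome_interval.seq_id, hit.subject_id), []).append(hit)
    for group in by_key.values():
        group.sort(key=hit_sort_key)
        chosen: list[TranslatedHit] = []
        for hit in group:
            if not any(hit.genome_interval.overlaps(c.genome_interval) for c in chosen):
                chosen.append(hit)
        kept.extend(chosen)
    kept.sort(
        key=lambda h: (h.genome_interval.seq_id, h.genome_interval.start, h.subject_id)
    )
    return kept


def host_protein_screen(
    candidates: Sequence[tuple[str, object]],
    host_proteome: Sequence[ProteinRecord],
    params: SearchParams | None = None,
) -> list[tuple[str, object]]:
    """False-positive screen against the host proteome.

    ``candidates`` are (nucleotide sequence, payload) pairs; a candidate is
    discarded iff a translated search of its sequence against the host
    proteome produces any hit under the same thresholds. Order is preserved.
    """
    params = params or SearchParams()
    retained: list[tuple[str, object]] = []
    for i, (nt_seq, payload) in enumerate(candidates):
        query = [SequenceRecord(id=f"candidate_{i}", seq=nt_seq)]
        if not translated_search(query, host_proteome, params):
            retained.append((nt_seq, payload))
    return retained


def hits_from_tabular(
    rows: Iterable[TabularHitRow],
    taxonomy: Mapping[str, tuple[str, str]],
    default_frame: int = 1,
) -> list[TranslatedHit]:
    """Convert externally produced 12-column rows to :class:`TranslatedHit`.

    Query coordinates in the tabular dialect are 1-based inclusive nucleotide
    positions on the query (genome) with q_start > q_end for minus-strand
    hits; ``taxonomy`` maps subject id -> (family, protein_class).
    """
    out: list[TranslatedHit] = []
    for row in rows:
        lo, hi = sorted((row.q_start, row.q_end))
        strand = "+" if row.q_end >= row.q_start else "-"
        family, protein_class = taxonomy.get(row.subject_id, ("", ""))
        out.append(
            TranslatedHit(
                genome_interval=GenomicInterval(
                    seq_id=row.query_id, start=lo - 1, end=hi, strand=strand
                ),
                frame=default_frame if strand == "+" else -default_frame,
                subject_id=row.subject_id,
                subject_family=family,
                subject_protein_class=protein_class,
                pct_identity=row.pct_identity,
                score=row.bitscore,
                aln_len_aa=row.aln_length,
            )
        )
    return out
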