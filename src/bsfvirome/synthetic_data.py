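"""Ground-truth synthetic inputs for every stage of the pipeline.

The generator emulates the situations the pipeline must resolve, with truth
labels attached: host genome assemblies carrying planted, sequence-degraded
viral fragments (orthologous across assemblies when their insertion site and
flanking sequence are shared), a labelled viral protein reference, a host
proteome (optionally salted with a viral "decoy" to exercise the
false-positive screen), and error-free RNA-seq reads with known per-feature
counts.

Stated world, fixed once:
- host background is i.i.d. uniform nucleotides (the screens under test are
  homology- and interval-based, not repeat-aware);
- EVE degradation is substitution-only toward a target nucleotide identity,
  so realized identity is exactly controllable;
- reverse translation draws codons uniformly per residue;
- reads are error-free, single-end, uniform-start.

Everything is reproducible: the same seed regenerates every sequence
byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .homology_search import ProteinRecord, six_frame_translate
from .io_formats import GenomicInterval, SequenceRecord

__all__ = [
    "SpecError",
    "EvePlantSpec",
    "PlantedEve",
    "SyntheticTruth",
    "generate_viral_proteome",
    "plant_eves",
    "generate_host_proteome",
    "simulate_reads",
    "reverse_translate",
    "totivirus_like_contig",
    "EveScenario",
    "default_eve_scenario",
    "orthology_scenario",
    "match_calls_to_truth",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"
PROTEIN_CLASSES = ("Capsid", "RdRP", "ORF1")
FLANK_WINDOW_NT = 20_000  # conserved-flank extent around an orthologous insertion

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_CODON_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)


class SpecError(ValueError):
    """A planting specification is internally inconsistent."""


@dataclass(frozen=True)
class EvePlantSpec:
    """One endogenization event to plant.

    ``fragment_aa_range`` selects a half-open residue slice of the source
    protein; ``target_nt_identity`` is the nucleotide identity of the planted
    copy to its clean reverse translation (substitutions only, so it is
    realized exactly up to rounding). ``insert_contig`` names the per-assembly
    contig and ``insert_pos`` the 0-based start of the EVE. When
    ``flank_conserved`` and several assemblies are listed, the insertion site
    and up to 20 kb of flanking sequence are shared across those assemblies.
    ``tag`` is free text carried into the truth record (e.g. "edge", "decoy").
    """

    family: str
    source_protein_id: str
    fragment_aa_range: tuple[int, int]
    target_nt_identity: float
    insert_contig: str
    insert_pos: int
    present_in_assemblies: frozenset[str]
    flank_conserved: bool = True
    tag: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.fragment_aa_range
        if hi - lo < 30:
            raise SpecError("EVE fragment must be at least 30 aa")
        if not 0.3 <= self.target_nt_identity <= 1.0:
            raise SpecError(
                "target_nt_identity below 0.3 is outside the detectable regime; "
                "truth labels cannot promise recovery there"
            )
        if not self.present_in_assemblies:
            raise SpecError("present_in_assemblies must be non-empty")


@dataclass(frozen=True)
class PlantedEve:
    """Truth record of one planted EVE instance."""

    assembly: str
    interval: GenomicInterval
    family: str
    source_protein_id: str
    realized_identity: float
    tag: str = ""


@dataclass
class SyntheticTruth:
    """Everything a recovery test needs to score the pipeline."""

    planted_eves: list[PlantedEve] = field(default_factory=list)
    transcript_abundances: dict[str, float] = field(default_factory=dict)
    seeds: list[int] = field(default_factory=list)


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(AA_ALPHABET))[rng.integers(0, 20, size=n)])


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(NT_ALPHABET))[rng.integers(0, 4, size=n)])


def generate_viral_proteome(
    n_per_family: int,
    families: Sequence[str],
    mean_len_aa: int = 500,
    seed: int = 0,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Random labelled viral proteins plus their taxonomy table.

    Sequences are i.i.d. uniform over the 20 amino acids; lengths are drawn
    around ``mean_len_aa`` (+-10%); each protein carries a family and a
    protein-class label cycling through Capsid/RdRP/ORF1.
    """
    if n_per_family < 1:
        raise ValueError("n_per_family must be >= 1")
    if not families:
        raise ValueError("families must be non-empty")
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    rows = []
    for family in families:
        for i in range(n_per_family):
            lo = max(30, int(mean_len_aa * 0.9))
            hi = max(lo + 1, int(mean_len_aa * 1.1))
            length = int(rng.integers(lo, hi))
            pid = f"{family[:4].upper()}_{i + 1:03d}"
            protein_class = PROTEIN_CLASSES[i % len(PROTEIN_CLASSES)]
            records.append(
                ProteinRecord(
                    id=pid,
                    seq=_random_aa(rng, length),
                    family=family,
                    protein_class=protein_class,
                )
            )
            rows.append(
                {"protein_id": pid, "family": family, "protein_class": protein_class}
            )
    return records, pd.DataFrame(rows)


def reverse_translate(protein_aa: str, rng: np.random.Generator) -> str:
    """Reverse-translate a protein, drawing codons uniformly per residue."""
    codons = []
    for aa in protein_aa:
        options = _CODONS_FOR.get(aa)
        if options is None:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        codons.append(options[int(rng.integers(0, len(options)))])
    return "".join(codons)


def _mutate_to_identity(seq: str, identity: float, rng: np.random.Generator) -> tuple[str, float]:
    """Substitute positions so the result has exactly the target identity."""
    n = len(seq)
    n_mut = round((1.0 - identity) * n)
    if n_mut == 0:
        return seq, 1.0
    positions = rng.choice(n, size=n_mut, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [c for c in NT_ALPHABET if c != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars), 1.0 - n_mut / n


def plant_eves(
    assembly_specs: Mapping[str, tuple[int, int]],
    eve_specs: Sequence[EvePlantSpec],
    proteome: Sequence[ProteinRecord],
    seed: int = 0,
) -> tuple[dict[str, list[SequenceRecord]], SyntheticTruth]:
    """Generate host assemblies with EVEs planted at known positions.

    ``assembly_specs`` maps assembly name -> (n_contigs, contig_len); contigs
    are named ``c1..cN`` within each assembly (edge-case contigs may be named
    explicitly via specs referencing indices within range). Each planted EVE
    is the reverse translation of the specified protein fragment, point-
    mutated once to the target identity and shared verbatim across the
    assemblies that carry it; with ``flank_conserved`` the surrounding
    sequence (up to +-20 kb, clipped to the contig) is shared too.

    Insert positions must leave at least 50 nt of host flank on both sides
    unless the spec deliberately places the EVE at a contig edge (to exercise
    the contamination filter). Overlapping inserts raise :class:`SpecError`.
    """
    rng = np.random.default_rng(seed)
    proteins = {p.id: p for p in proteome}
    assemblies: dict[str, list[str]] = {}
    contig_lens: dict[str, list[int]] = {}
    for name in sorted(assembly_specs):
        n_contigs, contig_len = assembly_specs[name]
        assemblies[name] = [_random_nt(rng, contig_len) for _ in range(n_contigs)]
        contig_lens[name] = [contig_len] * n_contigs

    truth = SyntheticTruth(seeds=[seed])
    occupied: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for spec in eve_specs:
        protein = proteins.get(spec.source_protein_id)
        if protein is None:
            raise SpecError(f"unknown source protein {spec.source_protein_id!r}")
        lo, hi = spec.fragment_aa_range
        if hi > len(protein.seq):
            raise SpecError(
                f"fragment {lo}-{hi} exceeds protein {protein.id} length {len(protein.seq)}"
            )
        clean_nt = reverse_translate(protein.seq[lo:hi], rng)
        eve_nt, realized = _mutate_to_identity(clean_nt, spec.target_nt_identity, rng)
        eve_len = len(eve_nt)
        targets = sorted(spec.present_in_assemblies)
        for a in targets:
            if a not in assemblies:
                raise SpecError(f"spec targets unknown assembly {a!r}")
        conserved = spec.flank_conserved and len(targets) > 1
        shared_left = _random_nt(rng, FLANK_WINDOW_NT) if conserved else ""
        shared_right = _random_nt(rng, FLANK_WINDOW_NT) if conserved else ""
        for assembly in targets:
            idx = _contig_index(spec.insert_contig, len(assemblies[assembly]))
            contig_len = contig_lens[assembly][idx]
            start, end = spec.insert_pos, spec.insert_pos + eve_len
            if start < 0 or end > contig_len:
                raise SpecError(
                    f"insert {start}-{end} outside contig of length {contig_len}"
                )
            left, right = start, contig_len - end
            if (left < 50 or right < 50) and not (left == 0 or right == 0):
                raise SpecError(
                    "insert leaves <50 nt flank without touching a contig edge"
                )
            key = (assembly, spec.insert_contig)
            for o_start, o_end in occupied.get(key, ()):
                if start < o_end and o_start < end:
                    raise SpecError(
                        f"insert {start}-{end} overlaps a previous insert on "
                        f"{assembly}/{spec.insert_contig}"
                    )
            occupied.setdefault(key, []).append((start, end))
            contig = assemblies[assembly][idx]
            if conserved:
                l_ext = min(FLANK_WINDOW_NT, start)
                r_ext = min(FLANK_WINDOW_NT, contig_len - end)
                cassette = shared_left[len(shared_left) - l_ext :] + eve_nt + shared_right[:r_ext]
                contig = contig[: start - l_ext] + cassette + contig[end + r_ext :]
            else:
                contig = contig[:start] + eve_nt + contig[end:]
            assemblies[assembly][idx] = contig
            truth.planted_eves.append(
                PlantedEve(
                    assembly=assembly,
                    interval=GenomicInterval(
                        seq_id=spec.insert_contig, start=start, end=end, strand="."
                    ),
                    family=spec.family,
                    source_protein_id=spec.source_protein_id,
                    realized_identity=realized,
                    tag=spec.tag,
                )
            )
    out = {
        name: [
            SequenceRecord(id=f"c{i + 1}", seq=seq)
            for i, seq in enumerate(contigs)
        ]
        for name, contigs in assemblies.items()
    }
    return out, truth


def _contig_index(name: str, n_contigs: int) -> int:
    if not name.startswith("c"):
        raise SpecError(f"contig names are c1..cN, got {name!r}")
    idx = int(name[1:]) - 1
    if not 0 <= idx < n_contigs:
        raise SpecError(f"contig {name!r} out of range (assembly has {n_contigs})")
    return idx


def generate_host_proteome(
    assemblies: Mapping[str, Sequence[SequenceRecord]],
    n_proteins: int = 10,
    seed: int = 0,
    decoys: Sequence[ProteinRecord] = (),
    avoid: Sequence[PlantedEve] = (),
    min_len_aa: int = 40,
) -> list[ProteinRecord]:
    """Host proteins as translations of randomly chosen host genome stretches.

    Each protein is the longest stop-free run of a translated random window
    (frame +1) of a host contig; windows overlapping planted EVEs (``avoid``)
    are rejected so the proteome stays genuinely host-derived. ``decoys`` are
    appended verbatim, re-labelled as host proteins, to exercise the
    false-positive screen's discard path.
    """
    rng = np.random.default_rng(seed)
    pool = [
        (name, contig)
        for name, contigs in sorted(assemblies.items())
        for contig in contigs
    ]
    blocked: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for eve in avoid:
        blocked.setdefault((eve.assembly, eve.interval.seq_id), []).append(
            (eve.interval.start, eve.interval.end)
        )
    proteins: list[ProteinRecord] = []
    attempts = 0
    window_nt = 3000
    while len(proteins) < n_proteins and attempts < 50 * n_proteins:
        attempts += 1
        name, contig = pool[int(rng.integers(0, len(pool)))]
        if len(contig.seq) <= window_nt:
            continue
        start = int(rng.integers(0, len(contig.seq) - window_nt))
        if any(
            start < e and s < start + window_nt
            for s, e in blocked.get((name, contig.id), ())
        ):
            continue
        aa = six_frame_translate(contig.seq[start : start + window_nt])[1]
        longest = max(aa.split("*"), key=len)
        if len(longest) < min_len_aa:
            continue
        proteins.append(
            ProteinRecord(
                id=f"HOST_{len(proteins) + 1:03d}",
                seq=longest,
                family="host",
                protein_class="",
            )
        )
    if len(proteins) < n_proteins:
        raise RuntimeError("could not sample enough host proteins; contigs too short?")
    for i, decoy in enumerate(decoys, start=1):
        proteins.append(
            ProteinRecord(
                id=f"HOST_DECOY_{i:03d}", seq=decoy.seq, family="host", protein_class=""
            )
        )
    return proteins


def simulate_reads(
    features: Sequence[tuple[str, str, int]],
    read_len: int = 100,
    seed: int = 0,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Exactly ``true_count`` error-free reads per (id, sequence, count) feature.

    Start positions are uniform; reads are plus-strand substrings. The truth
    records each feature's share of the total read mass.
    """
    rng = np.random.default_rng(seed)
    for fid, seq, _count in features:
        if len(seq) < read_len:
            raise SpecError(
                f"feature {fid!r} ({len(seq)} nt) shorter than read length {read_len}"
            )
    reads: list[SequenceRecord] = []
    total = sum(count for _, _, count in features)
    truth = SyntheticTruth(seeds=[seed])
    for fid, seq, count in features:
        starts = rng.integers(0, len(seq) - read_len + 1, size=count)
        for i, start in enumerate(starts, start=1):
            reads.append(
                SequenceRecord(
                    id=f"{fid}_r{i}", seq=seq[int(start) : int(start) + read_len]
                )
            )
        truth.transcript_abundances[fid] = count / total if total else 0.0
    return reads, truth


def totivirus_like_contig(
    gag_len_aa: int = 660,
    pol_len_aa: int = 900,
    total_len_nt: int = 7247,
    seed: int = 0,
) -> tuple[SequenceRecord, dict[str, GenomicInterval]]:
    """A totivirus-organised contig: 5'UTR, GAG ORF, spacer, POL ORF, 3'UTR.

    An in-frame stop immediately precedes each ATG so the annotated ORF starts
    exactly where planted. Returns the contig and the expected GAG/POL
    intervals (stop codon included).
    """
    rng = np.random.default_rng(seed)
    gag_nt = "ATG" + reverse_translate(_random_aa(rng, gag_len_aa - 1), rng) + "TAA"
    pol_nt = "ATG" + reverse_translate(_random_aa(rng, pol_len_aa - 1), rng) + "TAA"
    core = "TAA" + gag_nt + _random_nt(rng, 30) + "TAA" + pol_nt
    utr_budget = total_len_nt - len(core)
    if utr_budget < 20:
        raise SpecError("total_len_nt too short for the requested ORFs")
    left = utr_budget // 2
    contig_seq = _random_nt(rng, left) + core + _random_nt(rng, utr_budget - left)
    gag_start = left + 3
    pol_start = left + 3 + len(gag_nt) + 30 + 3
    expected = {
        "GAG": GenomicInterval("totivirus_like", gag_start, gag_start + len(gag_nt), "+"),
        "POL": GenomicInterval("totivirus_like", pol_start, pol_start + len(pol_nt), "+"),
    }
    return SequenceRecord(id="totivirus_like", seq=contig_seq), expected


@dataclass
class EveScenario:
    """A complete synthetic EVE-discovery world with its truth."""

    assemblies: dict[str, list[SequenceRecord]]
    viral_proteome: list[ProteinRecord]
    taxonomy: pd.DataFrame
    host_proteome: list[ProteinRecord]
    truth: SyntheticTruth
    reference_assembly: str
    eve_specs: list[EvePlantSpec]


# Locus plan mirroring a three-assembly screen: five loci shared by all three
# assemblies, three shared by two, one private to the reference — nine in all
# — plus one flankless (contamination) insert and one host-decoy insert.
_DEFAULT_LOCI: list[tuple[str, frozenset[str], float]] = [
    ("Totiviridae", frozenset({"A1", "A2", "A3"}), 0.65),
    ("Totiviridae", frozenset({"A1", "A2", "A3"}), 0.70),
    ("Totiviridae", frozenset({"A1", "A2", "A3"}), 0.75),
    ("Partitiviridae", frozenset({"A1", "A2", "A3"}), 0.80),
    ("Rhabdoviridae", frozenset({"A1", "A2", "A3"}), 0.85),
    ("Parvoviridae", frozenset({"A2", "A3"}), 0.60),
    ("Parvoviridae", frozenset({"A2", "A3"}), 0.90),
    ("Parvoviridae", frozenset({"A1", "A3"}), 0.70),
    ("Xinmoviridae", frozenset({"A3"}), 0.60),
]

DEFAULT_FAMILIES = (
    "Partitiviridae",
    "Parvoviridae",
    "Rhabdoviridae",
    "Totiviridae",
    "Xinmoviridae",
)


def default_eve_scenario(seed: int = 0, contig_len: int = 30_000) -> EveScenario:
    """The canonical three-assembly scenario used by recovery tests.

    Nine orthologous loci (fragment identities 0.6-0.9, lengths 120-250 aa),
    one EVE occupying an entire short contig (no host flank -> the
    contamination filter must discard it) and one decoy insert whose source
    protein also sits in the host proteome (the false-positive screen must
    discard it). Contigs c1..c9 carry one locus each; c10 is the flankless
    contig (present only meaningfully in A2); c11 carries the decoy in A1.
    """
    rng = np.random.default_rng(seed)
    proteome, taxonomy = generate_viral_proteome(
        n_per_family=2, families=list(DEFAULT_FAMILIES), mean_len_aa=500, seed=seed
    )
    by_family: dict[str, list[ProteinRecord]] = {}
    for p in proteome:
        by_family.setdefault(p.family, []).append(p)

    specs: list[EvePlantSpec] = []
    per_family_use: dict[str, int] = {}
    eve_len_nt_edge = None
    for i, (family, present, identity) in enumerate(_DEFAULT_LOCI):
        use = per_family_use.get(family, 0)
        protein = by_family[family][use % len(by_family[family])]
        per_family_use[family] = use + 1
        frag_len = int(rng.integers(120, 251))
        frag_lo = int(rng.integers(0, len(protein.seq) - frag_len))
        specs.append(
            EvePlantSpec(
                family=family,
                source_protein_id=protein.id,
                fragment_aa_range=(frag_lo, frag_lo + frag_len),
                target_nt_identity=identity,
                insert_contig=f"c{i + 1}",
                insert_pos=contig_len // 2,
                present_in_assemblies=present,
                flank_conserved=True,
                tag="locus",
            )
        )
    # flankless insert: the EVE spans its entire (short) contig c10
    edge_protein = by_family["Totiviridae"][0]
    edge_frag = (0, 200)
    eve_len_nt_edge = 3 * (edge_frag[1] - edge_frag[0])
    specs.append(
        EvePlantSpec(
            family="Totiviridae",
            source_protein_id=edge_protein.id,
            fragment_aa_range=edge_frag,
            target_nt_identity=0.95,
            insert_contig="c10",
            insert_pos=0,
            present_in_assemblies=frozenset({"A2"}),
            flank_conserved=False,
            tag="edge",
        )
    )
    # decoy insert: its source protein is copied into the host proteome.
    # Partitiviridae's second protein seeds no genuine locus, so the host
    # screen removes only the decoy.
    decoy_protein = by_family["Partitiviridae"][1]
    specs.append(
        EvePlantSpec(
            family="Partitiviridae",
            source_protein_id=decoy_protein.id,
            fragment_aa_range=(0, 150),
            target_nt_identity=1.0,
            insert_contig="c11",
            insert_pos=contig_len // 2,
            present_in_assemblies=frozenset({"A1"}),
            flank_conserved=False,
            tag="decoy",
        )
    )

    assembly_specs = {name: (11, contig_len) for name in ("A1", "A2", "A3")}
    assemblies, truth = plant_eves(assembly_specs, specs, proteome, seed=seed)
    # shrink c10 to exactly the edge EVE in every assembly: a contig that is
    # all-viral in A2 and a short random stub elsewhere
    for name in assemblies:
        contig = assemblies[name][9]
        assemblies[name][9] = SequenceRecord(id=contig.id, seq=contig.seq[:eve_len_nt_edge])
    host_proteome = generate_host_proteome(
        assemblies,
        n_proteins=10,
        seed=seed + 1,
        decoys=[decoy_protein],
        avoid=truth.planted_eves,
    )
    return EveScenario(
        assemblies=assemblies,
        viral_proteome=proteome,
        taxonomy=taxonomy,
        host_proteome=host_proteome,
        truth=truth,
        reference_assembly="A3",
        eve_specs=specs,
    )


def orthology_scenario(
    seed: int = 0, contig_len: int = 8_000
) -> tuple[EveScenario, dict[str, set[tuple[str, str]]]]:
    """A small randomized three-assembly world for locus-assignment tests.

    Plants 3-5 loci with conserved flanks at identity 1.0 (orthologs are
    verbatim copies), each present in a random subset of assemblies that
    includes the reference, plus up to one locus absent from the reference
    (whose members must come back unplaced). Returns the scenario and the
    expected partition: locus key -> set of (assembly, contig) members; the
    key "np" collects expected-unplaced members.
    """
    rng = np.random.default_rng(seed)
    families = list(DEFAULT_FAMILIES)
    proteome, taxonomy = generate_viral_proteome(
        n_per_family=2, families=families, mean_len_aa=300, seed=seed
    )
    by_family: dict[str, list[ProteinRecord]] = {}
    for p in proteome:
        by_family.setdefault(p.family, []).append(p)
    n_loci = int(rng.integers(3, 6))
    assemblies_all = ("A1", "A2", "A3")
    reference = "A3"
    specs: list[EvePlantSpec] = []
    expected: dict[str, set[tuple[str, str]]] = {"np": set()}
    include_orphan = bool(rng.integers(0, 2))
    for i in range(n_loci):
        family = families[int(rng.integers(0, len(families)))]
        protein = by_family[family][int(rng.integers(0, 2))]
        frag_len = int(rng.integers(100, 181))
        frag_lo = int(rng.integers(0, len(protein.seq) - frag_len))
        if include_orphan and i == n_loci - 1:
            members = frozenset({"A1", "A2"})  # absent from the reference
        else:
            others = [a for a in assemblies_all if a != reference and rng.integers(0, 2)]
            members = frozenset({reference, *others})
        spec = EvePlantSpec(
            family=family,
            source_protein_id=protein.id,
            fragment_aa_range=(frag_lo, frag_lo + frag_len),
            target_nt_identity=1.0,
            insert_contig=f"c{i + 1}",
            insert_pos=contig_len // 2,
            present_in_assemblies=members,
            flank_conserved=True,
            tag=f"locus{i + 1}",
        )
        specs.append(spec)
        key = spec.tag if reference in members else "np"
        expected.setdefault(key, set())
        for assembly in members:
            expected[key].add((assembly, spec.insert_contig))
    assembly_specs = {name: (n_loci, contig_len) for name in assemblies_all}
    assemblies, truth = plant_eves(assembly_specs, specs, proteome, seed=seed)
    scenario = EveScenario(
        assemblies=assemblies,
        viral_proteome=proteome,
        taxonomy=taxonomy,
        host_proteome=[],
        truth=truth,
        reference_assembly=reference,
        eve_specs=specs,
    )
    return scenario, expected


def match_calls_to_truth(
    truth: SyntheticTruth,
    calls: Sequence,
    include_tags: Iterable[str] = ("locus",),
) -> tuple[int, int, int]:
    """Score EVE calls against planted truth.

    A truth instance (with a tag in ``include_tags``) counts as recovered
    when a call in the same assembly overlaps its interval with the same
    family; a call overlapping no planted interval at all (any tag) is a
    false positive. Returns (n_truth, n_recovered, n_false_positive).
    """
    wanted = [e for e in truth.planted_eves if e.tag in set(include_tags)]
    recovered = 0
    for eve in wanted:
        if any(
            call.assembly == eve.assembly
            and call.family == eve.family
            and call.interval.overlaps(eve.interval)
            for call in calls
        ):
            recovered += 1
    false_positives = 0
    for call in calls:
        if not any(
            call.assembly == eve.assembly and call.interval.overlaps(eve.interval)
            for eve in truth.planted_eves
        ):
            false_positives += 1
    return len(wanted), recovered, false_positives
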