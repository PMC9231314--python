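import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bsfvirome.io_formats import SequenceRecord
from bsfvirome.synthetic_data import _random_nt, totivirus_like_contig
from bsfvirome.virus_annotator import (
    Alignment,
    concat_alignments,
    find_orfs,
    pairwise_identity,
    read_alignment,
    triage_viral_contigs,
    trim_alignment,
    write_alignment,
)


class TestFindOrfs:
    def test_minimal_orf(self):
        ann = find_orfs(SequenceRecord(id="c", seq="ATGAAATAA"), min_len_aa=2)
        assert len(ann.orfs) == 1
        orf = ann.orfs[0]
        assert (orf.interval.start, orf.interval.end) == (0, 9)  # stop included
        assert orf.length_aa == 2

    def test_short_orfs_filtered(self):
        ann = find_orfs(SequenceRecord(id="c", seq="ATGAAATAA"), min_len_aa=3)
        assert ann.orfs == ()

    def test_planted_two_orf_contig_recovered_with_labels(self):
        contig, expected = totivirus_like_contig(
            gag_len_aa=400, pol_len_aa=620, total_len_nt=7247, seed=5
        )
        ann = find_orfs(contig, min_len_aa=150)
        gag, pol = ann.labelled("GAG"), ann.labelled("POL")
        assert gag is not None and pol is not None
        assert (gag.interval.start, gag.interval.end) == (
            expected["GAG"].start, expected["GAG"].end
        )
        assert (pol.interval.start, pol.interval.end) == (
            expected["POL"].start, expected["POL"].end
        )
        assert gag.interval.start < pol.interval.start  # GAG is 5' of POL

    def test_random_sequence_rarely_has_long_orfs(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ann = find_orfs(
                SequenceRecord(id="c", seq=_random_nt(rng, 1_000)), min_len_aa=300
            )
            hits += bool(ann.orfs)
        assert hits == 0  # stop codons every ~20 codons make 300-mers vanishing

    def test_reverse_complement_mirrors_coordinates(self):
        contig, _ = totivirus_like_contig(400, 620, 7247, seed=6)
        rc = SequenceRecord(
            id="c", seq=contig.seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        )
        n = len(contig.seq)
        fwd = {(o.interval.start, o.interval.end, o.interval.strand)
               for o in find_orfs(contig, 150).orfs}
        rev = {(n - o.interval.end, n - o.interval.start,
                {"+": "-", "-": "+"}[o.interval.strand])
               for o in find_orfs(rc, 150).orfs}
        assert fwd == rev


class TestTriage:
    def test_long_two_orf_contig_near_complete(self):
        contig, _ = totivirus_like_contig(660, 900, 7247, seed=1)
        partition = triage_viral_contigs([contig])
        assert [a.contig_id for a in partition["near_complete"]] == ["totivirus_like"]
        assert partition["partial"] == []

    def test_short_single_orf_fragment_partial(self, rng):
        seq = "TAAATG" + "GCT" * 400 + "TAA"
        contig = SequenceRecord(id="frag", seq=_random_nt(rng, 400) + seq + _random_nt(rng, 400))
        partition = triage_viral_contigs([contig])
        assert [a.contig_id for a in partition["partial"]] == ["frag"]

    def test_mixed_partition_sizes_and_order_invariance(self, rng):
        longs = [
            totivirus_like_contig(500, 700, 6_500, seed=s)[0] for s in range(5)
        ]
        longs = [SequenceRecord(id=f"long{i}", seq=c.seq) for i, c in enumerate(longs)]
        shorts = [
            SequenceRecord(id=f"short{i}", seq=_random_nt(rng, 1_500))
            for i in range(48)
        ]
        contigs = longs + shorts
        partition = triage_viral_contigs(contigs)
        assert len(partition["near_complete"]) == 5
        assert len(partition["partial"]) == 48
        shuffled = list(contigs)
        np.random.default_rng(0).shuffle(shuffled)
        again = triage_viral_contigs(shuffled)
        assert {a.contig_id for a in again["near_complete"]} == {
            a.contig_id for a in partition["near_complete"]
        }

    def test_length_bar_is_strict(self):
        contig, _ = totivirus_like_contig(300, 400, 5_000, seed=2)
        partition = triage_viral_contigs([contig])
        assert partition["near_complete"] == []  # 5000 nt is not "longer than 5 kb"


def aln(*rows):
    return Alignment(rows=tuple((f"t{i}", seq) for i, seq in enumerate(rows)))


class TestTrimAlignment:
    def test_exact_boundary_occupancy_kept(self):
        # interior column with occupancy exactly 10% (1 residue in 10 rows):
        # "at least 10%" is inclusive, so it survives the filter
        rows = ["AAA"] + ["A-A"] * 9
        trimmed = trim_alignment(aln(*rows))
        assert trimmed.n_cols == 3

    def test_all_gap_column_removed(self):
        trimmed = trim_alignment(aln("A-A", "A-A", "A-A"))
        assert [seq for _, seq in trimmed.rows] == ["AA", "AA", "AA"]

    def test_low_occupancy_ends_trimmed(self):
        # leading/trailing columns below 50% occupancy are cut before filtering
        trimmed = trim_alignment(aln("A--A", "-AAA", "--A-", "--AA"))
        assert trimmed.n_cols == 2  # first col 25%, second col 25% -> trimmed

    def test_matches_per_column_oracle(self, rng):
        for _ in range(50):
            a = _random_alignment(rng)
            trimmed = trim_alignment(a)
            assert [seq for _, seq in trimmed.rows] == _oracle_trim(a)

    def test_idempotent(self, rng):
        for _ in range(25):
            a = _random_alignment(rng)
            once = trim_alignment(a)
            assert trim_alignment(once) == once

    def test_lower_occupancy_keeps_more(self, rng):
        a = _random_alignment(rng)
        assert trim_alignment(a, min_occupancy=0.05).n_cols >= trim_alignment(
            a, min_occupancy=0.30
        ).n_cols


def _random_alignment(rng, max_rows=12, max_cols=40):
    n_rows = int(rng.integers(2, max_rows))
    n_cols = int(rng.integers(1, max_cols))
    letters = np.array(list("ACDEFGHIKL-"))
    mat = letters[rng.integers(0, len(letters), size=(n_rows, n_cols))]
    return Alignment(
        rows=tuple((f"t{i}", "".join(row)) for i, row in enumerate(mat))
    )


def _oracle_trim(a, min_occupancy=0.10, end_occupancy=0.50):
    """Column-by-column recount, independent of the vectorised implementation."""
    cols = list(zip(*[seq for _, seq in a.rows]))
    occ = [sum(ch != "-" for ch in col) / len(col) for col in cols]
    dense = [i for i, o in enumerate(occ) if o >= end_occupancy]
    if not dense:
        return ["" for _ in a.rows]
    keep = [i for i in range(dense[0], dense[-1] + 1) if occ[i] >= min_occupancy]
    return ["".join(seq[i] for i in keep) for _, seq in a.rows]


class TestConcatAlignments:
    def test_simple_concat(self):
        one = Alignment(rows=(("t", "AB"),))
        two = Alignment(rows=(("t", "CD"),))
        combined = concat_alignments([one, two])
        assert combined.rows == (("t", "ABCD"),)
        assert combined.partitions == (("part1", 0, 2), ("part2", 2, 4))

    def test_widths_add(self, rng):
        a = _random_alignment(rng, max_rows=4, max_cols=101)
        b = Alignment(rows=tuple(
            (t, "".join("ACDEFGHIKL-"[int(rng.integers(0, 11))] for _ in range(250)))
            for t, _ in a.rows
        ))
        assert concat_alignments([a, b]).n_cols == a.n_cols + b.n_cols

    def test_row_order_keyed_by_taxon(self):
        one = Alignment(rows=(("x", "AA"), ("y", "CC")))
        two = Alignment(rows=(("y", "GG"), ("x", "TT")))
        combined = concat_alignments([one, two])
        assert combined.rows == (("x", "AATT"), ("y", "CCGG"))

    def test_taxon_mismatch_lists_offenders(self):
        one = Alignment(rows=(("x", "AA"),))
        two = Alignment(rows=(("z", "GG"),))
        with pytest.raises(ValueError, match="missing \\['x'\\]"):
            concat_alignments([one, two])


class TestPairwiseIdentity:
    def test_identical_rows(self):
        mat = pairwise_identity(aln("ACDE", "ACDE"))
        assert mat[0, 1] == 100.0

    def test_three_quarters(self):
        assert pairwise_identity(aln("AAAA", "AAAT"))[0, 1] == 75.0

    def test_gaps_excluded_from_denominator(self):
        mat = pairwise_identity(aln("AA--", "AAAA"))
        assert mat[0, 1] == 100.0  # only 2 co-occupied columns, both match

    def test_disjoint_occupancy_is_nan(self):
        mat = pairwise_identity(aln("AA--", "--AA"))
        assert np.isnan(mat[0, 1])

    def test_matches_hand_count(self, rng):
        a = _random_alignment(rng, max_rows=3, max_cols=30)
        mat = pairwise_identity(a)
        r0, r1 = a.rows[0][1], a.rows[1][1]
        both = [(x, y) for x, y in zip(r0, r1) if x != "-" and y != "-"]
        if both:
            expected = 100.0 * sum(x == y for x, y in both) / len(both)
            assert mat[0, 1] == pytest.approx(expected)


def test_alignment_fasta_round_trip(tmp_path):
    a = aln("AC-E", "ACDE", "A--E")
    p = write_alignment(a, tmp_path / "aln.fasta")
    assert read_alignment(p) == a
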