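import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bsfvirome.eve_caller import (
    EveRecord,
    call_eves,
    contamination_filter,
    merge_hits,
    summarize_eves,
)
from bsfvirome.homology_search import TranslatedHit
from bsfvirome.io_formats import GenomicInterval, SequenceRecord
from bsfvirome.fixtures import load_fixture, table1_eve_records


def make_hit(seq_id, start, end, family="Totiviridae", subject="P1", score=100.0,
             identity=50.0):
    return TranslatedHit(
        genome_interval=GenomicInterval(seq_id, start, end, "+"),
        frame=1, subject_id=subject, subject_family=family,
        subject_protein_class="Capsid", pct_identity=identity, score=score,
        aln_len_aa=max(1, (end - start) // 3),
    )


def oracle_merge(hits, max_gap=50):
    """Brute-force transitive interval clustering, independent of merge_hits."""
    def linked(a, b):
        ia, ib = a.genome_interval, b.genome_interval
        if ia.seq_id != ib.seq_id or a.subject_family != b.subject_family:
            return False
        gap = max(ia.start, ib.start) - min(ia.end, ib.end)
        return gap < max_gap

    n = len(hits)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if linked(hits[i], hits[j]):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(hits[i])
    out = set()
    for members in groups.values():
        out.add(
            (
                members[0].genome_interval.seq_id,
                members[0].subject_family,
                min(h.genome_interval.start for h in members),
                max(h.genome_interval.end for h in members),
            )
        )
    return out


class TestMergeHits:
    def test_single_hit_single_candidate(self):
        hit = make_hit("c1", 100, 200)
        (cand,) = merge_hits([hit])
        assert (cand.interval.start, cand.interval.end) == (100, 200)
        assert cand.hits == (hit,)

    def test_gap_below_threshold_merges(self):
        cands = merge_hits([make_hit("c1", 100, 200), make_hit("c1", 230, 300)])
        assert len(cands) == 1
        assert (cands[0].interval.start, cands[0].interval.end) == (100, 300)

    def test_gap_at_threshold_does_not_merge(self):
        # "closer than 50" is strict: a gap of exactly 50 stays split
        cands = merge_hits([make_hit("c1", 100, 200), make_hit("c1", 250, 300)])
        assert len(cands) == 2

    def test_family_barrier(self):
        cands = merge_hits(
            [make_hit("c1", 100, 200, family="Totiviridae"),
             make_hit("c1", 210, 300, family="Parvoviridae")]
        )
        assert len(cands) == 2

    def test_best_hit_tie_break(self):
        a = make_hit("c1", 100, 200, subject="B", score=90.0, identity=40.0)
        b = make_hit("c1", 150, 250, subject="A", score=90.0, identity=40.0)
        (cand,) = merge_hits([a, b])
        assert cand.best_hit.subject_id == "A"  # equal score/identity -> lexicographic

    def test_matches_brute_force_oracle_on_random_sets(self, rng):
        for _ in range(200):
            hits = _random_hits(rng)
            got = {
                (c.interval.seq_id, c.family, c.interval.start, c.interval.end)
                for c in merge_hits(hits)
            }
            assert got == oracle_merge(hits)

    @given(st.randoms(use_true_random=False))
    def test_shuffle_invariance_and_idempotence(self, random):
        rng = np.random.default_rng(7)
        hits = _random_hits(rng)
        base = merge_hits(hits)
        shuffled = list(hits)
        random.shuffle(shuffled)
        assert merge_hits(shuffled) == base
        # idempotence: merging the merged candidates' spans changes nothing
        spans = {(c.interval.seq_id, c.family, c.interval.start, c.interval.end)
                 for c in base}
        again = merge_hits([h for c in base for h in c.hits])
        assert {(c.interval.seq_id, c.family, c.interval.start, c.interval.end)
                for c in again} == spans

    def test_candidates_pairwise_disjoint_within_group(self, rng):
        for _ in range(50):
            cands = merge_hits(_random_hits(rng))
            by_group = {}
            for c in cands:
                by_group.setdefault((c.interval.seq_id, c.family), []).append(c)
            for group in by_group.values():
                group.sort(key=lambda c: c.interval.start)
                for a, b in zip(group, group[1:]):
                    assert a.interval.end <= b.interval.start


def _random_hits(rng, max_hits=30):
    n = int(rng.integers(0, max_hits))
    hits = []
    for _ in range(n):
        start = int(rng.integers(0, 2000))
        length = int(rng.integers(3, 400))
        hits.append(
            make_hit(
                seq_id=f"c{rng.integers(1, 3)}",
                start=start,
                end=start + length,
                family=("Totiviridae", "Parvoviridae")[int(rng.integers(0, 2))],
                subject=f"P{rng.integers(1, 4)}",
                score=float(rng.integers(50, 500)),
            )
        )
    return hits


class TestContaminationFilter:
    CONTIGS = [SequenceRecord(id="c1", seq="A" * 1000),
               SequenceRecord(id="tiny", seq="A" * 300)]

    def test_whole_contig_candidate_discarded(self):
        (cand,) = merge_hits([make_hit("tiny", 0, 300)])
        retained, discarded = contamination_filter([cand], self.CONTIGS)
        assert retained == []
        assert discarded[0][1] == "no host flank"

    def test_interior_candidate_retained(self):
        (cand,) = merge_hits([make_hit("c1", 60, 900)])
        retained, discarded = contamination_filter([cand], self.CONTIGS)
        assert [c.interval for c in retained] == [cand.interval]
        assert discarded == []

    def test_one_sided_flank_suffices(self):
        # 0 nt left flank but ample right flank: a contig-edge EVE, not contamination
        (cand,) = merge_hits([make_hit("c1", 0, 500)])
        retained, _ = contamination_filter([cand], self.CONTIGS)
        assert len(retained) == 1

    def test_unknown_contig_raises(self):
        (cand,) = merge_hits([make_hit("ghost", 0, 100)])
        with pytest.raises(KeyError):
            contamination_filter([cand], self.CONTIGS)


class TestCallEves:
    def test_no_planted_eves_no_calls(self, rng):
        from bsfvirome.synthetic_data import plant_eves, generate_viral_proteome

        proteome, _ = generate_viral_proteome(2, ["Totiviridae"], 300, seed=3)
        assemblies, truth = plant_eves({"A1": (2, 20_000)}, [], proteome, seed=3)
        assert truth.planted_eves == []
        assert call_eves(assemblies, proteome) == []

    def test_host_screen_disabled_is_superset(self, scenario):
        with_screen = call_eves(
            scenario.assemblies, scenario.viral_proteome, scenario.host_proteome
        )
        without = call_eves(
            scenario.assemblies, scenario.viral_proteome, scenario.host_proteome,
            host_screen=False,
        )
        keys = lambda calls: {(c.assembly, c.interval, c.family) for c in calls}
        assert keys(with_screen) <= keys(without)
        assert len(without) > len(with_screen)  # the decoy comes back


class TestSummarizeEves:
    def test_table_fixture_summary(self):
        summary = summarize_eves(table1_eve_records(), "BGA3")
        assert summary.total == 27
        assert summary.per_family["Partitiviridae"] == 5
        assert (summary.span_min, summary.span_max) == (148, 3750)
        assert summary.n_loci == 9
        assert summary.n_contigs_in_assembly == 4

    def test_single_record(self):
        rec = EveRecord(
            name="TotiEVE", assembly="A1",
            interval=GenomicInterval("c1", 10, 200), family="Totiviridae",
            best_hit_subject="P", best_hit_pct_identity=50.0, protein_class="RdRP",
        )
        summary = summarize_eves([rec], "A1")
        assert summary.total == 1
        assert summary.span_min == summary.span_max == 190

    def test_removing_a_row_decrements_counts(self):
        records = table1_eve_records()
        dropped = records[0]
        summary = summarize_eves(records[1:], "BGA3")
        assert summary.total == 26
        assert summary.per_family[dropped.family] == 4

    def test_empty_input_all_zero(self):
        summary = summarize_eves([], "BGA3")
        assert summary.total == 0 and summary.n_loci == 0
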