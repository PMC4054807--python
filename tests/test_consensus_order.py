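"""Scaffold placement, adjacency voting, group linking, and AGP I/O."""

import io

import pytest

from carapace.alignment import AlignmentBlock
from carapace.ordering import (
    AdjacencyRelation, ConsensusConfig, OrderedGroup, Placement,
    build_groups, canonical_pair, derive_adjacencies, place_scaffolds,
    read_agp, vote_adjacencies, write_agp,
)
from carapace.synthetic import make_truth_set, simulate_alignments


def blk(sid, chrom, r_start, r_end, strand="+", ref="ref1", s_start=0,
        aligned=None):
    span = r_end - r_start
    return AlignmentBlock(sid, s_start, s_start + span, ref, chrom,
                          r_start, r_end, strand,
                          span if aligned is None else aligned)


class TestPlaceScaffolds:
    def test_clear_majority_chromosome(self):
        blocks = [blk("s1", "chr5", 0, 9000),
                  blk("s1", "chr2", 100000, 101000, s_start=9000)]
        (p,) = place_scaffolds(blocks)
        assert (p.chrom, p.orientation) == ("chr5", "+")
        assert p.placed_fraction == pytest.approx(0.9)

    def test_even_split_rejected(self):
        blocks = [blk("s1", "chr5", 0, 5000),
                  blk("s1", "chr2", 0, 5000, s_start=5000)]
        assert place_scaffolds(blocks) == []

    def test_midpoint_of_union_span_floors(self):
        (p,) = place_scaffolds([blk("s1", "chr1", 10, 21)])
        assert p.position == (10 + 21) // 2

    def test_orientation_by_majority_aligned_bases(self):
        blocks = [blk("s1", "chr1", 0, 7000, strand="-"),
                  blk("s1", "chr1", 8000, 11000, strand="+", s_start=7000)]
        (p,) = place_scaffolds(blocks)
        assert p.orientation == "-"


def place(sid, pos, orient="+", ref="ref1", chrom="chr1", aligned=1000):
    return Placement(sid, ref, chrom, pos, orient, 1.0, aligned)


class TestDeriveAndVote:
    def test_consecutive_pairs_one_per_gap(self):
        two = derive_adjacencies([place("A", 100), place("B", 5000)])
        three = derive_adjacencies([place("A", 100), place("B", 5000),
                                    place("C", 9000)])
        assert len(two) == 1 and len(three) == 2

    def test_reverse_complement_relations_merge(self):
        rels = derive_adjacencies([
            place("A", 100, "+", ref="ref1"), place("B", 5000, "+", ref="ref1"),
            place("B", 100, "-", ref="ref2"), place("A", 5000, "-", ref="ref2"),
        ])
        assert len(rels) == 1
        assert rels[0].supporting_refs == {"ref1", "ref2"}

    def test_canonical_pair_involution(self):
        key = canonical_pair("B", "-", "A", "+")
        assert key == canonical_pair("A", "-", "B", "+") == ("A", "B", "-", "+")

    def test_vote_threshold(self):
        r3 = AdjacencyRelation("A", "B", "+", "+", {"r1", "r2", "r3"})
        r2 = AdjacencyRelation("A", "C", "+", "+", {"r1", "r2"})
        cfg = ConsensusConfig(min_support=3)
        assert vote_adjacencies([r3, r2], cfg) == [r3]
        assert len(vote_adjacencies([r3, r2],
                                    ConsensusConfig(min_support=1))) == 2

    def test_chromosomes_and_references_kept_separate(self):
        rels = derive_adjacencies([
            place("A", 100, chrom="chr1"), place("B", 100, chrom="chr2"),
        ])
        assert rels == []


LENGTHS = {"A": 1000, "B": 500, "C": 800, "D": 400}


def rel(a, b, oa="+", ob="+", refs=("r1", "r2", "r3"), weight=0):
    key = canonical_pair(a, oa, b, ob)
    return AdjacencyRelation(key[0], key[1], key[2], key[3],
                             set(refs), weight)


class TestBuildGroups:
    def test_simple_chain(self):
        groups = build_groups([rel("A", "B"), rel("B", "C")], LENGTHS)
        linked = [g for g in groups if not g.unplaced]
        assert [m[:2] for m in linked[0].members] == \
            [("A", "+"), ("B", "+"), ("C", "+")]
        assert {g.members[0][0] for g in groups if g.unplaced} == {"D"}

    def test_conflicting_relations_resolved_by_support(self):
        strong = rel("A", "B", refs=("r1", "r2", "r3", "r4"))
        weak = rel("A", "C", refs=("r1", "r2", "r3"))
        groups = build_groups([strong, weak], LENGTHS)
        linked = [g for g in groups if not g.unplaced]
        assert len(linked) == 1
        assert [m[0] for m in linked[0].members] == ["A", "B"]

    def test_cycle_broken_at_weakest_relation(self):
        groups = build_groups([
            rel("A", "B", refs=("r1", "r2", "r3", "r4")),
            rel("B", "C", refs=("r1", "r2", "r3", "r4")),
            rel("C", "A", refs=("r1", "r2", "r3")),
        ], LENGTHS)
        linked = [g for g in groups if not g.unplaced]
        assert len(linked) == 1
        assert [m[0] for m in linked[0].members] == ["A", "B", "C"]

    def test_orientation_propagates_through_reversed_members(self):
        # A+ then B-: entering B at its right end flips its sign
        groups = build_groups([rel("A", "B", "+", "-")], LENGTHS)
        linked = [g for g in groups if not g.unplaced]
        assert [m[:2] for m in linked[0].members] == [("A", "+"), ("B", "-")]

    def test_canonical_direction_is_lexicographic(self):
        # the same physical path written from either end yields one form
        g1 = build_groups([rel("C", "A", "+", "+")], LENGTHS)
        linked = [g for g in g1 if not g.unplaced]
        assert [m[:2] for m in linked[0].members] == [("A", "-"), ("C", "-")]

    def test_unknown_scaffold_rejected(self):
        with pytest.raises(KeyError):
            build_groups([rel("A", "Z")], LENGTHS)


class TestAgp:
    def test_component_and_gap_arithmetic(self):
        g = OrderedGroup("grp1", [("A", "+", 1000), ("B", "-", 500)])
        text = write_agp([g], ConsensusConfig(gap_length=100))
        lines = [l for l in text.splitlines() if not l.startswith("#")]
        assert lines == [
            "grp1\t1\t1000\t1\tW\tA\t1\t1000\t+",
            "grp1\t1001\t1100\t2\tU\t100\tcontig\tno",
            "grp1\t1101\t1600\t3\tW\tB\t1\t500\t-",
        ]

    def test_total_length_bookkeeping(self):
        g = OrderedGroup("g", [("A", "+", 1000), ("B", "-", 500),
                               ("C", "+", 800)])
        cfg = ConsensusConfig(gap_length=100)
        text = write_agp([g], cfg)
        last_end = int(text.strip().splitlines()[-1].split("\t")[2])
        assert last_end == 1000 + 500 + 800 + 2 * cfg.gap_length

    def test_singletons_skipped_unless_requested(self):
        g = OrderedGroup("g", [("A", "+", 1000)], unplaced=True)
        assert read_agp(write_agp([g], ConsensusConfig())) == []
        back = read_agp(write_agp([g], ConsensusConfig(),
                                  include_singletons=True))
        assert back[0].members == [("A", "+", 1000)]

    def test_round_trip_is_byte_identical(self):
        groups = [OrderedGroup("grp1", [("A", "+", 1000), ("B", "-", 500)]),
                  OrderedGroup("grp2", [("C", "+", 800), ("D", "-", 400),
                                        ("E", "+", 123)])]
        cfg = ConsensusConfig(gap_length=100)
        text = write_agp(groups, cfg)
        assert write_agp(read_agp(text), cfg) == text

    def test_coordinate_discontinuity_rejected(self):
        bad = ("##agp-version\t1.1\n"
               "g\t1\t1000\t1\tW\tA\t1\t1000\t+\n"
               "g\t1002\t1101\t2\tU\t100\tcontig\tno\n")
        with pytest.raises(ValueError, match="line 3"):
            read_agp(bad)

    def test_non_consecutive_part_numbers_rejected(self):
        bad = ("g\t1\t1000\t1\tW\tA\t1\t1000\t+\n"
               "g\t1001\t1100\t3\tU\t100\tcontig\tno\n")
        with pytest.raises(ValueError, match="part_number"):
            read_agp(bad)

    def test_linkage_yes_tolerated(self):
        text = ("g\t1\t1000\t1\tW\tA\t1\t1000\t+\n"
                "g\t1001\t1100\t2\tU\t100\tcontig\tyes\n"
                "g\t1101\t1600\t3\tW\tB\t1\t500\t-\n")
        groups = read_agp(text)
        assert [m[0] for m in groups[0].members] == ["A", "B"]

    def test_empty_group_list(self):
        assert read_agp(write_agp([], ConsensusConfig())) == []
        assert write_agp([], ConsensusConfig()).startswith("#")


def _run_pipeline(blocks, lengths, cfg):
    placements = place_scaffolds(blocks, cfg)
    relations = vote_adjacencies(derive_adjacencies(placements, cfg), cfg)
    groups = build_groups(relations, lengths, cfg)
    found = set()
    for g in groups:
        for (a, oa, _), (b, ob, _) in zip(g.members, g.members[1:]):
            found.add(canonical_pair(a, oa, b, ob))
    return groups, found


class TestEndToEnd:
    def test_noise_free_truth_recovery(self):
        truth = make_truth_set(11, 400_000, 4, 12, 0.0)
        blocks = simulate_alignments(truth, seed=11)
        cfg = ConsensusConfig(min_support=3, n_references=4)
        _groups, found = _run_pipeline(blocks, truth.scaffold_lengths, cfg)
        assert found == truth.true_adjacencies()

    def test_orientation_consistency_under_global_reversal(self):
        """Reversing every strand and reference axis leaves groups unchanged."""
        truth = make_truth_set(13, 400_000, 4, 10, 0.0)
        blocks = simulate_alignments(truth, seed=13)
        axis = max(b.r_end for b in blocks) + 1
        flipped = [
            AlignmentBlock(b.scaffold_id, b.s_start, b.s_end, b.reference_id,
                           b.chrom, axis - b.r_end, axis - b.r_start,
                           "-" if b.strand == "+" else "+", b.aligned_bases)
            for b in blocks
        ]
        cfg = ConsensusConfig(min_support=3, n_references=4)
        _g1, found = _run_pipeline(blocks, truth.scaffold_lengths, cfg)
        _g2, found_flipped = _run_pipeline(flipped, truth.scaffold_lengths, cfg)
        assert found == found_flipped
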