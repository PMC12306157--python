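import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pefinder as pf
from pefinder.genome_io import revcomp
from pefinder.palindrome_scan import ArmPair, ScanConfig, pairs_ok

from oracles import brute_force_seed_pairs

# 22-nt worked example: GC-rich arms around a TTTT/AT core
WORKED = "AA" + "GCCGGAT" + "TTTT" + "ATCCGGC" + "AA"


class TestKmerize:
    def test_count_is_length_minus_k_plus_one(self):
        assert len(pf.kmerize("ACGTACG", 6)) == 2
        assert pf.kmerize("ACGTA", 6) == []

    def test_offsets_in_order(self):
        kmers = pf.kmerize("ACGTAC", 3)
        assert [(k.pos, k.seq) for k in kmers] == [
            (0, "ACG"), (1, "CGT"), (2, "GTA"), (3, "TAC")
        ]

    def test_n_containing_kmers_not_seedable(self):
        kmers = pf.kmerize("ACGNTAG", 3)
        assert [k.seedable for k in kmers] == [True, False, False, False, True]


class TestFindSeedPairs:
    def test_worked_example_seed(self):
        pairs = pf.find_seed_pairs(WORKED, ScanConfig())
        spans = {(p.left_start, p.right_start) for p in pairs}
        assert (2, 14) in spans
        assert spans == brute_force_seed_pairs(WORKED, 6, 50)

    def test_homopolymer_has_no_pairs(self):
        assert pf.find_seed_pairs("A" * 60, ScanConfig()) == []

    def test_span_threshold_excludes_distant_pairs(self):
        arm = "GCCGGA"
        seq = arm + "A" * 50 + revcomp(arm)
        assert pf.find_seed_pairs(seq, ScanConfig()) == []
        assert len(pf.find_seed_pairs(seq, ScanConfig(max_span=62))) == 1

    def test_start_span_mode(self):
        arm = "GCCGGA"
        seq = arm + "A" * 40 + revcomp(arm)  # outer span 52, start offset 46
        assert pf.find_seed_pairs(seq, ScanConfig()) == []
        assert len(pf.find_seed_pairs(seq, ScanConfig(span_mode="start"))) == 1

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_random_sequences(self, seed):
        rng = random.Random(seed)
        n = rng.randint(15, 400)
        seq = "".join(rng.choice("ACGTN") for _ in range(n))
        got = {(p.left_start, p.right_start) for p in pf.find_seed_pairs(seq, ScanConfig())}
        assert got == brute_force_seed_pairs(seq, 6, 50)


class TestExtendPair:
    def test_worked_example_extension(self):
        p = pf.extend_pair(ArmPair(2, 8, 14, 20), WORKED)
        assert (p.left_start, p.left_end, p.right_start, p.right_end) == (2, 9, 13, 20)
        assert p.loop_len == 4

    def test_no_outward_growth_at_edge(self):
        arm = "GCCGGA"
        seq = arm + "TTTT" + revcomp(arm)
        p = pf.extend_pair(ArmPair(0, 6, 10, 16), seq)
        assert (p.left_start, p.right_end) == (0, 16)

    def test_arms_never_cross(self):
        # perfect 16-nt palindrome: inward extension must stop at loop 0
        s = "GCGCGATC"
        seq = "AA" + s + revcomp(s) + "AA"
        p = pf.extend_pair(ArmPair(2, 8, 12, 18), seq)
        assert p.left_end <= p.right_start

    def test_wobble_pairs_extend(self):
        # G.T accepted inward: G at left_end, T pairing anti-parallel
        seq = "CGCGCG" + "G" + "AA" + "T" + revcomp("CGCGCG")
        p = pf.extend_pair(ArmPair(0, 6, 10, 16), seq)
        assert (p.left_end, p.right_start) == (7, 9)

    def test_extension_maximality(self):
        rng = random.Random(99)
        for _ in range(50):
            seq = "".join(rng.choice("ACGT") for _ in range(120))
            for p in pf.find_seed_pairs(seq, ScanConfig()):
                e = pf.extend_pair(p, seq)
                if e.right_start - e.left_end >= 2:
                    assert not pairs_ok(seq[e.left_end], seq[e.right_start - 1])
                if e.left_start >= 1 and e.right_end < len(seq):
                    assert not pairs_ok(seq[e.left_start - 1], seq[e.right_end])


class TestAssemblePairs:
    # Two stems separated by short interruptions. left1 ends in G and
    # left2 starts with C so the inserted A can pair with neither
    # neighbour and extension genuinely stops at the interruption.
    LEFT1, LEFT2, LOOP = "GCCGGAG", "CGGCTG", "TTATT"

    def test_one_sided_bulge_merges_with_recorded_gap(self):
        seq = (
            self.LEFT1 + "A" + self.LEFT2 + self.LOOP
            + revcomp(self.LEFT2) + revcomp(self.LEFT1)
        )
        pairs = [
            pf.extend_pair(p, seq) for p in pf.find_seed_pairs(seq, ScanConfig())
        ]
        merged = pf.assemble_pairs(pairs, ScanConfig())
        assert len(merged) == 1
        (m,) = merged
        assert (m.left_start, m.left_end) == (0, 14)
        assert (m.right_start, m.right_end) == (19, 32)
        assert m.gap_positions() == [("L", 7)]

    def test_facing_inserts_pair_off_with_no_recorded_gap(self):
        # 1-nt insert on BOTH arms (A facing G: not a valid pair)
        seq = (
            self.LEFT1 + "A" + self.LEFT2 + self.LOOP
            + revcomp(self.LEFT2) + "G" + revcomp(self.LEFT1)
        )
        pairs = [
            pf.extend_pair(p, seq) for p in pf.find_seed_pairs(seq, ScanConfig())
        ]
        merged = pf.assemble_pairs(pairs, ScanConfig())
        assert len(merged) == 1
        (m,) = merged
        assert (m.left_start, m.left_end) == (0, 14)
        assert (m.right_start, m.right_end) == (19, 33)
        assert m.gap_positions() == []

    def test_gap_above_threshold_not_merged(self):
        seq = (
            self.LEFT1 + "AAA" + self.LEFT2 + self.LOOP
            + revcomp(self.LEFT2) + revcomp(self.LEFT1)
        )
        pairs = [
            pf.extend_pair(p, seq) for p in pf.find_seed_pairs(seq, ScanConfig())
        ]
        merged = pf.assemble_pairs(pairs, ScanConfig())
        assert all(len(m.segments) == 1 for m in merged)

    def test_duplicates_collapse(self):
        p = ArmPair(0, 6, 10, 16)
        assert pf.assemble_pairs([p, p], ScanConfig()) == [p]

    def test_contained_pairs_removed(self):
        outer = ArmPair(0, 8, 12, 20)
        inner = ArmPair(1, 7, 13, 19)
        assert pf.assemble_pairs([outer, inner], ScanConfig()) == [outer]


def test_scan_determinism_byte_identical():
    rng = random.Random(5)
    seq = "".join(rng.choice("ACGT") for _ in range(800))
    a = pf.scan_sequence(seq, ScanConfig())
    b = pf.scan_sequence(seq, ScanConfig())
    assert a == b


def test_config_validation():
    with pytest.raises(ValueError):
        ScanConfig(k=1)
    with pytest.raises(ValueError):
        ScanConfig(max_span=10, k=6)
    with pytest.raises(ValueError):
        ScanConfig(min_stem_loop_ratio=0)
    with pytest.raises(ValueError):
        ScanConfig(span_mode="middle")
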