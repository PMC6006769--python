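"""REP scanner: foot search, hairpin folding, double feet, full scans."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import best_fold, brute_scan, naive_find_foot
from reptronkit.dna import revcomp
from reptronkit.rep_scanner import (
    RepRuleSet,
    detect_double_foot,
    find_foot,
    fold_hairpin,
    scan,
)
from reptronkit.synthetic_data import make_rep, plant, random_genome

dna = st.text(alphabet="ACGT", min_size=0, max_size=250)


class TestFindFoot:
    def test_single_match(self):
        assert find_foot("AAGTAGAA", ["GTRG"]) == [2]

    def test_overlapping_matches_reported(self):
        assert find_foot("GTGGTGG", ["GTRG"]) == [0, 3]

    def test_non_iupac_motif_rejected(self):
        with pytest.raises(ValueError):
            find_foot("ACGT", ["GTZG"])

    def test_matches_naive_scan_on_random_sequence(self):
        seq = random_genome(10_000, 0.5, seed=11)
        assert find_foot(seq, ["GTRG"]) == naive_find_foot(seq, ["GTRG"])

    def test_degenerate_motifs(self):
        assert find_foot("ACGGA", ["CNGA"]) == [1]


class TestFoldHairpin:
    def test_planted_short_hairpin_recovered(self, default_rules):
        rep, _ = make_rep(default_rules, "GTAG", 0, 7, 2, gc_stem=1.0, seed=3)
        seq = "A" * 10 + rep + "A" * 10
        cand = fold_hairpin(seq, 10, default_rules)
        assert cand is not None
        assert cand.start == 10
        assert cand.stem1_len >= 7
        assert cand.hairpin_kind == "short"

    def test_unpairable_tail_gives_none(self, default_rules):
        assert fold_hairpin("GTAG" + "A" * 30, 0, default_rules) is None

    def test_basal_stem_needs_three_gc(self, default_rules):
        # paired 7-nt stem whose first four bases are ATAT (< 3 G/C)
        arm = "ATATGCA"
        seq = "GTAG" + arm + "TT" + revcomp(arm)
        assert fold_hairpin(seq, 0, default_rules) is None
        # same geometry with a G/C-rich basal quartet is accepted
        arm_ok = "GCGTGCA"
        seq_ok = "GTAG" + arm_ok + "TT" + revcomp(arm_ok)
        cand = fold_hairpin(seq_ok, 0, default_rules)
        assert cand is not None and cand.stem1_len == 7

    def test_non_foot_position_rejected(self, default_rules):
        with pytest.raises(ValueError):
            fold_hairpin("AAAAAAAA", 0, default_rules)

    def test_long_hairpin_geometry(self, default_rules):
        rep, geo = make_rep(default_rules, "GTGG", 1, 9, 3, 2, 4, seed=5)
        cand = fold_hairpin(rep, 0, default_rules)
        assert cand.hairpin_kind == "long"
        assert (cand.stem1_len, cand.loop_len, cand.bulge_len, cand.stem2_len) == (9, 3, 2, 4)
        assert cand.paired_len == 13

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_bruteforce_enumeration(self, seed, default_rules):
        seq = random_genome(800, 0.55, seed=seed)
        for foot in find_foot(seq, default_rules.foot_motifs):
            cand = fold_hairpin(seq, foot, default_rules)
            oracle = best_fold(seq, foot, default_rules)
            if oracle is None:
                assert cand is None
            else:
                off, kind, s1, loop, b, s2, end = oracle
                assert cand is not None
                got = (cand.foot_offset, cand.hairpin_kind, cand.stem1_len,
                       cand.loop_len, cand.bulge_len, cand.stem2_len, cand.hairpin_end)
                assert got == oracle


class TestDoubleFoot:
    def _cand(self, default_rules, tail):
        rep, _ = make_rep(default_rules, "GTAG", 0, 8, 3, seed=9)
        seq = rep + tail
        cand = fold_hairpin(seq, 0, default_rules)
        assert cand.hairpin_end == len(rep)
        return detect_double_foot(cand, seq, default_rules), len(rep)

    def test_immediate_ctac(self, default_rules):
        cand, hp = self._cand(default_rules, "CTAC")
        assert cand.double_foot and cand.end == hp + 4

    def test_plain_tail_is_not_double_foot(self, default_rules):
        cand, _ = self._cand(default_rules, "AAAA")
        assert not cand.double_foot

    def test_spacer_and_ccac(self, default_rules):
        cand, hp = self._cand(default_rules, "TTCCAC")
        assert cand.double_foot and cand.end == hp + 2 + 4


class TestScan:
    def test_empty_sequence(self, default_rules):
        assert scan("", default_rules) == []

    def test_planted_reps_recovered_with_oracle_equivalence(self, default_rules):
        genome = random_genome(4000, 0.5, seed=21)
        planted = []
        pos = 200
        for i in range(6):
            rep, _ = make_rep(default_rules, "GTAG", i % 3, 8 + i, 2 + i % 4, seed=30 + i)
            genome, rec = plant(genome, rep, pos + i * 500)
            planted.append(rec)
        hits = scan(genome, default_rules, resolve_overlaps=False)
        got = {
            (c.start, c.end, c.strand, c.hairpin_kind, c.foot_offset, c.stem1_len,
             c.loop_len, c.bulge_len, c.stem2_len, c.double_foot,
             c.hairpin_start, c.hairpin_end)
            for c in hits
        }
        oracle = {
            (s, e, strand, kind, off, s1, loop, b, s2, df, hs, he)
            for (s, e, strand, kind, off, s1, loop, b, s2, df, hs, he) in brute_scan(
                genome, default_rules
            )
        }
        assert got == oracle
        spans = {(c.hairpin_start, c.hairpin_end) for c in hits if c.strand == "+"}
        for rec in planted:
            assert (rec.start, rec.end) in spans

    def test_minus_strand_forward_coordinates(self, default_rules):
        genome = random_genome(2000, 0.5, seed=41)
        rep, _ = make_rep(default_rules, "GTAG", 0, 10, 3, seed=42)
        genome, rec = plant(genome, revcomp(rep), 700)
        hits = [c for c in scan(genome, default_rules) if c.strand == "-"]
        assert any(
            (c.hairpin_start, c.hairpin_end) == (rec.start, rec.end) for c in hits
        )

    def test_sorted_by_start_then_strand(self, default_rules):
        genome = random_genome(3000, 0.5, seed=51)
        hits = scan(genome, default_rules)
        assert [(c.start, c.strand) for c in hits] == sorted(
            (c.start, c.strand) for c in hits
        )

    def test_non_acgt_never_pairs(self, default_rules):
        # Ns in the arm break "fully paired"
        arm = "GCGNGCA"
        seq = "GTAG" + arm + "TT" + revcomp(arm)
        hits = scan(seq, RepRuleSet(scan_both_strands=False))
        assert all(c.start != 0 or c.stem1_len < 7 for c in hits)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(dna)
    def test_strand_symmetry(self, seq):
        """scan(revcomp(S)) hits mirror scan(S) with strands flipped."""
        rules = RepRuleSet()
        n = len(seq)
        fwd = scan(seq, rules, resolve_overlaps=False)
        rev = scan(revcomp(seq), rules, resolve_overlaps=False)
        mirror = {
            (n - c.end, n - c.start, "+" if c.strand == "-" else "-",
             c.paired_len, c.hairpin_kind)
            for c in rev
        }
        direct = {
            (c.start, c.end, c.strand, c.paired_len, c.hairpin_kind) for c in fwd
        }
        assert direct == mirror

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_relaxing_rules_keeps_reported_feet(self, seed):
        """A superset rule set never loses a foot that reported a candidate
        (pre overlap-resolution)."""
        seq = random_genome(400, 0.5, seed=seed)
        tight = RepRuleSet(stem1=(8, 15), loop=(2, 4), scan_both_strands=False)
        relaxed = RepRuleSet(stem1=(7, 20), loop=(2, 5), scan_both_strands=False)
        feet_tight = {c.start for c in scan(seq, tight, resolve_overlaps=False)}
        feet_relaxed = {c.start for c in scan(seq, relaxed, resolve_overlaps=False)}
        assert feet_tight <= feet_relaxed

    def test_overlap_resolution_prefers_larger_paired_len(self, default_rules):
        genome = random_genome(2000, 0.5, seed=61)
        big, _ = make_rep(default_rules, "GTAG", 0, 18, 2, gc_stem=1.0, seed=62)
        genome, rec = plant(genome, big, 900)
        resolved = scan(genome, default_rules)
        unresolved = scan(genome, default_rules, resolve_overlaps=False)
        assert len(resolved) <= len(unresolved)
        kept = [c for c in resolved if c.hairpin_start == rec.start and c.strand == "+"]
        assert kept and kept[0].paired_len >= 18
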