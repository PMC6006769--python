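"""Generators: determinism, calibration, and round trips with the scanner."""

import numpy as np
import pytest

from reptronkit.dna import gc_fraction, revcomp
from reptronkit.mcl_core import WeightedGraph
from reptronkit.rep_scanner import scan
from reptronkit.synthetic_data import (
    make_protein_family,
    make_rep,
    plant,
    plant_reps,
    planted_partition_graph,
    random_genome,
    simulate_reptron_genome,
)


class TestRandomGenome:
    def test_length_and_determinism(self):
        a = random_genome(1000, 0.5, 7)
        b = random_genome(1000, 0.5, 7)
        assert len(a) == 1000 and a == b

    def test_gc_one_forces_alphabet(self):
        assert set(random_genome(100, 1.0, 7)) <= {"G", "C"}

    def test_gc_calibration(self):
        # binomial: sd of GC fraction at n=100k, p=0.6 is ~0.0015, so +-0.01
        # is a > 6-sigma band
        seq = random_genome(100_000, 0.6, 7)
        assert abs(gc_fraction(seq) - 0.6) < 0.01

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            random_genome(-1, 0.5, 0)


class TestMakeRep:
    def test_short_arithmetic(self, default_rules):
        seq, _ = make_rep(default_rules, "GTAG", 0, 7, 2, seed=1)
        assert len(seq) == 20  # 4 + 0 + 14 + 2

    def test_arms_reverse_complement(self, default_rules):
        seq, _ = make_rep(default_rules, "GTGG", 2, 20, 5, seed=1)
        assert len(seq) == 51
        arm1 = seq[6:26]
        arm2 = seq[31:51]
        assert revcomp(arm1) == arm2

    def test_out_of_range_rejected(self, default_rules):
        with pytest.raises(ValueError):
            make_rep(default_rules, "GTAG", 0, 6, 2)
        with pytest.raises(ValueError):
            make_rep(default_rules, "GTAG", 0, 7, 2, bulge=1)  # stem2 missing
        with pytest.raises(ValueError):
            make_rep(default_rules, "TTTT", 0, 7, 2)

    @pytest.mark.parametrize("geometry", [
        ("GTAG", 0, 7, 2, None, None),
        ("GTGG", 2, 20, 5, None, None),
        ("GTAG", 1, 12, 3, 2, 5),
        ("GTGG", 0, 7, 4, 3, 10),
    ])
    def test_round_trip_with_scanner(self, geometry, default_rules):
        foot, off, s1, loop, b, s2 = geometry
        rep, _ = make_rep(default_rules, foot, off, s1, loop, b, s2, seed=13)
        genome = random_genome(500, 0.5, 14)
        genome, rec = plant(genome, rep, 250)
        hits = scan(genome, default_rules)
        assert any(
            (c.hairpin_start, c.hairpin_end, c.strand) == (rec.start, rec.end, "+")
            for c in hits
        )


class TestPlant:
    def test_insertion_not_overwrite(self):
        genome, rec = plant("AAAA", "GG", 2)
        assert genome == "AAGGAA" and (rec.start, rec.end) == (2, 4)

    def test_prefix_insertion(self):
        genome, rec = plant("TTTT", "GG", 0)
        assert genome.startswith("GG") and rec.start == 0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            plant("AAAA", "GG", 5)

    def test_two_elements_with_shift_round_trip(self, default_rules):
        genome = random_genome(2000, 0.5, 23)
        # offset-0 elements: the stem cannot extend across the 3' boundary
        # by re-parsing spacer bases, so bare plant() round-trips exactly
        r1, _ = make_rep(default_rules, "GTAG", 0, 10, 3, seed=24)
        r2, _ = make_rep(default_rules, "GTGG", 0, 15, 2, seed=25)
        genome, rec1 = plant(genome, r1, 500)
        genome, rec2 = plant(genome, r2, 1500 + len(r1))  # adjusted by insertion
        spans = {(c.hairpin_start, c.hairpin_end) for c in scan(genome, default_rules)}
        assert (rec1.start, rec1.end) in spans
        assert (rec2.start, rec2.end) == (1500 + len(r1), 1500 + len(r1) + len(r2))
        assert (rec2.start, rec2.end) in spans


class TestPlantReps:
    def test_full_grid_recovery_and_determinism(self, default_rules):
        genome = random_genome(30_000, 0.5, 31)
        g1, t1 = plant_reps(genome, 60, default_rules, seed=32)
        g2, t2 = plant_reps(genome, 60, default_rules, seed=32)
        assert g1 == g2 and [(r.start, r.end) for r in t1.records] == [
            (r.start, r.end) for r in t2.records
        ]
        spans = {
            (c.hairpin_start, c.hairpin_end, c.strand) for c in scan(g1, default_rules)
        }
        assert all((r.start, r.end, r.strand) in spans for r in t1.records)
        assert {r.strand for r in t1.records} == {"+", "-"}


class TestMakeProteinFamily:
    def test_identity_one_gives_copies(self):
        fam = make_protein_family("MKVLA" * 20, 5, 1.0, seed=1)
        assert fam == ["MKVLA" * 20] * 5

    def test_mean_identity_calibrated(self):
        from reptronkit.synthetic_data import random_protein

        seed_prot = random_protein(200, 7)
        protected = list(range(50, 62))
        fam = make_protein_family(seed_prot, 50, 0.85, protected, seed=8)
        idents = [
            sum(a == b for a, b in zip(seed_prot, m)) / len(seed_prot) for m in fam
        ]
        assert 0.82 <= np.mean(idents) <= 0.88

    def test_protected_sites_untouched(self):
        from reptronkit.synthetic_data import random_protein

        seed_prot = random_protein(100, 9)
        protected = [0, 10, 50, 99]
        fam = make_protein_family(seed_prot, 20, 0.7, protected, seed=10)
        for m in fam:
            assert all(m[i] == seed_prot[i] for i in protected)

    def test_unabsorbable_divergence_rejected(self):
        with pytest.raises(ValueError):
            make_protein_family("MKVL" * 5, 3, 0.1, protected_sites=range(18), seed=0)


class TestPlantedPartitionGraph:
    def test_two_disjoint_triangles(self):
        g = planted_partition_graph([3, 3], p_in=1.0, p_out=0.0, seed=0)
        assert g.n == 6 and len(g.edges) == 6
        ends = {frozenset((u, v)) for u, v, _ in g.edges}
        assert all(
            (u < 3) == (v < 3) for u, v in (tuple(e) for e in ends)
        )

    def test_interblock_edge_count_near_expectation(self):
        g = planted_partition_graph([20] * 4, 0.9, 0.02, seed=1)
        inter = sum(1 for u, v, _ in g.edges if u // 20 != v // 20)
        expected = 0.02 * (3 * 20 * 20 * 4 / 2)  # p_out * cross pairs (2400)
        sd = np.sqrt(expected * (1 - 0.02))
        assert abs(inter - expected) < 5 * sd

    def test_seed_reproducibility(self):
        g1 = planted_partition_graph([10, 10], 0.8, 0.05, seed=3)
        g2 = planted_partition_graph([10, 10], 0.8, 0.05, seed=3)
        assert g1.edges == g2.edges

    def test_invalid_probabilities(self):
        with pytest.raises(ValueError):
            planted_partition_graph([5, 5], 0.5, 0.5, seed=0)


class TestSimulateReptronGenome:
    def test_layout_and_truth(self):
        sim = simulate_reptron_genome(seed=7, n_repin_pairs=3)
        reps = sim["truth"].of_kind("rep")
        gene = sim["gene"]
        assert len(reps) == 6
        assert sum(r.strand == "+" for r in reps) == 3
        # every REP within 1000 nt of the gene boundary
        for r in reps:
            dist = gene.start - r.end if r.end <= gene.start else r.start - gene.end
            assert dist <= 1000
        # determinism
        sim2 = simulate_reptron_genome(seed=7, n_repin_pairs=3)
        assert sim2["genome"] == sim["genome"]
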