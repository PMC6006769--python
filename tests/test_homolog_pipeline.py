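"""Protein graph construction, redundancy reduction, medoids, labels."""

import numpy as np
import pytest

from oracles import brute_medoid
from reptronkit.homolog_pipeline import (
    MedoidAssignment,
    ProteinRecord,
    graph_from_blast_tab,
    length_filter,
    medoid,
    pairwise_identities,
    propagate_labels,
    reduce_redundancy,
    two_level_labels,
)
from reptronkit.synthetic_data import (
    make_protein_family,
    random_protein,
    two_level_partition_graph,
)


class TestGraphFromBlastTab:
    def _line(self, q, s, e):
        return f"{q}\t{s}\t90.0\t100\t10\t0\t1\t100\t1\t100\t{e}\t200\n"

    def test_evalue_threshold_is_strict(self, tmp_path):
        p = tmp_path / "b.tab"
        p.write_text(self._line("a", "b", "1e-5"))
        g = graph_from_blast_tab(p)
        assert g.edges == [] and sorted(g.vertex_ids) == ["a", "b"]

    def test_one_direction_weight(self, tmp_path):
        p = tmp_path / "b.tab"
        p.write_text(self._line("a", "b", "1e-20"))
        g = graph_from_blast_tab(p)
        assert len(g.edges) == 1 and g.edges[0][2] == pytest.approx(20.0)

    def test_reciprocal_hits_merged_by_mean(self, tmp_path):
        p = tmp_path / "b.tab"
        p.write_text(self._line("a", "b", "1e-10") + self._line("b", "a", "1e-20"))
        g = graph_from_blast_tab(p)
        assert len(g.edges) == 1 and g.edges[0][2] == pytest.approx(15.0)

    def test_self_hits_dropped_and_zero_evalue_capped(self, tmp_path):
        p = tmp_path / "b.tab"
        p.write_text(self._line("a", "a", "0.0") + self._line("a", "b", "0.0"))
        g = graph_from_blast_tab(p)
        assert len(g.edges) == 1 and g.edges[0][2] == pytest.approx(200.0)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "b.tab"
        p.write_text(self._line("a", "b", "1e-20") + "broken line\n")
        with pytest.raises(ValueError, match=":2"):
            graph_from_blast_tab(p)


class TestMedoid:
    def test_identical_members_lexicographic_tie(self):
        members = ["c", "a", "b"]
        lengths = {m: 100 for m in members}
        assert medoid(members, {}, lengths) == "a"

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_on_random_clusters(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 31))
        members = [f"p{i:02d}" for i in range(n)]
        lengths = {m: int(rng.integers(100, 300)) for m in members}
        dissim = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.9:  # some missing pairs -> default 100
                    dissim[(members[i], members[j])] = float(rng.uniform(0, 100))
        assert medoid(members, dissim, lengths) == brute_medoid(members, dissim, lengths)

    def test_length_constraint_excludes_outlier(self):
        members = ["long", "x", "y"]
        lengths = {"long": 400, "x": 200, "y": 210}
        # "long" has zero dissimilarity to everyone but is 2x median
        dissim = {("long", "x"): 0.0, ("long", "y"): 0.0, ("x", "y"): 50.0}
        assert medoid(members, dissim, lengths) in ("x", "y")

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            medoid([], {}, {})


class TestReduceRedundancy:
    def _families(self, n_fam, members, identity, length=180, seed0=0):
        # founder + descendants: every member is within `identity` of the
        # founder, the star structure a duplication burst produces
        proteins = []
        for f in range(n_fam):
            founder = random_protein(length, 1000 + seed0 * 100 + f)
            family = [founder] + make_protein_family(
                founder, members - 1, identity, seed=2000 + seed0 * 100 + f
            )
            for i, s in enumerate(family):
                proteins.append(ProteinRecord(f"f{f}_m{i}", s))
        return proteins

    def test_planted_families_recovered(self):
        proteins = self._families(5, 5, 0.85)
        assignments = reduce_redundancy(proteins, 0.70)
        assert len(assignments) == 5
        for a in assignments:
            prefixes = {m.split("_")[0] for m in a.member_ids}
            assert len(prefixes) == 1
            assert a.medoid_id in a.member_ids

    def test_divergent_families_fragment_to_singletons(self):
        proteins = self._families(3, 4, 0.50, seed0=1)
        assignments = reduce_redundancy(proteins, 0.70)
        assert len(assignments) == len(proteins)
        assert all(len(a.member_ids) == 1 for a in assignments)

    def test_single_protein(self):
        p = ProteinRecord("only", random_protein(150, 5))
        assignments = reduce_redundancy([p])
        assert len(assignments) == 1 and assignments[0].medoid_id == "only"


class TestPropagateLabels:
    def _assignments(self):
        return [
            MedoidAssignment("C0", "m", ["m", "b", "c"], 100),
            MedoidAssignment("C1", "s", ["s"], 100),
        ]

    def test_members_inherit_medoid_subclass(self):
        labels = propagate_labels({"m": "2.2", "s": "1.1"}, self._assignments())
        by_id = {l.protein_id: l for l in labels}
        assert by_id["b"].subclass_id == "2.2" and by_id["b"].provenance == "propagated"
        assert by_id["m"].provenance == "direct"
        assert by_id["s"].subclass_id == "1.1" and by_id["s"].provenance == "direct"
        assert by_id["b"].class_id == "2"

    def test_discarded_medoid_discards_members(self):
        labels = propagate_labels({"m": None, "s": "1.1"}, self._assignments())
        assert sum(l.provenance == "discarded" for l in labels) == 3

    def test_unlabelled_medoid_errors_with_cluster_ids(self):
        with pytest.raises(KeyError, match="C0"):
            propagate_labels({"s": "1.1"}, self._assignments())

    def test_label_count_conservation(self):
        rng = np.random.default_rng(3)
        assignments = []
        total = 0
        for k in range(30):
            size = int(rng.integers(1, 6))
            members = [f"c{k}_p{i}" for i in range(size)]
            total += size
            assignments.append(MedoidAssignment(f"C{k}", members[0], members, 100))
        labels = propagate_labels({a.medoid_id: "1.1" for a in assignments}, assignments)
        assert len(labels) == total


class TestLengthFilter:
    def test_boundary_inclusive(self):
        from reptronkit.homolog_pipeline import SubclassLabel

        labels = [SubclassLabel(f"p{i}", "1", "1.1", "propagated") for i in range(5)]
        lengths = {"p0": 60, "p1": 100, "p2": 100, "p3": 100, "p4": 167}
        out = length_filter(labels, lengths)  # median 100; bounds [60, 167]
        assert all(l.provenance != "discarded" for l in out)

    def test_fusion_discarded(self):
        from reptronkit.homolog_pipeline import SubclassLabel

        labels = [SubclassLabel(f"p{i}", "1", "1.1", "propagated") for i in range(5)]
        lengths = {"p0": 100, "p1": 100, "p2": 100, "p3": 100, "p4": 250}
        out = length_filter(labels, lengths)
        assert sum(l.provenance == "discarded" for l in out) == 1

    def test_uniform_lengths_untouched(self):
        from reptronkit.homolog_pipeline import SubclassLabel

        labels = [SubclassLabel(f"p{i}", "2", "2.1", "propagated") for i in range(4)]
        out = length_filter(labels, {f"p{i}": 150 for i in range(4)})
        assert all(l.provenance != "discarded" for l in out)


class TestTwoLevelLabels:
    def test_class_subclass_hierarchy(self):
        graph, truth = two_level_partition_graph([[15, 15], [15, 15]], seed=9)
        labels = two_level_labels(graph, if_class=1.4, if_subclass=3.0)
        assert set(labels) == set(graph.vertex_ids)
        classes = {l.split(".")[0] for l in labels.values()}
        assert len(classes) == 2
        assert len(set(labels.values())) == 4
        # vertices in the same planted sub-block share a label
        by_block = {}
        for v, (s, b) in zip(graph.vertex_ids, truth):
            by_block.setdefault((s, b), set()).add(labels[v])
        assert all(len(ls) == 1 for ls in by_block.values())
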