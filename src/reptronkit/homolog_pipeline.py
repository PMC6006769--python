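"""Protein similarity graph, redundancy reduction, medoids and labels.

The workflow mirrors how a large transposase-like protein harvest is turned
into a classified, non-redundant library:

1. all-against-all pairwise identity (local alignment, BLOSUM62);
2. identity graph at a 70% cutoff, clustered with MCL, collapsing
   near-duplicate sequences (strain replicates, recent paralogs);
3. one representative per cluster - the *medoid*, the member minimising
   average dissimilarity to the rest, constrained to lie near the cluster's
   median length;
4. a similarity graph over the representatives (here from BLAST tabular
   output or internal alignment), partitioned with MCL at a coarse inflate
   factor for classes and a finer one for subclasses;
5. labels propagated from each medoid back to its cluster members, and
   per-subclass length outliers (fusions, partial sequences) discarded.

Pairwise identity is identities / aligned columns of a Smith-Waterman-style
local alignment (BLOSUM62, gap open -11 / extend -1, BLAST-like).  An
inverted 5-mer index prescreens pairs: sequences sharing no 5-mer are scored
as unaligned (identity 0), which is how word-seeded search would treat them.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from statistics import median

from Bio import Align
from Bio.Align import substitution_matrices

from .mcl_core import MclParams, Partition, WeightedGraph, mcl

__all__ = [
    "ProteinRecord",
    "MedoidAssignment",
    "SubclassLabel",
    "protein_identity",
    "pairwise_identities",
    "graph_from_blast_tab",
    "identity_graph",
    "reduce_redundancy",
    "medoid",
    "two_level_labels",
    "propagate_labels",
    "length_filter",
]

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ProteinRecord:
    protein_id: str
    sequence: str
    genome_id: str = ""
    species_id: str = ""
    taxon_label: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - _AA20 - {"X"}
        if bad:
            raise ValueError(
                f"{self.protein_id}: non-amino-acid characters {sorted(bad)}"
            )


@dataclass
class MedoidAssignment:
    cluster_id: str
    medoid_id: str
    member_ids: list[str]
    median_length: float


@dataclass
class SubclassLabel:
    protein_id: str
    class_id: str | None            # "1" | "2" | "3" | None
    subclass_id: str | None         # e.g. "1.1", "2.9", "3"
    provenance: str                 # direct | propagated | discarded


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def protein_identity(
    a: str,
    b: str,
    aligner: Align.PairwiseAligner | None = None,
    min_coverage: float = 0.5,
) -> float:
    """Percent-identity-like fraction from a local alignment:
    identities / aligned columns (internal gaps included).

    The optimal local alignment of two unrelated sequences is a short
    high-identity segment, which would make a bare identity fraction
    meaningless; the identity is therefore reported as 0.0 unless the
    aligned region covers at least ``min_coverage`` of the shorter
    sequence (homologs in one family align over most of their length).
    """
    if not a or not b:
        return 0.0
    aligner = aligner or _local_aligner()
    a = a.upper().replace("X", "A")  # X has no BLOSUM62 row; treat as neutral
    b = b.upper().replace("X", "A")
    try:
        aln = aligner.align(a, b)[0]
    except IndexError:
        return 0.0
    c = aln.counts()
    cols = c.identities + c.mismatches + c.internal_insertions + c.internal_deletions
    if not cols or cols < min_coverage * min(len(a), len(b)):
        return 0.0
    return c.identities / cols


def _kmer_index(seqs: dict[str, str], k: int = 5) -> dict[str, set[str]]:
    index: dict[str, set[str]] = defaultdict(set)
    for pid, seq in seqs.items():
        for i in range(len(seq) - k + 1):
            index[seq[i : i + k]].add(pid)
    return index


def pairwise_identities(
    proteins: list[ProteinRecord], k: int = 5, min_shared_kmers: int = 1
) -> dict[tuple[str, str], float]:
    """All-against-all identities with a shared-k-mer prescreen.

    Pairs sharing fewer than ``min_shared_kmers`` words are omitted
    (identity treated as 0 / dissimilarity 100 downstream), analogous to a
    word-seeded search reporting no hit.
    """
    seqs = {p.protein_id: p.sequence.upper() for p in proteins}
    index = _kmer_index(seqs, k)
    shared: dict[tuple[str, str], int] = defaultdict(int)
    for members in index.values():
        ms = sorted(members)
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                shared[(ms[i], ms[j])] += 1
    aligner = _local_aligner()
    out: dict[tuple[str, str], float] = {}
    for (a, b), count in shared.items():
        if count >= min_shared_kmers:
            out[(a, b)] = protein_identity(seqs[a], seqs[b], aligner)
    return out


def identity_graph(
    proteins: list[ProteinRecord],
    identity_cutoff: float = 0.70,
    identities: dict[tuple[str, str], float] | None = None,
) -> WeightedGraph:
    """Graph with an edge (weight = identity) wherever pairwise identity
    >= ``identity_cutoff``; every protein is a vertex (singletons allowed)."""
    if identities is None:
        identities = pairwise_identities(proteins)
    ids = [p.protein_id for p in proteins]
    edges = [
        (a, b, ident) for (a, b), ident in identities.items() if ident >= identity_cutoff
    ]
    return WeightedGraph(ids, edges)


def graph_from_blast_tab(
    path, evalue_max: float = 1e-5, weight_cap: float = 200.0
) -> WeightedGraph:
    """Similarity graph from BLAST tabular output (outfmt 6).

    Edges for hits with e-value strictly below ``evalue_max``; weight is
    ``min(-log10(e-value), weight_cap)`` (reported e-value 0 takes the cap);
    reciprocal hits are merged by mean weight; self-hits are dropped.
    """
    weights: dict[tuple[str, str], list[float]] = defaultdict(list)
    vertices: list[str] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 12 tab-separated fields, "
                    f"got {len(fields)}"
                )
            query, subject = fields[0], fields[1]
            try:
                evalue = float(fields[10])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad e-value {fields[10]!r}") from exc
            for x in (query, subject):
                if x not in seen:
                    seen.add(x)
                    vertices.append(x)
            if query == subject:
                continue
            if not evalue < evalue_max:
                continue
            w = weight_cap if evalue <= 0 else min(-math.log10(evalue), weight_cap)
            key = (query, subject) if query <= subject else (subject, query)
            weights[key].append(w)
    edges = [(a, b, sum(ws) / len(ws)) for (a, b), ws in weights.items()]
    return WeightedGraph(vertices, edges)


def medoid(
    member_ids: list[str],
    pairwise_dissimilarity: dict[tuple[str, str], float],
    lengths: dict[str, int],
    length_tolerance: float = 0.10,
) -> str:
    """Cluster representative: the member minimising mean dissimilarity to
    all other members, restricted to members whose length is within
    ``length_tolerance`` of the cluster's median length.

    Missing pairs count as dissimilarity 100.  If no member satisfies the
    length constraint it relaxes to the member(s) nearest the median length.
    Ties: smaller |len - median|, then lexicographic id.
    """
    if not member_ids:
        raise ValueError("empty cluster")
    if len(member_ids) == 1:
        return member_ids[0]
    med = median(lengths[m] for m in member_ids)

    def diss(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        return pairwise_dissimilarity.get(key, 100.0)

    eligible = [m for m in member_ids if abs(lengths[m] - med) <= length_tolerance * med]
    if not eligible:
        closest = min(abs(lengths[m] - med) for m in member_ids)
        eligible = [m for m in member_ids if abs(lengths[m] - med) == closest]
    best = min(
        eligible,
        key=lambda m: (
            sum(diss(m, other) for other in member_ids if other != m)
            / (len(member_ids) - 1),
            abs(lengths[m] - med),
            m,
        ),
    )
    return best


def reduce_redundancy(
    proteins: list[ProteinRecord],
    identity_cutoff: float = 0.70,
    mcl_params: MclParams | None = None,
    identities: dict[tuple[str, str], float] | None = None,
) -> list[MedoidAssignment]:
    """Collapse near-duplicate proteins: identity graph at
    ``identity_cutoff`` clustered with MCL; one :class:`MedoidAssignment`
    per cluster (singletons are their own medoid)."""
    if not proteins:
        return []
    if identities is None:
        identities = pairwise_identities(proteins)
    graph = identity_graph(proteins, identity_cutoff, identities)
    partition = mcl(graph, mcl_params or MclParams(inflate_factor=2.0))
    lengths = {p.protein_id: len(p.sequence) for p in proteins}
    dissim = {
        key: 100.0 * (1.0 - ident) for key, ident in identities.items()
    }
    out = []
    for k, members in enumerate(partition.clusters()):
        members = sorted(members)
        out.append(
            MedoidAssignment(
                cluster_id=f"C{k:04d}",
                medoid_id=medoid(members, dissim, lengths),
                member_ids=members,
                median_length=median(lengths[m] for m in members),
            )
        )
    return out


def two_level_labels(
    graph: WeightedGraph,
    if_class: float = 1.2,
    if_subclass: float = 3.0,
    params: MclParams | None = None,
) -> dict[str, str]:
    """Hierarchical class/subclass labels for every vertex of a similarity
    graph: MCL at a coarse inflate factor defines classes (numbered by
    decreasing size), a finer one defines subclasses; each subclass is
    attached to the class holding the majority of its members and numbered
    within it by decreasing size ("1.1", "2.3", ...).  A class that does not
    decompose (single subclass) keeps its bare class number, mirroring a
    coherent class."""
    base = params or MclParams()

    def run(factor: float) -> Partition:
        return mcl(
            graph,
            MclParams(
                inflate_factor=factor,
                expansion_power=base.expansion_power,
                prune_threshold=base.prune_threshold,
                max_iterations=base.max_iterations,
                convergence_tol=base.convergence_tol,
            ),
        )

    classes = run(if_class).clusters()
    classes.sort(key=lambda ms: (-len(ms), ms[0]))
    class_of = {v: i + 1 for i, ms in enumerate(classes) for v in ms}
    subclusters = run(if_subclass).clusters()
    per_class: dict[int, list[list]] = defaultdict(list)
    for members in subclusters:
        votes = defaultdict(int)
        for v in members:
            votes[class_of[v]] += 1
        best_class = max(votes, key=lambda c: (votes[c], -c))
        per_class[best_class].append(members)
    labels: dict[str, str] = {}
    for cls, subs in per_class.items():
        subs.sort(key=lambda ms: (-len(ms), ms[0]))
        for idx, members in enumerate(subs, start=1):
            name = str(cls) if len(subs) == 1 else f"{cls}.{idx}"
            for v in members:
                labels[v] = name
    return labels


def propagate_labels(
    medoid_labels: dict[str, str | None],
    assignments: list[MedoidAssignment],
) -> list[SubclassLabel]:
    """Give every cluster member its medoid's subclass label.

    The medoid itself is ``direct``, other members ``propagated``; members
    of a medoid labelled ``None`` (a discarded representative, e.g. a false
    positive) are marked ``discarded``.  An unlabelled medoid (missing key)
    is an error listing the offending clusters.
    """
    missing = [a.cluster_id for a in assignments if a.medoid_id not in medoid_labels]
    if missing:
        raise KeyError(f"unlabelled medoids in clusters: {missing}")
    out = []
    for a in assignments:
        label = medoid_labels[a.medoid_id]
        for m in a.member_ids:
            if label is None:
                out.append(SubclassLabel(m, None, None, "discarded"))
            else:
                cls = label.split(".")[0]
                prov = "direct" if m == a.medoid_id else "propagated"
                out.append(SubclassLabel(m, cls, label, prov))
    return out


def length_filter(
    labels: list[SubclassLabel],
    lengths: dict[str, int],
    lower_frac: float = 0.6,
    upper_frac: float = 1.67,
) -> list[SubclassLabel]:
    """Discard per-subclass length outliers (gene fusions, partial
    sequences): members outside ``[lower_frac, upper_frac] x subclass
    median length`` (inclusive bounds retained) are re-marked discarded."""
    by_subclass: dict[str, list[SubclassLabel]] = defaultdict(list)
    for lab in labels:
        if lab.provenance != "discarded" and lab.subclass_id is not None:
            by_subclass[lab.subclass_id].append(lab)
    out = []
    medians = {
        sub: median(lengths[lab.protein_id] for lab in labs)
        for sub, labs in by_subclass.items()
    }
    for lab in labels:
        if lab.provenance == "discarded" or lab.subclass_id is None:
            out.append(lab)
            continue
        med = medians[lab.subclass_id]
        length = lengths[lab.protein_id]
        if lower_frac * med <= length <= upper_frac * med:
            out.append(lab)
        else:
            out.append(SubclassLabel(lab.protein_id, None, None, "discarded"))
    return out
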