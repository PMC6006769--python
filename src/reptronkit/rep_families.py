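"""REP family clustering, BIME/REPIN assembly and REPtron calling.

REP candidates found by the scanner are clustered into sequence families
(pairwise identity graph + MCL), assembled into BIMEs (runs of >= 2 REPs
whose consecutive gaps are at most 150 nt; a REPIN is the special case of
exactly two REPs in inverted orientation), and families with at least one
copy in the +/- 1000 nt vicinity of a tnpA-like gene are reported as that
gene's REPtron.

Pairwise REP identity uses global alignment with free end gaps (identity =
matches / aligned overlap columns); REPs are short (~20-65 nt), where
word-seeded search is unreliable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio import Align

from .mcl_core import MclParams, WeightedGraph, mcl
from .rep_scanner import RepCandidate

__all__ = [
    "GeneFeature",
    "RepFamily",
    "Bime",
    "Reptron",
    "rep_identity",
    "rep_identity_graph",
    "cluster_rep_families",
    "assemble_bimes",
    "call_reptrons",
    "analyze_reptrons",
]


@dataclass
class GeneFeature:
    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str
    product_label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class RepFamily:
    family_id: str
    member_ids: list[str]
    consensus: str
    modal_geometry: tuple  # (kind, stem1, loop, bulge, stem2)


@dataclass
class Bime:
    contig_id: str
    member_ids: list[str]          # ordered along the contig, >= 2
    span: tuple[int, int]
    is_repin: bool


@dataclass
class Reptron:
    gene: GeneFeature
    families: list[str]
    upstream_reps: list[str]
    downstream_reps: list[str]
    inside_gene_reps: list[str] = field(default_factory=list)


def _free_end_gap_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -1.0
    # free end gaps: overhangs cost nothing and are excluded from identity
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def rep_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Pairwise nucleotide identity from a global alignment with free end
    gaps: matches divided by aligned columns of the overlap (terminal
    overhangs excluded, internal gaps counted)."""
    if not a or not b:
        return 0.0
    aligner = aligner or _free_end_gap_aligner()
    aln = aligner.align(a.upper(), b.upper())[0]
    c = aln.counts()
    cols = c.identities + c.mismatches + c.internal_insertions + c.internal_deletions
    return c.identities / cols if cols else 0.0


def rep_identity_graph(
    candidates: list[RepCandidate], min_identity: float = 0.80
) -> WeightedGraph:
    """Undirected graph on candidate ids with an edge of weight = identity
    wherever pairwise identity >= ``min_identity``."""
    for i, cand in enumerate(candidates):
        if not cand.rep_id:
            cand.rep_id = f"{cand.contig_id}:REP{i:04d}"
    ids = [c.rep_id for c in candidates]
    aligner = _free_end_gap_aligner()
    edges = []
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            ident = rep_identity(candidates[i].sequence, candidates[j].sequence, aligner)
            if ident >= min_identity:
                edges.append((ids[i], ids[j], ident))
    return WeightedGraph(ids, edges)


def _consensus(seqs: list[str]) -> str:
    """Per-column majority over the modal-length subset (ties: smaller
    length for the mode, lexicographically smallest base per column)."""
    lengths = Counter(len(s) for s in seqs)
    modal_len = min(
        (length for length, cnt in lengths.items() if cnt == max(lengths.values())),
    )
    stack = [s for s in seqs if len(s) == modal_len]
    cols = []
    for i in range(modal_len):
        counts = Counter(s[i] for s in stack)
        top = max(counts.values())
        cols.append(min(b for b, cnt in counts.items() if cnt == top))
    return "".join(cols)


def cluster_rep_families(
    graph: WeightedGraph,
    candidates: list[RepCandidate],
    mcl_params: MclParams | None = None,
) -> list[RepFamily]:
    """MCL clusters of the identity graph as :class:`RepFamily` records.

    The consensus is the per-column majority over the modal-length members;
    the modal geometry is the most common (kind, stem1, loop, bulge, stem2)
    among members.  Every candidate belongs to exactly one family.
    """
    if graph.n == 0:
        return []
    by_id = {c.rep_id: c for c in candidates}
    partition = mcl(graph, mcl_params or MclParams(inflate_factor=2.0))
    families = []
    for k, members in enumerate(partition.clusters()):
        cands = [by_id[m] for m in members]
        geometry = Counter(
            (c.hairpin_kind, c.stem1_len, c.loop_len, c.bulge_len, c.stem2_len)
            for c in cands
        ).most_common(1)[0][0]
        families.append(
            RepFamily(
                family_id=f"F{k:03d}",
                member_ids=list(members),
                consensus=_consensus([c.sequence for c in cands]),
                modal_geometry=geometry,
            )
        )
    return families


def assemble_bimes(candidates: list[RepCandidate], max_gap: int = 150) -> list[Bime]:
    """Maximal runs of >= 2 REPs with consecutive gaps
    (``next.start - prev.end``) <= ``max_gap``, per contig.

    ``is_repin`` marks runs of exactly two members on opposite strands
    (a REP doublet in inverted orientation).
    """
    bimes = []
    by_contig: dict[str, list[RepCandidate]] = {}
    for c in candidates:
        by_contig.setdefault(c.contig_id, []).append(c)
    for contig_id, cands in by_contig.items():
        cands = sorted(cands, key=lambda c: (c.start, c.end))
        run: list[RepCandidate] = []
        for cand in cands:
            if run and cand.start - run[-1].end <= max_gap:
                run.append(cand)
            else:
                if len(run) >= 2:
                    bimes.append(_make_bime(contig_id, run))
                run = [cand]
        if len(run) >= 2:
            bimes.append(_make_bime(contig_id, run))
    return bimes


def _make_bime(contig_id: str, run: list[RepCandidate]) -> Bime:
    return Bime(
        contig_id=contig_id,
        member_ids=[c.rep_id for c in run],
        span=(run[0].start, run[-1].end),
        is_repin=len(run) == 2 and run[0].strand != run[1].strand,
    )


def _vicinity_distance(cand: RepCandidate, gene: GeneFeature) -> int:
    """Distance from the gene boundary to the nearest REP edge; 0 when the
    REP overlaps the gene."""
    if cand.end <= gene.start:
        return gene.start - cand.end
    if cand.start >= gene.end:
        return cand.start - gene.end
    return 0


def call_reptrons(
    families: list[RepFamily],
    candidates: list[RepCandidate],
    genes: list[GeneFeature],
    window: int = 1000,
) -> tuple[list[Reptron], list[RepFamily]]:
    """Retain families with >= 1 member within ``window`` nt of a gene
    boundary (inclusive at exactly ``window``) and build one
    :class:`Reptron` per gene with at least one such family.

    Members are split into upstream/downstream by midpoint side; REPs
    overlapping the gene itself are kept and additionally listed in
    ``inside_gene_reps``.
    """
    by_id = {c.rep_id: c for c in candidates}
    retained: list[RepFamily] = []
    for fam in families:
        near = any(
            by_id[m].contig_id == g.contig_id
            and _vicinity_distance(by_id[m], g) <= window
            for m in fam.member_ids
            for g in genes
        )
        if near:
            retained.append(fam)
    reptrons = []
    for gene in genes:
        fam_ids, up, down, inside = [], [], [], []
        for fam in retained:
            members_near = [
                m
                for m in fam.member_ids
                if by_id[m].contig_id == gene.contig_id
                and _vicinity_distance(by_id[m], gene) <= window
            ]
            if not members_near:
                continue
            fam_ids.append(fam.family_id)
            for m in members_near:
                cand = by_id[m]
                if _vicinity_distance(cand, gene) == 0 and not (
                    cand.end <= gene.start or cand.start >= gene.end
                ):
                    inside.append(m)
                mid = (cand.start + cand.end) / 2
                (up if mid < gene.midpoint else down).append(m)
        if fam_ids:
            up.sort(key=lambda m: by_id[m].start)
            down.sort(key=lambda m: by_id[m].start)
            reptrons.append(
                Reptron(
                    gene=gene,
                    families=fam_ids,
                    upstream_reps=up,
                    downstream_reps=down,
                    inside_gene_reps=inside,
                )
            )
    return reptrons, retained


def analyze_reptrons(
    candidates: list[RepCandidate],
    genes: list[GeneFeature],
    min_identity: float = 0.80,
    max_gap: int = 150,
    window: int = 1000,
    mcl_params: MclParams | None = None,
) -> dict:
    """End-to-end REP family / BIME / REPtron analysis for one genome.

    BIMEs are assembled among the members of retained families (the copies a
    tnpA-like gene plausibly mobilises), so isolated background structures
    far from any gene do not contribute.
    """
    graph = rep_identity_graph(candidates, min_identity)
    families = cluster_rep_families(graph, candidates, mcl_params)
    reptrons, retained = call_reptrons(families, candidates, genes, window)
    retained_ids = {m for fam in retained for m in fam.member_ids}
    bimes = assemble_bimes(
        [c for c in candidates if c.rep_id in retained_ids], max_gap
    )
    return {
        "families": families,
        "retained_families": retained,
        "bimes": bimes,
        "reptrons": reptrons,
    }
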