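"""Synthetic genomes, REP elements, REPtrons and protein families.

The generator produces data with *known ground truth* matching the
statistical structure the analysis pipeline assumes: i.i.d. background
genomes with a chosen GC content, REP hairpins built to satisfy a
:class:`~reptronkit.rep_scanner.RepRuleSet` exactly, tnpA-like genes with
HuH/W/Y motifs at controlled spacings, protein families with controlled
pairwise identity, and planted-partition graphs with a one- or two-level
(class/subclass) block structure.

Everything is a pure function of its seed: the same seed gives bitwise
identical output.  Planting *inserts* (never overwrites), so background
sequence can never corrupt a planted element; truth coordinates are
recomputed after each insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import rep_scanner
from .dna import IUPAC, gc_fraction, matches_motif, revcomp

COMPLEMENT_BASE = {"A": "T", "T": "A", "C": "G", "G": "C"}
from .mcl_core import WeightedGraph
from .rep_scanner import RepCandidate, RepRuleSet

__all__ = [
    "SimConfig",
    "TruthRecord",
    "PlantedTruth",
    "random_genome",
    "random_protein",
    "make_rep",
    "mutate_rep",
    "plant",
    "plant_reps",
    "make_protein_family",
    "make_motif_protein",
    "planted_partition_graph",
    "two_level_partition_graph",
    "simulate_reptron_genome",
]

_BASES = np.array(list("ACGT"))
_AA = "ACDEFGHIKLMNPQRSTVWY"
# Scaffold alphabet for motif proteins: excludes residues that could form
# accidental HuH / W / Y-signature matches, so planted motifs are the only
# pattern occurrences (see docs/methods.md).
_SCAFFOLD_AA = "ACDEFGIKLMRST"


@dataclass(frozen=True)
class SimConfig:
    """Top-level simulation settings for the CLI ``simulate`` command."""

    seed: int = 0
    genome_length: int = 100_000
    gc: float = 0.5
    substitution_rate: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must lie in [0, 1]")
        if self.genome_length < 0:
            raise ValueError("genome_length must be >= 0")


@dataclass
class TruthRecord:
    """One planted element, 0-based half-open coordinates."""

    kind: str                        # rep | gene | bime | reptron
    contig_id: str
    start: int
    end: int
    strand: str
    params: dict = field(default_factory=dict)


@dataclass
class PlantedTruth:
    records: list[TruthRecord] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[TruthRecord]:
        return [r for r in self.records if r.kind == kind]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_genome(length: int, gc: float, seed) -> str:
    """Random DNA with i.i.d. bases; P(G)+P(C)=gc, split equally in each pair."""
    if length < 0:
        raise ValueError("length must be >= 0")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = _rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=p))


def random_protein(length: int, seed, alphabet: str = _AA) -> str:
    rng = _rng(seed)
    return "".join(rng.choice(list(alphabet), size=length))


def _random_stem(length: int, gc_frac: float, rng) -> str:
    p = [(1 - gc_frac) / 2, gc_frac / 2, gc_frac / 2, (1 - gc_frac) / 2]
    return "".join(rng.choice(_BASES, size=length, p=p))


def make_rep(
    rules: RepRuleSet,
    foot: str,
    offset: int,
    stem1: int,
    loop: int,
    bulge: int | None = None,
    stem2: int | None = None,
    gc_stem: float = 0.8,
    seed=0,
) -> tuple[str, dict]:
    """Construct a REP element with the exact geometry requested.

    Returns ``(sequence, geometry)`` where the sequence is
    ``foot + spacer + 5'arm(s) + loop + 3'arm(s)`` with the 3' arms exact
    reverse complements of the 5' arms, and the geometry dict records the
    planted parameters.  The element is rebuilt (bounded retries on the same
    RNG stream) until the scanner's best parse at its foot reproduces the
    requested geometry over the full span, so the round trip with
    :func:`reptronkit.rep_scanner.scan` is exact by construction.
    """
    if (bulge is None) != (stem2 is None):
        raise ValueError("bulge and stem2 must both be set (long) or both None (short)")
    kind = "short" if bulge is None else "long"
    if not matches_motif(foot, rules.foot_motifs[0]) and not any(
        matches_motif(foot, m) for m in rules.foot_motifs
    ):
        raise ValueError(f"foot {foot!r} does not match rule motifs {rules.foot_motifs}")
    for name, value, rng_ in (
        ("foot_offset", offset, rules.foot_offset),
        ("stem1", stem1, rules.stem1),
        ("loop", loop, rules.loop),
    ):
        if not rng_[0] <= value <= rng_[1]:
            raise ValueError(f"{name}={value} outside rule range {rng_}")
    if kind == "long":
        if not rules.bulge[0] <= bulge <= rules.bulge[1]:
            raise ValueError(f"bulge={bulge} outside rule range {rules.bulge}")
        if not rules.stem2[0] <= stem2 <= rules.stem2[1]:
            raise ValueError(f"stem2={stem2} outside rule range {rules.stem2}")
    rng = _rng(seed)
    geometry = {
        "kind": kind,
        "foot": foot.upper(),
        "offset": offset,
        "stem1": stem1,
        "loop": loop,
        "bulge": bulge,
        "stem2": stem2,
    }
    for _ in range(200):
        spacer = "".join(rng.choice(_BASES, size=offset))
        arm1 = _random_stem(stem1, gc_stem, rng)
        if kind == "short":
            if sum(b in "GC" for b in arm1[:4]) < rules.basal4_min_gc:
                continue
            loop_seq = "".join(rng.choice(_BASES, size=loop))
            seq = foot.upper() + spacer + arm1 + loop_seq + revcomp(arm1)
        else:
            arm2 = _random_stem(stem2, gc_stem, rng)
            if gc_fraction(arm1 + arm2) < rules.stem_min_gc:
                continue
            bulge_seq = "".join(rng.choice(_BASES, size=bulge))
            loop_seq = "".join(rng.choice(_BASES, size=loop))
            seq = (
                foot.upper() + spacer + arm1 + bulge_seq + arm2
                + loop_seq + revcomp(arm2) + revcomp(arm1)
            )
        if _fold_matches(seq, rules, geometry):
            return seq, geometry
    raise RuntimeError(
        "could not construct an element whose best parse equals the requested "
        "geometry; rules and parameters may be incompatible"
    )


def _fold_matches(seq: str, rules: RepRuleSet, geometry: dict) -> bool:
    cand = rep_scanner.fold_hairpin(seq, 0, rules)
    return (
        cand is not None
        and cand.hairpin_end == len(seq)
        and cand.foot_offset == geometry["offset"]
        and cand.hairpin_kind == geometry["kind"]
        and cand.stem1_len == geometry["stem1"]
        and cand.loop_len == geometry["loop"]
        and cand.bulge_len == geometry["bulge"]
        and cand.stem2_len == geometry["stem2"]
    )


def mutate_rep(seq: str, geometry: dict, rate: float, seed, rules: RepRuleSet) -> str:
    """Substitute bases of a REP element at ``rate`` while preserving its
    structure: 5'-arm substitutions are mirrored onto the 3' arm
    (compensatory changes), the foot is kept, spacer/bulge/loop bases mutate
    freely.  Retries on the same RNG stream until the mutant's best parse
    still equals the planted geometry."""
    rng = _rng(seed)
    foot_len = 4
    off = geometry["offset"]
    s1, loop = geometry["stem1"], geometry["loop"]
    b = geometry["bulge"] or 0
    s2 = geometry["stem2"] or 0
    h = foot_len + off
    for _ in range(100):
        chars = list(seq)
        # free positions: spacer, bulge, loop
        free = list(range(foot_len, h))
        free += list(range(h + s1, h + s1 + b))
        loop_start = h + s1 + b + s2
        free += list(range(loop_start, loop_start + loop))
        for i in free:
            if rng.random() < rate:
                chars[i] = rng.choice([c for c in "ACGT" if c != chars[i]])
        # compensatory arm substitutions
        n = len(seq)
        for i in range(h, h + s1):            # basal 5' arm; partner in 3' arm
            if rng.random() < rate:
                new = rng.choice([c for c in "ACGT" if c != chars[i]])
                chars[i] = new
                chars[n - 1 - (i - h)] = revcomp(new)
        for k in range(s2):                    # second 5' arm
            i = h + s1 + b + k
            j = loop_start + loop + (s2 - 1 - k)
            if rng.random() < rate:
                new = rng.choice([c for c in "ACGT" if c != chars[i]])
                chars[i] = new
                chars[j] = revcomp(new)
        mutant = "".join(chars)
        if _fold_matches(mutant, rules, geometry):
            return mutant
    raise RuntimeError("could not produce a structure-preserving mutant")


def plant(genome: str, element: str, position: int) -> tuple[str, TruthRecord]:
    """Insert ``element`` into ``genome`` at ``position`` (insertion, not
    replacement) and return the new genome plus a truth record with 0-based
    half-open coordinates in the *new* genome."""
    if not 0 <= position <= len(genome):
        raise ValueError(f"position {position} outside [0, {len(genome)}]")
    new = genome[:position] + element + genome[position:]
    rec = TruthRecord(
        kind="rep", contig_id="contig", start=position,
        end=position + len(element), strand="+",
    )
    return new, rec


def _grid_geometries(rules: RepRuleSet) -> list[dict]:
    """A deterministic sweep over the rule grid (all offsets, stems, loops;
    long geometries subsampled over bulge/stem2)."""
    out = []
    for off in range(rules.foot_offset[0], rules.foot_offset[1] + 1):
        for loop in range(rules.loop[0], rules.loop[1] + 1):
            for s1 in range(rules.stem1[0], rules.stem1[1] + 1):
                out.append({"offset": off, "stem1": s1, "loop": loop,
                            "bulge": None, "stem2": None})
    if rules.allow_long:
        for off in range(rules.foot_offset[0], rules.foot_offset[1] + 1):
            for b in range(rules.bulge[0], rules.bulge[1] + 1):
                for s2 in range(rules.stem2[0], rules.stem2[1] + 1):
                    s1 = rules.stem1[0] + (b + s2) % (rules.stem1[1] - rules.stem1[0] + 1)
                    loop = rules.loop[0] + (s2 % (rules.loop[1] - rules.loop[0] + 1))
                    out.append({"offset": off, "stem1": s1, "loop": loop,
                                "bulge": b, "stem2": s2})
    return out


def _patch_spacer_boundary(
    seq: str, geometry: dict, bad_bases: set[str], rules: RepRuleSet, rng
) -> str | None:
    """Make a planted element safe against stem extension across its 3'
    boundary.

    An element with foot offset o >= 1 can be re-parsed at a smaller offset
    with a one-longer stem whenever its last spacer base happens to pair the
    first background base after the insertion (the alternative parse lies on
    the same pairing anti-diagonal, so it costs a single chance pairing).
    Replacing the last spacer base with one outside ``bad_bases`` removes
    every such parse.  Returns the patched element (unchanged if already
    safe), or ``None`` if no safe replacement preserves the geometry.
    """
    offset = geometry["offset"]
    if offset == 0:
        return seq
    idx = 4 + offset - 1
    if seq[idx] not in bad_bases:
        return seq
    options = [b for b in "ACGT" if b not in bad_bases and b != seq[idx]]
    rng.shuffle(options)
    for b in options:
        patched = seq[:idx] + b + seq[idx + 1 :]
        if _fold_matches(patched, rules, geometry):
            return patched
    return None


def plant_reps(
    genome: str,
    n_reps: int,
    rules: RepRuleSet,
    seed,
    contig_id: str = "contig",
    both_strands: bool = True,
    min_gap: int = 80,
    validate: bool = True,
) -> tuple[str, PlantedTruth]:
    """Plant ``n_reps`` REP elements spanning the rule grid at random,
    well-separated positions, on both strands.

    Ground-truth hygiene: with ``validate`` (default) the finished genome is
    re-scanned and the placement is redrawn (derived seed) whenever the
    random background happens to produce a higher-priority parse at a planted
    foot, which would make the planted coordinates wrong rather than the
    scanner wrong.  This is rare (~1e-3 per element) and keeps truth labels
    valid; see docs/methods.md.
    """
    base_seed = int(_rng(seed).integers(0, 2**31 - 1))
    grid = _grid_geometries(rules)
    for attempt in range(20):
        rng = np.random.default_rng((base_seed + attempt) % (2**31 - 1))
        elements = []
        for i in range(n_reps):
            geo = grid[i % len(grid)]
            foot = "GTAG" if rng.random() < 0.5 else "GTGG"
            if not any(matches_motif(foot, m) for m in rules.foot_motifs):
                # custom rule sets: realise the first motif concretely
                foot = "".join(
                    rng.choice(list(IUPAC[c.upper()])) for c in rules.foot_motifs[0]
                )
            seq, geometry = make_rep(
                rules, foot, geo["offset"], geo["stem1"], geo["loop"],
                geo["bulge"], geo["stem2"], seed=rng,
            )
            strand = "-" if both_strands and i % 2 else "+"
            elements.append((seq, geometry, strand))
        # choose ascending insertion points with at least min_gap separation
        slack = len(genome) - n_reps * min_gap
        if slack <= 0:
            raise ValueError("genome too short for the requested number of REPs")
        cuts = np.sort(rng.choice(slack, size=n_reps, replace=False))
        positions = [int(c + i * min_gap) for i, c in enumerate(cuts)]
        new = genome
        shift = 0
        truth = PlantedTruth()
        ok = True
        for (seq, geometry, strand), pos in zip(elements, positions):
            at = pos + shift
            # guard the element's 3' boundary against chance stem extension
            if strand == "+":
                nxt = new[at] if at < len(new) else ""
                bad = {COMPLEMENT_BASE[nxt]} if nxt in "ACGT" else set()
            else:
                prev = new[at - 1] if at > 0 else ""
                bad = {prev} if prev in "ACGT" else set()
            patched = _patch_spacer_boundary(seq, geometry, bad, rules, rng)
            if patched is None:
                ok = False
                break
            seq = patched
            ins = seq if strand == "+" else revcomp(seq)
            new, _ = plant(new, ins, at)
            truth.records.append(
                TruthRecord(
                    kind="rep", contig_id=contig_id, start=at,
                    end=at + len(seq), strand=strand,
                    params=dict(geometry),
                )
            )
            shift += len(seq)
        if not ok:
            continue
        if not validate:
            return new, truth
        hits = rep_scanner.scan(new, rules, contig_id=contig_id)
        found = {(c.hairpin_start, c.hairpin_end, c.strand) for c in hits}
        if all((r.start, r.end, r.strand) in found for r in truth.records):
            return new, truth
    raise RuntimeError("could not achieve a collision-free placement")


def make_protein_family(
    seed_protein: str,
    n: int,
    target_identity: float,
    protected_sites=(),
    seed=0,
) -> list[str]:
    """``n`` descendants of ``seed_protein`` with expected identity
    ``target_identity`` to the seed, substitutions restricted to unprotected
    sites (planted motifs stay intact) and replacements drawn uniformly from
    the 19 non-identical amino acids."""
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must lie in (0, 1]")
    L = len(seed_protein)
    protected = set(protected_sites)
    free = [i for i in range(L) if i not in protected]
    expected_subs = (1 - target_identity) * L
    if free and expected_subs / len(free) > 1 or (not free and expected_subs > 0):
        raise ValueError("unprotected sites cannot absorb the requested divergence")
    rate = expected_subs / len(free) if free else 0.0
    rng = _rng(seed)
    out = []
    for _ in range(n):
        chars = list(seed_protein)
        for i in free:
            if rng.random() < rate:
                chars[i] = rng.choice([a for a in _AA if a != chars[i]])
        out.append("".join(chars))
    return out


def make_motif_protein(
    class_id: int,
    distance: int,
    length: int = 220,
    huh_pos: int = 30,
    seed=0,
) -> tuple[str, dict]:
    """A protein scaffold with one HuH motif, one class-specific Y motif at
    ``distance`` residues downstream of the second H, and a conserved W five
    residues before the Y.

    The scaffold alphabet excludes H/N/P/Q/V?/W/Y-forming residues outside
    the planted motifs, so the planted pair is the only valid HuH/Y pair.
    Returns ``(sequence, info)`` with the planted positions (0-based).
    """
    rng = _rng(seed)
    u = {1: "V", 2: "L", 3: "V"}[class_id]
    y_ctx = {1: "TTTQ", 2: "TTTNP", 3: "TTTTQ"}[class_id]  # Y-x3-Q / Y-x3-NP / Y-x4-Q
    second_h = huh_pos + 2
    y_pos = second_h + distance
    w_pos = y_pos - 5
    min_len = y_pos + 1 + len(y_ctx) + 10
    length = max(length, min_len)
    chars = list(random_protein(length, rng, alphabet=_SCAFFOLD_AA))
    chars[huh_pos : huh_pos + 3] = ["H", u, "H"]
    chars[w_pos] = "W"
    chars[y_pos] = "Y"
    chars[y_pos + 1 : y_pos + 1 + len(y_ctx)] = list(y_ctx)
    protected = list(range(huh_pos, huh_pos + 3)) + [w_pos] + list(
        range(y_pos, y_pos + 1 + len(y_ctx))
    )
    info = {
        "class_id": class_id,
        "huh_pos": huh_pos,
        "second_h": second_h,
        "w_pos": w_pos,
        "y_pos": y_pos,
        "distance": distance,
        "protected_sites": protected,
    }
    return "".join(chars), info


def planted_partition_graph(
    blocks,
    p_in: float,
    p_out: float,
    weight_in: float = 1.0,
    weight_out: float = 1.0,
    seed=0,
) -> WeightedGraph:
    """Undirected planted-partition graph: within-block edges with
    probability ``p_in`` and weight ``weight_in``; between-block edges with
    ``p_out``/``weight_out``.  Vertices are integers ``0..n-1`` laid out
    block by block (block membership is implied by ``blocks``)."""
    if p_out >= p_in:
        raise ValueError("p_out must be < p_in")
    rng = _rng(seed)
    labels = np.concatenate([[k] * b for k, b in enumerate(blocks)]) if blocks else np.array([])
    n = int(labels.size)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            same = labels[i] == labels[j]
            p, w = (p_in, weight_in) if same else (p_out, weight_out)
            if rng.random() < p:
                edges.append((i, j, w))
    return WeightedGraph(list(range(n)), edges)


def two_level_partition_graph(
    structure,
    p_sub: float = 0.9,
    p_super: float = 0.3,
    p_out: float = 0.02,
    weight_sub: float = 2.0,
    weight_super: float = 1.0,
    weight_out: float = 0.5,
    seed=0,
) -> tuple[WeightedGraph, list[tuple[int, int]]]:
    """Graph with a class/subclass hierarchy: ``structure`` is a list of
    super-blocks, each a list of sub-block sizes.  Returns the graph and the
    per-vertex ``(super, sub)`` labels.  A coarse partitioning (low inflate
    factor) should recover the super-blocks, a fine one the sub-blocks."""
    rng = _rng(seed)
    labels: list[tuple[int, int]] = []
    for s, subs in enumerate(structure):
        for b, size in enumerate(subs):
            labels += [(s, b)] * size
    n = len(labels)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                p, w = p_sub, weight_sub
            elif labels[i][0] == labels[j][0]:
                p, w = p_super, weight_super
            else:
                p, w = p_out, weight_out
            if rng.random() < p:
                edges.append((i, j, w))
    return WeightedGraph(list(range(n)), edges), labels


def simulate_reptron_genome(
    seed=0,
    genome_length: int = 12_000,
    gc: float = 0.5,
    n_repin_pairs: int = 3,
    pair_gap: int = 40,
    inter_pair_gap: int = 250,
    gene_length: int = 450,
    mutation_rate: float = 0.04,
    rules: RepRuleSet | None = None,
) -> dict:
    """One genome with a tnpA-like gene flanked by inverted REP pairs.

    Mirrors the canonical REPtron layout: a single tnpA_REP-like gene with
    ``n_repin_pairs`` REP sequence pairs in inverted orientation within the
    +/-1000 nt vicinity, all copies drawn from one REP family (structure-
    preserving mutants of one seed element).  Pairs are separated by more
    than the BIME gap so each inverted pair forms its own BIME/REPIN.
    The finished genome is re-scanned and regenerated (derived seed) in the
    rare case that random background spoils a planted locus or lands a
    spurious hit next to a planted element (ground-truth hygiene, see
    docs/methods.md).

    Returns a dict with ``genome``, ``truth`` (:class:`PlantedTruth` holding
    gene + rep records), ``rules`` and ``family_seed`` (the founder REP).
    """
    rules = rules or RepRuleSet()
    base_seed = int(_rng(seed).integers(0, 2**31 - 1))
    for attempt in range(20):
        out = _build_reptron_genome(
            np.random.default_rng((base_seed + attempt) % (2**31 - 1)),
            genome_length, gc, n_repin_pairs, pair_gap, inter_pair_gap,
            gene_length, mutation_rate, rules,
        )
        hits = rep_scanner.scan(out["genome"], rules)
        spans = {(c.hairpin_start, c.hairpin_end, c.strand) for c in hits}
        reps = out["truth"].of_kind("rep")
        planted_ok = all((r.start, r.end, r.strand) in spans for r in reps)
        # no unplanned hit close to a planted element or the gene vicinity
        guard_lo = min(r.start for r in reps) - 200
        guard_hi = max(r.end for r in reps) + 200
        planted_spans = {(r.start, r.end, r.strand) for r in reps}
        clean = all(
            (c.hairpin_start, c.hairpin_end, c.strand) in planted_spans
            or c.end <= guard_lo or c.start >= guard_hi
            for c in hits
        )
        if planted_ok and clean:
            return out
    raise RuntimeError("could not build a clean REPtron genome")


def _build_reptron_genome(
    rng,
    genome_length,
    gc,
    n_repin_pairs,
    pair_gap,
    inter_pair_gap,
    gene_length,
    mutation_rate,
    rules,
) -> dict:
    founder, geometry = make_rep(rules, "GTAG", 1, 12, 3, seed=rng, gc_stem=0.85)
    copies = [founder] + [
        mutate_rep(founder, geometry, mutation_rate, rng, rules)
        for _ in range(2 * n_repin_pairs - 1)
    ]
    gene_seq = random_genome(gene_length, gc, rng)
    pairs = [(copies[2 * k], copies[2 * k + 1]) for k in range(n_repin_pairs)]
    upstream_pairs = (n_repin_pairs + 1) // 2
    genome = random_genome(genome_length, gc, rng)
    # place elements with controlled gaps around the genome midpoint so every
    # REP lies within 1000 nt of the gene boundaries
    mid = genome_length // 2
    truth = PlantedTruth()
    gap_to_gene = 120
    items: list[tuple[int, str, str, str, int]] = []  # (bg pos, kind, seq, strand, pair)
    bg_pos = mid - gap_to_gene
    for k in range(upstream_pairs - 1, -1, -1):  # laid right-to-left from the gene
        plus, minus = pairs[k]
        items.append((bg_pos, "rep", minus, "-", k))
        bg_pos -= pair_gap
        items.append((bg_pos, "rep", plus, "+", k))
        bg_pos -= inter_pair_gap
    items.append((mid, "gene", gene_seq, "+", -1))
    bg_pos = mid + gap_to_gene
    for k in range(upstream_pairs, n_repin_pairs):
        plus, minus = pairs[k]
        items.append((bg_pos, "rep", plus, "+", k))
        bg_pos += pair_gap
        items.append((bg_pos, "rep", minus, "-", k))
        bg_pos += inter_pair_gap
    items.sort(key=lambda t: t[0])
    new = genome
    shift = 0
    gene_rec = None
    for bg, kind, seq, strand, pairidx in items:
        ins = seq if strand == "+" or kind == "gene" else revcomp(seq)
        new, _ = plant(new, ins, bg + shift)
        rec = TruthRecord(
            kind=kind, contig_id="contig", start=bg + shift,
            end=bg + shift + len(ins), strand=strand,
            params={} if kind == "gene" else {"pair": pairidx, **geometry},
        )
        if kind == "gene":
            rec.params = {"gene_id": "tnpA_0001", "product": "tnpA"}
            gene_rec = rec
        truth.records.append(rec)
        shift += len(ins)
    assert gene_rec is not None
    return {
        "genome": new,
        "truth": truth,
        "rules": rules,
        "family_seed": founder,
        "geometry": geometry,
        "gene": gene_rec,
    }
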