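"""Structural detection of REP (Repetitive Extragenic Palindromic) elements.

A REP element is modelled as a 4-nt guide ("foot") tetranucleotide, typically
GT[AG]G, sitting 0-2 nt 5' of a DNA hairpin.  Two hairpin shapes are allowed:

* **short** - a single fully paired basal stem of 7-20 nt closed by a 2-5 nt
  loop, whose first four stem nucleotides contain at least three G/C;
* **long** - the basal stem plus a second fully paired stem of 1-10 nt,
  connected by a 1-3 nt bulge (modelled as unpaired bases on the 5' arm only),
  with the overall 5'-arm stem GC content >= 50%.

"Fully paired" means exact Watson-Crick complementarity (A.T, G.C); there is
no wobble pairing, as befits a DNA secondary structure.  All rule ranges are
configurable through :class:`RepRuleSet`, which also accommodates atypical
families (e.g. CnGA-footed elements) purely by supplying alternative foot
motifs or relaxed ranges.

Coordinates are 0-based, half-open, forward strand.  Minus-strand hits are
reported in forward coordinates with ``strand == '-'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dna import encode, gc_fraction, iupac_regex, matches_motif, revcomp

__all__ = [
    "RepRuleSet",
    "RepCandidate",
    "find_foot",
    "fold_hairpin",
    "detect_double_foot",
    "scan",
]


@dataclass(frozen=True)
class RepRuleSet:
    """Structural descriptor for REP candidates.

    Ranges are inclusive ``(low, high)`` pairs in nucleotides.
    """

    foot_motifs: tuple[str, ...] = ("GTRG",)  # GT[AG]G
    foot_offset: tuple[int, int] = (0, 2)
    stem1: tuple[int, int] = (7, 20)
    loop: tuple[int, int] = (2, 5)
    bulge: tuple[int, int] = (1, 3)
    stem2: tuple[int, int] = (1, 10)
    basal4_min_gc: int = 3          # short hairpins: G/C among first 4 stem nt
    stem_min_gc: float = 0.50       # long hairpins: GC fraction of the 5' arms
    scan_both_strands: bool = True
    allow_long: bool = True
    allow_short: bool = True

    def __post_init__(self) -> None:
        for name in ("foot_offset", "stem1", "loop", "bulge", "stem2"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"empty or negative range for {name}: ({lo}, {hi})")
        if not 0 <= self.basal4_min_gc <= 4:
            raise ValueError("basal4_min_gc must be in 0..4")
        if not self.foot_motifs:
            raise ValueError("at least one foot motif required")
        for m in self.foot_motifs:
            if len(m) != 4:
                raise ValueError(f"foot motif {m!r} is not a tetranucleotide")
            iupac_regex(m)  # validates IUPAC alphabet

    @property
    def max_span(self) -> int:
        """Largest possible hairpin span (foot excluded) under these rules."""
        span = self.foot_offset[1] + 2 * self.stem1[1] + self.loop[1]
        if self.allow_long:
            span += self.bulge[1] + 2 * self.stem2[1]
        return span


@dataclass
class RepCandidate:
    """A detected REP element.

    ``start``/``end`` span the whole element including a 3' double foot when
    present; ``hairpin_start``/``hairpin_end`` span foot + spacer + hairpin
    only.  For plus-strand hits ``start == hairpin_start``; for minus-strand
    hits ``end == hairpin_end`` (the double foot extends leftwards in forward
    coordinates).
    """

    contig_id: str
    start: int
    end: int
    strand: str
    foot_seq: str
    foot_offset: int
    hairpin_kind: str               # "short" | "long"
    stem1_len: int
    loop_len: int
    bulge_len: int | None
    stem2_len: int | None
    double_foot: bool
    sequence: str                   # element sequence in strand orientation
    hairpin_start: int = 0
    hairpin_end: int = 0
    rep_id: str = ""

    @property
    def paired_len(self) -> int:
        return self.stem1_len + (self.stem2_len or 0)


def find_foot(seq: str, motifs) -> list[int]:
    """All (possibly overlapping) start positions of any foot motif,
    ascending and deduplicated."""
    hits: set[int] = set()
    for motif in motifs:
        pat = iupac_regex(motif)
        hits.update(m.start() for m in pat.finditer(seq.upper()))
    return sorted(hits)


class _FoldContext:
    """Precomputed pairing-run and GC tables for one sequence.

    ``run[d][i]`` is the number of consecutive Watson-Crick pairs obtained by
    starting at positions ``(i, i + d)`` and stepping inwards
    ``(i+1, i+d-1), ...``; it satisfies the recurrence
    ``run[d][i] = pairs(i, i+d) ? 1 + run[d-2][i+1] : 0``.
    Memory and time are O(n * max_span).
    """

    def __init__(self, seq: str, rules: RepRuleSet):
        self.seq = seq.upper()
        self.rules = rules
        self.n = len(seq)
        codes = encode(self.seq)
        self.codes = codes
        gc = np.zeros(self.n + 1, dtype=np.int64)
        if self.n:
            isgc = (codes == 1) | (codes == 2)
            np.cumsum(isgc, out=gc[1:])
        self._gc = gc
        d_max = rules.max_span  # largest possible (end-1) - start distance
        run: dict[int, np.ndarray] = {}
        n = self.n
        for d in range(1, d_max + 1):
            if d >= n:
                run[d] = np.zeros(0, dtype=np.int16)
                continue
            paired = (codes[: n - d].astype(np.int16) + codes[d:]) == 3
            r = paired.astype(np.int16)
            prev = run.get(d - 2)
            if prev is not None and prev.size > 1:
                m = min(n - d, prev.size - 1)
                r[:m] += paired[:m] * prev[1 : m + 1]
            run[d] = r
        self.run = run

    def run_at(self, i: int, d: int) -> int:
        r = self.run.get(d)
        if r is None or i < 0 or i >= r.size:
            return 0
        return int(r[i])

    def gc_count(self, i: int, j: int) -> int:
        return int(self._gc[j] - self._gc[i])


def _best_fold(ctx: _FoldContext, foot_pos: int) -> RepCandidate | None:
    """Best hairpin candidate at one foot position, or ``None``.

    Tie-breaking: maximise ``paired_len``; then shorter foot offset; then
    shorter loop; then short kind over long; residual ties resolved by
    smaller bulge, then larger basal stem (deterministic).
    """
    rules = ctx.rules
    n = ctx.n
    best_key = None
    best = None  # (offset, kind, s1, loop, bulge, s2, end)
    o_lo, o_hi = rules.foot_offset
    s1_lo, s1_hi = rules.stem1
    l_lo, l_hi = rules.loop
    b_lo, b_hi = rules.bulge
    s2_lo, s2_hi = rules.stem2
    for off in range(o_lo, o_hi + 1):
        h = foot_pos + 4 + off
        if h >= n:
            break
        if rules.allow_short and h + 4 <= n and ctx.gc_count(h, h + 4) >= rules.basal4_min_gc:
            for loop in range(l_lo, l_hi + 1):
                for s1 in range(s1_lo, s1_hi + 1):
                    end = h + 2 * s1 + loop
                    if end > n:
                        break
                    if ctx.run_at(h, 2 * s1 + loop - 1) < s1:
                        continue
                    key = (-s1, off, loop, 0, 0, -s1)
                    if best_key is None or key < best_key:
                        best_key = key
                        best = (off, "short", s1, loop, None, None, end)
        if not rules.allow_long:
            continue
        for bulge in range(b_lo, b_hi + 1):
            for s2 in range(s2_lo, s2_hi + 1):
                for loop in range(l_lo, l_hi + 1):
                    d_in_base = 2 * s2 + loop - 1
                    for s1 in range(s1_lo, s1_hi + 1):
                        end = h + 2 * s1 + bulge + 2 * s2 + loop
                        if end > n:
                            break
                        h2 = h + s1 + bulge
                        if ctx.run_at(h, end - 1 - h) < s1:
                            continue
                        if ctx.run_at(h2, d_in_base) < s2:
                            continue
                        gc = ctx.gc_count(h, h + s1) + ctx.gc_count(h2, h2 + s2)
                        if gc < rules.stem_min_gc * (s1 + s2):
                            continue
                        key = (-(s1 + s2), off, loop, 1, bulge, -s1)
                        if best_key is None or key < best_key:
                            best_key = key
                            best = (off, "long", s1, loop, bulge, s2, end)
    if best is None:
        return None
    off, kind, s1, loop, bulge, s2, end = best
    return RepCandidate(
        contig_id="",
        start=foot_pos,
        end=end,
        strand="+",
        foot_seq=ctx.seq[foot_pos : foot_pos + 4],
        foot_offset=off,
        hairpin_kind=kind,
        stem1_len=s1,
        loop_len=loop,
        bulge_len=bulge,
        stem2_len=s2,
        double_foot=False,
        sequence=ctx.seq[foot_pos:end],
        hairpin_start=foot_pos,
        hairpin_end=end,
    )


def fold_hairpin(seq: str, foot_pos: int, rules: RepRuleSet) -> RepCandidate | None:
    """Best REP candidate anchored at ``foot_pos``, or ``None``.

    ``foot_pos`` must be a match of one of the rule set's foot motifs.
    """
    seq = seq.upper()
    window = seq[foot_pos : foot_pos + 4]
    if not any(matches_motif(window, m) for m in rules.foot_motifs):
        raise ValueError(f"position {foot_pos} does not match any foot motif")
    ctx = _FoldContext(seq, rules)
    return _best_fold(ctx, foot_pos)


def detect_double_foot(
    cand: RepCandidate, seq: str, rules: RepRuleSet | None = None
) -> RepCandidate:
    """Flag and extend a candidate whose 3' arm is followed (within 0-2 nt)
    by the reverse complement of a foot motif (e.g. C[TC]AC for GT[AG]G).

    ``cand`` coordinates must refer to ``seq`` in the candidate's own strand
    orientation (as produced during scanning, before strand mapping).  The
    double-foot motif set is the reverse complement of the rule set's foot
    motifs (C[TC]AC under the defaults); without ``rules`` it falls back to
    the reverse complement of the foot that opened the element.
    """
    seq = seq.upper()
    if rules is not None:
        motifs = {revcomp(m) for m in rules.foot_motifs}
    else:
        motifs = {revcomp(cand.foot_seq)}
    o_lo, o_hi = 0, 2
    for off in range(o_lo, o_hi + 1):
        j = cand.hairpin_end + off
        window = seq[j : j + 4]
        if len(window) < 4:
            break
        if any(matches_motif(window, m) for m in motifs):
            new = replace(cand, double_foot=True, end=j + 4)
            new.sequence = seq[new.start : new.end]
            return new
    return cand


def _resolve_overlaps(cands: list[RepCandidate]) -> list[RepCandidate]:
    """Greedy same-strand overlap resolution: accept by descending
    ``paired_len`` (ties: leftmost start); drop candidates sharing >= 1 nt
    with an accepted candidate on the same strand.  Opposite-strand overlaps
    are kept (inverted REP pairs / REPINs need them)."""
    accepted: list[RepCandidate] = []
    for cand in sorted(cands, key=lambda c: (-c.paired_len, c.start, c.strand)):
        clash = any(
            a.strand == cand.strand
            and a.contig_id == cand.contig_id
            and cand.start < a.end
            and a.start < cand.end
            for a in accepted
        )
        if not clash:
            accepted.append(cand)
    return accepted


def _scan_one_strand(seq: str, rules: RepRuleSet) -> list[RepCandidate]:
    ctx = _FoldContext(seq, rules)
    out = []
    for pos in find_foot(seq, rules.foot_motifs):
        cand = _best_fold(ctx, pos)
        if cand is not None:
            out.append(detect_double_foot(cand, seq, rules))
    return out


def scan(
    contig: str,
    rules: RepRuleSet,
    contig_id: str = "contig",
    resolve_overlaps: bool = True,
) -> list[RepCandidate]:
    """Scan a contig for REP candidates under ``rules``.

    Both strands are scanned when ``rules.scan_both_strands``; minus-strand
    hits are reported in forward coordinates with ``strand == '-'`` and their
    ``sequence`` in minus-strand orientation.  With ``resolve_overlaps``
    (default) same-strand overlapping candidates are reduced greedily; the
    pre-resolution per-foot output is available with
    ``resolve_overlaps=False``.  Output is sorted by ``(start, strand)``.
    """
    contig = contig.upper()
    n = len(contig)
    cands: list[RepCandidate] = []
    for cand in _scan_one_strand(contig, rules):
        cand.contig_id = contig_id
        cands.append(cand)
    if rules.scan_both_strands:
        rc = revcomp(contig)
        for cand in _scan_one_strand(rc, rules):
            fwd = replace(
                cand,
                contig_id=contig_id,
                strand="-",
                start=n - cand.end,
                end=n - cand.start,
                hairpin_start=n - cand.hairpin_end,
                hairpin_end=n - cand.start,
            )
            cands.append(fwd)
    if resolve_overlaps:
        cands = _resolve_overlaps(cands)
    cands.sort(key=lambda c: (c.start, c.strand))
    for i, cand in enumerate(cands):
        if not cand.rep_id:
            cand.rep_id = f"{contig_id}:REP{i:04d}"
    return cands
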