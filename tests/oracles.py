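"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's optimised code paths: REP detection
is exhaustive enumeration with string slicing, motif search is a naive
window scan, the medoid is an explicit argmin.  They share only the
*declared* tie-breaking policy with the implementation.
"""

from __future__ import annotations

from reptronkit.dna import gc_fraction, matches_motif, revcomp
from reptronkit.rep_scanner import RepRuleSet


def naive_find_foot(seq: str, motifs) -> list[int]:
    seq = seq.upper()
    out = []
    for i in range(len(seq) - 3):
        if any(matches_motif(seq[i : i + 4], m) for m in motifs):
            out.append(i)
    return out


def _is_revcomp(a: str, b: str) -> bool:
    """Exact Watson-Crick reverse complementarity (no ambiguity codes)."""
    return set(a + b) <= set("ACGT") and revcomp(a) == b


def enumerate_folds(seq: str, foot: int, rules: RepRuleSet) -> list[tuple]:
    """Every (offset, kind, stem1, loop, bulge, stem2, end) combination at
    one foot that satisfies the rule set, by direct string comparison."""
    seq = seq.upper()
    n = len(seq)
    found = []
    for off in range(rules.foot_offset[0], rules.foot_offset[1] + 1):
        h = foot + 4 + off
        for s1 in range(rules.stem1[0], rules.stem1[1] + 1):
            for loop in range(rules.loop[0], rules.loop[1] + 1):
                if rules.allow_short:
                    end = h + 2 * s1 + loop
                    if end <= n:
                        arm1 = seq[h : h + s1]
                        arm2 = seq[h + s1 + loop : end]
                        if (
                            _is_revcomp(arm1, arm2)
                            and sum(c in "GC" for c in arm1[:4]) >= rules.basal4_min_gc
                        ):
                            found.append((off, "short", s1, loop, None, None, end))
                if not rules.allow_long:
                    continue
                for b in range(rules.bulge[0], rules.bulge[1] + 1):
                    for s2 in range(rules.stem2[0], rules.stem2[1] + 1):
                        end = h + 2 * s1 + b + 2 * s2 + loop
                        if end > n:
                            continue
                        h2 = h + s1 + b
                        arm1 = seq[h : h + s1]
                        arm1b = seq[end - s1 : end]
                        arm2 = seq[h2 : h2 + s2]
                        arm2b = seq[h2 + 2 * s2 + loop - s2 : h2 + 2 * s2 + loop]
                        if not (_is_revcomp(arm1, arm1b) and _is_revcomp(arm2, arm2b)):
                            continue
                        if gc_fraction(arm1 + arm2) < rules.stem_min_gc:
                            continue
                        found.append((off, "long", s1, loop, b, s2, end))
    return found


def _fold_key(combo: tuple) -> tuple:
    off, kind, s1, loop, b, s2, _end = combo
    paired = s1 + (s2 or 0)
    return (-paired, off, loop, 0 if kind == "short" else 1, b or 0, -s1)


def best_fold(seq: str, foot: int, rules: RepRuleSet) -> tuple | None:
    """Per-foot best combination under the declared tie-break policy."""
    combos = enumerate_folds(seq, foot, rules)
    return min(combos, key=_fold_key) if combos else None


def naive_double_foot(seq: str, end: int, rules: RepRuleSet) -> int | None:
    """Extended end if a reverse-complement foot follows within 0-2 nt."""
    motifs = [revcomp(m) for m in rules.foot_motifs]
    for off in range(0, 3):
        window = seq[end + off : end + off + 4]
        if len(window) == 4 and any(matches_motif(window, m) for m in motifs):
            return end + off + 4
    return None


def brute_scan(seq: str, rules: RepRuleSet) -> list[tuple]:
    """Pre-overlap scan by exhaustive enumeration, both strands.

    Returns tuples ``(start, end, strand, kind, offset, s1, loop, b, s2,
    double_foot, hairpin_start, hairpin_end)`` in forward coordinates.
    """
    seq = seq.upper()
    n = len(seq)
    out = []

    def one_strand(s: str, strand: str):
        for foot in naive_find_foot(s, rules.foot_motifs):
            combo = best_fold(s, foot, rules)
            if combo is None:
                continue
            off, kind, s1, loop, b, s2, end = combo
            ext = naive_double_foot(s, end, rules)
            full_end = ext if ext is not None else end
            if strand == "+":
                out.append(
                    (foot, full_end, "+", kind, off, s1, loop, b, s2,
                     ext is not None, foot, end)
                )
            else:
                out.append(
                    (n - full_end, n - foot, "-", kind, off, s1, loop, b, s2,
                     ext is not None, n - end, n - foot)
                )

    one_strand(seq, "+")
    if rules.scan_both_strands:
        one_strand(revcomp(seq), "-")
    out.sort()
    return out


def naive_huh(seq: str, hydrophobic: set[str]) -> list[int]:
    seq = seq.upper()
    return [
        i
        for i in range(len(seq) - 2)
        if seq[i] == "H" and seq[i + 1] in hydrophobic and seq[i + 2] == "H"
    ]


def naive_y(seq: str, gap: int, anchor: str) -> list[int]:
    seq = seq.upper()
    return [
        i
        for i in range(len(seq))
        if seq[i] == "Y" and seq[i + 1 + gap : i + 1 + gap + len(anchor)] == anchor
    ]


def brute_medoid(members, dissim, lengths, tol=0.10):
    """Exhaustive medoid under the length constraint and declared ties."""
    from statistics import median

    med = median(lengths[m] for m in members)
    if len(members) == 1:
        return members[0]

    def d(a, b):
        key = (a, b) if a <= b else (b, a)
        return dissim.get(key, 100.0)

    eligible = [m for m in members if abs(lengths[m] - med) <= tol * med]
    if not eligible:
        closest = min(abs(lengths[m] - med) for m in members)
        eligible = [m for m in members if abs(lengths[m] - med) == closest]
    scored = [
        (
            sum(d(m, o) for o in members if o != m) / (len(members) - 1),
            abs(lengths[m] - med),
            m,
        )
        for m in eligible
    ]
    return min(scored)[2]


def rank_sum_statistic(x, y) -> float:
    """Mann-Whitney U for group x by explicit rank computation."""
    pooled = sorted((v, 0, i) for i, v in enumerate(x)) + sorted(
        (v, 1, i) for i, v in enumerate(y)
    )
    pooled.sort(key=lambda t: t[0])
    # mid-ranks with ties
    ranks = {}
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and pooled[j + 1][0] == pooled[i][0]:
            j += 1
        avg = (i + j + 2) / 2  # 1-based mid-rank
        for k in range(i, j + 1):
            ranks[(pooled[k][1], pooled[k][2])] = avg
        i = j + 1
    r1 = sum(ranks[(0, i)] for i in range(len(x)))
    return r1 - len(x) * (len(x) + 1) / 2
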