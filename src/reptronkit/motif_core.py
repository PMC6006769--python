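"""HuH / W / Y catalytic motif annotation of TnpA_Y1-like proteins.

The catalytic core of these single-tyrosine (Y1) HuH endonucleases carries
two motifs: the metal-coordinating **HuH** motif (two histidines separated
by a bulky hydrophobic residue) and the catalytic tyrosine **Y** whose
local context is class specific - ``Y-x3-Q`` (class 1), ``Y-x3-NP``
(class 2), ``Y-x4-Q`` (class 3) - plus a conserved tryptophan shortly
before the Y.  The spacing between HuH and Y is roughly constant (median
about 58-67 residues in most subclasses, longer in a few), so a protein is
considered to have a *complete core* when an HuH occurs upstream of a
class-matching Y at a spacing inside configured bounds.

Distance convention: Y position minus the position of the *second* H of the
chosen HuH motif (0-based).  When several HuH/Y pairs are valid the pair
with spacing closest to 62 residues (the canonical value) is chosen.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = [
    "ClassSignature",
    "MotifAnnotation",
    "Alignment",
    "default_signatures",
    "find_huh",
    "find_y",
    "annotate_core",
    "classify_by_signature",
    "trim_columns",
    "load_subclass_motifs",
    "match_subclass_motifs",
]

_CANONICAL_DISTANCE = 62  # midpoint of the common 58-67 AA spacing range


@dataclass(frozen=True)
class ClassSignature:
    """Class-level motif signature.

    ``y_gap`` is the number of unconstrained residues between Y and the
    anchor (3 for Y-x3-Q / Y-x3-NP, 4 for Y-x4-Q); ``y_anchor`` the literal
    residue(s) that follow.
    """

    class_id: int
    hydrophobic_set: frozenset[str]
    y_gap: int
    y_anchor: str


def default_signatures() -> list[ClassSignature]:
    """The three class signatures.

    Class 1 (IS200-like): u in {V, I}, Y-x3-Q.
    Class 2 (TnpA_REP-like): u in {L, V, I, F, Y, M}, Y-x3-NP.
    Class 3: u in {V, I} (only V observed; I admitted as its conservative
    exchange, as in class 1 whose Y signature class 3 mirrors), Y-x4-Q.
    """
    return [
        ClassSignature(1, frozenset("VI"), 3, "Q"),
        ClassSignature(2, frozenset("LVIFYM"), 3, "NP"),
        ClassSignature(3, frozenset("VI"), 4, "Q"),
    ]


@dataclass
class MotifAnnotation:
    protein_id: str
    huh_hits: list[int]                       # positions of the second H
    w_hits: list[int]                         # W positions before the chosen Y
    y_hits: list[tuple[int, tuple[int, ...]]]  # (position, matched class ids)
    huh_y_distance: int | None
    core_complete: bool
    chosen_h: int | None = None               # second-H position of chosen pair
    chosen_y: int | None = None
    chosen_classes: tuple[int, ...] = ()


@dataclass
class Alignment:
    sequence_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.sequence_ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("ragged alignment rows")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def find_huh(seq: str, sig: ClassSignature) -> list[int]:
    """All positions of the *first* H of an H-u-H match, overlaps included."""
    seq = seq.upper()
    return [
        i
        for i in range(len(seq) - 2)
        if seq[i] == "H" and seq[i + 2] == "H" and seq[i + 1] in sig.hydrophobic_set
    ]


def find_y(seq: str, sigs: list[ClassSignature]) -> list[tuple[int, int]]:
    """Every (position, class_id) where a Y's downstream context matches a
    class signature; one Y may match several classes."""
    seq = seq.upper()
    out = []
    for i, ch in enumerate(seq):
        if ch != "Y":
            continue
        for sig in sigs:
            anchor = seq[i + 1 + sig.y_gap : i + 1 + sig.y_gap + len(sig.y_anchor)]
            if anchor == sig.y_anchor:
                out.append((i, sig.class_id))
    return out


def annotate_core(
    seq: str,
    sigs: list[ClassSignature] | None = None,
    distance_bounds: tuple[int, int] = (30, 160),
    protein_id: str = "",
) -> MotifAnnotation:
    """Choose the HuH/Y pair (HuH strictly before Y) whose spacing lies in
    ``distance_bounds``, preferring the spacing closest to the canonical 62
    residues; record a conserved W in the ten residues before the chosen Y.

    ``core_complete`` is true iff such a pair exists.
    """
    sigs = sigs or default_signatures()
    seq = seq.upper()
    second_h = sorted(
        {i + 2 for sig in sigs for i in find_huh(seq, sig)}
    )
    y_raw = find_y(seq, sigs)
    y_by_pos: dict[int, list[int]] = {}
    for pos, cls in y_raw:
        y_by_pos.setdefault(pos, []).append(cls)
    y_hits = [(pos, tuple(sorted(set(cs)))) for pos, cs in sorted(y_by_pos.items())]
    lo, hi = distance_bounds
    best = None  # (|d-62|, y_pos, h_pos)
    for h in second_h:
        for y, _classes in y_hits:
            d = y - h
            if h < y and lo <= d <= hi:
                key = (abs(d - _CANONICAL_DISTANCE), y, h)
                if best is None or key < best:
                    best = key
    if best is None:
        return MotifAnnotation(
            protein_id=protein_id,
            huh_hits=second_h,
            w_hits=[],
            y_hits=y_hits,
            huh_y_distance=None,
            core_complete=False,
        )
    _, y, h = best
    w_hits = [i for i in range(max(0, y - 10), y) if seq[i] == "W"]
    return MotifAnnotation(
        protein_id=protein_id,
        huh_hits=second_h,
        w_hits=w_hits,
        y_hits=y_hits,
        huh_y_distance=y - h,
        core_complete=True,
        chosen_h=h,
        chosen_y=y,
        chosen_classes=dict(y_hits)[y],
    )


def classify_by_signature(annotation: MotifAnnotation):
    """Class of the chosen Y's signature: the unique matching class id,
    ``"ambiguous"`` when several classes match, ``None`` when the core is
    incomplete or no signature matched."""
    if not annotation.core_complete:
        return None
    classes = annotation.chosen_classes
    if len(classes) == 1:
        return classes[0]
    if len(classes) > 1:
        return "ambiguous"
    return None


def trim_columns(aln: Alignment, max_gap_fraction: float = 0.5) -> Alignment:
    """Remove alignment columns whose gap fraction exceeds
    ``max_gap_fraction`` (strictly), preserving row order.  Idempotent."""
    if not aln.rows:
        return Alignment(list(aln.sequence_ids), [])
    n = len(aln.rows)
    keep = []
    for j in range(aln.n_columns):
        gaps = sum(1 for row in aln.rows if row[j] in "-.")
        if gaps / n <= max_gap_fraction:
            keep.append(j)
    rows = ["".join(row[j] for j in keep) for row in aln.rows]
    return Alignment(list(aln.sequence_ids), rows)


def load_subclass_motifs() -> dict[str, dict[str, str]]:
    """Subclass-level key-motif consensus patterns (editable data file).

    Patterns use a restricted regex syntax (literals, ``[..]`` choices and
    ``.`` wildcards).  They refine a class-level assignment; several Table-
    style consensus strings are only partially legible in the source data
    and are transcribed conservatively with wildcards.
    """
    text = resources.files("reptronkit.data").joinpath("subclass_motifs.yaml").read_text()
    return yaml.safe_load(text)


def match_subclass_motifs(
    seq: str,
    annotation: MotifAnnotation,
    motifs: dict[str, dict[str, str]] | None = None,
) -> list[str]:
    """Subclasses whose HuH-context pattern matches around the chosen HuH
    (and whose W/Y patterns, where given, match near the chosen W/Y).
    Purely an optional refinement after class-level assignment."""
    if not annotation.core_complete:
        return []
    motifs = motifs or load_subclass_motifs()
    seq = seq.upper()
    cls = classify_by_signature(annotation)
    hits = []
    for subclass, patterns in motifs.items():
        if isinstance(cls, int) and not subclass.startswith(str(cls)):
            continue
        ok = True
        for key, anchor in (("huh", annotation.chosen_h), ("y", annotation.chosen_y)):
            pat = patterns.get(key)
            if not pat:
                continue
            window = seq[max(0, anchor - 6) : anchor + 8]
            if not re.search(pat, window):
                ok = False
                break
        if ok:
            hits.append(subclass)
    return hits
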