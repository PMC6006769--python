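"""Small DNA sequence utilities shared across the package.

Coordinates everywhere in the package are 0-based, half-open, on the
forward strand.
"""

from __future__ import annotations

import re

import numpy as np

COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn", "TGCAYRMKVBHDNtgcayrmkvbhdn")

#: IUPAC degenerate nucleotide codes -> set of concrete bases.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# base -> small integer code; complementarity is code + comp-code == 3.
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases; 0.0 for an empty sequence."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def encode(seq: str) -> np.ndarray:
    """Encode bases as uint8 codes; non-ACGT characters get a sentinel
    that never Watson-Crick pairs and never matches a motif."""
    out = np.full(len(seq), 100, dtype=np.uint8)
    for base, code in _CODE.items():
        out[np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord(base)] = code
    return out


def pairs(a: str, b: str) -> bool:
    """Exact Watson-Crick pairing (A.T, G.C); anything else, including
    wobble and ambiguity codes, does not pair."""
    ca, cb = _CODE.get(a), _CODE.get(b)
    return ca is not None and cb is not None and ca + cb == 3


def iupac_regex(motif: str) -> re.Pattern:
    """Compile a degenerate nucleotide motif into an overlap-reporting
    regex (lookahead), raising ``ValueError`` on non-IUPAC characters."""
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise ValueError(f"non-IUPAC character {ch!r} in motif {motif!r}")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile(r"(?=" + "".join(parts) + r")")


def matches_motif(seq: str, motif: str) -> bool:
    """Does ``seq`` match the degenerate ``motif`` exactly (same length)?"""
    if len(seq) != len(motif):
        return False
    return all(b in IUPAC.get(m.upper(), "") for b, m in zip(seq.upper(), motif))
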