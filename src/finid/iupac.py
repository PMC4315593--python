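"""IUPAC nucleotide ambiguity algebra.

The whole toolkit reasons about bases as *sets* of unambiguous nucleotides:
``K`` means {G, T}, ``N`` means {A, C, G, T} and the alignment gap ``-``
denotes the empty set. Two characters are *compatible* when their sets
intersect — this, not literal equality, is what defines a diagnostic
difference, so that a polymorphic consensus state like ``R`` is never
scored as differing from a concrete ``G``.

A fast-path bitmask encoding (A=1, C=2, G=4, T=8) is exposed for the
vectorised identity search; ``code_to_mask[ord(c)]`` maps a byte to its
mask, with 0 for the gap.
"""

from __future__ import annotations

import numpy as np

from .errors import AlphabetError

# canonical expansions
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "-": frozenset(),
}

ALPHABET: frozenset[str] = frozenset(IUPAC_SETS)

# minimal code covering a given set of unambiguous bases
SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

_MASKS = {code: sum(_BASE_BIT[b] for b in bases) for code, bases in IUPAC_SETS.items()}

#: uint8 lookup table indexed by byte value; 255 marks an illegal character.
code_to_mask = np.full(256, 255, dtype=np.uint8)
for _c, _m in _MASKS.items():
    code_to_mask[ord(_c)] = _m

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N", "-": "-",
}


def iupac_set(code: str) -> frozenset[str]:
    """Expand a single IUPAC character to its set of unambiguous bases.

    The gap ``-`` expands to the empty set.
    """
    try:
        return IUPAC_SETS[code]
    except KeyError:
        raise AlphabetError(f"{code!r} is not an IUPAC nucleotide code") from None


def iupac_code(bases: frozenset[str] | set[str]) -> str:
    """Minimal IUPAC character covering a set of unambiguous bases."""
    try:
        return SET_TO_CODE[frozenset(bases)]
    except KeyError:
        raise AlphabetError(f"{set(bases)!r} is not a valid base set") from None


def compatible(a: str, b: str) -> bool:
    """True iff the expansions of ``a`` and ``b`` intersect.

    Symmetric and, on non-gap codes, reflexive; anything is incompatible
    with a gap (the gap's expansion is empty).
    """
    return bool(iupac_set(a) & iupac_set(b))


def reverse_complement(bases: str) -> str:
    """Reverse complement, honouring ambiguity codes (and preserving gaps)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(bases))
    except KeyError as exc:
        raise AlphabetError(f"{exc.args[0]!r} is not an IUPAC nucleotide code") from None


def encode(bases: str) -> np.ndarray:
    """Encode a sequence as the uint8 bitmask vector used by the fast paths."""
    arr = code_to_mask[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = bases[int(np.argmax(arr == 255))]
        raise AlphabetError(f"{bad!r} is not an IUPAC nucleotide code")
    return arr
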