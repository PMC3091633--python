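"""IUPAC degenerate nucleotide alphabet: base sets, compatibility, complements.

The 15-letter IUPAC nucleotide code maps each symbol to the subset of
{A, C, G, T} it denotes (``R`` = purines A/G, ``Y`` = pyrimidines C/T,
``N`` = any base, ...).  Two symbols are *compatible* -- i.e. a primer
position can anneal to a template position -- when their base sets
intersect.  ``U`` is treated as a synonym of ``T`` and normalised away on
input; gap or stop characters (``-``, ``*``) are rejected rather than
skipped, because silently dropping characters shifts coordinates.
"""

from __future__ import annotations

__all__ = [
    "IUPAC_SETS",
    "IUPAC_SYMBOLS",
    "COMPLEMENT",
    "bases_compatible",
    "complement",
    "reverse_complement",
    "normalize_sequence",
    "is_degenerate",
]

#: Base set denoted by each legal symbol (after U -> T normalisation).
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
}

IUPAC_SYMBOLS: frozenset[str] = frozenset(IUPAC_SETS)

#: Complement table; degenerate codes complement their base sets
#: (R <-> Y, K <-> M, B <-> V, D <-> H; S, W, N are self-complementary).
COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

# Pairwise compatibility, precomputed once: _COMPAT[a][b] is True iff the
# base sets of a and b intersect.
_COMPAT: dict[str, dict[str, bool]] = {
    a: {b: not IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b]) for b in IUPAC_SETS}
    for a in IUPAC_SETS
}


class IllegalSymbolError(ValueError):
    """Raised when a sequence or primer contains a non-IUPAC character."""


def _check_symbol(s: str) -> str:
    sym = s.upper()
    if sym == "U":
        sym = "T"
    if sym not in IUPAC_SETS:
        raise IllegalSymbolError(f"illegal nucleotide symbol: {s!r}")
    return sym


def bases_compatible(a: str, b: str) -> bool:
    """True iff the base sets of symbols *a* and *b* intersect.

    Symmetric and reflexive over legal symbols; ``N`` is compatible with
    everything, ``R``/``C`` are not.
    """
    return _COMPAT[_check_symbol(a)][_check_symbol(b)]


def normalize_sequence(seq: str) -> str:
    """Uppercase *seq*, map U to T, and reject any non-IUPAC character.

    Raises
    ------
    IllegalSymbolError
        on the first illegal character, naming it and its 0-based position.
    """
    up = seq.upper().replace("U", "T")
    for i, ch in enumerate(up):
        if ch not in IUPAC_SETS:
            raise IllegalSymbolError(
                f"illegal nucleotide symbol {seq[i]!r} at position {i}"
            )
    return up


def is_degenerate(symbol: str) -> bool:
    """True iff *symbol* denotes more than one base."""
    return len(IUPAC_SETS[_check_symbol(symbol)]) > 1


def complement(symbol: str) -> str:
    return COMPLEMENT[_check_symbol(symbol)]


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string (an involution).

    Degenerate codes map to the code of the complemented base set, so
    compatibility is preserved under complementation: a primer symbol
    clashes with a template symbol iff their complements clash.
    """
    norm = normalize_sequence(seq)
    return "".join(COMPLEMENT[c] for c in reversed(norm))
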