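"""Mismatch-tolerant primer search: bit-parallel core and naive oracle.

The search is substitutions-only (primer-template annealing has a fixed
length, so indels are not modelled): a window of the text matches a
pattern when at most ``k`` positions are incompatible under IUPAC
base-set intersection AND no incompatible position falls in a protected
set (by default the 3'-terminal ``exact_suffix_len`` pattern positions,
where a real polymerase will not extend over a mispaired base).

Degenerate symbols on either side use the same intersection rule: a
template ``N`` is compatible with every primer symbol, a template ``R``
with any primer symbol whose base set contains a purine.

The production engine is a Bitap/Agrep-style shift-add automaton with one
bit vector per mismatch level, packed in Python integers (patterns up to
63 nt; longer patterns fall back to the naive scan, keeping the contract
total).  ``brute_force_find`` is the literal sliding-window definition and
is kept permanently as the differential-test reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Collection, Optional

from .iupac import IUPAC_SETS, bases_compatible, normalize_sequence

__all__ = [
    "MatchParameters",
    "MatchSpan",
    "count_mismatches",
    "find_matches",
    "brute_force_find",
]

_BITAP_MAX_LEN = 63


@dataclass(frozen=True)
class MatchParameters:
    """Mismatch budget and protected 3' suffix length.

    Defaults (k=2, exact_suffix_len=3) reproduce the stringent standard
    setting: up to two mismatches per primer, none on the last three
    bases of the 3' end.
    """

    max_mismatches: int = 2
    exact_suffix_len: int = 3

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.exact_suffix_len < 0:
            raise ValueError("exact_suffix_len must be >= 0")


@dataclass(frozen=True)
class MatchSpan:
    """One pattern occurrence: 0-based half-open [start, end) with its
    mismatch count; ``strand`` is set by callers that scan both strands."""

    start: int
    end: int
    mismatches: int
    strand: str = "+"


def count_mismatches(pattern: str, window: str) -> int:
    """Number of positions where *pattern* and *window* are incompatible.

    Raises ``ValueError`` when lengths differ (the count is undefined) or
    on illegal symbols.
    """
    p = normalize_sequence(pattern)
    w = normalize_sequence(window)
    if len(p) != len(w):
        raise ValueError(
            f"undefined for unequal lengths ({len(p)} vs {len(w)})"
        )
    return sum(1 for a, b in zip(p, w) if not bases_compatible(a, b))


def _protected_set(
    pattern_len: int,
    params: MatchParameters,
    protected_positions: Optional[Collection[int]],
) -> frozenset[int]:
    """Positions where a mismatch abolishes the match.

    ``protected_positions`` (0-based pattern offsets) overrides the
    default 3'-suffix rule, giving the generic protected-position API.
    """
    if protected_positions is not None:
        pos = frozenset(protected_positions)
        if pos and (min(pos) < 0 or max(pos) >= pattern_len):
            raise ValueError("protected position outside pattern")
        return pos
    s = min(params.exact_suffix_len, pattern_len)
    return frozenset(range(pattern_len - s, pattern_len))


def brute_force_find(
    pattern: str,
    text: str,
    params: MatchParameters = MatchParameters(),
    protected_positions: Optional[Collection[int]] = None,
) -> list[MatchSpan]:
    """Literal sliding-window implementation of the matching contract.

    Checks every offset: reject on any incompatibility at a protected
    position, else accept when the total count is within budget.  Kept as
    the permanent independent oracle for the bit-parallel engine.
    """
    p = normalize_sequence(pattern)
    t = normalize_sequence(text)
    m, n = len(p), len(t)
    if m > n:
        return []
    protected = _protected_set(m, params, protected_positions)
    k = params.max_mismatches
    compat = _COMPAT_CACHE
    spans: list[MatchSpan] = []
    for start in range(n - m + 1):
        mism = 0
        ok = True
        for i in range(m):
            if not compat[p[i]][t[start + i]]:
                if i in protected:
                    ok = False
                    break
                mism += 1
                if mism > k:
                    ok = False
                    break
        if ok:
            spans.append(MatchSpan(start=start, end=start + m, mismatches=mism))
    return spans


# symbol-pair compatibility lookup shared by both engines
_COMPAT_CACHE: dict[str, dict[str, bool]] = {
    a: {b: not IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b]) for b in IUPAC_SETS}
    for a in IUPAC_SETS
}


def _bitap_masks(pattern: str) -> dict[str, int]:
    """Per-text-symbol bit masks: bit i set iff pattern[i] is compatible."""
    masks = {}
    for sym in IUPAC_SETS:
        mask = 0
        for i, p in enumerate(pattern):
            if _COMPAT_CACHE[p][sym]:
                mask |= 1 << i
        masks[sym] = mask
    return masks


def find_matches(
    pattern: str,
    text: str,
    params: MatchParameters = MatchParameters(),
    protected_positions: Optional[Collection[int]] = None,
) -> list[MatchSpan]:
    """All occurrences of *pattern* in *text* within the mismatch budget.

    Returns every offset where the total mismatch count is <= k and no
    mismatch falls on a protected position, sorted by start, with the
    exact mismatch count recorded per span.  Identical by contract (and
    by differential test) to :func:`brute_force_find`.

    Patterns longer than 63 nt use the naive scan; all practically used
    primers (<= ~30 nt) go through the bit-parallel engine.
    """
    p = normalize_sequence(pattern)
    t = normalize_sequence(text)
    m, n = len(p), len(t)
    if m > n:
        return []
    if m > _BITAP_MAX_LEN:
        return brute_force_find(p, t, params, protected_positions)

    protected = _protected_set(m, params, protected_positions)
    k = params.max_mismatches
    masks = _bitap_masks(p)
    # substitutions are only allowed at unprotected positions
    sub_allowed = 0
    for i in range(m):
        if i not in protected:
            sub_allowed |= 1 << i
    accept_bit = 1 << (m - 1)

    # R[d]: bit i set iff pattern[0..i] matches the text window ending at
    # the current position with <= d mismatches (none protected).
    R = [0] * (k + 1)
    spans: list[MatchSpan] = []
    for j, c in enumerate(t):
        mask = masks[c]
        prev_shifted = (R[0] << 1) | 1
        R[0] = prev_shifted & mask
        for d in range(1, k + 1):
            cur_shifted = (R[d] << 1) | 1
            R[d] = (cur_shifted & mask) | (prev_shifted & sub_allowed)
            prev_shifted = cur_shifted
        if R[k] & accept_bit:
            # smallest level accepting = exact mismatch count
            for d in range(k + 1):
                if R[d] & accept_bit:
                    spans.append(
                        MatchSpan(start=j - m + 1, end=j + 1, mismatches=d)
                    )
                    break
    return spans
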