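"""In silico PCR: pair primer sites in amplifiable orientation and distance.

A template is "amplified" when the forward primer matches it and the
reverse primer matches the opposite strand downstream, within a mismatch
budget per primer and an insert-length window.  Both template strands are
scanned (the '+' orientation takes the stored sequence as-is; the '-'
orientation repeats the search on its reverse complement), and every
valid pairing is reported -- no best-hit filtering.

The reported ``barcode_seq`` is the template substring strictly between
the two primer sites, 5'->3' relative to the forward primer.
``insert_len`` excludes the primer sites (the convention under which the
classic COI Folmer fragment is 658 bp); ``product_len`` adds both primer
lengths back so either convention can be checked.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO

import pandas as pd

from .iupac import reverse_complement
from .match import MatchParameters, MatchSpan, brute_force_find, find_matches
from .records import Primer, SequenceRecord
from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)

__all__ = [
    "AmplificationConstraints",
    "AmpliconHit",
    "amplify_record",
    "amplify_database",
    "mismatch_profile",
    "write_hits_tsv",
    "read_hits_tsv",
    "HIT_COLUMNS",
]


@dataclass(frozen=True)
class AmplificationConstraints:
    """Insert-length window and per-primer match parameters.

    ``min_insert_len``/``max_insert_len`` bound the length of the region
    between (excluding) the primer sites; the default upper bound of
    2000 nt comfortably covers standard barcode fragments (<= ~700 bp)
    while keeping the pairing step bounded.
    """

    min_insert_len: int = 0
    max_insert_len: int = 2000
    match_params: MatchParameters = field(default_factory=MatchParameters)

    def __post_init__(self) -> None:
        if self.min_insert_len < 0:
            raise ValueError("min_insert_len must be >= 0")
        if self.min_insert_len > self.max_insert_len:
            raise ValueError("min_insert_len must be <= max_insert_len")


@dataclass(frozen=True)
class AmpliconHit:
    """One successful in silico amplification.

    Spans are 0-based half-open in the forward-primer orientation frame:
    for '-' hits, coordinates refer to the reverse complement of the
    stored sequence.  ``insert_len == reverse_span.start - forward_span.end``
    always holds.
    """

    record_id: str
    taxid: Optional[int]
    strand: str  # '+' or '-'
    forward_span: MatchSpan
    reverse_span: MatchSpan
    barcode_seq: str
    species: str = ""
    genus: str = ""
    family: str = ""

    @property
    def insert_len(self) -> int:
        return len(self.barcode_seq)

    @property
    def product_len(self) -> int:
        return (
            self.insert_len
            + (self.forward_span.end - self.forward_span.start)
            + (self.reverse_span.end - self.reverse_span.start)
        )


def _suffix_protected_rc(primer: Primer) -> frozenset[int]:
    # reverse-complementing the pattern moves the 3' end to the front
    return frozenset(range(min(primer.exact_suffix_len, len(primer))))


def _scan_orientation(
    seq: str,
    record: SequenceRecord,
    strand: str,
    fwd: Primer,
    rev: Primer,
    constraints: AmplificationConstraints,
    engine=find_matches,
) -> list[AmpliconHit]:
    params = constraints.match_params
    fwd_params = MatchParameters(params.max_mismatches, fwd.exact_suffix_len)
    fwd_spans = engine(fwd.pattern, seq, fwd_params)
    if not fwd_spans:
        return []
    rc_rev = reverse_complement(rev.pattern)
    rev_spans = engine(
        rc_rev,
        seq,
        MatchParameters(params.max_mismatches, 0),
        protected_positions=_suffix_protected_rc(rev),
    )
    hits: list[AmpliconHit] = []
    for f in fwd_spans:
        for r in rev_spans:
            if r.start < f.end:
                continue  # overlapping footprints cannot both anneal
            insert = r.start - f.end
            if constraints.min_insert_len <= insert <= constraints.max_insert_len:
                hits.append(
                    AmpliconHit(
                        record_id=record.record_id,
                        taxid=record.taxid,
                        strand=strand,
                        forward_span=MatchSpan(f.start, f.end, f.mismatches, strand),
                        reverse_span=MatchSpan(r.start, r.end, r.mismatches, strand),
                        barcode_seq=seq[f.end:r.start],
                    )
                )
    return hits


def amplify_record(
    record: SequenceRecord,
    fwd: Primer,
    rev: Primer,
    constraints: AmplificationConstraints = AmplificationConstraints(),
    _engine=find_matches,
) -> list[AmpliconHit]:
    """All amplifiable forward/reverse primer-site pairings on *record*.

    Every pair (forward match, reverse-complement-of-reverse match
    starting at or after the forward match's end) whose insert length
    satisfies the constraints yields one hit; the '-' orientation repeats
    the procedure on the reverse complement of the sequence.  Hits are
    sorted by (strand, forward start); a record with no sites yields an
    empty list.
    """
    hits = _scan_orientation(record.sequence, record, "+", fwd, rev, constraints, _engine)
    hits += _scan_orientation(
        reverse_complement(record.sequence), record, "-", fwd, rev, constraints, _engine
    )
    hits.sort(key=lambda h: (h.strand, h.forward_span.start, h.reverse_span.start))
    return hits


def brute_force_amplify(
    record: SequenceRecord,
    fwd: Primer,
    rev: Primer,
    constraints: AmplificationConstraints = AmplificationConstraints(),
) -> list[AmpliconHit]:
    """Oracle: the same pairing built on :func:`brute_force_find` results."""
    return amplify_record(record, fwd, rev, constraints, _engine=brute_force_find)


def amplify_database(
    records: Sequence[SequenceRecord],
    fwd: Primer,
    rev: Primer,
    constraints: AmplificationConstraints = AmplificationConstraints(),
    taxonomy: Optional[Taxonomy] = None,
) -> list[AmpliconHit]:
    """Amplify every record and annotate hits with taxonomy rank names.

    Hit order is deterministic: input record order, then within-record
    order.  A taxid that does not resolve in the taxonomy is logged as a
    warning; the hit is kept with empty rank names.
    """
    all_hits: list[AmpliconHit] = []
    for record in records:
        names = {"species": "", "genus": "", "family": ""}
        if taxonomy is not None and record.taxid is not None:
            if record.taxid in taxonomy:
                for rank in names:
                    anc = taxonomy.ancestor_at_rank(record.taxid, rank)
                    if anc is not None:
                        names[rank] = taxonomy.name(anc)
            else:
                logger.warning(
                    "record %s: taxid %d not in taxonomy; rank names left empty",
                    record.record_id,
                    record.taxid,
                )
        elif record.taxid is None:
            logger.warning("record %s has no taxid", record.record_id)
        for hit in amplify_record(record, fwd, rev, constraints):
            all_hits.append(
                AmpliconHit(
                    record_id=hit.record_id,
                    taxid=hit.taxid,
                    strand=hit.strand,
                    forward_span=hit.forward_span,
                    reverse_span=hit.reverse_span,
                    barcode_seq=hit.barcode_seq,
                    **names,
                )
            )
    return all_hits


def mismatch_profile(
    records: Sequence[SequenceRecord],
    primer: Primer,
    kmax: int = 8,
    respect_suffix: bool = False,
) -> pd.DataFrame:
    """Distribution of the best per-record mismatch count for one primer.

    For each record, takes the minimum mismatch count of the primer over
    both strands within budget *kmax*; by default the protected-suffix
    rule is ignored (``respect_suffix=True`` enables it).  Returns a
    DataFrame with columns ``m``, ``count`` and ``cumulative_fraction``
    for m = 0..kmax, where the cumulative fraction is taken over the
    records that matched at all (the "amplified" ones).
    """
    if kmax < 0:
        raise ValueError("kmax must be >= 0")
    suffix = primer.exact_suffix_len if respect_suffix else 0
    params = MatchParameters(kmax, suffix)
    counts = [0] * (kmax + 1)
    for record in records:
        best: Optional[int] = None
        for seq in (record.sequence, reverse_complement(record.sequence)):
            for span in find_matches(primer.pattern, seq, params):
                if best is None or span.mismatches < best:
                    best = span.mismatches
        if best is not None:
            counts[best] += 1
    total = sum(counts)
    cum: list[float] = []
    running = 0
    for c in counts:
        running += c
        cum.append(running / total if total else float("nan"))
    return pd.DataFrame(
        {"m": range(kmax + 1), "count": counts, "cumulative_fraction": cum}
    )


HIT_COLUMNS = [
    "record_id", "taxid", "species", "genus", "family", "strand",
    "fwd_start", "fwd_end", "fwd_mismatches",
    "rev_start", "rev_end", "rev_mismatches",
    "insert_len", "product_len", "barcode_seq",
]


def hits_to_frame(hits: Iterable[AmpliconHit]) -> pd.DataFrame:
    """Tabulate hits; coordinates 1-based inclusive in the output."""
    rows = []
    for h in hits:
        rows.append(
            {
                "record_id": h.record_id,
                "taxid": "" if h.taxid is None else h.taxid,
                "species": h.species,
                "genus": h.genus,
                "family": h.family,
                "strand": h.strand,
                "fwd_start": h.forward_span.start + 1,
                "fwd_end": h.forward_span.end,
                "fwd_mismatches": h.forward_span.mismatches,
                "rev_start": h.reverse_span.start + 1,
                "rev_end": h.reverse_span.end,
                "rev_mismatches": h.reverse_span.mismatches,
                "insert_len": h.insert_len,
                "product_len": h.product_len,
                "barcode_seq": h.barcode_seq,
            }
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hits_tsv(
    hits: Iterable[AmpliconHit],
    path_or_handle: str | Path | TextIO,
    cmdline: Optional[str] = None,
) -> None:
    """Write the hit table as UTF-8 TSV (header row; optional provenance
    comment line ``#cmdline: ...`` first)."""
    frame = hits_to_frame(hits)
    own = isinstance(path_or_handle, (str, Path))
    handle = open(path_or_handle, "w", encoding="utf-8") if own else path_or_handle
    try:
        if cmdline is not None:
            handle.write(f"#cmdline: {cmdline}\n")
        frame.to_csv(handle, sep="\t", index=False)
    finally:
        if own:
            handle.close()


def read_hits_tsv(path: str | Path) -> list[AmpliconHit]:
    """Read a hit TSV back into :class:`AmpliconHit` objects (comment
    lines starting with '#' are skipped; coordinates converted back to
    the internal 0-based half-open convention)."""
    frame = pd.read_csv(
        path, sep="\t", comment="#", dtype={"barcode_seq": str}, keep_default_na=False
    )
    hits = []
    for row in frame.itertuples(index=False):
        taxid = None if row.taxid in ("", None) else int(row.taxid)
        strand = str(row.strand)
        hits.append(
            AmpliconHit(
                record_id=str(row.record_id),
                taxid=taxid,
                strand=strand,
                forward_span=MatchSpan(
                    int(row.fwd_start) - 1, int(row.fwd_end), int(row.fwd_mismatches), strand
                ),
                reverse_span=MatchSpan(
                    int(row.rev_start) - 1, int(row.rev_end), int(row.rev_mismatches), strand
                ),
                barcode_seq=str(row.barcode_seq),
                species=str(row.species),
                genus=str(row.genus),
                family=str(row.family),
            )
        )
    return hits
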