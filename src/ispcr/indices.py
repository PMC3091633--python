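"""Barcode-quality indices: taxonomic coverage B_c and resolution B_s.

Coverage (B_c) asks how *universal* a primer pair is: the fraction of
taxa at a chosen rank, among those present in the reference database,
that yield at least one in silico amplicon.

Resolution (B_s) asks how *diagnostic* the amplified fragment is.  It is
built on four sets -- taxa T, individuals I (amplified sequence records),
barcodes B (distinct insert strings) and the region r (the primer pair)
-- connected by the mappings E (taxon -> its amplified individuals),
Img (individual -> its barcodes) and E' (all barcodes seen for r).  For a
taxon t, the barcode set

    Omega(t, r) = Img(E(t)) ∩ E'(r)

collects every barcode any of its individuals produced; t is
*unambiguously identified* iff the owners of those barcodes are exactly
its own individuals:

    Img^-1(Omega(t, r)) = E(t)

i.e. no individual of any other taxon shares a barcode with t.  B_s is
the fraction of taxa satisfying this criterion.  Because a small
amplified sample says little about resolution, results are flagged as
under-powered unless the primer pair amplified more than 10 species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO

from .amplify import AmpliconHit
from .records import SequenceRecord
from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)

__all__ = [
    "BarcodeTable",
    "CoverageResult",
    "ResolutionResult",
    "coverage_index",
    "build_barcode_table",
    "omega",
    "is_unambiguous",
    "resolution_index",
    "write_report",
]

MIN_SPECIES_FOR_RESOLUTION = 10


@dataclass
class BarcodeTable:
    """The T/I/B sets and E/Img/E' mappings for one barcode region.

    Individuals are record_ids with >= 1 hit; a record's barcode set is
    its distinct uppercase barcode strings (one individual may yield
    several amplicons); taxa are the distinct rank-level ancestors of the
    individuals.  Records whose lineage lacks the evaluation rank are
    excluded (counted in ``excluded_records``): they can neither be
    identified nor confused at that rank.
    """

    region_label: str
    rank: str
    taxa: set[int] = field(default_factory=set)
    individuals: set[str] = field(default_factory=set)
    E: dict[int, set[str]] = field(default_factory=dict)
    Img: dict[str, set[str]] = field(default_factory=dict)
    eprime: set[str] = field(default_factory=set)
    n_species_amplified: int = 0
    excluded_records: int = 0

    def taxon_of(self, record_id: str) -> int:
        for t, members in self.E.items():
            if record_id in members:
                return t
        raise KeyError(f"record {record_id!r} not in table")


@dataclass(frozen=True)
class CoverageResult:
    """B_c = amplified_taxa / total_taxa at the evaluation rank."""

    bc: Optional[float]
    amplified_taxa: int
    total_taxa: int
    rank: str
    excluded_taxa: int = 0  # reference records with no ancestor at the rank


@dataclass(frozen=True)
class ResolutionResult:
    """B_s = identified_taxa / total_taxa; ``sufficient_data`` is False
    when the region amplified 10 or fewer species (B_s still reported)."""

    bs: Optional[float]
    identified_taxa: int
    total_taxa: int
    rank: str
    sufficient_data: bool


def coverage_index(
    reference_records: Sequence[SequenceRecord],
    hits: Iterable[AmpliconHit],
    taxonomy: Taxonomy,
    rank: str = "species",
) -> CoverageResult:
    """Fraction of rank-level taxa in the reference set with >= 1 hit.

    The denominator counts distinct rank ancestors over all reference
    records; the numerator counts those possessing at least one hit.
    Records whose lineage lacks the rank are excluded from both counts.
    An empty denominator yields ``bc=None`` rather than a division error.
    """
    total: set[int] = set()
    excluded = 0
    for rec in reference_records:
        if rec.taxid is None or rec.taxid not in taxonomy:
            excluded += 1
            continue
        anc = taxonomy.ancestor_at_rank(rec.taxid, rank)
        if anc is None:
            excluded += 1
        else:
            total.add(anc)
    amplified: set[int] = set()
    for hit in hits:
        if hit.taxid is None or hit.taxid not in taxonomy:
            continue
        anc = taxonomy.ancestor_at_rank(hit.taxid, rank)
        if anc is not None and anc in total:
            amplified.add(anc)
    if excluded:
        logger.info("coverage at rank %s: %d record(s) without the rank", rank, excluded)
    bc = len(amplified) / len(total) if total else None
    return CoverageResult(
        bc=bc,
        amplified_taxa=len(amplified),
        total_taxa=len(total),
        rank=rank,
        excluded_taxa=excluded,
    )


def build_barcode_table(
    hits: Iterable[AmpliconHit],
    taxonomy: Taxonomy,
    rank: str = "species",
    region_label: str = "",
) -> BarcodeTable:
    """Assemble the E/Img/E' mappings from amplification hits."""
    table = BarcodeTable(region_label=region_label, rank=rank)
    species_seen: set[int] = set()
    skipped: set[str] = set()
    for hit in hits:
        if hit.taxid is None or hit.taxid not in taxonomy:
            skipped.add(hit.record_id)
            continue
        anc = taxonomy.ancestor_at_rank(hit.taxid, rank)
        if anc is None:
            skipped.add(hit.record_id)
            continue
        barcode = hit.barcode_seq.upper()
        table.taxa.add(anc)
        table.individuals.add(hit.record_id)
        table.E.setdefault(anc, set()).add(hit.record_id)
        table.Img.setdefault(hit.record_id, set()).add(barcode)
        table.eprime.add(barcode)
        sp = taxonomy.ancestor_at_rank(hit.taxid, "species")
        if sp is not None:
            species_seen.add(sp)
    table.n_species_amplified = len(species_seen)
    table.excluded_records = len(skipped - table.individuals)
    if table.excluded_records:
        logger.info(
            "barcode table (%s, rank %s): %d record(s) dropped (no ancestor at rank)",
            region_label, rank, table.excluded_records,
        )
    return table


def omega(table: BarcodeTable, taxon: int) -> set[str]:
    """Omega(t, r) = Img(E(t)) ∩ E'(r): all barcodes of taxon *t*."""
    if taxon not in table.taxa:
        raise KeyError(f"taxon {taxon} not in table")
    out: set[str] = set()
    for individual in table.E[taxon]:
        out |= table.Img[individual]
    return out & table.eprime


def is_unambiguous(table: BarcodeTable, taxon: int) -> bool:
    """Img^-1(Omega(t, r)) == E(t): no other taxon's individual owns any
    of *taxon*'s barcodes."""
    target = omega(table, taxon)
    owners = {
        individual
        for individual, barcodes in table.Img.items()
        if barcodes & target
    }
    return owners == table.E[taxon]


def resolution_index(table: BarcodeTable) -> ResolutionResult:
    """B_s over the table's taxa; flagged under-powered at <= 10 species."""
    if not table.taxa:
        return ResolutionResult(
            bs=None, identified_taxa=0, total_taxa=0,
            rank=table.rank, sufficient_data=False,
        )
    identified = sum(1 for t in table.taxa if is_unambiguous(table, t))
    return ResolutionResult(
        bs=identified / len(table.taxa),
        identified_taxa=identified,
        total_taxa=len(table.taxa),
        rank=table.rank,
        sufficient_data=table.n_species_amplified > MIN_SPECIES_FOR_RESOLUTION,
    )


REPORT_COLUMNS = [
    "region_label", "rank", "total_taxa", "amplified_taxa", "bc",
    "identified_taxa", "bs", "sufficient_data",
]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return str(x).lower()
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_report(
    path_or_handle: str | Path | TextIO,
    region_label: str,
    rank: str,
    coverage: Optional[CoverageResult] = None,
    resolution: Optional[ResolutionResult] = None,
    cmdline: Optional[str] = None,
) -> None:
    """One-row TSV report combining coverage and/or resolution results;
    fields not computed for this run are left empty."""
    total = ""
    if coverage is not None:
        total = coverage.total_taxa
    elif resolution is not None:
        total = resolution.total_taxa
    row = [
        region_label,
        rank,
        total,
        coverage.amplified_taxa if coverage else "",
        coverage.bc if coverage else "",
        resolution.identified_taxa if resolution else "",
        resolution.bs if resolution else "",
        resolution.sufficient_data if resolution else "",
    ]
    own = isinstance(path_or_handle, (str, Path))
    handle = open(path_or_handle, "w", encoding="utf-8") if own else path_or_handle
    try:
        if cmdline is not None:
            handle.write(f"#cmdline: {cmdline}\n")
        handle.write("\t".join(REPORT_COLUMNS) + "\n")
        handle.write("\t".join(_fmt(x) for x in row) + "\n")
    finally:
        if own:
            handle.close()
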