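"""Reference-database construction: per-species subsampling, clade cuts.

A reference database for primer evaluation should not over-represent the
handful of heavily sequenced species, so one sequence is drawn uniformly
at random per species-level taxon.  Clade restriction keeps only records
whose lineage passes through a given root, enabling per-clade coverage
and resolution analyses.
"""

from __future__ import annotations

import logging
import random
from typing import Sequence

from .records import SequenceRecord
from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)

__all__ = ["one_per_species", "clade_filter"]


def one_per_species(
    records: Sequence[SequenceRecord],
    taxonomy: Taxonomy,
    seed: int,
) -> list[SequenceRecord]:
    """Select exactly one record per species-level taxon, uniformly at
    random with an explicit seed (no global randomness).

    Output order follows the first appearance of each species in the
    input; records without a species-level ancestor are excluded and
    counted in a log message.
    """
    rng = random.Random(seed)
    by_species: dict[int, list[SequenceRecord]] = {}
    order: list[int] = []
    dropped = 0
    for rec in records:
        if rec.taxid is None or rec.taxid not in taxonomy:
            dropped += 1
            continue
        sp = taxonomy.ancestor_at_rank(rec.taxid, "species")
        if sp is None:
            dropped += 1
            continue
        if sp not in by_species:
            by_species[sp] = []
            order.append(sp)
        by_species[sp].append(rec)
    if dropped:
        logger.info("one_per_species: %d record(s) without species-level taxid", dropped)
    return [rng.choice(by_species[sp]) for sp in order]


def clade_filter(
    records: Sequence[SequenceRecord],
    taxonomy: Taxonomy,
    root_taxid: int,
) -> list[SequenceRecord]:
    """Records whose lineage contains *root_taxid*, input order preserved."""
    if root_taxid not in taxonomy:
        raise KeyError(f"unknown clade root taxid {root_taxid}")
    out = []
    for rec in records:
        if rec.taxid is None or rec.taxid not in taxonomy:
            continue
        if taxonomy.is_descendant(rec.taxid, root_taxid):
            out.append(rec)
    return out
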