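"""Sequence records, primers, and taxon-annotated FASTA I/O.

Template sequences are the "individuals" of the resolution-index
formalism: each carries an optional integer taxid, stored in the FASTA
description line as a whitespace-separated ``key=value;`` token
(``>seq1 taxid=9606; Homo sapiens``).  Reading and writing go through
Biopython; sequences are validated against the IUPAC alphabet and stored
uppercase with U normalised to T.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .iupac import normalize_sequence

__all__ = ["SequenceRecord", "Primer", "read_fasta", "write_fasta"]

_TOKEN_RE = re.compile(r"(\w+)=([^;\s]+);")


@dataclass(frozen=True)
class SequenceRecord:
    """One template sequence with its taxon annotation.

    Parameters
    ----------
    record_id : str
        Unique identifier within a dataset.
    sequence : str
        IUPAC nucleotide string, length >= 1; normalised on construction.
    taxid : int, optional
        Taxon identifier; ``None`` when the record is unannotated.
    description : str
        Free text carried after the ID (taxid token excluded).
    """

    record_id: str
    sequence: str
    taxid: Optional[int] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.record_id!r}: empty sequence")
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Primer:
    """A PCR primer: 5'->3' IUPAC pattern with a protected 3' suffix.

    ``exact_suffix_len`` counts 3'-terminal positions where mismatches are
    forbidden (default 3), mimicking the polymerase's requirement for a
    correctly paired 3' end.
    """

    name: str
    pattern: str
    exact_suffix_len: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", normalize_sequence(self.pattern))
        if len(self.pattern) < 8:
            raise ValueError(
                f"primer {self.name!r}: pattern must be >= 8 nt, "
                f"got {len(self.pattern)}"
            )
        if not 0 <= self.exact_suffix_len <= len(self.pattern):
            raise ValueError(
                f"primer {self.name!r}: exact_suffix_len {self.exact_suffix_len} "
                f"outside [0, {len(self.pattern)}]"
            )

    def __len__(self) -> int:
        return len(self.pattern)


def _parse_description(desc: str) -> tuple[Optional[int], str, dict[str, str]]:
    """Extract ``key=value;`` tokens; return (taxid, residual text, tokens)."""
    tokens = dict(_TOKEN_RE.findall(desc))
    residual = _TOKEN_RE.sub("", desc).strip()
    taxid: Optional[int] = None
    if "taxid" in tokens:
        try:
            taxid = int(tokens["taxid"])
        except ValueError as exc:
            raise ValueError(f"non-integer taxid token {tokens['taxid']!r}") from exc
    return taxid, residual, tokens


def read_fasta(path: str | Path, taxid_key: str = "taxid") -> list[SequenceRecord]:
    """Read a (possibly empty) multi-record FASTA file.

    The taxid is parsed from a ``<taxid_key>=<int>;`` token in the
    description line when present.  Duplicate record IDs and non-IUPAC
    characters raise ``ValueError``.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    token_re = re.compile(rf"{re.escape(taxid_key)}=([^;\s]+);")
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        if seq_rec.id in seen:
            raise ValueError(f"{path}: duplicate record_id {seq_rec.id!r}")
        seen.add(seq_rec.id)
        # description includes the id itself; strip it
        desc = seq_rec.description
        if desc.startswith(seq_rec.id):
            desc = desc[len(seq_rec.id):].strip()
        m = token_re.search(desc)
        taxid = None
        if m:
            try:
                taxid = int(m.group(1))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: record {seq_rec.id!r}: non-integer "
                    f"{taxid_key} token {m.group(1)!r}"
                ) from exc
            desc = (desc[: m.start()] + desc[m.end():]).strip()
        try:
            records.append(
                SequenceRecord(
                    record_id=seq_rec.id,
                    sequence=str(seq_rec.seq),
                    taxid=taxid,
                    description=desc,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: record {seq_rec.id!r}: {exc}") from exc
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    path: str | Path,
    taxid_key: str = "taxid",
) -> None:
    """Write records as 60-column-wrapped FASTA, taxid as a header token.

    Inverse of :func:`read_fasta`: a write/read round trip preserves
    record_id, sequence, taxid and description for every record.
    """
    seq_records = []
    for rec in records:
        parts = []
        if rec.taxid is not None:
            parts.append(f"{taxid_key}={rec.taxid};")
        if rec.description:
            parts.append(rec.description)
        seq_records.append(
            SeqRecord(Seq(rec.sequence), id=rec.record_id, description=" ".join(parts))
        )
    with open(path, "w") as handle:
        writer = FastaWriter(handle, wrap=60)
        writer.write_file(seq_records)
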