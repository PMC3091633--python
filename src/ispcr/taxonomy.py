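"""Ranked taxonomy: NCBI-taxdump and simple-TSV loading, rank queries.

A taxonomy is a rooted tree of nodes (taxid, parent, rank, name) with the
root marked by ``parent == taxid``, NCBI style.  Ranks are free strings
compared case-insensitively; no ordering between ranks is assumed, so
"species", "genus", "family" work alongside any other NCBI rank label.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

__all__ = ["TaxonomyNode", "Taxonomy", "load_taxonomy", "write_taxonomy_tsv"]


@dataclass(frozen=True)
class TaxonomyNode:
    taxid: int
    parent_taxid: int
    rank: str
    scientific_name: str


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy file (cycle, orphan, no root)."""


class Taxonomy:
    """Ranked tree with ancestor-at-rank queries.

    Validates on construction: exactly one root (its own parent), every
    non-root parent resolves, parent links are acyclic.
    """

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self._nodes: dict[int, TaxonomyNode] = {}
        for node in nodes:
            if node.taxid in self._nodes:
                raise TaxonomyError(f"duplicate taxid {node.taxid}")
            self._nodes[node.taxid] = node
        roots = [n.taxid for n in self._nodes.values() if n.parent_taxid == n.taxid]
        if len(roots) != 1:
            raise TaxonomyError(
                f"expected exactly one root (parent == taxid), found {len(roots)}"
            )
        self.root: int = roots[0]
        for node in self._nodes.values():
            if node.parent_taxid not in self._nodes:
                raise TaxonomyError(
                    f"taxid {node.taxid}: parent {node.parent_taxid} does not exist"
                )
        # acyclicity: walk every lineage, memoising visited nodes
        ok: set[int] = {self.root}
        for taxid in self._nodes:
            trail = []
            cur = taxid
            seen_here = set()
            while cur not in ok:
                if cur in seen_here:
                    raise TaxonomyError(f"cycle detected involving taxid {cur}")
                seen_here.add(cur)
                trail.append(cur)
                cur = self._nodes[cur].parent_taxid
            ok.update(trail)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, taxid: int) -> TaxonomyNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise KeyError(f"unknown taxid {taxid}") from None

    def name(self, taxid: int) -> str:
        return self.node(taxid).scientific_name

    def lineage(self, taxid: int) -> list[int]:
        """Taxids from *taxid* up to and including the root."""
        out = [taxid]
        cur = self.node(taxid)
        while cur.parent_taxid != cur.taxid:
            cur = self._nodes[cur.parent_taxid]
            out.append(cur.taxid)
        return out

    def ancestor_at_rank(self, taxid: int, rank: str) -> Optional[int]:
        """The unique ancestor (including self) whose rank matches, or
        ``None`` when the lineage has no node of that rank -- e.g. a
        record annotated at genus level queried at species rank."""
        want = rank.lower()
        for anc in self.lineage(taxid):
            if self._nodes[anc].rank.lower() == want:
                return anc
        return None

    def is_descendant(self, taxid: int, root_taxid: int) -> bool:
        """True iff *root_taxid* appears in the lineage of *taxid*."""
        return root_taxid in self.lineage(taxid)

    def __iter__(self):
        return iter(self._nodes.values())


def _load_tsv(path: Path) -> Taxonomy:
    nodes = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise TaxonomyError(
                    f"{path}:{lineno}: expected 4 tab-separated columns "
                    f"(taxid, parent, rank, name), got {len(fields)}"
                )
            try:
                taxid, parent = int(fields[0]), int(fields[1])
            except ValueError:
                raise TaxonomyError(
                    f"{path}:{lineno}: non-integer taxid/parent"
                ) from None
            nodes.append(TaxonomyNode(taxid, parent, fields[2], fields[3]))
    return Taxonomy(nodes)


def _load_taxdump(path: Path) -> Taxonomy:
    """NCBI taxdump dialect: nodes.dmp + names.dmp with pipe-tab delimiters
    (``<tab>|<tab>`` between fields); only 'scientific name' entries are
    used from names.dmp.  *path* is the directory holding both files."""
    nodes_path = path / "nodes.dmp"
    names_path = path / "names.dmp"
    for p in (nodes_path, names_path):
        if not p.exists():
            raise FileNotFoundError(f"taxdump dialect requires {p}")
    names: dict[int, str] = {}
    with open(names_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("|\n").split("\t|")]
            if len(fields) < 4:
                raise TaxonomyError(f"{names_path}:{lineno}: malformed names.dmp line")
            if fields[3].strip("\t") == "scientific name":
                names[int(fields[0])] = fields[1].strip("\t")
    nodes = []
    with open(nodes_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("|\n").split("\t|")]
            if len(fields) < 3:
                raise TaxonomyError(f"{nodes_path}:{lineno}: malformed nodes.dmp line")
            taxid = int(fields[0])
            nodes.append(
                TaxonomyNode(
                    taxid=taxid,
                    parent_taxid=int(fields[1]),
                    rank=fields[2].strip("\t"),
                    scientific_name=names.get(taxid, ""),
                )
            )
    return Taxonomy(nodes)


def load_taxonomy(path: str | Path, dialect: str = "tsv") -> Taxonomy:
    """Load a taxonomy.

    dialect="tsv": 4-column file (taxid, parent, rank, name).
    dialect="taxdump": directory containing nodes.dmp and names.dmp.
    """
    path = Path(path)
    if dialect == "tsv":
        return _load_tsv(path)
    if dialect == "taxdump":
        return _load_taxdump(path)
    raise ValueError(f"unknown taxonomy dialect {dialect!r}")


def write_taxonomy_tsv(taxonomy: Taxonomy, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("#taxid\tparent\trank\tname\n")
        for node in sorted(taxonomy, key=lambda n: n.taxid):
            handle.write(
                f"{node.taxid}\t{node.parent_taxid}\t{node.rank}\t{node.scientific_name}\n"
            )
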