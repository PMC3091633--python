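"""Synthetic communities with analytically known coverage and resolution.

The generator builds a balanced family/genus/species taxonomy and one
template record per species.  Each non-dropout template carries exactly
one forward and one reverse primer site with *planted* mismatch counts
(mismatching positions drawn at seeded random among unprotected,
non-degenerate primer positions), flanked by random background, with the
barcode insert in between.  Species listed in a shared-barcode group
receive byte-identical inserts, so which taxa share a barcode -- and
therefore the exact coverage B_c and resolution B_s at any rank and any
mismatch budget up to ``clean_k`` -- is known by construction.

Exactness rests on rejection sampling: a candidate template is accepted
only if a brute-force scan (both strands, both primers, budget
``clean_k``, no suffix protection) finds exactly the planted sites and
nothing else.  Ground truth is therefore exact, not probabilistic, for
budgets k <= clean_k.

Background and insert composition is uniform over {A,C,G,T}; fixtures
contain no degenerate symbols, keeping the ground truth analytic.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .iupac import IUPAC_SETS, is_degenerate, reverse_complement
from .match import MatchParameters, brute_force_find
from .records import Primer, SequenceRecord, write_fasta
from .taxonomy import Taxonomy, TaxonomyNode, write_taxonomy_tsv

__all__ = ["CommunitySpec", "GroundTruth", "SpeciesTruth", "generate_community",
           "write_community", "GenerationError"]

_BASES = "ACGT"
_MAX_ATTEMPTS = 100


class GenerationError(RuntimeError):
    """Raised when a community cannot be planted as specified."""


@dataclass(frozen=True)
class CommunitySpec:
    """Recipe for one synthetic community.

    ``planted_mismatches`` maps a species index (0-based, family-major
    enumeration order) to its (m_fwd, m_rev) pair; unlisted species get
    exact sites.  ``shared_barcode_groups`` lists disjoint sets of
    species indices forced to share one identical insert.
    ``dropout_species`` get a random template with no primer sites at
    all.  ``clean_k`` is the budget up to which the ground truth is
    guaranteed exact (default: max(2, largest planted mismatch count)).
    """

    n_families: int = 3
    n_genera_per_family: int = 2
    n_species_per_genus: int = 2
    insert_len_range: tuple[int, int] = (50, 120)
    flank_len: int = 20
    planted_mismatches: dict[int, tuple[int, int]] = field(default_factory=dict)
    shared_barcode_groups: tuple[frozenset[int], ...] = ()
    dropout_species: frozenset[int] = frozenset()
    clean_k: Optional[int] = None
    seed: int = 0

    @property
    def n_species(self) -> int:
        return self.n_families * self.n_genera_per_family * self.n_species_per_genus

    def __post_init__(self) -> None:
        # normalise container types so YAML-loaded specs behave identically
        object.__setattr__(
            self,
            "shared_barcode_groups",
            tuple(frozenset(g) for g in self.shared_barcode_groups),
        )
        object.__setattr__(self, "dropout_species", frozenset(self.dropout_species))
        object.__setattr__(
            self,
            "planted_mismatches",
            {int(k): (int(v[0]), int(v[1])) for k, v in self.planted_mismatches.items()},
        )
        object.__setattr__(
            self, "insert_len_range",
            (int(self.insert_len_range[0]), int(self.insert_len_range[1])),
        )
        n = self.n_species
        if min(self.n_families, self.n_genera_per_family, self.n_species_per_genus) < 1:
            raise ValueError("taxonomy shape counts must be >= 1")
        lo, hi = self.insert_len_range
        if not 1 <= lo <= hi:
            raise ValueError("insert_len_range must satisfy 1 <= lo <= hi")
        all_idx = set(range(n))
        seen: set[int] = set()
        for group in self.shared_barcode_groups:
            if not group <= all_idx:
                raise ValueError("shared group references unknown species index")
            if group & seen:
                raise ValueError("shared_barcode_groups must be disjoint")
            seen |= group
        if not self.dropout_species <= all_idx:
            raise ValueError("dropout_species references unknown species index")
        for idx in self.planted_mismatches:
            if idx not in all_idx:
                raise ValueError(f"planted_mismatches references unknown species {idx}")

    def effective_clean_k(self) -> int:
        planted_max = max(
            (max(v) for v in self.planted_mismatches.values()), default=0
        )
        if self.clean_k is not None:
            if self.clean_k < planted_max:
                raise ValueError("clean_k must cover the largest planted mismatch")
            return self.clean_k
        return max(2, planted_max)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CommunitySpec":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "insert_len_range" in raw:
            raw["insert_len_range"] = tuple(raw["insert_len_range"])
        if "shared_barcode_groups" in raw:
            raw["shared_barcode_groups"] = tuple(
                frozenset(int(i) for i in g) for g in raw["shared_barcode_groups"]
            )
        if "dropout_species" in raw:
            raw["dropout_species"] = frozenset(int(i) for i in raw["dropout_species"])
        if "planted_mismatches" in raw:
            raw["planted_mismatches"] = {
                int(k): (int(v[0]), int(v[1]))
                for k, v in raw["planted_mismatches"].items()
            }
        return cls(**raw)


@dataclass(frozen=True)
class SpeciesTruth:
    """Planted facts for one species."""

    index: int
    taxid: int
    record_id: str
    genus_taxid: int
    family_taxid: int
    m_fwd: int
    m_rev: int
    dropout: bool
    barcode_group: Optional[int]  # index into shared_barcode_groups, or None
    insert: str


@dataclass(frozen=True)
class GroundTruth:
    """Analytic expectations for a generated community.

    Valid for mismatch budgets k <= clean_k (with the protected-suffix
    rule active or not: planted mismatches never sit in a protected
    suffix, so both settings agree on the planted sites).
    """

    species: tuple[SpeciesTruth, ...]
    clean_k: int

    def _anc(self, sp: SpeciesTruth, rank: str) -> int:
        return {
            "species": sp.taxid,
            "genus": sp.genus_taxid,
            "family": sp.family_taxid,
        }[rank]

    def amplified(self, k: int) -> list[SpeciesTruth]:
        self._check_k(k)
        return [
            s for s in self.species
            if not s.dropout and s.m_fwd <= k and s.m_rev <= k
        ]

    def _check_k(self, k: int) -> None:
        if k > self.clean_k:
            raise ValueError(
                f"ground truth only guaranteed for k <= clean_k={self.clean_k}"
            )

    def expected_bc(self, rank: str, k: int) -> float:
        total = {self._anc(s, rank) for s in self.species}
        amp = {self._anc(s, rank) for s in self.amplified(k)}
        return len(amp) / len(total)

    def expected_bs(self, rank: str, k: int) -> Optional[float]:
        amplified = self.amplified(k)
        if not amplified:
            return None
        taxa: dict[int, list[SpeciesTruth]] = {}
        for s in amplified:
            taxa.setdefault(self._anc(s, rank), []).append(s)
        by_group: dict[int, list[SpeciesTruth]] = {}
        for s in amplified:
            if s.barcode_group is not None:
                by_group.setdefault(s.barcode_group, []).append(s)
        n_ok = 0
        for t, members in taxa.items():
            ambiguous = any(
                s.barcode_group is not None
                and any(
                    self._anc(other, rank) != t
                    for other in by_group[s.barcode_group]
                )
                for s in members
            )
            if not ambiguous:
                n_ok += 1
        return n_ok / len(taxa)

    def sufficient_data(self, k: int) -> bool:
        return len(self.amplified(k)) > 10

    def to_json_dict(self) -> dict:
        ranks = ("species", "genus", "family")
        expected = {}
        for k in range(self.clean_k + 1):
            expected[str(k)] = {
                rank: {
                    "bc": self.expected_bc(rank, k),
                    "bs": self.expected_bs(rank, k),
                }
                for rank in ranks
            }
        return {
            "clean_k": self.clean_k,
            "n_species": len(self.species),
            "expected": expected,
            "species": [asdict(s) for s in self.species],
        }


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _plantable_positions(primer: Primer) -> list[int]:
    """Unprotected, non-degenerate primer positions (mismatch-eligible)."""
    limit = len(primer.pattern) - primer.exact_suffix_len
    return [
        i for i in range(limit) if not is_degenerate(primer.pattern[i])
    ]


def _instantiate_site(primer: Primer, n_mismatches: int, rng: random.Random) -> str:
    """A concrete ACGT string matching the primer at all but exactly
    *n_mismatches* planted positions."""
    eligible = _plantable_positions(primer)
    if n_mismatches > len(eligible):
        raise GenerationError(
            f"primer {primer.name!r}: cannot plant {n_mismatches} mismatches; "
            f"only {len(eligible)} unprotected non-degenerate positions"
        )
    site = [rng.choice(sorted(IUPAC_SETS[c])) for c in primer.pattern]
    for pos in rng.sample(eligible, n_mismatches):
        incompatible = sorted(set(_BASES) - IUPAC_SETS[primer.pattern[pos]])
        site[pos] = rng.choice(incompatible)
    return "".join(site)


def _clean(seq: str, patterns: Sequence[tuple[str, list]], k: int) -> bool:
    """True iff each scan of *seq* yields exactly the expected spans.

    *patterns* pairs a pattern with the expected list of (start, m);
    scanning uses the brute-force reference at budget k, no suffix rule.
    """
    params = MatchParameters(max_mismatches=k, exact_suffix_len=0)
    for pattern, expected in patterns:
        found = [(s.start, s.mismatches) for s in brute_force_find(pattern, seq, params)]
        if found != sorted(expected):
            return False
    return True


def generate_community(
    spec: CommunitySpec,
    fwd: Primer,
    rev: Primer,
) -> tuple[Taxonomy, list[SequenceRecord], GroundTruth]:
    """Build (taxonomy, one record per species, ground truth).

    Deterministic for a fixed spec (including its seed) and primer pair.
    Raises :class:`GenerationError` when a requested planting is
    infeasible or rejection sampling cannot find a clean template.
    """
    rng = random.Random(spec.seed)
    clean_k = spec.effective_clean_k()
    # feasibility up front, so errors do not depend on sampling luck
    for idx, (m_f, m_r) in spec.planted_mismatches.items():
        if m_f > len(_plantable_positions(fwd)):
            raise GenerationError(
                f"species {idx}: cannot plant {m_f} forward mismatches"
            )
        if m_r > len(_plantable_positions(rev)):
            raise GenerationError(
                f"species {idx}: cannot plant {m_r} reverse mismatches"
            )

    nodes = [TaxonomyNode(1, 1, "root", "root")]
    next_id = 2
    species_meta: list[tuple[int, int, int]] = []  # (species, genus, family)
    for f in range(spec.n_families):
        fam_id = next_id
        next_id += 1
        nodes.append(TaxonomyNode(fam_id, 1, "family", f"Family{f + 1}"))
        for g in range(spec.n_genera_per_family):
            gen_id = next_id
            next_id += 1
            nodes.append(TaxonomyNode(gen_id, fam_id, "genus", f"Genus{f + 1}.{g + 1}"))
            for s in range(spec.n_species_per_genus):
                sp_id = next_id
                next_id += 1
                nodes.append(
                    TaxonomyNode(
                        sp_id, gen_id, "species",
                        f"Species{f + 1}.{g + 1}.{s + 1}",
                    )
                )
                species_meta.append((sp_id, gen_id, fam_id))
    taxonomy = Taxonomy(nodes)

    group_of = {
        idx: gi
        for gi, group in enumerate(spec.shared_barcode_groups)
        for idx in group
    }
    rc_rev = reverse_complement(rev.pattern)
    used_inserts: set[str] = set()
    group_inserts: dict[int, str] = {}
    for gi in range(len(spec.shared_barcode_groups)):
        ins = _fresh_insert(rng, spec, fwd, rev, rc_rev, clean_k, used_inserts)
        group_inserts[gi] = ins
        used_inserts.add(ins)

    records: list[SequenceRecord] = []
    truths: list[SpeciesTruth] = []
    for idx, (sp_id, gen_id, fam_id) in enumerate(species_meta):
        record_id = f"rec{idx:04d}"
        m_f, m_r = spec.planted_mismatches.get(idx, (0, 0))
        dropout = idx in spec.dropout_species
        gi = group_of.get(idx)
        if dropout:
            length = 2 * spec.flank_len + len(fwd) + len(rev) + spec.insert_len_range[0]
            seq = _rejection_sample(
                lambda: _random_seq(rng, length),
                lambda s: _clean(
                    s,
                    [(fwd.pattern, []), (rc_rev, [])], clean_k,
                ) and _clean(
                    reverse_complement(s),
                    [(fwd.pattern, []), (rc_rev, [])], clean_k,
                ),
                record_id,
            )
            insert = ""
        else:
            def build() -> str:
                site_f = _instantiate_site(fwd, m_f, rng)
                site_r = _instantiate_site(rev, m_r, rng)
                ins = (
                    group_inserts[gi]
                    if gi is not None
                    else _random_seq(rng, rng.randint(*spec.insert_len_range))
                )
                if gi is None and ins in used_inserts:
                    ins = None  # collision: force retry
                if ins is None:
                    return ""
                return (
                    _random_seq(rng, spec.flank_len)
                    + site_f + ins + reverse_complement(site_r)
                    + _random_seq(rng, spec.flank_len)
                )

            fwd_at = spec.flank_len

            def check(s: str) -> bool:
                if not s:
                    return False
                ins_len = len(s) - 2 * spec.flank_len - len(fwd) - len(rev)
                rev_at = fwd_at + len(fwd) + ins_len
                return _clean(
                    s,
                    [
                        (fwd.pattern, [(fwd_at, m_f)]),
                        (rc_rev, [(rev_at, m_r)]),
                    ],
                    clean_k,
                ) and _clean(
                    reverse_complement(s),
                    [(fwd.pattern, []), (rc_rev, [])],
                    clean_k,
                )

            seq = _rejection_sample(build, check, record_id)
            insert = seq[
                spec.flank_len + len(fwd): len(seq) - spec.flank_len - len(rev)
            ]
            if gi is None:
                used_inserts.add(insert)
        records.append(
            SequenceRecord(
                record_id=record_id,
                sequence=seq,
                taxid=sp_id,
                description=taxonomy.name(sp_id),
            )
        )
        truths.append(
            SpeciesTruth(
                index=idx,
                taxid=sp_id,
                record_id=record_id,
                genus_taxid=gen_id,
                family_taxid=fam_id,
                m_fwd=m_f,
                m_rev=m_r,
                dropout=dropout,
                barcode_group=gi,
                insert=insert,
            )
        )
    return taxonomy, records, GroundTruth(species=tuple(truths), clean_k=clean_k)


def _fresh_insert(
    rng: random.Random,
    spec: CommunitySpec,
    fwd: Primer,
    rev: Primer,
    rc_rev: str,
    clean_k: int,
    used: set[str],
) -> str:
    """An insert free of internal primer sites on either strand."""
    for _ in range(_MAX_ATTEMPTS):
        ins = _random_seq(rng, rng.randint(*spec.insert_len_range))
        if ins in used:
            continue
        ok = _clean(ins, [(fwd.pattern, []), (rc_rev, [])], clean_k) and _clean(
            reverse_complement(ins), [(fwd.pattern, []), (rc_rev, [])], clean_k
        )
        if ok:
            return ins
    raise GenerationError("could not draw a primer-site-free shared insert")


def _rejection_sample(build, check, record_id: str) -> str:
    for _ in range(_MAX_ATTEMPTS):
        seq = build()
        if seq and check(seq):
            return seq
    raise GenerationError(
        f"{record_id}: rejection sampling failed after {_MAX_ATTEMPTS} attempts; "
        "try a different seed or less repetitive primers"
    )


def random_spec(seed: int) -> CommunitySpec:
    """A randomised, always-feasible community recipe.

    Draws a small taxonomy shape, a handful of planted mismatch pairs
    (up to 3 per primer, guaranteed exact up to ``clean_k=3``), up to two
    shared-barcode groups and a few dropout species -- the full space of
    planted structure the generator supports.  Used for end-to-end
    recovery checks where many independent communities are needed.
    """
    rng = random.Random(seed)
    nf = rng.randint(2, 3)
    ng = rng.randint(1, 2)
    ns = rng.randint(1, 3)
    n = nf * ng * ns
    planted = {
        i: (rng.randint(0, 3), rng.randint(0, 3))
        for i in rng.sample(range(n), rng.randint(0, max(1, n // 3)))
    }
    pool = list(range(n))
    rng.shuffle(pool)
    groups: list[frozenset[int]] = []
    while len(pool) >= 2 and len(groups) < 2 and rng.random() < 0.7:
        size = min(len(pool), rng.randint(2, 3))
        groups.append(frozenset(pool[:size]))
        pool = pool[size:]
    dropouts = frozenset(rng.sample(range(n), rng.randint(0, max(0, n // 4))))
    return CommunitySpec(
        n_families=nf,
        n_genera_per_family=ng,
        n_species_per_genus=ns,
        insert_len_range=(40, 90),
        planted_mismatches=planted,
        shared_barcode_groups=tuple(groups),
        dropout_species=dropouts,
        clean_k=3,
        seed=rng.randrange(2**31),
    )


def write_community(
    out_dir: str | Path,
    taxonomy: Taxonomy,
    records: Sequence[SequenceRecord],
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write community.fasta, taxonomy.tsv and ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "community.fasta",
        "taxonomy": out / "taxonomy.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_fasta(records, paths["fasta"])
    write_taxonomy_tsv(taxonomy, paths["taxonomy"])
    with open(paths["ground_truth"], "w") as handle:
        json.dump(truth.to_json_dict(), handle, indent=2)
        handle.write("\n")
    return paths
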