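"""Coverage B_c and resolution B_s, including the shared-barcode worked
example: three taxa, six individuals, one barcode (B4) shared between an
individual of T2 and one of T3, so only T1 is unambiguously identified."""

import itertools

import pytest

from ispcr.amplify import AmpliconHit
from ispcr.indices import (
    BarcodeTable,
    build_barcode_table,
    coverage_index,
    is_unambiguous,
    omega,
    resolution_index,
)
from ispcr.match import MatchSpan
from ispcr.records import SequenceRecord
from ispcr.taxonomy import Taxonomy, TaxonomyNode


def _table(assignment: dict[str, tuple[int, set[str]]], rank="species") -> BarcodeTable:
    """Build a BarcodeTable directly from individual -> (taxon, barcodes)."""
    table = BarcodeTable(region_label="R1", rank=rank)
    for ind, (taxon, barcodes) in assignment.items():
        table.taxa.add(taxon)
        table.individuals.add(ind)
        table.E.setdefault(taxon, set()).add(ind)
        table.Img[ind] = set(barcodes)
        table.eprime |= barcodes
    table.n_species_amplified = len(table.taxa)
    return table


@pytest.fixture
def shared_barcode_scenario() -> BarcodeTable:
    # T1: I1->B1, I2->B2; T2: I3->B3, I4->B4; T3: I5->B5, I6->B4
    return _table(
        {
            "I1": (1, {"B1"}),
            "I2": (1, {"B2"}),
            "I3": (2, {"B3"}),
            "I4": (2, {"B4"}),
            "I5": (3, {"B5"}),
            "I6": (3, {"B4"}),
        }
    )


def test_scenario_shape(shared_barcode_scenario):
    t = shared_barcode_scenario
    assert len(t.taxa) == 3
    assert len(t.individuals) == 6
    assert "B4" in t.eprime and len(t.eprime) == 5


def test_omega_collects_taxon_barcodes(shared_barcode_scenario):
    assert omega(shared_barcode_scenario, 2) == {"B3", "B4"}
    assert "B4" in omega(shared_barcode_scenario, 3)


def test_omega_single_taxon_equals_eprime():
    t = _table({"I1": (1, {"B1", "B2"}), "I2": (1, {"B3"})})
    assert omega(t, 1) == t.eprime


def test_unambiguity_in_shared_barcode_scenario(shared_barcode_scenario):
    t = shared_barcode_scenario
    assert is_unambiguous(t, 1) is True
    assert is_unambiguous(t, 2) is False  # B4 also owned by I6 of T3
    assert is_unambiguous(t, 3) is False  # B4 also owned by I4 of T2


def test_resolution_one_third(shared_barcode_scenario):
    res = resolution_index(shared_barcode_scenario)
    assert res.bs == pytest.approx(1 / 3)
    assert res.identified_taxa == 1
    assert res.total_taxa == 3
    assert res.sufficient_data is False  # only 3 species amplified


def test_all_private_barcodes_fully_resolved():
    t = _table({f"I{i}": (i, {f"B{i}"}) for i in range(1, 5)})
    assert all(is_unambiguous(t, i) for i in t.taxa)
    assert resolution_index(t).bs == 1.0


def test_two_taxa_sharing_single_barcode():
    t = _table({"I1": (1, {"B1"}), "I2": (2, {"B1"})})
    assert resolution_index(t).bs == 0.0


def test_adding_cross_taxon_individual_flips_to_ambiguous():
    base = {"I1": (1, {"B1"}), "I2": (2, {"B2"})}
    assert is_unambiguous(_table(base), 1)
    base["I3"] = (2, {"B1"})  # taxon 2 now owns taxon 1's barcode
    t = _table(base)
    assert not is_unambiguous(t, 1)
    assert not is_unambiguous(t, 2)


def test_unambiguity_agrees_with_pairwise_overlap_check(rng):
    """Exhaustive pairwise-barcode-overlap oracle on random tables."""
    for _ in range(100):
        assignment = {}
        n_taxa = rng.randint(1, 5)
        barcodes = [f"B{i}" for i in range(rng.randint(1, 6))]
        for i in range(rng.randint(1, 12)):
            assignment[f"I{i}"] = (
                rng.randint(1, n_taxa),
                {rng.choice(barcodes) for _ in range(rng.randint(1, 3))},
            )
        t = _table(assignment)
        for taxon in t.taxa:
            mine = set().union(*(t.Img[i] for i in t.E[taxon]))
            others = set().union(
                *(
                    t.Img[i]
                    for other in t.taxa
                    if other != taxon
                    for i in t.E[other]
                ),
                set(),
            )
            assert is_unambiguous(t, taxon) == (not mine & others)


def test_omega_unknown_taxon_raises(shared_barcode_scenario):
    with pytest.raises(KeyError):
        omega(shared_barcode_scenario, 99)


def test_empty_table_flagged_not_error():
    res = resolution_index(BarcodeTable(region_label="r", rank="species"))
    assert res.bs is None and res.total_taxa == 0


# --- coverage ---------------------------------------------------------------


def _species_tree(n_species: int) -> Taxonomy:
    nodes = [TaxonomyNode(1, 1, "root", "root"), TaxonomyNode(2, 1, "family", "F")]
    nodes += [TaxonomyNode(10 + i, 2, "species", f"sp{i}") for i in range(n_species)]
    return Taxonomy(nodes)


def _hit(record_id, taxid, barcode="AC"):
    span = MatchSpan(0, 2, 0)
    return AmpliconHit(record_id, taxid, "+", span, MatchSpan(4, 6, 0), barcode)


def test_coverage_direct_ratio():
    tax = _species_tree(10)
    recs = [SequenceRecord(f"r{i}", "ACGT", taxid=10 + i) for i in range(10)]
    hits = [_hit(f"r{i}", 10 + i) for i in range(8)]
    cov = coverage_index(recs, hits, tax, "species")
    assert cov.bc == 0.8
    assert (cov.amplified_taxa, cov.total_taxa) == (8, 10)


def test_coverage_no_hits_is_zero():
    tax = _species_tree(3)
    recs = [SequenceRecord(f"r{i}", "ACGT", taxid=10 + i) for i in range(3)]
    assert coverage_index(recs, [], tax, "species").bc == 0.0


def test_coverage_empty_reference_flagged():
    tax = _species_tree(1)
    cov = coverage_index([], [], tax, "species")
    assert cov.bc is None


def test_coverage_excludes_records_lacking_the_rank():
    tax = _species_tree(2)
    recs = [
        SequenceRecord("r0", "ACGT", taxid=10),
        SequenceRecord("r1", "ACGT", taxid=2),  # annotated at family only
    ]
    cov = coverage_index(recs, [_hit("r0", 10)], tax, "species")
    assert (cov.amplified_taxa, cov.total_taxa, cov.excluded_taxa) == (1, 1, 1)
    assert cov.bc == 1.0


def test_coverage_at_genus_rank_equals_hand_enumeration():
    # two genera, three species each; hits in all of genus A, none of B
    nodes = [TaxonomyNode(1, 1, "root", "root")]
    nodes += [TaxonomyNode(2, 1, "genus", "A"), TaxonomyNode(3, 1, "genus", "B")]
    nodes += [TaxonomyNode(10 + i, 2, "species", f"a{i}") for i in range(3)]
    nodes += [TaxonomyNode(20 + i, 3, "species", f"b{i}") for i in range(3)]
    tax = Taxonomy(nodes)
    recs = [SequenceRecord(f"r{t}", "ACGT", taxid=t) for t in (10, 11, 12, 20, 21, 22)]
    hits = [_hit(f"r{t}", t) for t in (10, 11, 12)]
    cov = coverage_index(recs, hits, tax, "genus")
    assert (cov.amplified_taxa, cov.total_taxa) == (1, 2)
    assert cov.bc == 0.5


def test_build_table_from_hits_set_semantics():
    tax = _species_tree(2)
    hits = [
        _hit("r0", 10, "ACGT"),
        _hit("r0", 10, "ACGT"),  # identical amplicon: one barcode
        _hit("r0", 10, "acgt"),  # case-normalised: still the same barcode
        _hit("r1", 11, "TTTT"),
    ]
    table = build_barcode_table(hits, tax, "species", "R1")
    assert table.Img["r0"] == {"ACGT"}
    assert len(table.taxa) == 2 and len(table.individuals) == 2
    assert table.eprime == {"ACGT", "TTTT"}


def test_build_table_drops_records_without_rank():
    tax = _species_tree(1)
    hits = [_hit("r0", 10), _hit("r1", 2)]  # r1 annotated at family
    table = build_barcode_table(hits, tax, "species")
    assert table.individuals == {"r0"}
    assert table.excluded_records == 1
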