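"""In silico PCR pairing: planted templates, strand symmetry, oracle."""

import random

import pytest

from ispcr import (
    AmplificationConstraints,
    MatchParameters,
    Primer,
    SequenceRecord,
    amplify_database,
    amplify_record,
    mismatch_profile,
    read_hits_tsv,
    reverse_complement,
    write_hits_tsv,
)
from ispcr.amplify import brute_force_amplify
from ispcr.community import CommunitySpec, generate_community


def _plant(rng, fwd, rev, insert_len=50, flank=20):
    insert = "".join(rng.choice("ACGT") for _ in range(insert_len))
    return (
        "".join(rng.choice("ACGT") for _ in range(flank))
        + fwd.pattern
        + insert
        + reverse_complement(rev.pattern)
        + "".join(rng.choice("ACGT") for _ in range(flank))
    ), insert


def test_planted_template_single_plus_hit(fwd_primer, rev_primer, rng):
    seq, insert = _plant(rng, fwd_primer, rev_primer)
    rec = SequenceRecord("t1", seq)
    (hit,) = amplify_record(rec, fwd_primer, rev_primer)
    assert hit.strand == "+"
    assert hit.barcode_seq == insert
    assert hit.insert_len == 50
    assert hit.product_len == 50 + len(fwd_primer) + len(rev_primer)
    assert hit.forward_span.mismatches == 0
    assert hit.reverse_span.mismatches == 0
    assert hit.reverse_span.start - hit.forward_span.end == hit.insert_len


def test_reverse_complemented_template_gives_minus_hit(fwd_primer, rev_primer, rng):
    seq, insert = _plant(rng, fwd_primer, rev_primer)
    rec = SequenceRecord("t1", reverse_complement(seq))
    (hit,) = amplify_record(rec, fwd_primer, rev_primer)
    assert hit.strand == "-"
    assert hit.barcode_seq == insert  # orientation-normalised


def test_barcode_is_exact_substring_at_reported_coords(fwd_primer, rev_primer, rng):
    seq, _ = _plant(rng, fwd_primer, rev_primer)
    rec = SequenceRecord("t1", reverse_complement(seq))
    (hit,) = amplify_record(rec, fwd_primer, rev_primer)
    frame_seq = reverse_complement(rec.sequence)  # '-' hit: rc frame
    assert (
        frame_seq[hit.forward_span.end: hit.reverse_span.start] == hit.barcode_seq
    )


def test_insert_length_constraints(fwd_primer, rev_primer, rng):
    seq, _ = _plant(rng, fwd_primer, rev_primer, insert_len=50)
    rec = SequenceRecord("t1", seq)
    tight = AmplificationConstraints(min_insert_len=51)
    assert amplify_record(rec, fwd_primer, rev_primer, tight) == []
    tight = AmplificationConstraints(max_insert_len=49)
    assert amplify_record(rec, fwd_primer, rev_primer, tight) == []


def test_zero_length_insert_allowed(fwd_primer, rev_primer, rng):
    seq, _ = _plant(rng, fwd_primer, rev_primer, insert_len=0)
    rec = SequenceRecord("t1", seq)
    (hit,) = amplify_record(rec, fwd_primer, rev_primer)
    assert hit.barcode_seq == ""
    assert hit.insert_len == 0


def test_multiple_pairings_all_reported(fwd_primer, rev_primer, rng):
    # fwd site, insert, rev site, spacer, rev site again -> two pairings
    rc = reverse_complement(rev_primer.pattern)
    seq = (
        "ACGTACGTAC" + fwd_primer.pattern + "A" * 30 + rc + "C" * 25 + rc + "GTACGTACGT"
    )
    hits = amplify_record(SequenceRecord("t", seq), fwd_primer, rev_primer)
    assert len(hits) == 2
    assert sorted(h.insert_len for h in hits) == [30, 30 + len(rc) + 25]


def test_random_templates_match_brute_force_pairing(fwd_primer, rev_primer, rng):
    """Differential test against the pairing built on the naive matcher."""
    for i in range(200):
        n_sites = rng.randint(0, 3)
        parts = ["".join(rng.choice("ACGT") for _ in range(rng.randint(5, 40)))]
        for _ in range(n_sites):
            site = rng.choice([fwd_primer.pattern, reverse_complement(rev_primer.pattern)])
            site = "".join(
                rng.choice("ACGT") if rng.random() < 0.08 else c for c in site
            )
            parts.append(site)
            parts.append("".join(rng.choice("ACGT") for _ in range(rng.randint(5, 60))))
        rec = SequenceRecord(f"t{i}", "".join(parts))
        assert amplify_record(rec, fwd_primer, rev_primer) == brute_force_amplify(
            rec, fwd_primer, rev_primer
        )


def test_database_annotation_and_planted_mismatch_budget(fwd_primer, rev_primer):
    spec = CommunitySpec(
        n_families=2, n_genera_per_family=2, n_species_per_genus=5,
        planted_mismatches={i: (3, 0) for i in range(5)}, seed=11, clean_k=3,
    )
    taxonomy, records, truth = generate_community(spec, fwd_primer, rev_primer)
    assert len(records) == 20
    hits = amplify_database(records, fwd_primer, rev_primer, taxonomy=taxonomy)
    # 5 species carry 3 forward mismatches; default budget k=2 excludes them
    assert len(hits) == 15
    assert all(h.species and h.genus and h.family for h in hits)
    relaxed = AmplificationConstraints(match_params=MatchParameters(3, 3))
    assert len(amplify_database(records, fwd_primer, rev_primer, relaxed, taxonomy)) == 20


def test_empty_database():
    assert amplify_database([], Primer("f", "ACGTACGTAC"), Primer("r", "ACGTACGTAC")) == []


def test_strand_symmetry_on_database(fwd_primer, rev_primer, rng):
    recs = []
    for i in range(10):
        seq, _ = _plant(rng, fwd_primer, rev_primer, insert_len=rng.randint(20, 60))
        recs.append(SequenceRecord(f"r{i}", seq))
    mirrored = [
        SequenceRecord(r.record_id, reverse_complement(r.sequence)) for r in recs
    ]
    direct = amplify_database(recs, fwd_primer, rev_primer)
    mirror = amplify_database(mirrored, fwd_primer, rev_primer)
    flip = {"+": "-", "-": "+"}
    assert [(h.record_id, h.barcode_seq, flip[h.strand]) for h in direct] == [
        (h.record_id, h.barcode_seq, h.strand) for h in mirror
    ]


def test_mismatch_profile_planted(fwd_primer, rev_primer):
    spec = CommunitySpec(
        n_families=1, n_genera_per_family=1, n_species_per_genus=5,
        planted_mismatches={1: (1, 0), 2: (2, 0), 3: (2, 0), 4: (3, 0)},
        seed=5, clean_k=3,
    )
    _, records, _ = generate_community(spec, fwd_primer, rev_primer)
    profile = mismatch_profile(records, fwd_primer, kmax=3)
    assert list(profile["count"]) == [1, 1, 2, 1]
    assert list(profile["cumulative_fraction"]) == [0.2, 0.4, 0.8, 1.0]


def test_mismatch_profile_all_exact(fwd_primer, rev_primer, rng):
    recs = [
        SequenceRecord(f"r{i}", _plant(rng, fwd_primer, rev_primer)[0])
        for i in range(4)
    ]
    profile = mismatch_profile(recs, fwd_primer, kmax=2)
    assert profile["count"].tolist() == [4, 0, 0]
    assert profile["cumulative_fraction"].tolist() == [1.0, 1.0, 1.0]


def test_hits_tsv_roundtrip(fwd_primer, rev_primer, rng, tmp_path):
    seq, _ = _plant(rng, fwd_primer, rev_primer)
    recs = [SequenceRecord("t1", seq, taxid=5)]
    hits = amplify_database(recs, fwd_primer, rev_primer)
    path = tmp_path / "hits.tsv"
    write_hits_tsv(hits, path, cmdline="test run")
    assert path.read_text().startswith("#cmdline: test run\n")
    back = read_hits_tsv(path)
    assert [(h.record_id, h.taxid, h.strand, h.barcode_seq) for h in back] == [
        (h.record_id, h.taxid, h.strand, h.barcode_seq) for h in hits
    ]
    assert back[0].forward_span == hits[0].forward_span
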