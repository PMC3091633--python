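# Methods

## Matching model

Primer–template annealing is modelled as fixed-length, substitutions-only
approximate matching. A primer pattern `p` (5′→3′, IUPAC alphabet) matches a
text window `w` of the same length when the number of *incompatible*
positions — positions where the IUPAC base sets of `p[i]` and `w[i]` are
disjoint — is at most the budget `k`, and no incompatible position falls in a
protected set. Insertions and deletions are not modelled: the quantity of
interest is the count of mispaired bases in a duplex of fixed length.

Degenerate symbols are treated by base-set intersection *symmetrically*: a
template `N` is compatible with every primer symbol, and a template `R`
with any primer symbol containing a purine. The symmetric rule was chosen
because it is the only one that makes compatibility a reflexive, symmetric
relation computable from the standard base-set table; whether template
ambiguity codes should instead always count as mismatches is a modelling
choice on which reasonable tools differ, and the rule is documented here as
this package's.

**Protected positions.** The general mechanism is an arbitrary set of
pattern positions where any mismatch abolishes the match
(`protected_positions`); the common case — the 3′-terminal
`exact_suffix_len` positions, default 3 — is the per-primer default. When
the reverse primer is searched as its reverse complement on the forward
strand, its protected 3′ suffix maps to the *first* positions of the
reverse-complemented pattern; the generic API handles this directly.

**Engine.** The production matcher is a Bitap (shift-add/Agrep family)
automaton with one machine word per mismatch level: bit `i` of level `d` is
set when `p[0..i]` matches the window ending at the current text position
with ≤ `d` mismatches, the substitution transition being gated by a mask of
unprotected positions. Patterns up to 63 nt run bit-parallel (all practical
primers are ≤ ~30 nt); longer patterns transparently use the naive scan, so
the contract is total. The naive sliding-window scan (`brute_force_find`) is
not test scaffolding but a permanent module member: the engine's central
correctness property is differential equality with it, exercised on ~10⁴
random degenerate-alphabet instances per run. The reported mismatch count of
a span is the smallest accepting level, which for a fixed window equals the
exact incompatible-position count.

Coordinates are 0-based half-open everywhere internally; the TSV outputs
convert to 1-based inclusive.

## Amplification

A hit is a pair (forward-primer match, match of the reverse complement of
the reverse primer) on the same strand, with the reverse site starting at or
after the forward site's end (overlapping primer footprints are rejected;
zero-length inserts are legal when `min_insert_len = 0`) and the insert
length within `[min_insert_len, max_insert_len]` (defaults 0 and 2000 nt —
an explicit bound is needed for the pairing step to be meaningful; all
standard barcodes are far below it). Both strands are scanned — the '−'
orientation repeats the search on the reverse complement — and **all** valid
pairings are reported, nested and overlapping alternatives included: the
model imposes only orientation and distance constraints, and any best-hit
heuristic would be an additional assumption.

Fragment size is reported both ways: `insert_len` excludes the primer
sites (the convention under which the classic COI Folmer fragment is
658 bp) and `product_len` includes them.

For '−' hits, span coordinates refer to the reverse-complemented template
(the forward-primer orientation frame), which keeps
`insert_len = rev_start − fwd_end` and the barcode-substring invariant
literally true on both strands; barcodes are thereby always reported 5′→3′
relative to the forward primer.

**Mismatch profile.** `mismatch_profile` reports, per record, the minimum
mismatch count of a single primer over both strands within a budget `kmax`
(default 8), plus the cumulative fraction of matched records with ≤ m
mismatches. By default the protected-suffix rule is *ignored* here — the
profile describes annealing affinity, not amplifiability — with a flag
(`respect_suffix`) to enable it; the denominator of the cumulative fraction
is the set of records matched at all within `kmax`.

## Indices

`B_c` divides the number of distinct rank-level taxa with ≥ 1 hit by the
number of distinct rank-level taxa among the reference records. Records
whose lineage lacks the evaluation rank are excluded from both counts and
reported; an empty denominator yields an explicitly undefined result, not an
exception.

`B_s` is computed from the barcode table: individuals are amplified records,
`Img` maps each to its *distinct* barcode strings (exact string equality
after uppercasing, in forward-primer orientation), `E` groups individuals by
rank-level ancestor. A taxon is unambiguous iff the owners of its barcodes
(`Img⁻¹(Ω(t, r))`) are exactly its own individuals. Three deliberate
choices:

- `E(t)` contains only *amplified* individuals. Including unamplified
  conspecifics would make every partly-amplified taxon automatically
  ambiguous, conflating coverage with resolution.
- Degenerate symbols inside extracted barcodes compare as literal
  characters. Set-compatible comparison would make "shares a barcode"
  intransitive; the cost is that an `N`-bearing amplicon never equals its
  resolved counterpart (a documented limitation).
- The >10-species rule is a reporting flag (`sufficient_data`), not a hard
  refusal: `B_s` over a handful of species is arithmetic, just not
  evidence.

## Reference-database utilities

`one_per_species` draws one record per species uniformly at random from an
explicitly seeded generator (no global RNG), preserving first-appearance
species order, so database construction is reproducible bit-for-bit.
`clade_filter` restricts to the records whose lineage passes through a given
root, enabling per-clade analyses.

## Synthetic communities and what they show

The generator plants, per species, one forward and one reverse site with
exact mismatch counts (positions drawn among unprotected, non-degenerate
primer positions; the incompatible replacement base drawn uniformly),
separated by the barcode insert and flanked by 20 nt of uniform-random
background. Shared-barcode groups receive byte-identical inserts; dropout
species get siteless random sequence. Ground truth for `B_c` and `B_s` at
any rank then follows by counting.

Exactness is enforced, not hoped for: every candidate template is scanned
with the brute-force matcher (both strands, both primers, no suffix
protection) at budget `clean_k` — default `max(2, largest planted count)` —
and rejected unless exactly the planted sites appear. Unique inserts are
additionally kept globally distinct. Ground truth is therefore exact for any
budget `k ≤ clean_k`; the guarantee is surfaced in the API (`GroundTruth`
refuses queries beyond `clean_k`). Rejection sampling retries up to 100
times per template before failing loudly.

What the fixtures deliberately do **not** emulate: realistic base
composition, substitution-model evolution, rate heterogeneity, length
variation between homologous barcodes, pseudogenes, or multiple sequences
per species. Passing tests demonstrate that the *accounting* —
matching, pairing, taxonomy traversal, index arithmetic — is exact on
communities whose truth is known by construction; they say nothing about
how any real primer pair behaves on real mitochondrial diversity, which
depends entirely on the reference database supplied.

## Problem sizes and determinism

The default verification workload uses 10⁴ random matcher instances
(patterns 8–30 nt over a degeneracy-enriched alphabet, texts ≤ 500 nt,
k ∈ 0..4), 10³ random amplifier templates with 0–3 corrupted planted sites,
and 50 randomised communities of up to 18 species — sizes at which the
differential checks are exhaustive in spirit while the whole suite stays
interactive. All stochastic components (tests, generator, acceptance
script) take explicit integer seeds; hypothesis-based property tests run
derandomised.

## Known limitations

- No thermodynamics: melting temperature, GC clamps and amplification
  efficiency are out of scope; a 2-mismatch hit and a 0-mismatch hit count
  equally.
- Substitutions only; a real bulged-primer duplex is invisible to the model.
- Barcode identity is exact string equality — no clustering, distance
  threshold or alignment — matching the shared/not-shared formalism of the
  indices.
- Taxonomy handling ignores merged/deleted taxids and name disambiguation;
  inputs are assumed internally consistent (and are validated for cycles,
  orphans and duplicate ids).
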