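# ispcr

In silico PCR and DNA-barcode quality evaluation: a library and CLI for
asking, before anyone touches a pipette, *which sequences in a database
would a given primer pair amplify, and how good is the amplified
fragment as a barcode?*

It is aimed at metabarcoding and barcoding study design — choosing
primer pairs for environmental DNA, diet analysis, or degraded-sample
identification — where the two properties that matter are:

- **taxonomic coverage** `B_c`: the fraction of taxa at a chosen rank in
  a reference database that the primer pair amplifies in silico
  (its *universality*), and
- **resolution capacity** `B_s`: the fraction of amplified taxa whose
  barcode — the fragment between the primer sites — is shared with no
  other taxon (its *diagnostic power*).

## The engine

In silico PCR selects database sequences carrying two primer-matching
sites in amplifiable orientation and distance. Matching is
substitutions-only and IUPAC-aware on both sides: a primer position and
a template position are compatible when their base sets intersect
(`R` = A/G anneals to `A`, `G`, `R`, `N`, ...). Each primer tolerates at
most `k` mismatches (default 2), with **zero** mismatches allowed on a
protected 3′-terminal zone (default: the last 3 bases), mimicking the
polymerase's requirement for a paired 3′ end. The search is an
Agrep-style bit-parallel (Bitap) automaton with one bit vector per
mismatch level; a literal sliding-window scan is kept permanently as its
differential-test oracle.

## The indices

With `T` the amplified taxa at the evaluation rank, `I` the amplified
sequence records ("individuals"), `E(t)` the individuals of taxon `t`,
`Img(i)` the barcode strings of individual `i` and `E′` all barcodes of
the region `r`:

```
Ω(t, r) = Img(E(t)) ∩ E′(r)            # all barcodes of taxon t
t is unambiguous  ⇔  Img⁻¹(Ω(t, r)) = E(t)
B_s(r) = |{t unambiguous}| / |T|
B_c    = amplified taxa / total taxa in the reference database
```

`B_s` is flagged as under-powered when the pair amplified ≤ 10 species.

## Worked example

Simulate a 12-species community (3 families × 2 genera × 2 species)
with planted imperfections — species 0 has one forward-primer mismatch,
species 1 has three (beyond the default budget), species 7 has no primer
sites at all, and species 4 and 5 share a byte-identical barcode — then
amplify it with the classic COI Folmer pair and score the result:

```
$ ispcr simulate --spec spec.yaml --seed 42 --out community
$ ispcr amplify --db community/community.fasta --taxonomy community/taxonomy.tsv \
    --fwd GGTCAACAAATCATAAAGATATTGG --rev TAAACTTCAGGGTGACCAAAAAATCA -o hits.tsv
$ cut -f1-9,13 hits.tsv | head -4
record_id  taxid  species       genus     family   strand  fwd_start  fwd_end  fwd_mismatches  insert_len
rec0000    4      Species1.1.1  Genus1.1  Family1  +       21         45       1               114
rec0002    7      Species1.2.1  Genus1.2  Family1  +       21         45       0               73
rec0003    8      Species1.2.2  Genus1.2  Family1  +       21         45       0               65
```

Ten of the twelve species amplified (species 1 exceeded the mismatch
budget; species 7 had no sites), so coverage is 10/12:

```
$ ispcr coverage --db community/community.fasta --taxonomy community/taxonomy.tsv \
    --hits hits.tsv --rank species
region_label  rank     total_taxa  amplified_taxa  bc        identified_taxa  bs  sufficient_data
              species  12          10              0.833333
```

Species 4 and 5 share their barcode, so neither can be told apart and
resolution is 8/10; `sufficient_data` is `false` because the >10-species
reporting threshold was not met:

```
$ ispcr resolution --hits hits.tsv --taxonomy community/taxonomy.tsv \
    --rank species --region-label LCO1490/HCO2198
region_label     rank     total_taxa  amplified_taxa  bc  identified_taxa  bs   sufficient_data
LCO1490/HCO2198  species  10                              8                0.8  false
```

`ispcr profile` tabulates, per record, the best mismatch count of one
primer over both strands — the histogram behind "how many more taxa
would a relaxed PCR recruit":

```
$ ispcr profile --db community/community.fasta --fwd GGTCAACAAATCATAAAGATATTGG --kmax 4
m   count  cumulative_fraction
0   9      0.8181818181818182
1   1      0.9090909090909091
2   0      0.9090909090909091
3   1      1.0
4   0      1.0
```

The same workflow is available as library calls (`generate_community`,
`amplify_database`, `coverage_index`, `build_barcode_table`,
`resolution_index`); every CLI command is a thin binding over them.

## Taxonomy formats

Either NCBI taxdump (`--dialect taxdump`, a directory with `nodes.dmp`
and `names.dmp`) or a 4-column TSV (`--dialect tsv`):

```
#taxid  parent  rank     name
1       1       root     root
2       1       family   Felidae
3       2       genus    Panthera
4       3       species  Panthera pardus
```

FASTA records carry their taxid as a header token:
`>seq1 taxid=4; Panthera pardus`.

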