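# asvdb

Genus-specific, primer-specific reference databases for amplicon
sequence variants (ASVs), built from public-database FASTA files by
simulated PCR.

## The problem

Amplicon surveys (16S, ITS, or single-copy genes such as EF1α) resolve
community composition into exact sequence variants, but taxonomic
classifiers trained on general references often stop at a genus-level
consensus: within the short amplified region, many congeneric species
are identical. Collapsing such a variant to "*Genus* spp." discards
information. `asvdb` takes the opposite approach: for one genus and one
primer pair it enumerates, from public reference sequences, every
amplicon the primers would produce, and records **all** species
consistent with each amplicon. A variant matching a single species is
named `Genus_Species`; a variant whose sequence is shared by two or
more species becomes a **shared amplicon** (SA) group named
`Genus_SAn`, with the member species kept in a manifest. The resulting
FASTA + taxonomy pair is used for a secondary, exact-match assignment
(100% identity, 100% coverage) after a conventional classifier has
placed a variant in the genus — or directly, for genus-specific assays.

## The method

For each source sequence the two primers are located by a *glocal*
alignment: the full primer is aligned against a free local window of
the template under a scoring scheme that prefers mismatches to gaps —
match +1, mismatch 0, gap-open −1, gap-extend −0.5. IUPAC degenerate
codes in a primer match their expansion set; ambiguity in the template
counts as a mismatch. A hit is accepted when its score reaches a
user-set fraction *t* of the primer's maximum score (its length `L`,
so a primer with `k` mismatches passes iff `L − k ≥ t·L`), and an
amplicon is produced only when the last three bases at each primer's
3′ end align without mismatch or gap — the polymerase-extension
requirement. The fragment between (or spanning, if requested) the two
primer sites is the amplicon. Identical amplicons are collapsed;
unwanted taxonomy (`sp.`, `aff.`, `cf.`) is filtered; multi-species
amplicons become SA groups numbered consecutively in lexicographic
sequence order; databases built from different sources can be merged,
which unions taxa per sequence and renumbers SA groups.

Record lineages can be verified by accession against the ENA browser
API with NCBI Entrez as fallback, through a TSV-backed cache; with
`--offline` the header-derived lineages are used and no network is
touched.

## Worked example

The package ships a synthetic-data generator (also available as the
`fixtures` subcommand) that plants primer sites and known structure, so
the whole pipeline can be exercised without downloads:

```sh
asvdb fixtures --n-species 4 --records-per-species 2 --shared-amplicons 1 \
    --unwanted-fraction 0.25 --seed 11 --fasta toy.fasta --manifest truth.tsv
asvdb pipeline --genus Fusarium --primers Fa-150,Ra-2 --offline \
    -i toy.fasta -o out
```

prints

```
total_variants	5
sa_variants	1
species_complex_variants	0
species_taxa	4
sa_taxa	1
attributions	5
n_sequences	5
n_sa_groups	1
outdir	out
```

The 12 input records (4 species × 2 records, 2 records of a shared
insert, 2 `Fusarium sp.` records removed by the taxonomy filter)
collapse to 5 unique variants: 4 single-species variants and 1 shared
amplicon. `attributions` is the number of distinct answers the
database can return — distinct species taxa plus one per SA group.
`out/taxonomy.tsv` maps each variant's MD5 feature ID to its taxon:

```
83df67d907bf621882d08f17d49234d4	g__Fusarium;s__Fusarium_SA1
83f4325dadbbaacaac49b33d2de4a338	g__Fusarium;s__Fusarium_plantedsp00
...
```

and `out/sa_groups.tsv` lists each SA group's member species:

```
group_id	n_species	species
Fusarium_SA1	2	Fusarium plantedsp00;Fusarium plantedsp02
```

Named primer presets (`515FB`, `926R`, `BITS`, `B58S3`, `Fa-150`,
`Ra-2`) are shipped with the package; arbitrary IUPAC sequences are
accepted in their place. Individual steps are also available as
`build`, `filter`, `group`, `merge`, `export` and `stats` subcommands
communicating through a JSON database document.

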