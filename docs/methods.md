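# Methods

## Primer matching model

Primer binding is modelled as a *glocal* pairwise alignment: the whole
primer must be consumed, while the template contributes a free local
window (unaligned template prefix and suffix cost nothing). Scoring
favours mismatches over gaps — match +1, mismatch 0, gap-open −1,
gap-extend −0.5 (the open penalty applies to the first column of a gap
run, the extend penalty to each further column). The rationale is
physical: a primer–template duplex tolerates internal mismatches far
better than bulges, and anchoring the full primer makes "the last
three 3′ bases" well defined. The implementation is a three-state
Gotoh dynamic program; ties are broken toward the smallest template
start, then the shortest aligned span, so results are deterministic
and independent of input order.

IUPAC degenerate codes are resolved asymmetrically. A degenerate
*primer* position matches any template base in its expansion set
(R = A/G, Y = C/T, ...). Ambiguity in the *template* (including N)
scores as a mismatch: this is deliberately conservative, so N-rich
reference sequences fail the 3′ rule rather than amplify spuriously.

### Amplification decision

For one template: (1) align the forward primer; (2) align the reverse
complement of the reverse primer downstream of the forward hit; (3)
accept only if each score reaches `threshold × primer_length` and each
primer's three 3′-terminal alignment columns are exact matches (no
mismatch and no gap — both are treated as extension-blocking). The
forward primer's 3′ end is its last three columns; the reverse
primer's 3′ end corresponds to the *first* three template-orientation
columns of its complemented alignment. The amplicon is the template
substring between the primer sites, or spanning them when
`keep_primers` is set. An empty insert (abutting or overlapping
primers) yields no amplicon.

The threshold is a fraction of the primer's maximum score (its
length), not an absolute score, so one setting is comparable across
primers of different lengths; the default is 0.9. Only the single
best hit per primer is used, so a multi-locus template yields at most
one amplicon — a known limitation. When the forward-strand pass
yields nothing the template's reverse complement is tried (public
archives deposit either strand); this can be disabled with
`--single-strand`.

## Taxon model

Each database is scoped to one genus (genus comparison is
case-insensitive and whitespace-trimmed; no inter-genus conflict
resolution is attempted). Taxa are species-level labels. Species
complexes ("Fusarium incarnatum-equiseti complex") are single taxa,
never expanded. Sub-species decorations (variety, forma specialis)
are truncated at the epithet, since the model is species-level.
Records identified only to genus are carried as "Genus sp." so the
unwanted-taxonomy filter decides their fate; the default filter
patterns remove `sp.`, `aff. ...` and `cf. ...` epithets.

A variant kept by the filter is named `Genus_Species` when a single
species explains it, and `Genus_SAn` when two or more do. SA numbers
run 1..K in lexicographic order of the amplicon sequence — the
numbering is therefore deterministic and independent of input order,
and it is reassigned from scratch whenever entries change (grouping
after a merge), because stable numbering across merges would require a
global registry that does not exist. Identical amplicons are collapsed
*before* taxonomy filtering; the alternative order changes only
filter-log counts, never the final entries.

## Lineage verification

Lineages parsed from FASTA headers can be verified by accession: ENA's
browser API (EMBL flat format) first, NCBI Entrez efetch (GenBank flat
format) as fallback. When the API and the header disagree, the API
wins and the discrepancy is logged — the lookup exists to verify, so
the archive is the authority. Lookups are rate-limited to 3 requests/s
with a descriptive User-Agent, retried 3 times with exponential
backoff, and never abort a build: total failure marks the record
`failed` and keeps the header lineage. Every outcome, failures
included, is appended to a TSV cache keyed by accession; verified
cache entries are never overwritten, and a cached accession costs no
network call on a rebuild. Offline mode skips lookups entirely and
marks lineages `unverified`.

## Export format

The on-disk reference is a FASTA whose IDs are lowercase hex MD5
digests of the uppercase amplicon sequence — the dominant feature-ID
convention of downstream amplicon pipelines — plus a two-column TSV
mapping each ID to a semicolon-joined taxon string with rank prefixes
(`k__...;g__Genus;s__Genus_Species`); a prefix-free mode exists. Rows
are sorted by feature ID, making output byte-stable across runs. SA
membership is written to a sidecar TSV (`group_id`, `n_species`,
semicolon-joined species), since the taxon string itself carries only
the group name. Intermediate pipeline state is a single JSON document
(entries, SA manifest, provenance, filter log) with canonically sorted
keys and collections, so merge results are byte-identical regardless
of argument order. Provenance records the full run configuration; its
timestamp honours `SOURCE_DATE_EPOCH` so reruns can be made
bit-reproducible.

## Synthetic data generator

Test inputs are generated, not downloaded. Each record is
`flank + forward-site + insert + revcomp(reverse-site) + flank` with
uniform-random ACGT flanks and inserts; degenerate primer positions
are resolved uniformly at random per record, so ambiguity matching is
exercised. The generator plants, per specification: species sharing an
identical insert (ground-truth SA groups), primer-site mutations at
chosen 3′-relative positions (a mutation whose replacement base stays
inside a degenerate position's match set is correctly *not* counted as
a mismatch), off-genus records, and genus-only "sp." records. Expected
amplifiability is derived from the scoring model (`L − k ≥ t·L` and no
effective mismatch at 3′ positions 1–3); each record is then checked
against the simulator and flanks are regenerated in the rare case a
random flank creates a spurious primer site that changes the outcome.
The manifest records each record's expected amplicon and final group,
plus the expected database summary.

Defaults describe a small but structured study: 5 species × 2 records,
one shared amplicon, 60 nt inserts, 30 nt flanks — large enough to
exercise collapsing, sharing and filtering, small enough that the full
test suite runs in seconds. What the generator does **not** emulate:
phylogenetic relatedness (records are independent random sequences),
sequencing error, chimeras, length variation within a locus, and the
taxonomic annotation errors of real archives. Passing tests therefore
demonstrate correctness of the pipeline's logic, not robustness to
noisy real-world references.

## Numerical and design choices

- Alignment scores are small floats (half-integer granularity); score
  comparisons in tests use exact or 1e-9 tolerance — no meaningful
  rounding occurs at these sizes.
- The aligner is cross-checked against two independent oracles: an
  exhaustive enumeration of all alignment paths on tiny instances, and
  Biopython's `PairwiseAligner` configured for glocal affine-gap
  alignment with an IUPAC-expansion substitution matrix on realistic
  sizes (primers ≤ 25 nt, templates ≤ 200 nt).
- Duplicate accessions within one input file are last-wins with a
  warning; records with non-IUPAC characters are dropped and counted.
- Empty databases are legal intermediate states (returned with a
  prominent log), but exporting one is a fatal error that names the
  stage which removed everything.
- The acceptance script sizes its problems (200 alignment instances,
  25 generator settings, two 38-record sources) to characterise
  behaviour while completing in seconds.

## Known limitations

- One amplicon per template: tandem or multi-copy loci are not
  enumerated.
- Genus scoping is strict; cross-genus shared amplicons are invisible
  by design and the tool must follow, not replace, a general
  classifier.
- Thermodynamics (melting temperature, primer dimers) are not
  modelled; the score threshold is a proxy.
- SA numbering is database-scoped: merging renumbers groups, so SA
  names are not comparable across database versions.
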