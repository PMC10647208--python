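"""Synthetic source FASTA files with planted, known ground truth.

Each generated record is ``flank + forward-site + insert +
revcomp(reverse-site) + flank``: a sequence that amplifies to exactly
the planted insert.  The generator controls which species share an
insert (shared-amplicon groups), plants primer mismatches at chosen
3'-relative positions, and mixes in off-genus and unidentified
("Genus sp.") records, so every pipeline stage can be tested offline
against an exact expected outcome.  Degenerate primer positions are
resolved to a concrete base uniformly at random per record, which
exercises ambiguity matching; everything is driven by one seed and is
byte-reproducible.

What this emulates -- and what it does not: records are independent
random sequences, not homologous genes, so there is no phylogenetic
signal, no chimeras and no length variation beyond the configured
insert size.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

from .pcr import IUPAC_EXPAND, PrimerPair, reverse_complement, simulate_pcr
from .seqio import Lineage, SequenceRecord

_BASES = "ACGT"
_MAX_FLANK_RETRIES = 20


@dataclass(frozen=True)
class Mismatch:
    """One planted primer-site mutation.

    ``position`` counts from the primer's 3' end, 1-based; positions
    1-3 violate the 3'-anchor rule and make the record non-amplifiable
    at any threshold.
    """

    record_index: int
    primer: str  # "forward" | "reverse"
    position: int
    replacement: str


@dataclass(frozen=True)
class FixtureSpec:
    genus: str = "Fusarium"
    n_species: int = 5
    n_records_per_species: int = 2
    n_shared_amplicons: int = 1
    insert_length: int = 60
    flank_length: int = 30
    mismatch_plan: tuple[Mismatch, ...] = ()
    offgenus_fraction: float = 0.0
    unwanted_taxa_fraction: float = 0.0
    seed: int = 0

    def validate(self, primers: PrimerPair) -> None:
        if self.n_species < 1 or self.n_records_per_species < 1:
            raise ValueError("need at least one species and one record each")
        max_pairs = self.n_species * (self.n_species - 1) // 2
        if self.n_shared_amplicons > max_pairs:
            raise ValueError(
                f"n_shared_amplicons={self.n_shared_amplicons} exceeds "
                f"C({self.n_species},2)={max_pairs}")
        if self.insert_length < 1:
            raise ValueError("insert_length must be positive")
        for mm in self.mismatch_plan:
            plen = len(primers.forward if mm.primer == "forward" else primers.reverse)
            if mm.primer not in ("forward", "reverse"):
                raise ValueError(f"unknown primer {mm.primer!r} in mismatch plan")
            if not 1 <= mm.position <= plen:
                raise ValueError(
                    f"mismatch position {mm.position} beyond {mm.primer} "
                    f"primer length {plen}")
            if mm.replacement not in _BASES:
                raise ValueError(f"replacement must be one of {_BASES}")


@dataclass
class PlantedRecord:
    accession: str
    species: str
    genus: str
    insert: str
    sequence: str = ""
    amplifiable: bool = True
    expected_amplicon: str = ""


@dataclass
class FixtureResult:
    records: list[SequenceRecord]
    planted: list[PlantedRecord]
    expected_summary: dict
    sa_memberships: list[tuple[str, ...]] = field(default_factory=list)
    expected_groups: dict[str, str] = field(default_factory=dict)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.accession} {rec.description}\n{rec.sequence}\n")

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("record_id\tspecies\texpected_amplicon\texpected_group\n")
            for p in self.planted:
                amp = p.expected_amplicon if p.amplifiable else "-"
                grp = self.expected_groups.get(p.accession, "-")
                fh.write(f"{p.accession}\t{p.species}\t{amp}\t{grp}\n")


def _resolve(primer: str, rng: random.Random) -> str:
    """Resolve degenerate positions to concrete bases, uniformly."""
    return "".join(b if b in _BASES else rng.choice(sorted(IUPAC_EXPAND[b]))
                   for b in primer)


def _rand_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _real_mismatches(plan, idx, primers):
    """Per-primer lists of (position, is_3prime) for *effective* mismatches:
    a replacement still inside the degenerate position's match set is
    not a mismatch."""
    rc_rev = reverse_complement(primers.reverse)
    out = {"forward": [], "reverse": []}
    for mm in plan:
        if mm.record_index != idx:
            continue
        if mm.primer == "forward":
            code = primers.forward[len(primers.forward) - mm.position]
        else:
            code = rc_rev[mm.position - 1]
        if mm.replacement not in IUPAC_EXPAND[code]:
            out[mm.primer].append(mm.position)
    return out


def generate(spec: FixtureSpec, primers: PrimerPair,
             fasta_path=None, manifest_path=None) -> FixtureResult:
    """Generate a synthetic source FASTA and its ground-truth manifest.

    Record order: per-species records, then shared-amplicon records,
    then "Genus sp." records, then off-genus records (mismatch-plan
    indices refer to this order).  Flanks are regenerated whenever a
    spurious primer site makes the simulated outcome differ from the
    planted expectation.  Shared-amplicon expectations assume
    ``keep_primers=False``; with primers kept, per-record degenerate
    resolution makes amplicons differ even for a shared insert.
    """
    spec.validate(primers)
    rng = random.Random(spec.seed)
    genus = spec.genus

    # distinct inserts: one per species plus one per shared group
    inserts: set[str] = set()

    def new_insert() -> str:
        while True:
            ins = _rand_seq(rng, spec.insert_length)
            if ins not in inserts:
                inserts.add(ins)
                return ins

    species = [f"{genus} plantedsp{i:02d}" for i in range(spec.n_species)]
    species_insert = {sp: new_insert() for sp in species}

    planted: list[PlantedRecord] = []
    for sp in species:
        for _ in range(spec.n_records_per_species):
            planted.append(PlantedRecord(accession="", species=sp, genus=genus,
                                         insert=species_insert[sp]))
    all_pairs = sorted(itertools.combinations(species, 2))
    sa_pairs = rng.sample(all_pairs, spec.n_shared_amplicons)
    for pair in sa_pairs:
        shared = new_insert()
        for sp in pair:
            planted.append(PlantedRecord(accession="", species=sp, genus=genus,
                                         insert=shared))
    n_base = spec.n_species * spec.n_records_per_species
    n_unwanted = int(round(spec.unwanted_taxa_fraction * n_base))
    for _ in range(n_unwanted):
        planted.append(PlantedRecord(accession="", species=f"{genus} sp.",
                                     genus=genus, insert=new_insert()))
    n_offgenus = int(round(spec.offgenus_fraction * n_base))
    for _ in range(n_offgenus):
        planted.append(PlantedRecord(accession="",
                                     species=f"Not{genus.lower()} plantedsp00",
                                     genus=f"Not{genus.lower()}",
                                     insert=new_insert()))
    for i, p in enumerate(planted):
        p.accession = f"FIX{i:05d}"

    # --- build template sequences, verifying the planted outcome -----
    records: list[SequenceRecord] = []
    for idx, p in enumerate(planted):
        fwd_site = _resolve(primers.forward, rng)
        rev_site = reverse_complement(_resolve(primers.reverse, rng))
        mms = _real_mismatches(spec.mismatch_plan, idx, primers)
        for mm in spec.mismatch_plan:  # apply *all* planned edits
            if mm.record_index != idx:
                continue
            if mm.primer == "forward":
                i = len(fwd_site) - mm.position
                fwd_site = fwd_site[:i] + mm.replacement + fwd_site[i + 1:]
            else:
                i = mm.position - 1
                rev_site = rev_site[:i] + mm.replacement + rev_site[i + 1:]
        # expected amplifiability under the scoring scheme
        lf, lr = len(primers.forward), len(primers.reverse)
        fail3 = any(pos <= 3 for pos in mms["forward"] + mms["reverse"])
        score_ok = (lf - len(mms["forward"]) >= primers.threshold * lf
                    and lr - len(mms["reverse"]) >= primers.threshold * lr)
        p.amplifiable = score_ok and not fail3
        if p.amplifiable:
            p.expected_amplicon = (fwd_site + p.insert + rev_site
                                   if primers.keep_primers else p.insert)
        core = fwd_site + p.insert + rev_site
        for attempt in range(_MAX_FLANK_RETRIES + 1):
            seq = _rand_seq(rng, spec.flank_length) + core + _rand_seq(rng, spec.flank_length)
            amp = simulate_pcr(seq, primers, accession=p.accession)
            got = amp.sequence if amp is not None else None
            want = p.expected_amplicon if p.amplifiable else None
            if got == want:
                break
            if attempt == _MAX_FLANK_RETRIES:
                raise RuntimeError(
                    f"could not realise planted outcome for {p.accession} "
                    f"after {_MAX_FLANK_RETRIES} flank regenerations")
        p.sequence = seq
        epithet = p.species.split(" ", 1)[1]
        lineage = Lineage(ranks=[("genus", p.genus), ("species", p.species)],
                          genus=p.genus, species_epithet=epithet)
        records.append(SequenceRecord(accession=p.accession,
                                      description=p.species,
                                      sequence=seq, lineage=lineage,
                                      source_db="generic"))

    result = FixtureResult(records=records, planted=planted,
                           expected_summary={}, sa_memberships=[],
                           expected_groups={})
    _compute_expectations(result, genus)
    if fasta_path is not None:
        result.write_fasta(fasta_path)
    if manifest_path is not None:
        result.write_manifest(manifest_path)
    return result


def _compute_expectations(result: FixtureResult, genus: str) -> None:
    """Expected post-pipeline state: collapse planted amplicons of
    genus-matched amplifiable records, drop 'sp.' labels, group."""
    entries: dict[str, set[str]] = {}
    contributors: dict[str, list[PlantedRecord]] = {}
    for p in result.planted:
        if p.genus != genus or not p.amplifiable:
            continue
        entries.setdefault(p.expected_amplicon, set()).add(p.species)
        contributors.setdefault(p.expected_amplicon, []).append(p)
    n_sp_removed = 0
    filtered: dict[str, set[str]] = {}
    for seq, taxa in entries.items():
        kept = {t for t in taxa if not t.endswith(" sp.")}
        n_sp_removed += len(taxa) - len(kept)
        if kept:
            filtered[seq] = kept
    sa_n = 0
    memberships = []
    for seq in sorted(filtered):
        taxa = filtered[seq]
        if len(taxa) >= 2:
            sa_n += 1
            name = f"{genus}_SA{sa_n}"
            memberships.append(tuple(sorted(taxa)))
        else:
            name = next(iter(taxa)).replace(" ", "_")
        for p in contributors.get(seq, []):
            if p.species in taxa:
                result.expected_groups[p.accession] = name
    species_taxa = {next(iter(t)) for t in filtered.values() if len(t) == 1}
    result.sa_memberships = memberships
    result.expected_summary = {
        "total_variants": len(filtered),
        "sa_variants": sa_n,
        "species_complex_variants": sum(
            1 for t in filtered.values()
            if len(t) == 1 and next(iter(t)).endswith("complex")),
        "species_taxa": len(species_taxa),
        "sa_taxa": sa_n,
        "attributions": len(species_taxa) + sa_n,
        "n_sp_labels_removed": n_sp_removed,
    }
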