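"""Genus-specific ASV database construction.

The pipeline collapses the amplifiable fragments of all source
sequences of one genus into unique amplicon sequence variants.  A
variant observed for a single species keeps that species as its taxon
(``Genus_Species``); a variant whose sequence is identical across two
or more species becomes a Shared Amplicon (SA) group and is assigned
the taxon ``Genus_SAn`` -- keeping every possible identification
instead of retreating to a genus-level consensus.  Species-complex
names (``... complex``) are treated as single taxa.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .pcr import PrimerPair, simulate_pcr
from .seqio import Lineage, SequenceRecord

#: Default unwanted-taxonomy patterns, matched against the part of the
#: species label after the genus ("sp.", "aff. x", "cf. x").
DEFAULT_EXCLUDE = (r"^sp\.$", r"^aff\.", r"^cf\.")


@dataclass
class DbEntry:
    """One unique amplicon sequence and everything that produced it."""

    sequence: str
    taxa: set[str] = field(default_factory=set)
    source_accessions: set[str] = field(default_factory=set)
    assigned_name: str = ""


@dataclass
class SharedAmpliconGroup:
    n: int
    sequence: str
    members: set[str] = field(default_factory=set)


@dataclass
class AsvDatabase:
    genus: str
    entries: dict[str, DbEntry] = field(default_factory=dict)
    sa_groups: list[SharedAmpliconGroup] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)
    filter_log: list[dict] = field(default_factory=list)
    rank_context: list[tuple[str, str]] = field(default_factory=list)

    def last_emptying_stage(self) -> Optional[str]:
        for event in reversed(self.filter_log):
            if event.get("entries_after") == 0:
                return event["stage"]
        return None

    # -- persistence --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "genus": self.genus,
            "rank_context": [list(r) for r in self.rank_context],
            "entries": [
                {"sequence": e.sequence,
                 "taxa": sorted(e.taxa),
                 "source_accessions": sorted(e.source_accessions),
                 "assigned_name": e.assigned_name}
                for e in sorted(self.entries.values(), key=lambda e: e.sequence)
            ],
            "sa_groups": [
                {"n": g.n, "sequence": g.sequence, "members": sorted(g.members)}
                for g in self.sa_groups
            ],
            "provenance": self.provenance,
            "filter_log": self.filter_log,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "AsvDatabase":
        db = cls(genus=doc["genus"])
        db.rank_context = [tuple(r) for r in doc.get("rank_context", [])]
        for e in doc.get("entries", []):
            db.entries[e["sequence"]] = DbEntry(
                sequence=e["sequence"], taxa=set(e["taxa"]),
                source_accessions=set(e["source_accessions"]),
                assigned_name=e.get("assigned_name", ""))
        db.sa_groups = [SharedAmpliconGroup(n=g["n"], sequence=g["sequence"],
                                            members=set(g["members"]))
                        for g in doc.get("sa_groups", [])]
        db.provenance = list(doc.get("provenance", []))
        db.filter_log = list(doc.get("filter_log", []))
        return db

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "AsvDatabase":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Step 2: build
# ---------------------------------------------------------------------------

def _species_label(lineage: Optional[Lineage], genus: str) -> Optional[str]:
    """Species taxon for a genus-matched record.

    Records identified only to genus get the placeholder "<Genus> sp."
    so the default unwanted-taxonomy filter decides their fate.
    """
    if lineage is None:
        return None
    label = lineage.species_label()
    if label is None:
        return f"{lineage.genus} sp."
    return label


def build_database(records: Iterable[SequenceRecord], genus: str,
                   primers: PrimerPair, source_db: str = "generic",
                   input_file: str = "", timestamp: Optional[str] = None,
                   try_reverse_strand: bool = True) -> AsvDatabase:
    """Amplify every genus-matched record and collapse identical amplicons.

    Records whose lineage genus differs from ``genus``
    (case-insensitively) are excluded; records yielding no amplicon are
    counted in the filter log.  An empty result is returned (with a
    prominent log entry), never raised.
    """
    genus = genus.strip()
    if not genus:
        raise ValueError("genus must be non-empty")
    want = genus.casefold()
    db = AsvDatabase(genus=genus)
    n_in = n_offgenus = n_no_amplicon = 0
    for rec in records:
        n_in += 1
        if rec.lineage is None or rec.lineage.genus.strip().casefold() != want:
            n_offgenus += 1
            continue
        if not db.rank_context and rec.lineage.ranks:
            db.rank_context = [(r, v) for r, v in rec.lineage.ranks
                               if r not in ("genus", "species") and v]
        amplicon = simulate_pcr(rec.sequence, primers, accession=rec.accession,
                                try_reverse_strand=try_reverse_strand)
        if amplicon is None:
            n_no_amplicon += 1
            continue
        label = _species_label(rec.lineage, genus)
        entry = db.entries.setdefault(amplicon.sequence,
                                      DbEntry(sequence=amplicon.sequence))
        entry.taxa.add(label)
        entry.source_accessions.add(rec.accession)
    db.provenance.append({
        "stage": "build", "source_db": source_db, "input_file": str(input_file),
        "genus": genus,
        "primers": {"forward": primers.forward, "reverse": primers.reverse,
                    "threshold": primers.threshold,
                    "keep_primers": primers.keep_primers},
        "timestamp": timestamp,
        "n_records_in": n_in, "n_off_genus": n_offgenus,
        "n_no_amplicon": n_no_amplicon,
    })
    db.filter_log.append({"stage": "build", "n_records_in": n_in,
                          "n_off_genus": n_offgenus,
                          "n_no_amplicon": n_no_amplicon,
                          "entries_after": len(db.entries)})
    return db


# ---------------------------------------------------------------------------
# Step 3: unwanted-taxonomy filter
# ---------------------------------------------------------------------------

def filter_taxa(db: AsvDatabase,
                exclude_patterns: Iterable[str] = DEFAULT_EXCLUDE) -> AsvDatabase:
    """Remove unwanted species labels ("sp.", "aff. ...", "cf. ...").

    Patterns are regexes applied to the portion of the species label
    after the genus name.  Entries whose taxa set empties are deleted;
    per-pattern removal counts land in the filter log.
    """
    patterns = [(p, re.compile(p)) for p in exclude_patterns]
    out = AsvDatabase(genus=db.genus, provenance=list(db.provenance),
                      filter_log=list(db.filter_log),
                      rank_context=list(db.rank_context))
    removal_counts = {p: 0 for p, _ in patterns}
    n_entries_deleted = 0
    for seq, entry in db.entries.items():
        kept = set()
        for label in entry.taxa:
            epithet_part = label.split(" ", 1)[1] if " " in label else label
            hit = next((p for p, rx in patterns if rx.search(epithet_part)), None)
            if hit is None:
                kept.add(label)
            else:
                removal_counts[hit] += 1
        if kept:
            out.entries[seq] = DbEntry(sequence=seq, taxa=kept,
                                       source_accessions=set(entry.source_accessions),
                                       assigned_name="")
        else:
            n_entries_deleted += 1
    out.filter_log.append({"stage": "filter_taxa",
                           "patterns": {p: c for p, c in removal_counts.items()},
                           "n_labels_removed": sum(removal_counts.values()),
                           "n_entries_deleted": n_entries_deleted,
                           "entries_after": len(out.entries)})
    return out


# ---------------------------------------------------------------------------
# Step 4: shared-amplicon grouping
# ---------------------------------------------------------------------------

def _underscore(label: str) -> str:
    return label.replace(" ", "_")


def make_sa_groups(db: AsvDatabase) -> AsvDatabase:
    """Assign final taxon names and (re)build the SA group list.

    Entries with two or more taxa become ``Genus_SAn`` with n running
    1..K in lexicographic order of the amplicon sequence -- a
    deterministic, input-order-independent numbering.  Single-taxon
    entries are named ``Genus_Species`` (spaces to underscores;
    complex names kept whole, e.g. ``Fusarium_tricinctum_complex``).
    """
    out = AsvDatabase(genus=db.genus, provenance=list(db.provenance),
                      filter_log=list(db.filter_log),
                      rank_context=list(db.rank_context))
    n = 0
    for seq in sorted(db.entries):
        entry = db.entries[seq]
        if len(entry.taxa) >= 2:
            n += 1
            name = f"{db.genus}_SA{n}"
            out.sa_groups.append(SharedAmpliconGroup(n=n, sequence=seq,
                                                     members=set(entry.taxa)))
        else:
            name = _underscore(next(iter(entry.taxa)))
        out.entries[seq] = DbEntry(sequence=seq, taxa=set(entry.taxa),
                                   source_accessions=set(entry.source_accessions),
                                   assigned_name=name)
    out.filter_log.append({"stage": "make_sa_groups", "n_sa_groups": n,
                           "entries_after": len(out.entries)})
    return out


# ---------------------------------------------------------------------------
# Step 5: merging
# ---------------------------------------------------------------------------

def merge(db1: AsvDatabase, db2: AsvDatabase) -> AsvDatabase:
    """Union two databases of the same genus, renumbering all SA groups.

    Identical sequences have their taxa and accession sets unioned, so
    a sequence known under different species in the two sources becomes
    a new SA group; exact duplicates collapse.  SA numbering is
    database-scoped and therefore reassigned from scratch.
    """
    if db1.genus.strip().casefold() != db2.genus.strip().casefold():
        raise ValueError(
            f"cannot merge databases of different genera: "
            f"{db1.genus!r} vs {db2.genus!r}")
    out = AsvDatabase(genus=db1.genus,
                      provenance=list(db1.provenance) + list(db2.provenance),
                      filter_log=list(db1.filter_log) + list(db2.filter_log),
                      rank_context=list(db1.rank_context) or list(db2.rank_context))
    for source in (db1, db2):
        for seq, entry in source.entries.items():
            tgt = out.entries.setdefault(seq, DbEntry(sequence=seq))
            tgt.taxa |= entry.taxa
            tgt.source_accessions |= entry.source_accessions
    out.filter_log.append({"stage": "merge",
                           "n_entries_db1": len(db1.entries),
                           "n_entries_db2": len(db2.entries),
                           "entries_after": len(out.entries)})
    return make_sa_groups(out)


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

def summarize(db: AsvDatabase) -> dict:
    """Variant and taxon counts for a finalized database.

    ``attributions`` is the total number of possible taxonomic answers
    the database can return: distinct species-level taxa (species
    complexes included) plus one per SA group.
    """
    total = len(db.entries)
    sa_variants = sum(1 for e in db.entries.values() if len(e.taxa) >= 2)
    complex_variants = sum(1 for e in db.entries.values()
                           if len(e.taxa) == 1
                           and next(iter(e.taxa)).endswith("complex"))
    species_taxa = {next(iter(e.taxa)) for e in db.entries.values()
                    if len(e.taxa) == 1}
    return {
        "total_variants": total,
        "sa_variants": sa_variants,
        "species_complex_variants": complex_variants,
        "species_taxa": len(species_taxa),
        "sa_taxa": len(db.sa_groups),
        "attributions": len(species_taxa) + len(db.sa_groups),
    }
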