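"""Reading source FASTA files and writing the reference database.

Source files come from public sequence databases whose FASTA header
dialects differ (SILVA's semicolon taxonomy paths, UNITE's
pipe-delimited records with ``k__``-prefixed ranks, plain
``accession description`` headers from ENA/NCBI/DDBJ, ...).  Header
grammars are table-driven so a new source is an entry in a dict, not a
code change.  The final database is written as a reference FASTA plus
a two-column feature-ID/taxonomy TSV, the pair consumed by downstream
amplicon classifiers for exact-match (100% identity, 100% coverage)
assignment.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Optional

from Bio import SeqIO

from .pcr import IUPAC_EXPAND

log = logging.getLogger("asvdb")

SOURCE_DBS = ("silva", "unite", "ena", "rnacentral", "ncbi", "ddbj", "generic")

#: Standard rank order, most to least inclusive.
RANK_ORDER = ("domain", "kingdom", "phylum", "class", "order", "family",
              "genus", "species")


class FastaFormatError(ValueError):
    """No parseable record was found for the dialect tried."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Lineage:
    """Taxonomic lineage of one source sequence.

    ``ranks`` is ordered from the most inclusive rank down to species;
    missing intermediate ranks are simply absent.  ``verified`` records
    whether the lineage was confirmed against an archive API.
    """

    ranks: list[tuple[str, str]] = field(default_factory=list)
    genus: str = ""
    species_epithet: Optional[str] = None
    is_complex: bool = False
    verified: str = "unverified"  # unverified | ena | ncbi | failed

    def species_label(self) -> Optional[str]:
        """Species-level taxon label, e.g. ``"Fusarium oxysporum"`` or
        ``"Fusarium incarnatum-equiseti complex"``; None if unknown."""
        if not self.genus or not self.species_epithet:
            return None
        return f"{self.genus} {self.species_epithet}"


@dataclass
class SequenceRecord:
    accession: str
    description: str
    sequence: str
    lineage: Optional[Lineage] = None
    source_db: str = "generic"


# ---------------------------------------------------------------------------
# Header dialect grammars
# ---------------------------------------------------------------------------

_BINOMIAL = re.compile(
    r"(?P<genus>[A-Z][A-Za-z-]+)\s+"
    r"(?P<epithet>sp\.|aff\.\s*\S*|cf\.\s*\S*|[a-z][a-z0-9.-]+)"
    r"(?P<rest>\s+\S.*)?$"
)

_COMPLEX_WORDS = 3  # look this many tokens past the epithet for "complex"


def _lineage_from_binomial(text: str) -> Optional[Lineage]:
    """Extract ``Genus epithet [... complex]`` from free header text."""
    m = _BINOMIAL.match(text.strip())
    if not m:
        return None
    genus, epithet = m.group("genus"), m.group("epithet")
    rest = (m.group("rest") or "").split()
    # species-complex names keep the words up to and including "complex"
    is_complex = False
    if "complex" in rest[:_COMPLEX_WORDS]:
        idx = rest.index("complex")
        epithet = " ".join([epithet] + rest[: idx + 1])
        is_complex = True
    elif epithet.endswith("complex"):
        is_complex = True
    return Lineage(ranks=[("genus", genus), ("species", f"{genus} {epithet}")],
                   genus=genus, species_epithet=epithet, is_complex=is_complex)


def _parse_generic(rec_id: str, description: str) -> tuple[str, Optional[Lineage]]:
    remainder = description[len(rec_id):].strip() if description.startswith(rec_id) else description
    return rec_id, _lineage_from_binomial(remainder)


def _parse_silva(rec_id: str, description: str) -> tuple[str, Optional[Lineage]]:
    remainder = description[len(rec_id):].strip()
    if not remainder:
        return rec_id, None
    path = [p.strip() for p in remainder.split(";") if p.strip()]
    if not path:
        return rec_id, None
    # SILVA taxonomy paths run domain;...;genus with the organism name last
    names = ("domain", "phylum", "class", "order", "family", "genus")
    last = path[-1]
    lineage = _lineage_from_binomial(last)
    if lineage is not None and len(path) >= 2:
        upper = path[:-1]
        ranks = [(names[i] if i < len(names) else f"rank{i + 1}", v)
                 for i, v in enumerate(upper)]
        lineage.ranks = ranks + [("species", last)]
        if lineage.genus == "" and len(upper) >= 6:
            lineage.genus = upper[5]
    elif lineage is None:
        # genus-level (or broken) path: keep what we have, no species
        lineage = Lineage(ranks=[(names[i] if i < len(names) else f"rank{i + 1}", v)
                                 for i, v in enumerate(path)],
                          genus=last if " " not in last else "")
    return rec_id, lineage


_UNITE_PREFIXES = {"k": "kingdom", "p": "phylum", "c": "class", "o": "order",
                   "f": "family", "g": "genus", "s": "species"}


def _parse_unite(rec_id: str, description: str) -> tuple[str, Optional[Lineage]]:
    parts = description.split("|")
    if len(parts) < 5:
        return rec_id, _lineage_from_binomial(description.replace("_", " "))
    accession = parts[1].strip()
    ranks: list[tuple[str, str]] = []
    genus, species = "", ""
    for item in parts[4].split(";"):
        item = item.strip()
        if len(item) >= 3 and item[1:3] == "__":
            rank = _UNITE_PREFIXES.get(item[0], item[0])
            value = item[3:].replace("_", " ").strip()
            ranks.append((rank, value))
            if rank == "genus":
                genus = value
            elif rank == "species":
                species = value
    lineage = _lineage_from_binomial(species) if species else None
    if lineage is None and genus:
        lineage = Lineage(genus=genus)
    if lineage is not None:
        lineage.ranks = ranks
        if genus:
            lineage.genus = genus
    return accession, lineage


_DIALECTS: dict[str, Callable[[str, str], tuple[str, Optional[Lineage]]]] = {
    "silva": _parse_silva,
    "unite": _parse_unite,
    "ena": _parse_generic,
    "ncbi": _parse_generic,
    "ddbj": _parse_generic,
    "rnacentral": _parse_generic,
    "generic": _parse_generic,
}


# ---------------------------------------------------------------------------
# FASTA input
# ---------------------------------------------------------------------------

def read_fasta(path, dialect: str = "generic") -> list[SequenceRecord]:
    """Read a source FASTA file, parsing taxonomy out of the headers.

    Sequences are upper-cased and U is normalised to T (RNA sources).
    Records whose sequence contains non-IUPAC characters are dropped
    and counted; duplicate accessions within one file are last-wins
    with a warning.  Raises :class:`FastaFormatError` when the file
    yields no parseable record.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {SOURCE_DBS}")
    parse_header = _DIALECTS[dialect]
    records: dict[str, SequenceRecord] = {}
    n_dropped = 0
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper().replace("U", "T")
            if not seq or any(b not in IUPAC_EXPAND for b in seq):
                n_dropped += 1
                continue
            accession, lineage = parse_header(rec.id, rec.description)
            if accession in records:
                log.warning("duplicate accession %s in %s: keeping last", accession, path)
            records[accession] = SequenceRecord(
                accession=accession, description=rec.description,
                sequence=seq, lineage=lineage, source_db=dialect)
    except ValueError as exc:
        raise FastaFormatError(
            f"no parseable FASTA records in {path} (dialect tried: {dialect}): "
            f"{exc}") from exc
    if n_dropped:
        log.warning("%d record(s) in %s dropped for alphabet violations", n_dropped, path)
    if not records:
        raise FastaFormatError(
            f"no parseable FASTA records in {path} (dialect tried: {dialect})")
    return list(records.values())


# ---------------------------------------------------------------------------
# Reference output
# ---------------------------------------------------------------------------

def feature_id(sequence: str) -> str:
    """Stable feature ID: lowercase hex MD5 of the upper-case sequence."""
    return hashlib.md5(sequence.upper().encode("ascii")).hexdigest()


_PREFIX_FOR_RANK = {"domain": "k", "kingdom": "k", "phylum": "p", "class": "c",
                    "order": "o", "family": "f", "genus": "g", "species": "s"}


def _taxon_string(db, assigned_name: str, rank_prefixes: bool) -> str:
    parts: list[str] = []
    for rank, value in db.rank_context:
        prefix = _PREFIX_FOR_RANK.get(rank)
        if prefix in (None, "s", "g"):
            continue
        parts.append(f"{prefix}__{value.replace(' ', '_')}" if rank_prefixes
                     else value.replace(" ", "_"))
    if rank_prefixes:
        parts.append(f"g__{db.genus}")
        parts.append(f"s__{assigned_name}")
    else:
        parts.append(db.genus)
        parts.append(assigned_name)
    return ";".join(parts)


def write_reference(db, seqs_path, tax_path, sa_manifest_path=None,
                    tsv_header: bool = False, rank_prefixes: bool = True) -> dict:
    """Write the finalized database as reference FASTA + taxonomy TSV.

    One FASTA entry per unique amplicon, ID = MD5 of the sequence;
    the TSV maps each ID to a semicolon-joined taxon string whose last
    field is ``Genus_Species`` or ``Genus_SAn``.  Entries are sorted by
    feature ID so output is byte-stable.  An optional SA manifest TSV
    lists each shared-amplicon group's member species.
    """
    if not db.entries:
        blame = db.last_emptying_stage() or "input (no amplifiable records)"
        raise ValueError(f"database is empty: everything was removed at stage: {blame}")
    rows = sorted((feature_id(e.sequence), e) for e in db.entries.values())
    with open(seqs_path, "w") as fa:
        for fid, entry in rows:
            fa.write(f">{fid}\n{entry.sequence}\n")
    with open(tax_path, "w") as tsv:
        if tsv_header:
            tsv.write("Feature ID\tTaxon\n")
        for fid, entry in rows:
            tsv.write(f"{fid}\t{_taxon_string(db, entry.assigned_name, rank_prefixes)}\n")
    if sa_manifest_path is not None:
        with open(sa_manifest_path, "w") as sat:
            sat.write("group_id\tn_species\tspecies\n")
            for group in db.sa_groups:
                members = ";".join(sorted(group.members))
                sat.write(f"{db.genus}_SA{group.n}\t{len(group.members)}\t{members}\n")
    return {"n_sequences": len(rows), "n_sa_groups": len(db.sa_groups)}
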