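"""Accession-based lineage verification with an offline cache.

A record's taxonomy is confirmed by querying its accession against the
European Nucleotide Archive browser API and, when ENA yields nothing,
the NCBI Entrez efetch API.  Every result -- including failures -- is
written to a TSV-backed cache so a rebuilt database issues no network
call for accessions already seen, and the whole pipeline runs offline
(records then keep their header-derived lineage, marked unverified).
When an API lineage disagrees with the header, the API wins: the point
of the lookup is verification, so the archive is the authority.
"""

from __future__ import annotations

import logging
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from typing import Callable, Optional

from .seqio import Lineage, _lineage_from_binomial

log = logging.getLogger("asvdb")

ENA_URL = "https://www.ebi.ac.uk/ena/browser/api/embl/{accession}"
NCBI_URL = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
            "?db=nuccore&id={accession}&rettype=gb&retmode=text")

USER_AGENT = "asvdb/0.1 (amplicon reference database builder)"
MIN_REQUEST_INTERVAL = 1.0 / 3.0  # polite: at most 3 requests per second
RETRIES = 3

_last_request_time = 0.0


def _default_transport(url: str, timeout: float = 30.0) -> str:
    """Rate-limited HTTP GET returning the response body as text."""
    global _last_request_time
    wait = MIN_REQUEST_INTERVAL - (time.monotonic() - _last_request_time)
    if wait > 0:
        time.sleep(wait)
    _last_request_time = time.monotonic()
    req = urllib.request.Request(url, headers={"User-Agent": USER_AGENT})
    with urllib.request.urlopen(req, timeout=timeout) as resp:
        return resp.read().decode("utf-8", errors="replace")


def _get_with_retry(transport: Callable[[str], str], url: str) -> Optional[str]:
    delay = 0.5
    for attempt in range(RETRIES):
        try:
            return transport(url)
        except urllib.error.HTTPError as exc:
            if exc.code == 404:
                return None  # definitive miss, no point retrying
            log.warning("HTTP %s from %s (attempt %d/%d)", exc.code, url,
                        attempt + 1, RETRIES)
        except (urllib.error.URLError, OSError, TimeoutError) as exc:
            log.warning("transport failure for %s: %s (attempt %d/%d)", url,
                        exc, attempt + 1, RETRIES)
        if attempt < RETRIES - 1:
            time.sleep(delay)
            delay *= 2
    return None


# ---------------------------------------------------------------------------
# Response parsing
# ---------------------------------------------------------------------------

def parse_embl_lineage(text: str) -> Optional[Lineage]:
    """Lineage from an EMBL flat-file record (ENA): OS organism, OC path."""
    organism = ""
    path: list[str] = []
    for line in text.splitlines():
        if line.startswith("OS "):
            organism = (organism + " " + line[2:].strip()).strip()
        elif line.startswith("OC "):
            path.extend(p.strip().rstrip(".")
                        for p in line[2:].split(";") if p.strip().rstrip("."))
    if not organism:
        return None
    lineage = _lineage_from_binomial(organism) or Lineage(genus=organism)
    lineage.ranks = ([(f"rank{i + 1}", v) for i, v in enumerate(path)]
                     + [("species", organism)])
    return lineage


def parse_genbank_lineage(text: str) -> Optional[Lineage]:
    """Lineage from a GenBank flat-file record (NCBI efetch)."""
    organism = ""
    path: list[str] = []
    lines = text.splitlines()
    for i, line in enumerate(lines):
        if line.strip().startswith("ORGANISM"):
            organism = line.split("ORGANISM", 1)[1].strip()
            for cont in lines[i + 1:]:
                if not cont.startswith(" " * 8):
                    break
                path.extend(p.strip().rstrip(".")
                            for p in cont.split(";") if p.strip().rstrip("."))
            break
    if not organism:
        return None
    lineage = _lineage_from_binomial(organism) or Lineage(genus=organism)
    lineage.ranks = ([(f"rank{i + 1}", v) for i, v in enumerate(path)]
                     + [("species", organism)])
    return lineage


# ---------------------------------------------------------------------------
# Cache
# ---------------------------------------------------------------------------

@dataclass
class LineageCache:
    """File-backed accession -> (lineage, source, timestamp) map.

    Append-only across runs; resolving never overwrites an existing
    verified entry.  The file is plain TSV so it can be inspected,
    diffed and committed.
    """

    path: Optional[str] = None
    _data: dict[str, tuple[Optional[Lineage], str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.path is not None:
            try:
                with open(self.path) as fh:
                    for line in fh:
                        self._load_row(line.rstrip("\n"))
            except FileNotFoundError:
                pass

    def _load_row(self, line: str) -> None:
        if not line or line.startswith("#"):
            return
        fields = line.split("\t")
        if len(fields) != 7:
            log.warning("skipping malformed cache row: %r", line)
            return
        acc, ranks, genus, epithet, is_complex, source, ts = fields
        if source == "failed" and not genus:
            self._data[acc] = (None, source, ts)
            return
        lineage = Lineage(
            ranks=[tuple(item.split("=", 1)) for item in ranks.split(";") if item],
            genus=genus, species_epithet=epithet or None,
            is_complex=is_complex == "1", verified=source)
        self._data[acc] = (lineage, source, ts)

    def get(self, accession: str) -> Optional[tuple[Optional[Lineage], str, str]]:
        return self._data.get(accession)

    def put(self, accession: str, lineage: Optional[Lineage], source: str) -> None:
        if accession in self._data and self._data[accession][1] != "failed":
            return  # never mutate an existing verified entry
        ts = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
        self._data[accession] = (lineage, source, ts)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(self._format_row(accession, lineage, source, ts))

    @staticmethod
    def _format_row(accession, lineage, source, ts) -> str:
        if lineage is None:
            return f"{accession}\t\t\t\t0\t{source}\t{ts}\n"
        ranks = ";".join(f"{r}={v}" for r, v in lineage.ranks)
        return (f"{accession}\t{ranks}\t{lineage.genus}\t"
                f"{lineage.species_epithet or ''}\t"
                f"{1 if lineage.is_complex else 0}\t{source}\t{ts}\n")

    def __len__(self) -> int:
        return len(self._data)

    def __contains__(self, accession: str) -> bool:
        return accession in self._data


# ---------------------------------------------------------------------------
# Resolution
# ---------------------------------------------------------------------------

def resolve_lineage(accession: str, cache: LineageCache, network: bool = True,
                    header_lineage: Optional[Lineage] = None,
                    transport: Optional[Callable[[str], str]] = None) -> Lineage:
    """Resolve one accession's lineage: cache, then ENA, then NCBI.

    With ``network=False`` (or after all lookups fail) the
    header-derived lineage is returned, marked ``unverified`` (or
    ``failed``); a build is never aborted by a lookup problem.
    """
    if not accession:
        raise ValueError("accession must be non-empty")
    hit = cache.get(accession)
    if hit is not None and hit[0] is not None:
        lineage, source, _ts = hit
        lineage.verified = source
        return lineage
    if not network:
        out = header_lineage if header_lineage is not None else Lineage()
        out.verified = "unverified"
        return out
    transport = transport or _default_transport
    text = _get_with_retry(transport, ENA_URL.format(accession=accession))
    lineage = parse_embl_lineage(text) if text else None
    source = "ena"
    if lineage is None:
        text = _get_with_retry(transport, NCBI_URL.format(accession=accession))
        lineage = parse_genbank_lineage(text) if text else None
        source = "ncbi"
    if lineage is None:
        cache.put(accession, None, "failed")
        out = header_lineage if header_lineage is not None else Lineage()
        out.verified = "failed"
        return out
    lineage.verified = source
    if (header_lineage is not None
            and header_lineage.species_label() != lineage.species_label()):
        log.info("lineage for %s: header says %r, %s says %r (using %s)",
                 accession, header_lineage.species_label(), source,
                 lineage.species_label(), source)
    cache.put(accession, lineage, source)
    return lineage


def resolve_all(records, cache: LineageCache, network: bool = True,
                transport: Optional[Callable[[str], str]] = None):
    """Resolve lineages for a list of records in place; returns the list."""
    for rec in records:
        rec.lineage = resolve_lineage(rec.accession, cache, network=network,
                                      header_lineage=rec.lineage,
                                      transport=transport)
    return records
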