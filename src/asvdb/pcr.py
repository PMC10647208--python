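"""In-silico PCR: primer alignment and amplicon extraction.

Locates primer binding sites on a template with a glocal affine-gap
alignment (the whole primer must align; the template contributes a free
local window) under a scoring scheme that favours mismatches over gaps:
match +1, mismatch 0, gap-open -1, gap-extend -0.5.  IUPAC ambiguity
codes in the *primer* expand to match sets; ambiguity in the *template*
scores as a mismatch.  A hit yields an amplicon only if both primers
reach the score threshold and their last three 3' alignment columns are
exact matches (no mismatch, no gap) -- the polymerase-extension rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

log = logging.getLogger("asvdb")

# ---------------------------------------------------------------------------
# IUPAC tables
# ---------------------------------------------------------------------------

IUPAC_EXPAND: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "S": "S", "W": "W", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

MATCH = 1.0
MISMATCH = 0.0
GAP_OPEN = -1.0
GAP_EXTEND = -0.5


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (upper-case output)."""
    out = []
    for i, base in enumerate(seq.upper()):
        comp = IUPAC_COMPLEMENT.get(base)
        if comp is None:
            raise ValueError(f"non-IUPAC character {base!r} at position {i}")
        out.append(comp)
    return "".join(reversed(out))


def _validate_iupac(seq: str, what: str) -> str:
    seq = seq.upper()
    for i, b in enumerate(seq):
        if b not in IUPAC_EXPAND:
            raise ValueError(f"non-IUPAC character {b!r} at position {i} of {what}")
    return seq


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with matching parameters.

    ``threshold`` is the fraction of a primer's maximum alignment score
    (its length, since match = +1) that a hit must reach; it is a
    fraction so the same setting is comparable across primers of
    different lengths.  ``keep_primers`` controls whether the extracted
    amplicon spans the primer sites or only the insert between them.
    """

    forward: str
    reverse: str
    threshold: float = 0.9
    keep_primers: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", _validate_iupac(self.forward, "forward primer"))
        object.__setattr__(self, "reverse", _validate_iupac(self.reverse, "reverse primer"))
        if len(self.forward) < 10 or len(self.reverse) < 10:
            raise ValueError("primers must be at least 10 nt long")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


@dataclass(frozen=True)
class AlignmentHit:
    """Best glocal alignment of one primer on a template.

    ``columns`` classifies every alignment column, 5'->3' along the
    primer as aligned, as one of ``match``, ``mismatch``,
    ``gap_primer`` (template base opposite a gap in the primer) or
    ``gap_template`` (primer base opposite a gap in the template).
    """

    score: float
    start: int  # 0-based inclusive template position
    end: int    # 0-based exclusive template position
    columns: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class Amplicon:
    sequence: str
    source_accession: str
    start: int
    end: int
    includes_primers: bool
    fwd_hit: AlignmentHit
    rev_hit: AlignmentHit
    strand: str = "+"


# ---------------------------------------------------------------------------
# Glocal affine-gap alignment (Gotoh, three states)
# ---------------------------------------------------------------------------

_NEG = float("-inf")


def align_primer(primer: str, template: str) -> AlignmentHit:
    """Best glocal affine-gap alignment of ``primer`` on ``template``.

    The full primer is consumed; any template prefix/suffix outside the
    aligned window is free.  Ties are broken toward the smallest start,
    then the shortest aligned span, so output is deterministic.
    """
    primer = _validate_iupac(primer, "primer")
    template = _validate_iupac(template, "template")
    if not template:
        raise ValueError("empty template")
    if not primer:
        raise ValueError("empty primer")

    m, n = len(primer), len(template)
    expand = [IUPAC_EXPAND[b] for b in primer]

    # State matrices over (primer index i, template index j):
    #   M: last column is diagonal (match/mismatch)
    #   X: last column is a gap in the template (primer base vs '-')
    #   Y: last column is a gap in the primer (template base vs '-')
    M = [[_NEG] * (n + 1) for _ in range(m + 1)]
    X = [[_NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[_NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        M[0][j] = 0.0  # free template prefix: alignment may start anywhere
    for i in range(1, m + 1):
        X[i][0] = GAP_OPEN + GAP_EXTEND * (i - 1)

    for i in range(1, m + 1):
        exp_i = expand[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, n + 1):
            s = MATCH if template[j - 1] in exp_i else MISMATCH
            best_prev = Mp[j - 1]
            if Xp[j - 1] > best_prev:
                best_prev = Xp[j - 1]
            if Yp[j - 1] > best_prev:
                best_prev = Yp[j - 1]
            Mi[j] = best_prev + s
            Xi[j] = max(Mp[j] + GAP_OPEN, Xp[j] + GAP_EXTEND)
            Yi[j] = max(Mi[j - 1] + GAP_OPEN, Yi[j - 1] + GAP_EXTEND)

    # Final score: primer fully consumed, free template suffix.  An
    # alignment may end in a template gap (trailing unaligned primer
    # bases); ending in a primer gap is never beneficial and only
    # widens the span, so it is excluded.
    best = _NEG
    for j in range(n + 1):
        if M[m][j] > best:
            best = M[m][j]
        if X[m][j] > best:
            best = X[m][j]

    candidates = []
    for j in range(n + 1):
        for state in ("M", "X"):
            if (M[m][j] if state == "M" else X[m][j]) == best:
                start, cols = _traceback(primer, template, M, X, Y, j, state)
                candidates.append((start, j - start, j, cols))
    start, _span, end, cols = min(candidates, key=lambda c: (c[0], c[1], c[2]))
    return AlignmentHit(score=best, start=start, end=end, columns=tuple(cols))


def _traceback(primer, template, M, X, Y, j, state):
    expand = IUPAC_EXPAND
    i = len(primer)
    cols: list[str] = []
    while i > 0:
        if state == "M":
            s = MATCH if (j > 0 and template[j - 1] in expand[primer[i - 1]]) else MISMATCH
            cols.append("match" if s == MATCH else "mismatch")
            target = M[i][j] - s
            i, j = i - 1, j - 1
            for prev in ("M", "X", "Y"):
                val = {"M": M, "X": X, "Y": Y}[prev][i][j]
                if val == target:
                    state = prev
                    break
        elif state == "X":
            cols.append("gap_template")
            if M[i - 1][j] + GAP_OPEN == X[i][j]:
                state = "M"
            else:
                state = "X"
            i -= 1
        else:  # Y: gap in primer, consumes a template base
            cols.append("gap_primer")
            if M[i][j - 1] + GAP_OPEN == Y[i][j]:
                state = "M"
            else:
                state = "Y"
            j -= 1
        if state == "M" and i == 0:
            break
    cols.reverse()
    return j, cols


# ---------------------------------------------------------------------------
# Amplification simulation
# ---------------------------------------------------------------------------

def _three_prime_ok(columns: tuple[str, ...], at_start: bool) -> bool:
    """Last three 3' columns must be exact matches (no mismatch/gap).

    For the forward primer the 3' end is the last three columns; for
    the reverse primer, aligned as its reverse complement in template
    orientation, the 3' end is the first three columns.
    """
    if len(columns) < 3:
        return False
    picked = columns[:3] if at_start else columns[-3:]
    return all(c == "match" for c in picked)


def _try_strand(template: str, primers: PrimerPair) -> Optional[tuple]:
    fwd = align_primer(primers.forward, template)
    if fwd.score < primers.threshold * len(primers.forward):
        return None
    if not _three_prime_ok(fwd.columns, at_start=False):
        return None
    downstream = template[fwd.end:]
    if not downstream:
        return None
    rc_rev = reverse_complement(primers.reverse)
    rev = align_primer(rc_rev, downstream)
    if rev.score < primers.threshold * len(primers.reverse):
        return None
    if not _three_prime_ok(rev.columns, at_start=True):
        return None
    rev = AlignmentHit(score=rev.score, start=rev.start + fwd.end,
                       end=rev.end + fwd.end, columns=rev.columns)
    return fwd, rev


def simulate_pcr(sequence: str, primers: PrimerPair, accession: str = "",
                 try_reverse_strand: bool = True) -> Optional[Amplicon]:
    """Simulate amplification of ``sequence`` with ``primers``.

    Returns the single best amplicon, or None when either primer fails
    the score threshold or the 3'-anchor rule.  When the forward-strand
    pass yields nothing the reverse complement of the template is tried
    (public-database entries are deposited in either orientation);
    coordinates are then reported on the minus strand.
    """
    template = _validate_iupac(sequence, f"sequence {accession or '<anonymous>'}")
    for strand in ("+", "-") if try_reverse_strand else ("+",):
        tpl = template if strand == "+" else reverse_complement(template)
        hits = _try_strand(tpl, primers)
        if hits is None:
            continue
        fwd, rev = hits
        if primers.keep_primers:
            start, end = fwd.start, rev.end
        else:
            start, end = fwd.end, rev.start
        if end - start < 1:
            log.debug("degenerate amplicon (primers abut/overlap) on %s", accession)
            continue
        return Amplicon(sequence=tpl[start:end], source_accession=accession,
                        start=start, end=end,
                        includes_primers=primers.keep_primers,
                        fwd_hit=fwd, rev_hit=rev, strand=strand)
    return None


# ---------------------------------------------------------------------------
# Primer presets
# ---------------------------------------------------------------------------

def load_presets() -> dict[str, str]:
    """Named primer sequences shipped with the package."""
    text = resources.files("asvdb").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def primer_pair_from_presets(forward_name: str, reverse_name: str,
                             threshold: float = 0.9,
                             keep_primers: bool = False) -> PrimerPair:
    presets = load_presets()
    try:
        fwd = presets[forward_name]
        rev = presets[reverse_name]
    except KeyError as exc:
        raise KeyError(f"unknown primer preset {exc.args[0]!r}; "
                       f"available: {', '.join(sorted(presets))}") from exc
    return PrimerPair(forward=fwd, reverse=rev, threshold=threshold,
                      keep_primers=keep_primers)
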