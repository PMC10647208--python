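"""Independent alignment oracles used to cross-check the aligner.

Two routes, neither sharing code with the implementation:

* :func:`biopython_glocal_score` -- Biopython's PairwiseAligner in
  global mode with free query end gaps, i.e. the full primer against a
  free local template window, with an IUPAC-expansion substitution
  matrix (match +1 when the template base is in the primer code's
  match set, else 0) and affine gaps (open -1, extend -0.5).
* :func:`enumerate_glocal_score` -- exhaustive recursive enumeration of
  every alignment path, feasible only for tiny instances.
"""

import functools

from Bio import Align
from Bio.Align import substitution_matrices

_ALPHABET = "ACGTRYSWKMBDHVN"
_EXPAND = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
           "S": "GC", "W": "AT", "K": "GT", "M": "AC", "B": "CGT",
           "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT"}


@functools.lru_cache(maxsize=1)
def _aligner():
    mat = substitution_matrices.Array(_ALPHABET, dims=2)
    for p in _ALPHABET:
        for t in _ALPHABET:
            mat[t, p] = 1.0 if t in _EXPAND[p] else 0.0  # [template, primer]
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = mat
    a.open_gap_score = -1.0
    a.extend_gap_score = -0.5
    a.end_deletion_score = 0.0  # template prefix/suffix are free
    return a


def biopython_glocal_score(primer: str, template: str) -> float:
    return _aligner().score(template, primer)


def enumerate_glocal_score(primer: str, template: str) -> float:
    """Brute force over all alignment paths (primer fully consumed)."""
    m, n = len(primer), len(template)
    best = [float("-inf")]

    def rec(i, j, score, last):
        if score + (m - i) <= best[0]:  # optimistic bound: all matches
            return
        if i == m:
            best[0] = max(best[0], score)
            return
        if j < n:
            s = 1.0 if template[j] in _EXPAND[primer[i]] else 0.0
            rec(i + 1, j + 1, score + s, "D")
        rec(i + 1, j, score + (-0.5 if last == "X" else -1.0), "X")
        if j < n and i > 0:
            rec(i, j + 1, score + (-0.5 if last == "Y" else -1.0), "Y")

    for start in range(n + 1):
        rec(0, start, 0.0, "D")
    return best[0]
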