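"""Protein alignment scoring shared by the anchor search and role assignment.

Scoring follows standard protein-search defaults: BLOSUM62, affine gaps with
open 11 / extend 1 (a gap of length k costs 11 + k).  Two local deviations
from the stock matrix:

* ``X`` (the translation of any N-containing codon) scores 0 against every
  residue, so ambiguous positions neither help nor hurt.
* ``*`` (stop sentinel in translated frames) scores -1000 against everything,
  so a local alignment never reads through an in-frame stop codon.  A gene
  split by an internal stop therefore produces two separate hits, which
  `mbnmine.anchors.merge_split_hits` can bridge.

Expectation values use Karlin-Altschul statistics with the standard gapped
BLOSUM62 constants (lambda = 0.267, K = 0.041).
"""
from __future__ import annotations

import math
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

GAP_OPEN = 11
GAP_EXTEND = 1
KA_LAMBDA = 0.267
KA_K = 0.041
LN2 = math.log(2.0)

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
STOP_PENALTY = -1000.0


@lru_cache(maxsize=None)
def scoring_matrix():
    """BLOSUM62 with the X and ``*`` adjustments described in the module docstring."""
    m = substitution_matrices.load("BLOSUM62")
    for c in m.alphabet:
        m["X", c] = 0.0
        m[c, "X"] = 0.0
        if c != "*":
            m["*", c] = STOP_PENALTY
            m[c, "*"] = STOP_PENALTY
    return m


def _make_aligner(mode: str) -> PairwiseAligner:
    a = PairwiseAligner()
    a.substitution_matrix = scoring_matrix()
    a.mode = mode
    # Biopython charges open_gap_score on the first gapped position, so
    # BLAST-style 11/1 (cost 11 + k) maps to open -12, extend -1.
    a.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    a.extend_gap_score = -GAP_EXTEND
    return a


@lru_cache(maxsize=None)
def local_aligner() -> PairwiseAligner:
    return _make_aligner("local")


@lru_cache(maxsize=None)
def global_aligner() -> PairwiseAligner:
    return _make_aligner("global")


def local_score(target: str, query: str) -> float:
    """Smith-Waterman score of query against target (affine gaps, BLOSUM62)."""
    if not target or not query:
        return 0.0
    return float(local_aligner().score(target, query))


def best_local_alignment(target: str, query: str):
    """Best local alignment; returns (score, (tstart, tend), (qstart, qend), q_covered).

    ``q_covered`` is the number of query positions inside aligned (non-gap)
    columns, used for the aligned-fraction bookkeeping.  Returns None when no
    positive-scoring alignment exists.
    """
    if not target or not query:
        return None
    alns = local_aligner().align(target, query)
    if len(alns) == 0 or alns.score <= 0:
        return None
    al = alns[0]
    tblocks, qblocks = al.aligned
    tstart, tend = int(tblocks[0][0]), int(tblocks[-1][1])
    qstart, qend = int(qblocks[0][0]), int(qblocks[-1][1])
    covered = int(sum(b[1] - b[0] for b in qblocks))
    return float(al.score), (tstart, tend), (qstart, qend), covered


def bitscore(raw: float) -> float:
    return (KA_LAMBDA * raw - math.log(KA_K)) / LN2


def evalue(raw: float, m: int, n: int) -> float:
    """Karlin-Altschul expectation for raw score over an m x n search space."""
    return m * n * math.pow(2.0, -bitscore(raw))


def evalue_threshold_score(e: float, m: int, n: int) -> float:
    """Smallest raw score whose expectation is below ``e`` (for early exits)."""
    return (math.log(KA_K * m * n / e)) / KA_LAMBDA
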