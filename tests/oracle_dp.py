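"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (plain
dynamic programming, exhaustive scans, explicit path sums) and never calls
into the package's alignment/enumeration code paths.
"""
from __future__ import annotations

import random

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

GAP_FIRST = 12  # BLAST-style open 11 / extend 1: gap of length k costs 11 + k
GAP_EXT = 1

NEG = float("-inf")


def local_affine_score(a: str, b: str) -> float:
    """Smith-Waterman with affine gaps, three-state DP, BLOSUM62."""
    n, m = len(a), len(b)
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, M[i - 1][j - 1] + s, X[i - 1][j - 1] + s, Y[i - 1][j - 1] + s)
            X[i][j] = max(M[i - 1][j] - GAP_FIRST, X[i - 1][j] - GAP_EXT, Y[i - 1][j] - GAP_FIRST)
            Y[i][j] = max(M[i][j - 1] - GAP_FIRST, Y[i][j - 1] - GAP_EXT, X[i][j - 1] - GAP_FIRST)
            best = max(best, M[i][j])
    return best


def global_affine_score(a: str, b: str) -> float:
    """Needleman-Wunsch with affine gaps (end gaps penalized), BLOSUM62."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -GAP_FIRST - GAP_EXT * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = -GAP_FIRST - GAP_EXT * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - GAP_FIRST, X[i - 1][j] - GAP_EXT, Y[i - 1][j] - GAP_FIRST)
            Y[i][j] = max(M[i][j - 1] - GAP_FIRST, Y[i][j - 1] - GAP_EXT, X[i][j - 1] - GAP_FIRST)
    return max(M[n][m], X[n][m], Y[n][m])


# ---------------------------------------------------------------------------
# Exhaustive small-ORF enumeration
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")
_STOPS = ("TAA", "TAG", "TGA")

_CODON_TO_AA = None


def _codon_table():
    global _CODON_TO_AA
    if _CODON_TO_AA is None:
        from Bio.Data import CodonTable

        t = CodonTable.unambiguous_dna_by_id[11]
        _CODON_TO_AA = dict(t.forward_table)
    return _CODON_TO_AA


def brute_force_orfs(window: str, start_codons, lo: int, hi):
    """Every (strand, start, end_incl_stop, peptide) small ORF in a window by
    scanning all start positions and walking codons to the first stop; nested
    starts sharing a stop collapse to the longest in-bounds start.

    Coordinates are forward-strand offsets into ``window``.
    """
    table = _codon_table()
    W = len(window)
    per_stop = {}
    for strand in "+-":
        s = window if strand == "+" else window.translate(_COMP)[::-1]
        for i in range(W - 2):
            if s[i : i + 3] not in start_codons:
                continue
            j = i + 3
            stop = None
            while j + 3 <= W:
                if s[j : j + 3] in _STOPS:
                    stop = j
                    break
                j += 3
            if stop is None:
                continue
            n_aa = (stop - i) // 3
            if not (lo <= n_aa <= (hi if hi is not None else n_aa)):
                continue
            pep = "M" + "".join(
                table.get(s[k : k + 3], "X") for k in range(i + 3, stop, 3)
            )
            if strand == "+":
                w0, w3 = i, stop + 3
            else:
                w0, w3 = W - (stop + 3), W - i
            key = (strand, stop)
            if key not in per_stop or per_stop[key][0] < n_aa:
                per_stop[key] = (n_aa, (strand, w0, w3, pep))
    return sorted(v for _n, v in per_stop.values())


# ---------------------------------------------------------------------------
# Random additive trees for NJ consistency checks
# ---------------------------------------------------------------------------

def random_additive_tree(n_taxa: int, rng: random.Random):
    """Build a random binary tree; returns (ids, distance_matrix) where the
    matrix holds exact leaf-to-leaf path lengths (hence additive)."""
    ids = [f"t{i}" for i in range(n_taxa)]
    # node -> parent, edge length; build by sequentially joining subtrees
    nodes = {i: None for i in range(n_taxa)}
    parent = {}
    elen = {}
    free = list(range(n_taxa))
    nxt = n_taxa
    while len(free) > 1:
        a = free.pop(rng.randrange(len(free)))
        b = free.pop(rng.randrange(len(free)))
        p = nxt
        nxt += 1
        parent[a], parent[b] = p, p
        elen[a] = round(rng.uniform(0.1, 1.0), 3)
        elen[b] = round(rng.uniform(0.1, 1.0), 3)
        free.append(p)
        nodes[p] = None

    def path_to_root(x):
        out = {}
        d = 0.0
        while x in parent:
            out[x] = d
            d += elen[x]
            x = parent[x]
        out[x] = d
        return out

    dist = [[0.0] * n_taxa for _ in range(n_taxa)]
    for i in range(n_taxa):
        pi = path_to_root(i)
        for j in range(i + 1, n_taxa):
            pj = path_to_root(j)
            common = min(pi[k] + pj[k] for k in pi if k in pj)
            dist[i][j] = dist[j][i] = common
    return ids, dist
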