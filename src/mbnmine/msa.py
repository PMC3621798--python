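"""Multiple alignment and neighbor-joining trees for Mbn protein families.

Progressive alignment in the classic style: pairwise global alignments give
p-distances, a neighbor-joining guide tree orders the merges, and profiles
are merged along the tree with an affine-gap profile-profile DP under
BLOSUM62 expected scores.  Trees for family organization use the standard
neighbor-joining agglomeration (scikit-bio's implementation for >= 3 taxa)
with Newick serialization.
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from . import align as _align

GAP = "-"
GAP_OPEN = -12.0
GAP_EXTEND = -1.0
NEG_INF = float("-inf")


@dataclass
class Alignment:
    ids: list
    rows: list

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must correspond")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("all alignment rows must have equal length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{r}\n" for i, r in zip(self.ids, self.rows))

    def to_stockholm(self) -> str:
        out = ["# STOCKHOLM 1.0"]
        width = max(len(i) for i in self.ids) + 2
        for i, r in zip(self.ids, self.rows):
            out.append(f"{i:<{width}}{r}")
        out.append("//")
        return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Pairwise and profile-profile global alignment
# ---------------------------------------------------------------------------

def _col_freqs(rows, j):
    freqs: dict = {}
    for r in rows:
        c = r[j]
        if c != GAP:
            freqs[c] = freqs.get(c, 0) + 1
    n = len(rows)
    return {a: k / n for a, k in freqs.items()}


def _profile_cols(rows):
    return [_col_freqs(rows, j) for j in range(len(rows[0]))] if rows[0] else []


def _col_score(fa, fb, matrix):
    s = 0.0
    for a, pa in fa.items():
        for b, pb in fb.items():
            s += pa * pb * matrix[a, b]
    return s


def _profile_align(rows_a, rows_b, matrix):
    """Global affine-gap DP over profile columns; returns merged rows."""
    ca, cb = _profile_cols(rows_a), _profile_cols(rows_b)
    n, m = len(ca), len(cb)
    S = np.zeros((n + 1, m + 1))
    for i in range(n):
        for j in range(m):
            S[i, j] = _col_score(ca[i], cb[j], matrix)
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # gap in B (A column vs gap)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + S[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND,
                          Y[i - 1, j] + GAP_OPEN)
            Y[i, j] = max(M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXTEND,
                          X[i, j - 1] + GAP_OPEN)
    # traceback
    i, j = n, m
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    score = float(max(M[i, j], X[i, j], Y[i, j]))
    path = []
    while i > 0 or j > 0:
        if state == 0:
            path.append("M")
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev)) if (i > 0 or j > 0) else 0
        elif state == 1:
            path.append("X")
            cands = [M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND,
                     Y[i - 1, j] + GAP_OPEN]
            i -= 1
            state = int(np.argmax(cands))
        else:
            path.append("Y")
            cands = [M[i, j - 1] + GAP_OPEN, X[i, j - 1] + GAP_OPEN,
                     Y[i, j - 1] + GAP_EXTEND]
            j -= 1
            state = int(np.argmax(cands))
        if i == 0 and j == 0:
            break
    path.reverse()
    new_a = ["" for _ in rows_a]
    new_b = ["" for _ in rows_b]
    ia = ja = 0
    for step in path:
        if step == "M":
            for k, r in enumerate(rows_a):
                new_a[k] += r[ia]
            for k, r in enumerate(rows_b):
                new_b[k] += r[ja]
            ia += 1
            ja += 1
        elif step == "X":
            for k, r in enumerate(rows_a):
                new_a[k] += r[ia]
            for k in range(len(rows_b)):
                new_b[k] += GAP
            ia += 1
        else:
            for k in range(len(rows_a)):
                new_a[k] += GAP
            for k, r in enumerate(rows_b):
                new_b[k] += r[ja]
            ja += 1
    return new_a + new_b, score


def pairwise_global(a: str, b: str):
    """Needleman-Wunsch with BLOSUM62 and affine 11/1 gaps; returns
    (score, aligned_a, aligned_b)."""
    matrix = _align.scoring_matrix()
    rows, score = _profile_align([a], [b], matrix)
    return score, rows[0], rows[1]


def p_distance(aligned_a: str, aligned_b: str) -> float:
    """Fraction of mismatching residues over columns where both rows have a
    residue (1.0 when no such column exists)."""
    both = [(x, y) for x, y in zip(aligned_a, aligned_b) if x != GAP and y != GAP]
    if not both:
        return 1.0
    return sum(1 for x, y in both if x != y) / len(both)


def align_progressive(seqs, ids=None, matrix=None) -> Alignment:
    """Progressive multiple alignment (NJ guide tree, profile merges)."""
    if not seqs:
        raise ValueError("no sequences to align")
    ids = list(ids) if ids is not None else [f"seq{i+1}" for i in range(len(seqs))]
    matrix = matrix if matrix is not None else _align.scoring_matrix()
    if len(seqs) == 1:
        return Alignment(ids, [seqs[0]])
    if len(seqs) == 2:
        _s, ra, rb = pairwise_global(seqs[0], seqs[1])
        return Alignment(ids, [ra, rb])

    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _s, ra, rb = pairwise_global(seqs[i], seqs[j])
            d[i, j] = d[j, i] = p_distance(ra, rb)
    guide = nj_tree(d, ids=[str(k) for k in range(n)])
    root = guide.skbio_tree()

    def merge(node):
        if node.is_tip():
            k = int(node.name)
            return [k], [seqs[k]]
        idx, rows = merge(node.children[0])
        for child in node.children[1:]:
            idx2, rows2 = merge(child)
            rows, _sc = _profile_align(rows, rows2, matrix)
            idx = idx + idx2
        return idx, rows

    order, rows = merge(root)
    # restore input order
    by_index = dict(zip(order, rows))
    return Alignment(ids, [by_index[k] for k in range(n)])


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class Tree:
    """A (generally unrooted) tree with branch lengths, held as Newick."""

    newick: str

    def skbio_tree(self) -> TreeNode:
        return TreeNode.read(_io.StringIO(self.newick))

    def leaves(self) -> list:
        return sorted(t.name for t in self.skbio_tree().tips())

    def tip_distance(self, a: str, b: str) -> float:
        t = self.skbio_tree()
        return float(t.find(a).distance(t.find(b)))

    def __str__(self) -> str:
        return self.newick


def nj_tree(dist, ids=None) -> Tree:
    """Neighbor-joining tree from a symmetric zero-diagonal distance matrix.

    Negative branch lengths are clamped to zero.  Two taxa produce the single
    edge split evenly; fewer than two is an error.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least two taxa")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    ids = list(ids) if ids is not None else [f"t{i+1}" for i in range(n)]
    if n == 2:
        h = dist[0, 1] / 2.0
        return Tree(f"({ids[0]}:{h:g},{ids[1]}:{h:g});")
    dm = DistanceMatrix(dist, ids)
    tree = _skbio_nj(dm, neg_as_zero=True)
    return Tree(str(tree).strip())
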