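"""Pairwise and progressive multiple alignment.

Global Needleman-Wunsch with affine gaps is the workhorse used both for
building seed alignments and for realigning curated homolog sets.  The gap
convention is fixed as: a gap of length L costs ``GOC + (L-1) * GEC``, and
terminal gaps are charged (true global alignment).  Ties are broken
deterministically: prefer an aligned pair, then a gap in the second
sequence, then a gap in the first.

The progressive stage is a guide-tree-ordered profile-profile alignment
with average-of-pairs column scoring; score-optimality is contractual only
for the pairwise steps.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import AA_ALPHABET, GAP_CHARS, Msa, ProteinRecord
from .trees import DistanceMatrix, Tree, TreeNode, neighbor_joining

# extended alphabet used for scoring: 20 residues + ambiguity X
SCORING_ALPHABET = AA_ALPHABET + "X"
_CHAR_INDEX = {c: i for i, c in enumerate(SCORING_ALPHABET)}

NEG = -1e30


@functools.lru_cache(maxsize=None)
def load_matrix(name: str) -> np.ndarray:
    """A named substitution matrix as a 21x21 integer table over
    ``ACDEFGHIKLMNPQRSTVWYX`` (X rows taken from the source matrix)."""
    src = substitution_matrices.load(name.upper())
    alpha = src.alphabet
    out = np.zeros((21, 21))
    for i, a in enumerate(SCORING_ALPHABET):
        for j, b in enumerate(SCORING_ALPHABET):
            if a in alpha and b in alpha:
                out[i, j] = src[a, b]
    return out


@dataclass
class AlignParams:
    """Alignment parameters: substitution matrix plus affine gap costs
    (gap opening cost GOC, gap extension cost GEC, both positive)."""

    matrix: str = "blosum62"
    gap_open_cost: float = 15.0
    gap_extend_cost: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open_cost <= 0 or self.gap_extend_cost <= 0:
            raise ValueError("gap costs must be positive")
        m = load_matrix(self.matrix)
        if not np.array_equal(m, m.T):
            raise ValueError(f"substitution matrix {self.matrix} is not symmetric")

    @property
    def score_table(self) -> np.ndarray:
        return load_matrix(self.matrix)


@dataclass
class PairwiseAlignment:
    gapped_a: str
    gapped_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("aligned strings must have equal length")


def _affine_dp(S: np.ndarray, goc: float, gec: float):
    """Fill M/X/Y matrices for the affine model over a precomputed
    position-score matrix S (n x m).

    M ends in an aligned pair, X in a column consuming a row of the first
    input (gap in the second), Y the converse.
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(goc + (i - 1) * gec)
    for j in range(1, m + 1):
        Y[0, j] = -(goc + (j - 1) * gec)
    js = np.arange(m + 1)
    for i in range(1, n + 1):
        M[i, 1:] = S[i - 1, :] + np.maximum.reduce(
            [M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]]
        )
        X[i, 1:] = np.maximum.reduce(
            [M[i - 1, 1:] - goc, X[i - 1, 1:] - gec, Y[i - 1, 1:] - goc]
        )
        if i > 1:
            X[i, 0] = X[i - 1, 0] - gec
        # Y within-row recurrence via weighted running max:
        # Y[i,j] = max_{j'<j} max(M,X)[i,j'] - (goc + (j-j'-1)*gec)
        W = np.maximum(M[i, :], X[i, :]) + gec * js
        run = np.maximum.accumulate(W[:-1])
        cand = run - goc - (js[1:] - 1) * gec
        Y[i, 1:] = np.maximum(Y[i, 1:], cand)
    return M, X, Y


def _traceback(S, M, X, Y, goc, gec):
    n, m = S.shape
    i, j = n, m
    # state preference: aligned pair (M), gap in second (X), gap in first (Y)
    cands = [M[i, j], X[i, j], Y[i, j]]
    state = int(np.argmax(cands))  # argmax returns first max -> preference order
    ops: list[str] = []  # 'D' aligned, 'A' consume first (gap in second), 'B' consume second
    while i > 0 or j > 0:
        if state == 0:
            ops.append("D")
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:
            ops.append("A")
            prev = [M[i - 1, j] - goc, X[i - 1, j] - gec, Y[i - 1, j] - goc]
            i -= 1
            state = int(np.argmax(prev))
        else:
            ops.append("B")
            prev = [M[i, j - 1] - goc, X[i, j - 1] - goc, Y[i, j - 1] - gec]
            j -= 1
            state = int(np.argmax(prev))
    ops.reverse()
    return ops


def _seq_to_indices(seq: str) -> np.ndarray:
    return np.array([_CHAR_INDEX[c] for c in seq], dtype=int)


def global_align(a: str, b: str, params: AlignParams | None = None) -> PairwiseAlignment:
    """Optimal global alignment of two sequences under the affine model."""
    params = params or AlignParams()
    if isinstance(a, ProteinRecord):
        a = a.sequence
    if isinstance(b, ProteinRecord):
        b = b.sequence
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    tab = params.score_table
    S = tab[np.ix_(_seq_to_indices(a), _seq_to_indices(b))]
    M, X, Y = _affine_dp(S, params.gap_open_cost, params.gap_extend_cost)
    score = float(max(M[-1, -1], X[-1, -1], Y[-1, -1]))
    ops = _traceback(S, M, X, Y, params.gap_open_cost, params.gap_extend_cost)
    ga, gb = [], []
    ia = ib = 0
    for op in ops:
        if op == "D":
            ga.append(a[ia]); gb.append(b[ib]); ia += 1; ib += 1
        elif op == "A":
            ga.append(a[ia]); gb.append("-"); ia += 1
        else:
            ga.append("-"); gb.append(b[ib]); ib += 1
    return PairwiseAlignment("".join(ga), "".join(gb), score)


def _pair_p_distance(aln: PairwiseAlignment) -> float:
    comp = mism = 0
    for x, y in zip(aln.gapped_a, aln.gapped_b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        comp += 1
        if x != y:
            mism += 1
    return mism / comp if comp else 1.0


def _normalize_inputs(seqs) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    for i, s in enumerate(seqs):
        if isinstance(s, ProteinRecord):
            out.append((s.id, s.sequence))
        elif isinstance(s, tuple):
            out.append((s[0], s[1]))
        else:
            out.append((f"s{i:04d}", s))
    if len({rid for rid, _ in out}) != len(out):
        raise ValueError("duplicate sequence ids")
    return out


def guide_tree(seqs, params: AlignParams | None = None) -> Tree:
    """NJ guide tree on pairwise p-distances from global alignments."""
    params = params or AlignParams()
    items = _normalize_inputs(seqs)
    if len(items) < 2:
        raise ValueError("guide_tree requires >= 2 sequences")
    n = len(items)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pair_p_distance(
                global_align(items[i][1], items[j][1], params)
            )
    return neighbor_joining(DistanceMatrix([rid for rid, _ in items], d))


def _profile_counts(rows: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-column residue count matrix (L x 21) and non-gap counts (L,)."""
    L = len(rows[0])
    counts = np.zeros((L, 21))
    for row in rows:
        for j, c in enumerate(row):
            if c not in GAP_CHARS:
                counts[j, _CHAR_INDEX[c]] += 1
    return counts, counts.sum(axis=1)


def _profile_align(rows_a: list[str], rows_b: list[str], params: AlignParams):
    """Align two profiles; column score = mean substitution score over all
    non-gap residue pairs (0 where a column is all gaps)."""
    tab = params.score_table
    ca, na = _profile_counts(rows_a)
    cb, nb = _profile_counts(rows_b)
    denom = np.outer(na, nb)
    S = ca @ tab @ cb.T
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denom > 0, S / np.maximum(denom, 1e-300), 0.0)
    M, X, Y = _affine_dp(S, params.gap_open_cost, params.gap_extend_cost)
    ops = _traceback(S, M, X, Y, params.gap_open_cost, params.gap_extend_cost)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("D", "A"):
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
        if op in ("D", "B"):
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += "-"
    return out_a, out_b


def progressive_msa(seqs, params: AlignParams | None = None) -> Msa:
    """Progressive multiple alignment along an NJ guide tree.

    Two sequences reduce exactly to :func:`global_align`; every input is
    recoverable by ungapping its row.
    """
    params = params or AlignParams()
    items = _normalize_inputs(seqs)
    if len(items) < 2:
        raise ValueError("progressive_msa requires >= 2 sequences")
    by_id = dict(items)
    if len(items) == 2:
        (ida, sa), (idb, sb) = items
        aln = global_align(sa, sb, params)
        return Msa([(ida, aln.gapped_a), (idb, aln.gapped_b)])
    tree = guide_tree(items, params)

    def merge(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_leaf():
            return [node.label], [by_id[node.label]]
        ids, rows = merge(node.children[0])
        for child in node.children[1:]:
            ids_b, rows_b = merge(child)
            rows, rows_b = _profile_align(rows, rows_b, params)
            ids = ids + ids_b
            rows = rows + rows_b
        return ids, rows

    ids, rows = merge(tree.root)
    order = {rid: k for k, rid in enumerate(ids)}
    records = sorted(zip(ids, rows), key=lambda kv: [r for r, _ in items].index(kv[0]))
    return Msa(records)
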