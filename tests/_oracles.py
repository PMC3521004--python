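"""Independent brute-force oracles used by the property and acceptance
tests: exhaustive enumeration over alignments and HMM state paths, and a
position-by-position motif check.  These deliberately share no code with
the implementations they verify."""

from __future__ import annotations

import math

import numpy as np

from curliscan.io_formats import AA_INDEX
from curliscan.phmm import (
    ProfileHMM,
    T_DD,
    T_DM,
    T_II,
    T_IM,
    T_MD,
    T_MI,
    T_MM,
)


def brute_force_global_align(a: str, b: str, score, goc: float, gec: float) -> float:
    """Maximum score over every global alignment, enumerating all monotone
    op sequences and charging each gap run goc + (len-1)*gec."""
    best = -math.inf
    ops: list[str] = []

    def total() -> float:
        s = 0.0
        ia = ib = 0
        run = None
        runlen = 0
        for op in ops + ["end"]:
            if op == run:
                runlen += 1
            else:
                if run in ("A", "B"):
                    s -= goc + (runlen - 1) * gec
                run, runlen = op, 1
            if op == "D":
                s += score(a[ia], b[ib])
                ia += 1
                ib += 1
            elif op == "A":
                ia += 1
            elif op == "B":
                ib += 1
        return s

    def rec(ia: int, ib: int) -> None:
        nonlocal best
        if ia == len(a) and ib == len(b):
            best = max(best, total())
            return
        if ia < len(a) and ib < len(b):
            ops.append("D"); rec(ia + 1, ib + 1); ops.pop()
        if ia < len(a):
            ops.append("A"); rec(ia + 1, ib); ops.pop()
        if ib < len(b):
            ops.append("B"); rec(ia, ib + 1); ops.pop()

    rec(0, 0)
    return best


def brute_force_hmm_scores(hmm: ProfileHMM, seq: str) -> tuple[float, float]:
    """(viterbi, forward) in bits by enumerating every core-anchored local
    state path: entry into any match column after any flank prefix, walk
    through M/I/D, exit from any match state, remaining residues flanking."""
    k, L = hmm.n_match, len(seq)
    x = [AA_INDEX.get(c, 20) for c in seq]
    mat, ins, lt = hmm._mat_lo, hmm._ins_lo, hmm._lt
    entry = -math.log2(k)
    scores: list[float] = []

    def walk(state: str, j: int, i: int, s: float) -> None:
        if state == "M":
            scores.append(s)  # exit after a match state costs nothing
        if state == "M" and j < k:
            if i < L:
                walk("M", j + 1, i + 1, s + lt[j, T_MM] + mat[j, x[i]])
                walk("I", j, i + 1, s + lt[j, T_MI] + ins[x[i]])
            walk("D", j + 1, i, s + lt[j, T_MD])
        elif state == "I":
            if i < L:
                walk("I", j, i + 1, s + lt[j, T_II] + ins[x[i]])
                if j < k:
                    walk("M", j + 1, i + 1, s + lt[j, T_IM] + mat[j, x[i]])
        elif state == "D" and j < k:
            if i < L:
                walk("M", j + 1, i + 1, s + lt[j, T_DM] + mat[j, x[i]])
            walk("D", j + 1, i, s + lt[j, T_DD])

    for p in range(L):
        for j in range(1, k + 1):
            walk("M", j, p + 1, entry + mat[j - 1, x[p]])
    vit = max(scores)
    fwd = math.log2(float(np.sum(np.exp2(np.array(scores) - vit)))) + vit
    return vit, fwd


def random_profile_hmm(rng: np.random.Generator, k: int) -> ProfileHMM:
    """A random, fully normalized profile for oracle comparisons."""
    me = rng.dirichlet(np.ones(20) * 0.5, size=k)
    tr = np.zeros((k + 1, 7))
    for j in range(k + 1):
        tr[j, 0:3] = rng.dirichlet(np.ones(3))
        tr[j, 3:5] = rng.dirichlet(np.ones(2))
        tr[j, 5:7] = rng.dirichlet(np.ones(2))
    return ProfileHMM(
        name="random",
        match_emissions=me,
        insert_emissions=np.full(20, 0.05),
        transitions=tr,
        background=np.full(20, 0.05),
    )


def brute_force_motif_starts(seq: str) -> list[int]:
    """Triple-anchor check of every 22-residue window."""
    out = []
    for s in range(len(seq) - 21):
        if seq[s + 6] == "Q" and seq[s + 8] == "G" and seq[s + 11] == "N":
            out.append(s)
    return out
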