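"""Profile hidden Markov models for remote-homology search.

A model is built from a curated alignment: columns with a gap fraction
below one half become match states, emissions are background-weighted
pseudocount estimates, and transitions among match/insert/delete states
are read off the alignment's gap structure with Laplace smoothing.

Search runs in local ("free flanking") mode: unmodelled prefix and suffix
residues score zero bits, the model may be entered at any match column
(uniform entry, costing ``-log2(n_match)`` bits) and left after any match
column at no cost.  A scored path must pass through at least one match
state; all scores are log-odds against the background, in bits.

Statistical calibration is empirical: the score cutoff is a quantile of
best-hit scores on decoy sequences, and the reported e-value is the
decoy-calibrated surrogate ``n_targets * 2**(-bit_score)`` rather than a
Gumbel fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import AA_ALPHABET, AA_INDEX, GAP_CHARS, Msa, ProteinRecord

NEG = -1e30
# transition-row layout (one row per layer, layer 0 = begin)
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)

UNIFORM_BACKGROUND = np.full(20, 0.05)


@dataclass
class ProfileHMM:
    """Match/insert/delete profile with probability parameters.

    ``match_emissions``: (n_match, 20) probabilities; ``insert_emissions``:
    (20,) probabilities; ``transitions``: (n_match + 1, 7) probabilities in
    the order MM MI MD IM II DM DD, row j holding the transitions out of
    layer j (row 0 is the begin layer).
    """

    name: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray
    score_cutoff: float | None = None

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        k = self.n_match
        if k < 1:
            raise ValueError("model needs at least one match state")
        if self.transitions.shape != (k + 1, 7):
            raise ValueError("transitions must have shape (n_match + 1, 7)")
        tol = 1e-9
        if np.any(np.abs(self.match_emissions.sum(axis=1) - 1) > tol):
            raise ValueError("match emission rows must sum to 1")
        if abs(self.insert_emissions.sum() - 1) > tol or abs(self.background.sum() - 1) > tol:
            raise ValueError("insert emissions and background must sum to 1")
        t = self.transitions
        for sl in (slice(T_MM, T_MD + 1), slice(T_IM, T_II + 1), slice(T_DM, T_DD + 1)):
            if np.any(np.abs(t[:, sl].sum(axis=1) - 1) > tol):
                raise ValueError("transition groups must each sum to 1")
        self._prepare_scores()

    @property
    def n_match(self) -> int:
        return self.match_emissions.shape[0]

    def _prepare_scores(self) -> None:
        with np.errstate(divide="ignore"):
            lo = np.log2(self.match_emissions) - np.log2(self.background)
            ins = np.log2(self.insert_emissions) - np.log2(self.background)
            lt = np.log2(self.transitions)
        # column 20 = ambiguity X, scored as background (0 bits)
        self._mat_lo = np.hstack([lo, np.zeros((self.n_match, 1))])
        self._ins_lo = np.append(ins, 0.0)
        self._lt = lt

    def consensus(self) -> str:
        """Most probable residue per match column."""
        return "".join(AA_ALPHABET[i] for i in np.argmax(self.match_emissions, axis=1))


@dataclass
class HmmHit:
    target_id: str
    bit_score: float
    start: int
    end: int
    model_span: tuple[int, int]
    evalue_surrogate: float


def build_profile(
    msa: Msa,
    background: np.ndarray | None = None,
    pseudocount_weight: float = 1.0,
    name: str = "model",
) -> ProfileHMM:
    """Estimate a profile HMM from an alignment.

    Match columns are those with gap fraction < 0.5.  Emissions are
    ``(counts + w * background) / (n + w)`` with ``n`` the residue count of
    the column.  Transitions are counted from each row's implied state path
    with add-one smoothing; insert runs flanked by a delete are collapsed
    (plan7 forbids D<->I moves).
    """
    if not msa.records:
        raise ValueError("empty alignment")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    nrows = len(msa.records)
    L = msa.length
    cols = [msa.column(j) for j in range(L)]
    gap_frac = [sum(c in GAP_CHARS for c in col) / nrows for col in cols]
    match_cols = [j for j in range(L) if gap_frac[j] < 0.5]
    if not match_cols:
        raise ValueError("no consensus columns (every column is majority-gap)")
    k = len(match_cols)

    emissions = np.zeros((k, 20))
    for mi, j in enumerate(match_cols):
        counts = np.zeros(20)
        for c in cols[j]:
            if c in AA_INDEX:
                counts[AA_INDEX[c]] += 1
        n = counts.sum()
        emissions[mi] = (counts + pseudocount_weight * bg) / (n + pseudocount_weight)

    # transition counting over the 7 allowed moves, one layer per match column
    tcounts = np.zeros((k + 1, 7))
    match_set = set(match_cols)
    insert_runs = _insert_runs(match_cols, L)
    for _, row in msa.records:
        states = ["M"] + [
            ("D" if row[j] in GAP_CHARS else "M") for j in match_cols
        ]  # layer 0 = begin, treated as M
        ninserts = [
            sum(row[j] not in GAP_CHARS for j in run) for run in insert_runs
        ]
        for layer in range(k):
            a, b = states[layer], states[layer + 1]
            nins = ninserts[layer]
            if nins > 0 and a == "M" and b == "M":
                tcounts[layer, T_MI] += 1
                tcounts[layer, T_II] += nins - 1
                tcounts[layer, T_IM] += 1
            else:
                # D-adjacent insert runs are collapsed onto the direct move
                if a == "M" and b == "M":
                    tcounts[layer, T_MM] += 1
                elif a == "M" and b == "D":
                    tcounts[layer, T_MD] += 1
                elif a == "D" and b == "M":
                    tcounts[layer, T_DM] += 1
                else:
                    tcounts[layer, T_DD] += 1
    tcounts += 1.0  # Laplace
    trans = np.zeros((k + 1, 7))
    for sl in (slice(T_MM, T_MD + 1), slice(T_IM, T_II + 1), slice(T_DM, T_DD + 1)):
        trans[:, sl] = tcounts[:, sl] / tcounts[:, sl].sum(axis=1, keepdims=True)

    return ProfileHMM(
        name=name,
        match_emissions=emissions,
        insert_emissions=bg.copy(),
        transitions=trans,
        background=bg,
    )


def _insert_runs(match_cols: list[int], L: int) -> list[list[int]]:
    """Insert-column index runs per layer: an empty run for the begin
    layer, then the columns between consecutive match columns (columns
    before the first and after the last match column are flanking context
    and not modelled)."""
    runs: list[list[int]] = [[]]
    for a, b in zip(match_cols[:-1], match_cols[1:]):
        runs.append(list(range(a + 1, b)))
    return runs


def _encode(seq: str) -> np.ndarray:
    return np.array([AA_INDEX.get(c, 20) for c in seq], dtype=int)


def viterbi(hmm: ProfileHMM, seq: str | ProteinRecord, want_path: bool = True):
    """Best core-anchored local alignment of ``seq`` to the model.

    Returns ``(path, bit_score)`` where ``path`` is a list of
    ``(state, column, seq_position)`` tuples covering the core (flanking
    residues are implicit).  Ties are broken preferring match over insert
    over delete and the leftmost start.  With ``want_path=False`` only the
    score is computed (returned as ``(None, score)``).
    """
    if isinstance(seq, ProteinRecord):
        seq = seq.sequence
    if not seq:
        raise ValueError("viterbi requires a non-empty sequence")
    x = _encode(seq)
    L, k = len(x), hmm.n_match
    mat, ins, lt = hmm._mat_lo, hmm._ins_lo, hmm._lt
    entry = -np.log2(k)
    lMM, lMI, lMD = lt[:, T_MM], lt[:, T_MI], lt[:, T_MD]
    lIM, lII = lt[:, T_IM], lt[:, T_II]
    lDM, lDD = lt[:, T_DM], lt[:, T_DD]
    # 1-based column arrays; index 0 is a sentinel
    M = np.full((L + 1, k + 1), NEG)
    I = np.full((L + 1, k + 1), NEG)
    D = np.full((L + 1, k + 1), NEG)
    cumDD = np.concatenate([[0.0], np.cumsum(lDD[1:k])])  # cumDD[j] = sum lDD[1..j]
    for i in range(1, L + 1):
        e = mat[:, x[i - 1]]
        prevM, prevI, prevD = M[i - 1], I[i - 1], D[i - 1]
        cand = np.full(k + 1, entry)
        np.maximum(cand[1:], np.maximum.reduce(
            [prevM[:-1] + np.append(NEG, lMM[1:k]),
             prevI[:-1] + np.append(NEG, lIM[1:k]),
             prevD[:-1] + np.append(NEG, lDM[1:k])]
        ), out=cand[1:])
        M[i, 1:] = e + cand[1:]
        I[i, 1:] = ins[x[i - 1]] + np.maximum(prevM[1:] + lMI[1:], prevI[1:] + lII[1:])
        I[i, k] = NEG  # no insert state after the last match column
        # deletes within the same row: D[i,j] = max_{f<j} M[i,f]+lMD[f]+sum(lDD[f+1..j-1])
        A = M[i, 1:] + lMD[1:k + 1] - np.concatenate([cumDD, [cumDD[-1]]])[1:]
        run = np.maximum.accumulate(A)
        D[i, 2:] = run[:-1] + cumDD[1:]
    best = float(M[1:, 1:].max()) if k and L else NEG
    if not want_path:
        return None, best
    # locate the end cell: max score, then leftmost i, then smallest column
    ends = np.argwhere(M[1:, 1:] >= best - 0.0)
    ends = [(int(i) + 1, int(j) + 1) for i, j in ends if M[i + 1, j + 1] == best]
    i, j = min(ends)
    path: list[tuple[str, int, int | None]] = []
    state = "M"
    while True:
        if state == "M":
            path.append(("M", j, i - 1))
            e = mat[j - 1, x[i - 1]]
            cands = [
                ("M", M[i - 1, j - 1] + (lMM[j - 1] if j > 1 else NEG)),
                ("I", I[i - 1, j - 1] + (lIM[j - 1] if j > 1 else NEG)),
                ("D", D[i - 1, j - 1] + (lDM[j - 1] if j > 1 else NEG)),
                ("ENTRY", entry),
            ]
            target = M[i, j] - e
            state = _pick(cands, target)
            i, j = i - 1, j - 1
            if state == "ENTRY":
                break
        elif state == "I":
            path.append(("I", j, i - 1))
            target = I[i, j] - ins[x[i - 1]]
            cands = [("M", M[i - 1, j] + lMI[j]), ("I", I[i - 1, j] + lII[j])]
            state = _pick(cands, target)
            i = i - 1
        else:  # D
            path.append(("D", j, None))
            target = D[i, j]
            cands = [("M", M[i, j - 1] + lMD[j - 1]), ("D", D[i, j - 1] + lDD[j - 1])]
            state = _pick(cands, target)
            j = j - 1
    path.reverse()
    return path, best


def _pick(cands, target):
    # prefer the first candidate whose value reproduces the DP cell
    best_val = max(v for _, v in cands)
    for name, v in cands:
        if v == best_val:
            return name
    raise AssertionError("traceback inconsistency")


def forward(hmm: ProfileHMM, seq: str | ProteinRecord) -> float:
    """Log-odds (bits) summed over all core-anchored local paths."""
    if isinstance(seq, ProteinRecord):
        seq = seq.sequence
    if not seq:
        raise ValueError("forward requires a non-empty sequence")
    x = _encode(seq)
    L, k = len(x), hmm.n_match
    mat, ins, lt = hmm._mat_lo, hmm._ins_lo, hmm._lt
    entry = -np.log2(k)
    lMM, lMI, lMD = lt[:, T_MM], lt[:, T_MI], lt[:, T_MD]
    lIM, lII = lt[:, T_IM], lt[:, T_II]
    lDM, lDD = lt[:, T_DM], lt[:, T_DD]
    M = np.full((L + 1, k + 1), NEG)
    I = np.full((L + 1, k + 1), NEG)
    D = np.full((L + 1, k + 1), NEG)
    cumDD = np.concatenate([[0.0], np.cumsum(lDD[1:k])])
    for i in range(1, L + 1):
        e = mat[:, x[i - 1]]
        prevM, prevI, prevD = M[i - 1], I[i - 1], D[i - 1]
        inflow = np.logaddexp2.reduce(
            [prevM[:-1] + np.append(NEG, lMM[1:k]),
             prevI[:-1] + np.append(NEG, lIM[1:k]),
             prevD[:-1] + np.append(NEG, lDM[1:k])], axis=0,
        )
        M[i, 1:] = e + np.logaddexp2(entry, inflow)
        I[i, 1:] = ins[x[i - 1]] + np.logaddexp2(prevM[1:] + lMI[1:], prevI[1:] + lII[1:])
        I[i, k] = NEG
        A = M[i, 1:] + lMD[1:k + 1] - np.concatenate([cumDD, [cumDD[-1]]])[1:]
        run = np.logaddexp2.accumulate(A)
        D[i, 2:] = run[:-1] + cumDD[1:]
    return float(np.logaddexp2.reduce(M[1:, 1:].ravel()))


def hit_from_path(hmm: ProfileHMM, target_id: str, path, score: float, n_targets: int) -> HmmHit:
    emit_pos = [p for _, _, p in path if p is not None]
    cols = [c for s, c, _ in path if s in ("M", "D")]
    return HmmHit(
        target_id=target_id,
        bit_score=score,
        start=min(emit_pos),
        end=max(emit_pos) + 1,
        model_span=(min(cols) - 1, max(cols)),
        evalue_surrogate=n_targets * 2.0 ** (-score),
    )


def search(
    hmm: ProfileHMM,
    proteome: list[ProteinRecord],
    cutoff_bits: float | None = None,
) -> list[HmmHit]:
    """One best-scoring hit per target with bit score >= cutoff,
    sorted by descending score (ties by target id)."""
    cutoff = hmm.score_cutoff if cutoff_bits is None else cutoff_bits
    if cutoff is None or not np.isfinite(cutoff):
        raise ValueError("search requires a finite bit-score cutoff")
    n = len(proteome)
    hits: list[HmmHit] = []
    for rec in proteome:
        _, score = viterbi(hmm, rec.sequence, want_path=False)
        if score >= cutoff:
            path, score = viterbi(hmm, rec.sequence, want_path=True)
            hits.append(hit_from_path(hmm, rec.id, path, score, n))
    hits.sort(key=lambda h: (-h.bit_score, h.target_id))
    return hits


def calibrate(
    hmm: ProfileHMM, decoys: list[ProteinRecord], fpr: float = 0.01
) -> float:
    """Empirical score cutoff: the (1 - fpr) quantile (upper empirical
    quantile) of decoy best-hit scores. Requires >= 100 decoys."""
    if len(decoys) < 100:
        raise ValueError(f"calibration requires >= 100 decoys, got {len(decoys)}")
    if not 0 <= fpr < 1:
        raise ValueError("fpr must be in [0, 1)")
    scores = np.array([viterbi(hmm, d.sequence, want_path=False)[1] for d in decoys])
    return float(np.quantile(scores, 1 - fpr, method="higher"))
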