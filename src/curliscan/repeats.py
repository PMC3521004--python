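"""Minimalistic curli-repeat detection and repeat-architecture analysis.

The minimalistic curli repeat is a 22-residue window, written X6QXGX2NX10:
six arbitrary residues, a literal glutamine, one arbitrary residue, a
literal glycine, two arbitrary residues, a literal asparagine and ten
arbitrary residues.  The scanner tests every window start exhaustively, so
mutually overlapping ("superimposed") repeats are all reported -- a
left-to-right consuming search would miss them.

A protein is considered a functional amyloid subunit candidate only when
it carries at least two repeat windows; proteins with zero or one window
are flagged non-functional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import AA_ALPHABET, Msa, ProteinRecord


@dataclass(frozen=True)
class RepeatMotif:
    """Window geometry of the minimalistic repeat (all counts in residues)."""

    prefix_len: int = 6
    q_offset: int = 6
    g_offset: int = 8
    n_offset: int = 11
    suffix_len: int = 10

    def __post_init__(self) -> None:
        if self.window != self.prefix_len + 1 + 1 + 2 + 1 + 1 + self.suffix_len:
            raise ValueError("inconsistent motif geometry")

    @property
    def window(self) -> int:
        return self.n_offset + 1 + self.suffix_len


DEFAULT_MOTIF = RepeatMotif()


@dataclass(frozen=True)
class RepeatMatch:
    start: int  # 0-based window start
    motif: RepeatMotif = DEFAULT_MOTIF

    @property
    def end(self) -> int:
        return self.start + self.motif.window

    @property
    def anchors(self) -> tuple[int, int, int]:
        m = self.motif
        return (self.start + m.q_offset, self.start + m.g_offset, self.start + m.n_offset)


@dataclass
class RepeatArchitecture:
    """Repeat organisation of one protein: all matches, overlap count,
    inter-start spacings and the two-repeat functionality flag."""

    protein_id: str
    matches: list[RepeatMatch]

    @property
    def n_repeats(self) -> int:
        return len(self.matches)

    @property
    def functional(self) -> bool:
        return self.n_repeats >= 2

    @property
    def overlapping_pairs(self) -> int:
        n = 0
        for i, a in enumerate(self.matches):
            for b in self.matches[i + 1:]:
                if b.start < a.end:
                    n += 1
        return n

    @property
    def spacings(self) -> list[int]:
        starts = [m.start for m in self.matches]
        return [b - a for a, b in zip(starts[:-1], starts[1:])]


def scan_repeats(seq: str | ProteinRecord, motif: RepeatMotif = DEFAULT_MOTIF) -> list[RepeatMatch]:
    """All minimalistic-repeat windows in a sequence, sorted by start.

    Every position is tested, so overlapping matches are enumerated.
    Anchors must be the literal residues Q/G/N; the wildcard positions
    accept any residue including the ambiguity letter X.
    """
    if isinstance(seq, ProteinRecord):
        seq = seq.sequence
    w = motif.window
    out = []
    for s in range(0, len(seq) - w + 1):
        if (
            seq[s + motif.q_offset] == "Q"
            and seq[s + motif.g_offset] == "G"
            and seq[s + motif.n_offset] == "N"
        ):
            out.append(RepeatMatch(start=s, motif=motif))
    return out


def architecture(protein: ProteinRecord, motif: RepeatMotif = DEFAULT_MOTIF) -> RepeatArchitecture:
    return RepeatArchitecture(protein_id=protein.id, matches=scan_repeats(protein, motif))


def extract_repeat_regions(
    protein: ProteinRecord | str,
    matches: list[RepeatMatch],
    merge_gap: int = 0,
) -> list[str]:
    """Merge overlapping/adjacent repeat windows (inter-window gap <=
    ``merge_gap``) into maximal regions and return their subsequences in
    sequence order."""
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if not matches:
        return []
    spans: list[list[int]] = []
    for m in sorted(matches, key=lambda m: m.start):
        if spans and m.start - spans[-1][1] <= merge_gap:
            spans[-1][1] = max(spans[-1][1], m.end)
        else:
            spans.append([m.start, m.end])
    return [seq[a:b] for a, b in spans]


@dataclass
class ConsensusProfile:
    """Per-column residue frequencies of an aligned repeat set with the
    conservation tiers used for consensus display: >=50%, >=80% and 100%."""

    columns: list[dict[str, float]]  # residue (or '-') -> frequency
    consensus: str                   # modal residue per column ('-' possible)
    tiers: list[int]                 # 0 (none), 50, 80 or 100 per column


def consensus(aligned_repeats: Msa) -> ConsensusProfile:
    """Column-wise consensus of aligned repeat regions.

    The modal residue's frequency (gaps counted in the denominator) sets
    the tier: 100 requires total conservation, the 80 and 50 tiers use
    inclusive thresholds.
    """
    if not aligned_repeats.records:
        raise ValueError("empty alignment")
    n = len(aligned_repeats.records)
    columns: list[dict[str, float]] = []
    cons = []
    tiers = []
    for j in range(aligned_repeats.length):
        col = aligned_repeats.column(j).replace(".", "-")
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        columns.append({c: k / n for c, k in counts.items()})
        # deterministic: highest count; among ties prefer a residue over a
        # gap, then the alphabetically first residue
        top = max(counts.values())
        modal = sorted([c for c, k in counts.items() if k == top],
                       key=lambda c: (c == "-", c))[0]
        cons.append(modal)
        k = counts[modal]
        # integer comparisons keep the inclusive 50/80/100 boundaries exact
        if k == n:
            tiers.append(100)
        elif 5 * k >= 4 * n:
            tiers.append(80)
        elif 2 * k >= n:
            tiers.append(50)
        else:
            tiers.append(0)
    return ConsensusProfile(columns=columns, consensus="".join(cons), tiers=tiers)
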