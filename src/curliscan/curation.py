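"""Iterative homolog identification with mechanized neighborhood curation.

The search loop mirrors the field's practice of alternating profile-HMM
searches with curation of the hits: build a model per Csg family from the
current homolog alignment, search every proteome, accept hits by an
explicit rule, realign the expanded set and rebuild, until the accepted
set stops growing.

Human curation is replaced by a two-clause rule so every decision is
reproducible and carries its evidence: a hit is accepted iff its bit score
passes the decoy-calibrated cutoff AND either (a) another csg homolog lies
within ``neighborhood_window`` genes on the same contig, or (b) for
subunit (CsgA/B) candidates, the protein carries at least
``min_repeats_for_AB`` minimalistic repeat windows.  Hits in genomes
without annotations cannot use clause (a); they are accepted on score (or
the repeat clause) but flagged "unplaceable" rather than silently dropped.

CsgD is searched like any other family but flagged non-probative in
reports: it belongs to a very large regulator family, so a CsgD hit alone
is no evidence of a curli system.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .align import AlignParams, progressive_msa
from .io_formats import GeneFeature, Msa, ProteinRecord
from .phmm import HmmHit, ProfileHMM, build_profile, calibrate, search
from .repeats import DEFAULT_MOTIF, RepeatMotif, scan_repeats

AB_FAMILY = "csgA/B"
NON_PROBATIVE_FAMILIES = {"csgD"}


@dataclass
class CurationParams:
    max_iterations: int = 10
    neighborhood_window: int = 5      # genes
    min_repeats_for_AB: int = 2
    # stringent by design: accepted hits feed back into model training, so
    # database inclusion uses a harder cutoff than a one-shot search would
    cutoff_fpr: float = 0.0025
    pseudocount_weight: float = 1.0
    motif: RepeatMotif = DEFAULT_MOTIF
    align: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        if min(self.max_iterations, self.neighborhood_window,
               self.min_repeats_for_AB) <= 0:
            raise ValueError("curation parameters must be positive")
        if not 0 <= self.cutoff_fpr < 1:
            raise ValueError("cutoff_fpr must be in [0, 1)")


@dataclass
class CurationDecision:
    """One accept/reject decision with its evidence."""

    locus: str
    family: str
    genome: str | None
    bit_score: float
    accepted: bool
    reason: str               # seed / neighborhood / repeats / rejected / unplaceable
    n_neighbors: int = 0
    repeat_count: int = 0
    unplaceable: bool = False
    iteration: int = 0        # search round that produced the decision


@dataclass
class HomologSet:
    """Accepted members per family; ids never leave once accepted."""

    members: dict[str, dict[str, CurationDecision]] = field(default_factory=dict)

    def family_ids(self, family: str) -> set[str]:
        return set(self.members.get(family, {}))

    def all_ids(self) -> set[str]:
        out: set[str] = set()
        for fam in self.members.values():
            out |= set(fam)
        return out

    def add(self, decision: CurationDecision) -> None:
        fam = self.members.setdefault(decision.family, {})
        other = self.family_of(decision.locus)
        if other is not None and other != decision.family:
            raise ValueError(
                f"locus {decision.locus!r} already assigned to {other}"
            )
        fam.setdefault(decision.locus, decision)

    def family_of(self, locus: str) -> str | None:
        for fam, members in self.members.items():
            if locus in members:
                return fam
        return None

    def size(self) -> int:
        return sum(len(m) for m in self.members.values())


@dataclass
class ValidationReport:
    """Hits / correct hits / missing hits, in the classic validation-table
    schema with integer-rounded percentages."""

    model: str
    hits: int
    correct: int
    truth_total: int
    probative: bool = True

    @property
    def missing(self) -> int:
        return self.truth_total - self.correct if self.correct <= self.truth_total else 0

    @property
    def correct_pct(self) -> int:
        return _pct(self.correct, self.hits)

    @property
    def missing_pct(self) -> int:
        return _pct(self.missing, self.truth_total)

    def row(self) -> str:
        return (
            f"{self.hits}\t{self.correct}/{self.hits} ({self.correct_pct}%)\t"
            f"{self.missing}/{self.truth_total} ({self.missing_pct}%)"
        )


def _pct(num: int, den: int) -> int:
    if den == 0:
        return 0
    return int(np.floor(100 * num / den + 0.5))  # round half up


def validate(predicted: set[str], truth: set[str], model_name: str,
             probative: bool = True) -> ValidationReport:
    """Compare predicted member ids against a truth set."""
    if not truth:
        raise ValueError("empty truth set")
    correct = len(predicted & truth)
    return ValidationReport(
        model=model_name,
        hits=len(predicted),
        correct=correct,
        truth_total=len(truth),
        probative=probative,
    )


def _gene_rank_index(features: list[GeneFeature]) -> dict[str, tuple[str, int]]:
    """locus -> (contig, rank along the contig)."""
    by_contig: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_contig.setdefault(f.contig, []).append(f)
    out: dict[str, tuple[str, int]] = {}
    for contig, genes in by_contig.items():
        for rank, g in enumerate(sorted(genes, key=lambda g: g.start)):
            out[g.locus_id] = (contig, rank)
    return out


def curate_hits(
    family: str,
    hits: list[HmmHit],
    rank_index: dict[str, tuple[str, int]],
    genome_of: dict[str, str],
    csg_context: set[str],
    repeat_counts: dict[str, int],
    params: CurationParams,
) -> list[CurationDecision]:
    """Apply the two-clause acceptance rule to a round of hits.

    ``csg_context`` holds every locus currently believed to be a csg gene
    (previously accepted plus this round's cross-family hits); a candidate
    never corroborates itself.
    """
    decisions: list[CurationDecision] = []
    for hit in hits:
        locus = hit.target_id
        genome = genome_of.get(locus)
        repeat_count = repeat_counts.get(locus, 0)
        placed = locus in rank_index
        n_neighbors = 0
        if placed:
            contig, rank = rank_index[locus]
            for other in csg_context:
                if other == locus or other not in rank_index:
                    continue
                ocontig, orank = rank_index[other]
                if ocontig == contig and abs(orank - rank) <= params.neighborhood_window:
                    n_neighbors += 1
        repeat_ok = family == AB_FAMILY and repeat_count >= params.min_repeats_for_AB
        if repeat_ok:
            accepted, reason = True, "repeats"
        elif placed and n_neighbors >= 1:
            accepted, reason = True, "neighborhood"
        elif not placed:
            # no annotation to judge the neighborhood: hold, do not drop
            accepted, reason = True, "unplaceable"
        else:
            accepted, reason = False, "rejected"
        decisions.append(CurationDecision(
            locus=locus, family=family, genome=genome, bit_score=hit.bit_score,
            accepted=accepted, reason=reason, n_neighbors=n_neighbors,
            repeat_count=repeat_count, unplaceable=not placed,
        ))
    return decisions


@dataclass
class IterationResult:
    homologs: HomologSet
    models: dict[str, ProfileHMM]
    cutoffs: dict[str, float]
    n_iterations: int
    converged: bool
    decisions: list[CurationDecision]


def iterate(
    seed_msas: dict[str, Msa],
    proteomes: dict[str, list[ProteinRecord]],
    annotations: dict[str, list[GeneFeature]],
    decoys: list[ProteinRecord],
    params: CurationParams | None = None,
) -> IterationResult:
    """Run the search/curate/rebuild loop to convergence.

    The homolog set starts from the seed alignment rows (the curated seed
    database), grows monotonically, and the loop stops when an iteration
    accepts nothing new or ``max_iterations`` is reached (the latter sets
    ``converged=False`` rather than raising).
    """
    params = params or CurationParams()
    if not seed_msas:
        raise ValueError("at least one seed alignment is required")
    families = sorted(seed_msas)
    all_proteins: list[ProteinRecord] = []
    genome_of: dict[str, str] = {}
    for genome in sorted(proteomes):
        for rec in proteomes[genome]:
            all_proteins.append(rec)
            genome_of[rec.id] = genome
    rank_index: dict[str, tuple[str, int]] = {}
    for genome in sorted(annotations):
        rank_index.update(_gene_rank_index(annotations[genome]))
    repeat_counts = {rec.id: len(scan_repeats(rec.sequence, params.motif))
                     for rec in all_proteins}
    seq_of = {rec.id: rec.sequence for rec in all_proteins}

    homologs = HomologSet()
    decisions: list[CurationDecision] = []
    for fam in families:
        for rid in seed_msas[fam].ids:
            homologs.add(CurationDecision(
                locus=rid, family=fam, genome=None, bit_score=float("nan"),
                accepted=True, reason="seed"))

    msas = dict(seed_msas)
    models: dict[str, ProfileHMM] = {}
    cutoffs: dict[str, float] = {}
    n_iter = 0
    converged = False
    while n_iter < params.max_iterations:
        n_iter += 1
        round_hits: dict[str, list[HmmHit]] = {}
        for fam in families:
            hmm = build_profile(msas[fam], pseudocount_weight=params.pseudocount_weight,
                                name=fam)
            cutoff = calibrate(hmm, decoys, fpr=params.cutoff_fpr)
            hmm.score_cutoff = cutoff
            models[fam] = hmm
            cutoffs[fam] = cutoff
            round_hits[fam] = search(hmm, all_proteins, cutoff)
        # corroboration comes from previously accepted members of probative
        # families plus this round's repeat-qualified subunit hits -- never
        # from unvetted co-hits or from CsgD, whose family is too large to
        # serve as evidence of a curli system
        context: set[str] = set()
        for fam, members in homologs.members.items():
            if fam not in NON_PROBATIVE_FAMILIES:
                context |= set(members)
        if AB_FAMILY in round_hits:
            context |= {
                h.target_id for h in round_hits[AB_FAMILY]
                if repeat_counts.get(h.target_id, 0) >= params.min_repeats_for_AB
            }
        candidates: dict[str, list[CurationDecision]] = {}
        for fam in families:
            new_hits = [h for h in round_hits[fam]
                        if h.target_id not in homologs.family_ids(fam)]
            for d in curate_hits(fam, new_hits, rank_index, genome_of, context,
                                 repeat_counts, params):
                d.iteration = n_iter
                assigned = homologs.family_of(d.locus)
                if d.accepted and assigned is None:
                    candidates.setdefault(d.locus, []).append(d)
                else:
                    if d.accepted and assigned is not None:
                        d = dataclasses.replace(
                            d, accepted=False,
                            reason=f"already_assigned_{assigned}")
                    decisions.append(d)
        added = 0
        for locus in sorted(candidates):
            # a locus accepted by several family models goes to the
            # best-scoring one; the others are logged as outcompeted
            ranked = sorted(candidates[locus],
                            key=lambda d: (-d.bit_score, d.family))
            winner = ranked[0]
            homologs.add(winner)
            decisions.append(winner)
            added += 1
            for loser in ranked[1:]:
                decisions.append(dataclasses.replace(
                    loser, accepted=False,
                    reason=f"outcompeted_by_{winner.family}"))
        if added == 0:
            converged = True
            break
        msas = _rebuild_msas(families, seed_msas, homologs, seq_of, params)
    return IterationResult(
        homologs=homologs, models=models, cutoffs=cutoffs,
        n_iterations=n_iter, converged=converged, decisions=decisions,
    )


def _rebuild_msas(
    families: list[str],
    seed_msas: dict[str, Msa],
    homologs: HomologSet,
    seq_of: dict[str, str],
    params: CurationParams,
) -> dict[str, Msa]:
    """Realign each family's non-redundant accepted set (plus seeds).

    The subunit family is special-cased: its alignment rows are the
    22-residue repeat windows of the accepted proteins (trivially aligned),
    matching a model trained solely on repeat regions.
    """
    out: dict[str, Msa] = {}
    for fam in families:
        seed = seed_msas[fam]
        new_ids = sorted(
            locus for locus in homologs.family_ids(fam) if locus in seq_of
        )
        if fam == AB_FAMILY:
            rows = list(seed.records)
            seen_rows = {row for _, row in rows}
            for locus in new_ids:
                seq = seq_of[locus]
                for w, m in enumerate(scan_repeats(seq, params.motif)):
                    window = seq[m.start:m.end]
                    if window not in seen_rows:
                        seen_rows.add(window)
                        rows.append((f"{locus}_r{w + 1}", window))
            out[fam] = Msa(rows)
            continue
        seqs: list[tuple[str, str]] = []
        seen: set[str] = set()
        for i in range(len(seed.records)):
            rid = seed.records[i][0]
            ungapped = seed.ungapped(i)
            if ungapped not in seen:
                seen.add(ungapped)
                seqs.append((rid, ungapped))
        for locus in new_ids:
            if seq_of[locus] not in seen:
                seen.add(seq_of[locus])
                seqs.append((locus, seq_of[locus]))
        if len(seqs) == 1:
            out[fam] = Msa([seqs[0]])
        else:
            out[fam] = progressive_msa(seqs, params.align)
    return out


def repeat_statistics(
    proteins: dict[str, str], motif: RepeatMotif = DEFAULT_MOTIF
) -> dict[str, float]:
    """Repeat-region summary over a subunit homolog set: fraction with >= 2
    repeat windows (the functional fraction), count with none or one, the
    longest protein and the largest repeat count."""
    if not proteins:
        raise ValueError("empty homolog set")
    counts = {pid: len(scan_repeats(seq, motif)) for pid, seq in proteins.items()}
    n = len(counts)
    functional = sum(1 for c in counts.values() if c >= 2)
    return {
        "n_proteins": n,
        "n_functional": functional,
        "functional_pct": _pct(functional, n),
        "n_nonfunctional": n - functional,
        "max_length": max(len(s) for s in proteins.values()),
        "max_repeats": max(counts.values()),
    }
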