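"""Synthetic genomes with planted curli systems and ground truth.

The generator emits what the annotation method consumes -- per-genome
protein FASTA and GFF -- plus seed alignments and truth tables, so every
pipeline stage is testable without downloads.  Nucleotide sequence is never
generated: no stage of the method reads DNA, so contigs exist only as
coordinate bookkeeping inside the GFF.

What is emulated:

* curli subunit (CsgA/B) proteins as concatenated 22-residue minimalistic
  repeat units with literal Q/G/N anchors and weakly conserved flanks
  (anchor identity 1.0, flank identity 0.3 to a family consensus), 2-22
  units per protein mirroring the observed range;
* accessory families CsgC-CsgH as point-mutated variants of fixed family
  consensus sequences, with genus-level sequence structure for the tree
  stages and a two-tier divergence ladder (near / mid / remote) in two
  families so the iterative search needs more than one round;
* the five canonical csg operon layouts, two genomes each;
* one genus whose subunit-adjacent marker protein derives from a distant
  lineage, emulating the Shewanella-style split seen in Csg trees;
* a 16S-like pre-aligned marker per genome for congruence checks;
* background decoy proteins, rejection-sampled to contain no repeat motif.

Planted repeat flanks avoid Q/G/N entirely, so the planted window starts
are exactly the motif matches in each subunit protein (the truth table is
exact, not a lower bound).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io_formats import (
    AA_ALPHABET,
    GeneFeature,
    Msa,
    ProteinRecord,
    write_fasta,
    write_gff,
    write_msa,
)
from .repeats import DEFAULT_MOTIF, RepeatMotif, scan_repeats

# flank residues exclude the anchor letters so planted starts are exact
FLANK_ALPHABET = "".join(c for c in AA_ALPHABET if c not in "QGN")

CANONICAL_CLASSES = (
    "divergent_two_operon",
    "co_oriented_two_operon",
    "divergent_csgD_detached",
    "single_operon_csgD_divergent",
    "single_operon",
)

# gene content per architecture class, in layout order
_CLASS_CONTENT: dict[str, dict] = {
    "divergent_two_operon": {"families": ["csgA/B", "csgC", "csgD", "csgE", "csgF", "csgG"]},
    "co_oriented_two_operon": {"families": ["csgA/B", "csgC", "csgD", "csgE", "csgF", "csgG"]},
    "divergent_csgD_detached": {"families": ["csgA/B", "csgC", "csgD", "csgE", "csgF", "csgG"]},
    "single_operon_csgD_divergent": {"families": ["csgA/B", "csgD", "csgE", "csgF", "csgG"]},
    "single_operon": {"families": ["csgA/B", "csgF", "csgG", "csgH"]},
}

FAMILY_LENGTHS = {"csgC": 110, "csgD": 180, "csgE": 100, "csgF": 130, "csgG": 230, "csgH": 95}


@dataclass
class SimParams:
    """Generator settings; defaults are the study conditions the whole
    test battery runs under."""

    seed: int = 0
    n_genomes: int = 10
    repeats_per_protein: tuple[int, int] = (2, 22)
    repeat_flank_conservation: float = 0.3  # anchors are always 1.0
    n_decoys: int = 30            # decoy genes per genome
    n_adjacent_decoys: int = 2    # decoys placed next to the csg cluster
    decoy_length: tuple[int, int] = (80, 300)
    n_seed_variants: int = 6
    seed_divergence: float = 0.05     # seed variants vs family consensus
    genus_divergence: float = 0.15    # genus consensus vs family consensus
    within_genus_divergence: float = 0.03
    mid_shift: float = 0.5            # two-tier: mid consensus vs family consensus
    remote_ancestral_identity: float = 0.18  # remote consensus vs family consensus
    tier_within: float = 0.03
    two_tier_families: tuple[str, ...] = ("csgD", "csgG")
    split_family: str = "csgF"        # family carrying the split-genus signal
    split_shift: float = 0.25
    n_calibration_decoys: int = 400
    motif: RepeatMotif = DEFAULT_MOTIF

    def __post_init__(self) -> None:
        if self.n_genomes <= 0 or self.n_decoys < 0:
            raise ValueError("counts must be positive")
        lo, hi = self.repeats_per_protein
        if lo < 1 or hi < lo:
            raise ValueError("bad repeats_per_protein range")
        if not 0 <= self.repeat_flank_conservation <= 1:
            raise ValueError("conservation must be in [0, 1]")


@dataclass
class TruthProtein:
    genome: str
    locus_id: str
    family: str          # csgA/B or csgC..csgH
    gff_label: str       # csgA, csgB, csgA/B, csgC..csgH
    tier: str            # seed/near/mid/remote (decoys: decoy)
    repeat_starts: tuple[int, ...] = ()


@dataclass
class TruthGenome:
    genome: str
    genus: str
    taxon_class: str
    architecture: str
    families: tuple[str, ...]
    n_csgAB_paralogs: int
    csgH_next_to_AB: bool | None


@dataclass
class Benchmark:
    """In-memory result of a generator run (see :func:`benchmark`)."""

    params: SimParams
    seed_msas: dict[str, Msa]
    proteomes: dict[str, list[ProteinRecord]]
    annotations: dict[str, list[GeneFeature]]
    truth_proteins: list[TruthProtein]
    truth_genomes: list[TruthGenome]
    ssu_msa: Msa
    genus_of: dict[str, str]       # genome -> genus
    calibration_decoys: list[ProteinRecord]


def _random_protein(length: int, rng: np.random.Generator, alphabet: str = AA_ALPHABET) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def mutate(seq: str, rate: float, rng: np.random.Generator, alphabet: str = AA_ALPHABET) -> str:
    """Point-mutate each position with probability ``rate`` to a different
    uniformly chosen letter."""
    letters = list(alphabet)
    out = []
    for c in seq:
        if rng.random() < rate:
            choices = [x for x in letters if x != c]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(c)
    return "".join(out)


def _remote_consensus(
    c0: str, c1: str, rng: np.random.Generator, ancestral_identity: float
) -> str:
    """The remote lineage of a two-tier divergence ladder.

    Starting from the mid-lineage consensus ``c1``, positions still shared
    with the ancestral consensus ``c0`` are mutated away (to a residue
    differing from both) except for an evenly spaced residual fraction
    ``ancestral_identity``.  Spreading the residual evenly leaves no long
    ancestral-like run, so a model trained on the ancestral lineage alone
    scores the remote members below any sensible cutoff, while a model
    broadened with mid-lineage members recognises them -- the condition
    that makes the iterative search need a second round.
    """
    L = len(c0)
    shared = [i for i in range(L) if c0[i] == c1[i]]
    n_keep = int(round(ancestral_identity * L))
    if n_keep and shared:
        keep = {shared[int(i)] for i in np.linspace(0, len(shared) - 1,
                                                    min(n_keep, len(shared)))}
    else:
        keep = set()
    out = list(c1)
    for i in shared:
        if i not in keep:
            choices = [c for c in AA_ALPHABET if c != c1[i] and c != c0[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _repeat_consensus(rng: np.random.Generator, motif: RepeatMotif) -> str:
    unit = list(_random_protein(motif.window, rng, FLANK_ALPHABET))
    unit[motif.q_offset] = "Q"
    unit[motif.g_offset] = "G"
    unit[motif.n_offset] = "N"
    return "".join(unit)


def _sample_repeat_unit(
    consensus: str, conservation: float, rng: np.random.Generator, motif: RepeatMotif
) -> str:
    anchors = {motif.q_offset, motif.g_offset, motif.n_offset}
    out = []
    for i, c in enumerate(consensus):
        if i in anchors:
            out.append(c)
        elif rng.random() < conservation:
            out.append(c)
        else:
            out.append(FLANK_ALPHABET[rng.integers(len(FLANK_ALPHABET))])
    return "".join(out)


def sample_repeat_protein(
    params: SimParams,
    rng: np.random.Generator,
    consensus: str | None = None,
    k: int | None = None,
    protein_id: str = "repeat_protein",
) -> tuple[ProteinRecord, tuple[int, ...]]:
    """A curli-subunit-like protein: ``k`` repeat units concatenated
    end-to-end between anchor-free termini; returns the planted window
    starts, which are exactly the motif matches."""
    motif = params.motif
    if consensus is None:
        consensus = _repeat_consensus(rng, motif)
    if k is None:
        lo, hi = params.repeats_per_protein
        k = int(rng.integers(lo, hi + 1))
    nterm = _random_protein(int(rng.integers(5, 31)), rng, FLANK_ALPHABET)
    cterm = _random_protein(int(rng.integers(5, 31)), rng, FLANK_ALPHABET)
    units = [_sample_repeat_unit(consensus, params.repeat_flank_conservation, rng, motif)
             for _ in range(k)]
    seq = nterm + "".join(units) + cterm
    starts = tuple(len(nterm) + i * motif.window for i in range(k))
    rec = ProteinRecord(id=protein_id, sequence=seq)
    found = tuple(m.start for m in scan_repeats(seq, motif))
    assert found == starts, "anchor-free flanks guarantee exact planted starts"
    return rec, starts


def sample_decoy(
    params: SimParams,
    rng: np.random.Generator,
    protein_id: str = "decoy",
    max_tries: int = 1000,
) -> ProteinRecord:
    """A background protein, rejection-sampled until it contains no
    minimalistic repeat window."""
    lo, hi = params.decoy_length
    for _ in range(max_tries):
        seq = _random_protein(int(rng.integers(lo, hi + 1)), rng)
        if not scan_repeats(seq, params.motif):
            return ProteinRecord(id=protein_id, sequence=seq)
    raise RuntimeError(f"could not sample a motif-free decoy in {max_tries} tries")


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

_OPERON_GAP = 50        # intra-operon intergenic gap (<= operon max_gap)
_DIVERGENT_GAP = 300    # shared intergenic region of divergent/adjacent units
_FAR_GAP = 5000         # separates independent transcription units


def _layout(architecture: str) -> list[tuple[list[tuple[str, str]], str, int]]:
    """Gene layout per class: blocks of (gff_label, family) in left-to-right
    order, with strand and the gap preceding the block."""
    ab = [("csgB", "csgA/B"), ("csgA", "csgA/B"), ("csgC", "csgC")]
    defg_rev = [("csgG", "csgG"), ("csgF", "csgF"), ("csgE", "csgE"), ("csgD", "csgD")]
    defg_fwd = [("csgD", "csgD"), ("csgE", "csgE"), ("csgF", "csgF"), ("csgG", "csgG")]
    efg_rev = [("csgG", "csgG"), ("csgF", "csgF"), ("csgE", "csgE")]
    if architecture == "divergent_two_operon":
        # <-GFED  ..  BAC->  (heads face the shared intergenic region)
        return [(defg_rev, "-", 0), (ab, "+", _DIVERGENT_GAP)]
    if architecture == "co_oriented_two_operon":
        return [(defg_fwd, "+", 0), (ab, "+", _DIVERGENT_GAP)]
    if architecture == "divergent_csgD_detached":
        return [
            (efg_rev, "-", 0),
            (ab, "+", _DIVERGENT_GAP),
            ([("csgD", "csgD")], "+", _FAR_GAP),
        ]
    if architecture == "single_operon_csgD_divergent":
        block = [("csgB", "csgA/B"), ("csgA", "csgA/B"), ("csgE", "csgE"),
                 ("csgF", "csgF"), ("csgG", "csgG")]
        return [(block, "+", 0), ([("csgD", "csgD")], "-", _DIVERGENT_GAP)]
    if architecture == "single_operon":
        block = [("csgH", "csgH"), ("csgB", "csgA/B"), ("csgA", "csgA/B"),
                 ("csgF", "csgF"), ("csgG", "csgG")]
        return [(block, "+", 0)]
    raise ValueError(f"unknown architecture class {architecture!r}")


def build_genome(
    params: SimParams,
    rng: np.random.Generator,
    genome: str,
    genus: str,
    architecture: str,
    family_seq: dict[str, str],     # per non-AB family: this genome's sequence
    tier_of: dict[str, str],        # per family: near/mid/remote tier tag
    ab_consensus: str,
) -> tuple[list[ProteinRecord], list[GeneFeature], list[TruthProtein], TruthGenome]:
    """Assemble one genome for the requested operon architecture class."""
    contig = f"{genome}_c1"
    proteins: list[ProteinRecord] = []
    features: list[GeneFeature] = []
    truth: list[TruthProtein] = []
    pos = 1000
    counter = 0
    n_ab = 0

    def add_gene(label: str, family: str | None, seq: str, strand: str,
                 gap: int, tier: str, starts: tuple[int, ...] = ()) -> None:
        nonlocal pos, counter
        counter += 1
        locus = f"{genome}_{counter:04d}"
        glen = 3 * len(seq) + 3
        start = pos + gap
        features.append(GeneFeature(contig, start, start + glen, strand, locus,
                                    label if family else None))
        proteins.append(ProteinRecord(id=locus, sequence=seq, genus=genus))
        pos = start + glen
        if family:
            truth.append(TruthProtein(genome, locus, family, label, tier, starts))
        else:
            truth.append(TruthProtein(genome, locus, "decoy", "", "decoy", ()))

    for block, strand, lead_gap in _layout(architecture):
        genes = block
        for gi, (label, family) in enumerate(genes):
            gap = lead_gap if gi == 0 else _OPERON_GAP
            if family == "csgA/B":
                if label == "csgB":
                    k = int(rng.integers(4, 7))
                elif label == "csgA":
                    k = int(rng.integers(*_clip_range(params.repeats_per_protein, 4)))
                else:
                    k = int(rng.integers(4, 13))
                rec, starts = sample_repeat_protein(
                    params, rng, consensus=ab_consensus, k=k)
                add_gene(label, family, rec.sequence, strand, gap, "near", starts)
                n_ab += 1
            else:
                add_gene(label, family, family_seq[family], strand, gap,
                         tier_of.get(family, "near"))

    # a couple of decoy genes directly beside the csg cluster, the rest far away
    for i in range(params.n_decoys):
        gap = _DIVERGENT_GAP if i < params.n_adjacent_decoys else _FAR_GAP
        decoy = sample_decoy(params, rng, protein_id="tmp")
        strand = "+" if rng.random() < 0.5 else "-"
        add_gene("", None, decoy.sequence, strand, gap, "decoy")

    content = _CLASS_CONTENT[architecture]["families"]
    tg = TruthGenome(
        genome=genome,
        genus=genus,
        taxon_class="Alphaproteobacteria" if architecture == "single_operon"
        else "Gammaproteobacteria",
        architecture=architecture,
        families=tuple(sorted(set(content))),
        n_csgAB_paralogs=n_ab,
        csgH_next_to_AB=True if architecture == "single_operon" else None,
    )
    return proteins, features, truth, tg


def _clip_range(r: tuple[int, int], lo: int) -> tuple[int, int]:
    return (max(r[0], lo), max(r[1], lo) + 1)


# ---------------------------------------------------------------------------
# full benchmark
# ---------------------------------------------------------------------------

def benchmark(params: SimParams) -> Benchmark:
    """Generate the full fixture set: seed alignments, genomes with the
    five canonical operon layouts (two genomes per class), a two-tier
    divergence ladder in two accessory families, a split genus in the tree
    marker family, 16S-like marker rows, and calibration decoys.

    Deterministic in ``params.seed``; two runs produce identical objects.
    """
    rng = np.random.Generator(np.random.PCG64(params.seed))
    genera = ["GenusA", "GenusB", "GenusC", "GenusD", "GenusE"]
    classes = list(CANONICAL_CLASSES)
    # genus -> (class, tier role): GenusC carries the mid tier and the split
    # marker; GenusD carries the remote tier.
    genome_plan: list[tuple[str, str, str]] = []  # (genome, genus, class)
    gid = 0
    for genus, arch in zip(genera, classes):
        for _ in range(2):
            gid += 1
            genome_plan.append((f"G{gid:02d}", genus, arch))
    if params.n_genomes != len(genome_plan):
        # smaller runs keep the class coverage by truncation
        genome_plan = genome_plan[: params.n_genomes]

    families = sorted(FAMILY_LENGTHS)
    consensus = {f: _random_protein(FAMILY_LENGTHS[f], rng) for f in families}
    ab_consensus = _repeat_consensus(rng, params.motif)

    # two-tier ladders: mid consensus (GenusB/GenusC) and remote (GenusD)
    mid_cons = {f: mutate(consensus[f], params.mid_shift, rng)
                for f in params.two_tier_families}
    remote_cons = {f: _remote_consensus(consensus[f], mid_cons[f], rng,
                                        params.remote_ancestral_identity)
                   for f in params.two_tier_families}
    # genus-level consensus for ordinary families
    genus_cons: dict[tuple[str, str], str] = {}
    for f in families:
        for genus in genera:
            genus_cons[(f, genus)] = mutate(consensus[f], params.genus_divergence, rng)
    # the split lineage for the tree marker family (second GenusC genome)
    split_cons = mutate(consensus[params.split_family], params.split_shift, rng)

    # seed alignments: variants near the family consensus
    seed_msas: dict[str, Msa] = {}
    for f in families:
        rows = []
        for i in range(params.n_seed_variants):
            rows.append((f"seed_{f.replace('/', '')}_{i + 1}",
                         mutate(consensus[f], params.seed_divergence, rng)))
        seed_msas[f] = Msa(rows)
    ab_rows = []
    for i in range(params.n_seed_variants):
        rec, starts = sample_repeat_protein(
            params, rng, consensus=ab_consensus, k=int(rng.integers(4, 7)),
            protein_id=f"seed_csgAB_{i + 1}")
        for w, s in enumerate(starts):
            ab_rows.append((f"{rec.id}_r{w + 1}",
                            rec.sequence[s:s + params.motif.window]))
    seed_msas["csgA/B"] = Msa(ab_rows)

    proteomes: dict[str, list[ProteinRecord]] = {}
    annotations: dict[str, list[GeneFeature]] = {}
    truth_proteins: list[TruthProtein] = []
    truth_genomes: list[TruthGenome] = []
    genus_of: dict[str, str] = {}
    split_assigned = False
    genus_counts: dict[str, int] = {}

    for genome, genus, arch in genome_plan:
        genus_counts[genus] = genus_counts.get(genus, 0) + 1
        family_seq: dict[str, str] = {}
        tier_of: dict[str, str] = {}
        for f in families:
            if f in params.two_tier_families and genus in ("GenusB", "GenusC"):
                family_seq[f] = mutate(mid_cons[f], params.tier_within, rng)
                tier_of[f] = "mid"
            elif f in params.two_tier_families and genus == "GenusD":
                family_seq[f] = mutate(remote_cons[f], params.tier_within, rng)
                tier_of[f] = "remote"
            elif (f == params.split_family and genus == "GenusC"
                  and genus_counts[genus] == 2 and not split_assigned):
                family_seq[f] = mutate(split_cons, params.within_genus_divergence, rng)
                tier_of[f] = "near"
            else:
                family_seq[f] = mutate(genus_cons[(f, genus)],
                                       params.within_genus_divergence, rng)
                tier_of[f] = "near"
        if genus == "GenusC" and genus_counts[genus] == 2:
            split_assigned = True
        prot, feat, tp, tg = build_genome(
            params, rng, genome, genus, arch, family_seq, tier_of, ab_consensus)
        proteomes[genome] = prot
        annotations[genome] = feat
        truth_proteins.extend(tp)
        truth_genomes.append(tg)
        genus_of[genome] = genus

    # 16S-like marker: genus structure, no split, pre-aligned (equal length)
    ssu_root = _random_protein(200, rng, "ACGT")
    ssu_genus = {g: mutate(ssu_root, 0.10, rng, "ACGT") for g in genera}
    ssu_rows = [(genome, mutate(ssu_genus[genus_of[genome]], 0.02, rng, "ACGT"))
                for genome, _, _ in genome_plan]
    ssu_msa = Msa(ssu_rows)

    decoys = [sample_decoy(params, rng, protein_id=f"caldecoy_{i + 1}")
              for i in range(params.n_calibration_decoys)]

    return Benchmark(
        params=params,
        seed_msas=seed_msas,
        proteomes=proteomes,
        annotations=annotations,
        truth_proteins=truth_proteins,
        truth_genomes=truth_genomes,
        ssu_msa=ssu_msa,
        genus_of=genus_of,
        calibration_decoys=decoys,
    )


def write_benchmark(bench: Benchmark, outdir: str | Path) -> None:
    """Materialize a benchmark as plain-text fixtures:
    ``seeds/*.aln.fasta``, ``genomes/*.faa`` + ``*.gff``, ``ssu.aln.fasta``,
    ``truth.tsv``, ``truth_genomes.tsv`` and ``genus_map.tsv``."""
    outdir = Path(outdir)
    (outdir / "seeds").mkdir(parents=True, exist_ok=True)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    for fam, msa in sorted(bench.seed_msas.items()):
        write_msa(msa, outdir / "seeds" / f"{fam.replace('/', '')}.aln.fasta")
    for genome in sorted(bench.proteomes):
        write_fasta(bench.proteomes[genome], outdir / "genomes" / f"{genome}.faa")
        write_gff(bench.annotations[genome], outdir / "genomes" / f"{genome}.gff")
    write_msa(bench.ssu_msa, outdir / "ssu.aln.fasta")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("genome\tlocus_id\tfamily\tgff_label\ttier\trepeat_starts\n")
        for t in bench.truth_proteins:
            fh.write("\t".join([
                t.genome, t.locus_id, t.family, t.gff_label, t.tier,
                ",".join(str(s) for s in t.repeat_starts),
            ]) + "\n")
    with open(outdir / "truth_genomes.tsv", "w") as fh:
        fh.write("genome\tgenus\ttaxon_class\tarchitecture\tfamilies\t"
                 "n_csgAB_paralogs\tcsgH_next_to_AB\n")
        for g in bench.truth_genomes:
            fh.write("\t".join([
                g.genome, g.genus, g.taxon_class, g.architecture,
                ",".join(g.families), str(g.n_csgAB_paralogs),
                "" if g.csgH_next_to_AB is None else str(g.csgH_next_to_AB),
            ]) + "\n")
    with open(outdir / "genus_map.tsv", "w") as fh:
        fh.write("genome\tgenus\ttaxon_class\n")
        for g in bench.truth_genomes:
            fh.write(f"{g.genome}\t{g.genus}\t{g.taxon_class}\n")
    write_fasta(bench.calibration_decoys, outdir / "decoys.faa")
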