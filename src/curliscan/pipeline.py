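"""End-to-end orchestration: seeds -> iterative search -> curation ->
operon/repeat/tree reports, with deterministic plain-text outputs.

The pipeline consumes per-genome protein FASTA and GFF plus one seed
alignment per Csg family, runs the iterative profile-HMM search to
convergence, then derives per-genome gene-content profiles, operon
architecture calls, repeat-architecture tables, validation statistics
(when a truth table is supplied) and NJ trees for the congruence check.
All outputs are sorted and timestamp-free, so a rerun on identical inputs
and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .align import AlignParams, progressive_msa
from .curation import (
    AB_FAMILY,
    NON_PROBATIVE_FAMILIES,
    CurationParams,
    IterationResult,
    ValidationReport,
    iterate,
    repeat_statistics,
    validate,
)
from .io_formats import (
    GeneFeature,
    Msa,
    ProteinRecord,
    read_fasta,
    read_gff,
    read_msa,
    write_hmm,
    write_newick,
)
from .operons import (
    AB_LABELS,
    ArchitectureCall,
    GeneContentProfile,
    assign_csgAB_roles,
    call_operons,
    classify_architecture,
    content_profile,
    csgH_adjacency,
)
from .repeats import architecture as repeat_architecture
from .synthetic import Benchmark, SimParams, sample_decoy
from .trees import Tree, genus_monophyly, neighbor_joining, p_distance, robinson_foulds


@dataclass
class PipelineParams:
    curation: CurationParams = field(default_factory=CurationParams)
    max_gap: int = 200
    divergence_window: int = 1000
    adjacency_window: int = 3
    tree_family: str = "csgF"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineParams":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cur = raw.pop("curation", {})
        cur_known = {f.name for f in dataclasses.fields(CurationParams)}
        bad = set(cur) - cur_known
        if bad:
            raise ValueError(f"unknown curation keys: {sorted(bad)}")
        aln = cur.pop("align", {})
        curation = CurationParams(**cur, align=AlignParams(**aln)) if (cur or aln) \
            else CurationParams()
        return cls(curation=curation, **raw)


@dataclass
class GenomeReport:
    genome: str
    labels: dict[str, str]                 # locus -> family/role label
    content: GeneContentProfile
    architecture: ArchitectureCall | None
    csgH_adjacent: bool | None


@dataclass
class PipelineResult:
    iteration: IterationResult
    genome_reports: dict[str, GenomeReport]
    validation: dict[str, ValidationReport]
    csg_tree: Tree | None
    ssu_tree: Tree | None
    congruence: dict
    repeat_stats: dict | None
    genome_of: dict[str, str]
    seq_of: dict[str, str]


def run_analysis(
    seed_msas: dict[str, Msa],
    proteomes: dict[str, list[ProteinRecord]],
    annotations: dict[str, list[GeneFeature]],
    decoys: list[ProteinRecord],
    params: PipelineParams | None = None,
    ssu_msa: Msa | None = None,
    genus_of: dict[str, str] | None = None,
    taxon_class_of: dict[str, str] | None = None,
    truth_families: dict[str, set[str]] | None = None,
) -> PipelineResult:
    """Run the full annotation workflow over in-memory inputs."""
    params = params or PipelineParams()
    result = iterate(seed_msas, proteomes, annotations, decoys, params.curation)
    genome_of = {rec.id: g for g, recs in proteomes.items() for rec in recs}
    seq_of = {rec.id: rec.sequence for recs in proteomes.values() for rec in recs}

    # locus -> family for loci found in the proteomes (seeds excluded)
    family_of: dict[str, str] = {}
    for fam, members in result.homologs.members.items():
        for locus in members:
            if locus in genome_of:
                family_of[locus] = fam

    genome_reports: dict[str, GenomeReport] = {}
    for genome in sorted(proteomes):
        loci = {l: fam for l, fam in family_of.items() if genome_of[l] == genome}
        feats = annotations.get(genome, [])
        labelled = [
            dataclasses.replace(f, label=loci[f.locus_id])
            for f in feats if f.locus_id in loci
        ]
        ops = call_operons(labelled, params.max_gap)
        arch: ArchitectureCall | None = None
        if any(op.labels for op in ops):
            arch = classify_architecture(ops, params.divergence_window)
        labels = dict(loci)
        tclass = (taxon_class_of or {}).get(genome)
        repeat_loci = {l for l, fam in loci.items() if fam == AB_FAMILY}
        for op in ops:
            member_repeats = {g.locus_id for g in op.genes} & repeat_loci
            if member_repeats:
                for locus, (role, confident) in assign_csgAB_roles(
                    op, member_repeats, tclass
                ).items():
                    if confident:
                        labels[locus] = role
        genome_reports[genome] = GenomeReport(
            genome=genome,
            labels=labels,
            content=content_profile(genome, loci),
            architecture=arch,
            csgH_adjacent=csgH_adjacency(feats, loci, params.adjacency_window),
        )

    validation: dict[str, ValidationReport] = {}
    if truth_families:
        for fam in sorted(truth_families):
            predicted = {l for l, f in family_of.items() if f == fam}
            validation[fam] = validate(
                predicted, truth_families[fam], fam,
                probative=fam not in NON_PROBATIVE_FAMILIES,
            )

    csg_tree = _family_tree(params.tree_family, family_of, genome_of, seq_of,
                            params.curation.align)
    ssu_tree = None
    if ssu_msa is not None and len(ssu_msa.records) >= 3:
        ssu_tree = neighbor_joining(p_distance(ssu_msa))

    congruence: dict = {}
    if genus_of:
        if csg_tree is not None:
            frac, violators = genus_monophyly(
                csg_tree,
                {l: genus_of[l.split("|")[0]] for l in csg_tree.leaf_labels()})
            congruence["csg_monophyly_fraction"] = frac
            congruence["csg_violating_genera"] = violators
        if ssu_tree is not None:
            frac, violators = genus_monophyly(
                ssu_tree, {l: genus_of[l] for l in ssu_tree.leaf_labels()})
            congruence["ssu_monophyly_fraction"] = frac
            congruence["ssu_violating_genera"] = violators
    if csg_tree is not None and ssu_tree is not None and (
        set(csg_tree.leaf_labels()) == set(ssu_tree.leaf_labels())
    ):
        congruence["robinson_foulds"] = robinson_foulds(csg_tree, ssu_tree)

    ab_proteins = {l: seq_of[l] for l, f in family_of.items() if f == AB_FAMILY}
    repeat_stats = repeat_statistics(ab_proteins, params.curation.motif) \
        if ab_proteins else None

    return PipelineResult(
        iteration=result,
        genome_reports=genome_reports,
        validation=validation,
        csg_tree=csg_tree,
        ssu_tree=ssu_tree,
        congruence=congruence,
        repeat_stats=repeat_stats,
        genome_of=genome_of,
        seq_of=seq_of,
    )


def _family_tree(
    family: str,
    family_of: dict[str, str],
    genome_of: dict[str, str],
    seq_of: dict[str, str],
    align_params: AlignParams,
) -> Tree | None:
    """NJ tree of one family's accepted members.

    Leaves are genome ids when each genome contributed one member (the
    common case, enabling direct comparison with a 16S tree), otherwise
    ``genome|locus``.
    """
    members = sorted(l for l, f in family_of.items() if f == family)
    if len(members) < 3:
        return None
    per_genome: dict[str, int] = {}
    for l in members:
        per_genome[genome_of[l]] = per_genome.get(genome_of[l], 0) + 1
    unique = all(c == 1 for c in per_genome.values())
    items = [
        (genome_of[l] if unique else f"{genome_of[l]}|{l}", seq_of[l])
        for l in members
    ]
    msa = progressive_msa(items, align_params)
    return neighbor_joining(p_distance(msa))


# ---------------------------------------------------------------------------
# file-based entry point
# ---------------------------------------------------------------------------

def _family_from_filename(stem: str) -> str:
    name = stem.split(".")[0]
    return "csgA/B" if name in ("csgAB", "csgA_B") else name


def load_inputs(seeds_dir: str | Path, genomes_dir: str | Path):
    """Read seed alignments (``<family>.aln.fasta``) and per-genome
    ``<genome>.faa`` / ``<genome>.gff`` pairs."""
    seeds_dir, genomes_dir = Path(seeds_dir), Path(genomes_dir)
    seed_msas: dict[str, Msa] = {}
    for path in sorted(seeds_dir.glob("*.aln.fasta")):
        seed_msas[_family_from_filename(path.name)] = read_msa(path)
    proteomes: dict[str, list[ProteinRecord]] = {}
    annotations: dict[str, list[GeneFeature]] = {}
    for faa in sorted(genomes_dir.glob("*.faa")):
        genome = faa.stem
        proteomes[genome] = read_fasta(faa)
        gff = faa.with_suffix(".gff")
        if gff.exists():
            annotations[genome] = read_gff(gff)
    return seed_msas, proteomes, annotations


def load_genus_map(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    genus_of: dict[str, str] = {}
    class_of: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if not cols or cols[0] in ("genome", ""):
                continue
            genus_of[cols[0]] = cols[1]
            if len(cols) > 2:
                class_of[cols[0]] = cols[2]
    return genus_of, class_of


def load_truth_families(path: str | Path) -> dict[str, set[str]]:
    """Family -> locus-id truth sets from a generator ``truth.tsv``."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            fam = cols[idx["family"]]
            if fam and fam != "decoy":
                out.setdefault(fam, set()).add(cols[idx["locus_id"]])
    return out


def default_decoys(seed: int, n: int = 400) -> list[ProteinRecord]:
    """Deterministic calibration decoys for file-based runs."""
    rng = np.random.Generator(np.random.PCG64(seed))
    params = SimParams(seed=seed)
    return [sample_decoy(params, rng, protein_id=f"caldecoy_{i + 1}")
            for i in range(n)]


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write homologs.tsv, validation.tsv, architecture.tsv, repeats.tsv,
    models/*.hmm, trees/*.nwk, congruence.tsv and run.log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "models").mkdir(exist_ok=True)
    (outdir / "trees").mkdir(exist_ok=True)

    with open(outdir / "homologs.tsv", "w") as fh:
        fh.write("family\tlocus\tgenome\tbit_score\treason\tn_neighbors\t"
                 "repeat_count\tprobative\n")
        for fam in sorted(result.iteration.homologs.members):
            members = result.iteration.homologs.members[fam]
            for locus in sorted(members):
                d = members[locus]
                fh.write("\t".join([
                    fam, locus, d.genome or "-",
                    "-" if np.isnan(d.bit_score) else f"{d.bit_score:.2f}",
                    d.reason, str(d.n_neighbors), str(d.repeat_count),
                    str(fam not in NON_PROBATIVE_FAMILIES),
                ]) + "\n")

    with open(outdir / "validation.tsv", "w") as fh:
        fh.write("Model\tHits\tCorrect hits\tMissing hits\tProbative\n")
        for fam in sorted(result.validation):
            rep = result.validation[fam]
            fh.write(f"{fam}\t{rep.row()}\t{rep.probative}\n")

    with open(outdir / "architecture.tsv", "w") as fh:
        fh.write("genome\tarchitecture\tcsgD_location\toperons\tcontent\t"
                 "n_csgAB_paralogs\tcsgH_adjacent\n")
        for genome in sorted(result.genome_reports):
            rep = result.genome_reports[genome]
            if rep.architecture:
                ops = ";".join(
                    "|".join(f"{g.locus_id}({rep.labels.get(g.locus_id, '?')}{op.strand})"
                             for g in op.genes)
                    for op in rep.architecture.operons
                )
                arch, dloc = rep.architecture.architecture, rep.architecture.csgD_location
            else:
                ops, arch, dloc = "", "none", "absent"
            c = rep.content
            content = ",".join(
                name for name, flag in [
                    ("csgA/B", c.csgAB), ("csgC", c.csgC), ("csgD", c.csgD),
                    ("csgE", c.csgE), ("csgF", c.csgF), ("csgG", c.csgG),
                    ("csgH", c.csgH)] if flag
            )
            adj = "" if rep.csgH_adjacent is None else str(rep.csgH_adjacent)
            fh.write(f"{genome}\t{arch}\t{dloc}\t{ops}\t{content}\t"
                     f"{c.n_csgAB_paralogs}\t{adj}\n")

    with open(outdir / "repeats.tsv", "w") as fh:
        fh.write("protein_id\tn_repeats\tstarts\toverlapping_pairs\tfunctional\n")
        ab = result.iteration.homologs.members.get(AB_FAMILY, {})
        for locus in sorted(l for l in ab if l in result.seq_of):
            arch = repeat_architecture(
                ProteinRecord(id=locus, sequence=result.seq_of[locus]))
            fh.write("\t".join([
                locus, str(arch.n_repeats),
                ",".join(str(m.start) for m in arch.matches),
                str(arch.overlapping_pairs), str(arch.functional),
            ]) + "\n")

    for fam in sorted(result.iteration.models):
        write_hmm(result.iteration.models[fam],
                  outdir / "models" / f"{fam.replace('/', '')}.hmm")
    if result.csg_tree is not None:
        write_newick(result.csg_tree, outdir / "trees" / "csg.nwk")
    if result.ssu_tree is not None:
        write_newick(result.ssu_tree, outdir / "trees" / "ssu.nwk")
    with open(outdir / "congruence.tsv", "w") as fh:
        for key in sorted(result.congruence):
            val = result.congruence[key]
            if isinstance(val, list):
                val = ",".join(val)
            fh.write(f"{key}\t{val}\n")

    with open(outdir / "run.log", "w") as fh:
        it = result.iteration
        fh.write(f"iterations\t{it.n_iterations}\nconverged\t{it.converged}\n")
        for fam in sorted(it.cutoffs):
            fh.write(f"cutoff_bits\t{fam}\t{it.cutoffs[fam]:.3f}\n")
        for d in it.decisions:
            fh.write("\t".join([
                "decision", d.family, d.locus, f"{d.bit_score:.2f}",
                "accept" if d.accepted else "reject", d.reason,
                f"neighbors={d.n_neighbors}", f"repeats={d.repeat_count}",
            ]) + "\n")


def evaluate_against_truth(result: PipelineResult, bench: Benchmark) -> dict:
    """Benchmark metrics against generator truth: pooled sensitivity,
    decoy specificity, convergence, architecture recovery, congruence and
    subunit repeat statistics."""
    truth_by_family: dict[str, set[str]] = {}
    decoy_loci: set[str] = set()
    for t in bench.truth_proteins:
        if t.family == "decoy":
            decoy_loci.add(t.locus_id)
        else:
            truth_by_family.setdefault(t.family, set()).add(t.locus_id)
    predicted: dict[str, set[str]] = {}
    for fam, members in result.iteration.homologs.members.items():
        predicted[fam] = {l for l in members if l in result.genome_of}

    truth_all = set().union(*truth_by_family.values())
    pred_all = set().union(*predicted.values()) if predicted else set()
    tp = len(pred_all & truth_all)
    fp = len(pred_all & decoy_loci)
    metrics: dict = {
        "sensitivity": tp / len(truth_all),
        "decoy_specificity": 1 - fp / len(decoy_loci),
        "n_iterations": result.iteration.n_iterations,
        "converged": result.iteration.converged,
    }
    arch_ok = 0
    classes_recovered = set()
    for tg in bench.truth_genomes:
        rep = result.genome_reports.get(tg.genome)
        called = rep.architecture.architecture if rep and rep.architecture else "none"
        if called == tg.architecture:
            arch_ok += 1
            classes_recovered.add(called)
    metrics["architecture_accuracy"] = arch_ok / len(bench.truth_genomes)
    metrics["n_architecture_classes_recovered"] = len(classes_recovered)
    metrics.update(result.congruence)
    if result.repeat_stats:
        for k, v in result.repeat_stats.items():
            metrics[f"csgAB_{k}"] = v
    for fam, rep in result.validation.items():
        tag = fam.replace("/", "")
        metrics[f"{tag}_correct_pct"] = rep.correct_pct
        metrics[f"{tag}_missing_pct"] = rep.missing_pct
    return metrics


def run_benchmark_pipeline(bench: Benchmark, params: PipelineParams | None = None) -> PipelineResult:
    """Convenience wrapper: run the full analysis on a generator benchmark."""
    truth: dict[str, set[str]] = {}
    for t in bench.truth_proteins:
        if t.family != "decoy":
            truth.setdefault(t.family, set()).add(t.locus_id)
    taxon_class = {g.genome: g.taxon_class for g in bench.truth_genomes}
    return run_analysis(
        bench.seed_msas,
        bench.proteomes,
        bench.annotations,
        bench.calibration_decoys,
        params=params,
        ssu_msa=bench.ssu_msa,
        genus_of=bench.genus_of,
        taxon_class_of=taxon_class,
        truth_families=truth,
    )
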