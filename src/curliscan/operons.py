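"""csg operon reconstruction and architecture classification.

Operons are called as maximal runs of same-contig, same-strand genes with
intergenic gaps at or below ``max_gap``.  The architecture classes follow
the canonical layouts observed across curli-carrying taxa:

* ``divergent_two_operon`` -- csgBAC and csgDEFG transcribed away from a
  shared intergenic region (the E. coli / Salmonella layout);
* ``co_oriented_two_operon`` -- the same two operons on one strand;
* ``divergent_csgD_detached`` -- divergent subunit and accessory operons
  with csgD transcribed alone;
* ``single_operon_csgD_divergent`` -- csgBAEFG in one operon with csgD
  divergently oriented next to it;
* ``single_operon`` -- every csg gene in one transcription unit;
* ``other`` -- anything else.

"Divergent" means the two transcription units point away from a shared
intergenic region, i.e. their 5' ends face each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import GeneFeature

AB_LABELS = {"csgA", "csgB", "csgA/B"}
EFG_LABELS = {"csgE", "csgF", "csgG"}
ARCHITECTURE_CLASSES = (
    "divergent_two_operon",
    "co_oriented_two_operon",
    "divergent_csgD_detached",
    "single_operon_csgD_divergent",
    "single_operon",
    "other",
)


@dataclass
class OperonModel:
    """An ordered, stranded run of genes treated as one transcription unit."""

    contig: str
    strand: str
    genes: list[GeneFeature]

    @property
    def start(self) -> int:
        return min(g.start for g in self.genes)

    @property
    def end(self) -> int:
        return max(g.end for g in self.genes)

    @property
    def head(self) -> int:
        """Coordinate of the transcription start (5' end) of the unit."""
        return self.start if self.strand == "+" else self.end

    @property
    def labels(self) -> set[str]:
        return {g.label for g in self.genes if g.label}

    def labelled_genes(self) -> list[GeneFeature]:
        genes = [g for g in self.genes if g.label]
        return genes if self.strand == "+" else list(reversed(genes))


@dataclass
class ArchitectureCall:
    architecture: str
    operons: list[OperonModel]
    csgD_location: str  # in_operon / detached / absent


@dataclass
class GeneContentProfile:
    taxon: str
    csgAB: bool
    csgC: bool
    csgD: bool
    csgE: bool
    csgF: bool
    csgG: bool
    csgH: bool
    n_csgAB_paralogs: int


def call_operons(features: list[GeneFeature], max_gap: int = 200) -> list[OperonModel]:
    """Partition genes into operons: maximal same-contig, same-strand runs
    with intergenic gaps <= ``max_gap`` base pairs."""
    by_contig: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_contig.setdefault(f.contig, []).append(f)
    operons: list[OperonModel] = []
    for contig in sorted(by_contig):
        genes = sorted(by_contig[contig], key=lambda g: (g.start, g.end))
        current: list[GeneFeature] = []
        for g in genes:
            if (
                current
                and g.strand == current[-1].strand
                and g.start - current[-1].end <= max_gap
            ):
                current.append(g)
            else:
                if current:
                    operons.append(OperonModel(contig, current[0].strand, current))
                current = [g]
        if current:
            operons.append(OperonModel(contig, current[0].strand, current))
    return operons


def _divergent(a: OperonModel, b: OperonModel, window: int) -> bool:
    """True when a and b transcribe away from a shared intergenic region
    of at most ``window`` bp (their heads are the facing ends)."""
    if a.contig != b.contig or a.strand == b.strand:
        return False
    left, right = (a, b) if a.start <= b.start else (b, a)
    gap = right.start - left.end
    return left.strand == "-" and right.strand == "+" and 0 <= gap <= window


def _adjacent(a: OperonModel, b: OperonModel, window: int) -> bool:
    if a.contig != b.contig:
        return False
    left, right = (a, b) if a.start <= b.start else (b, a)
    return 0 <= right.start - left.end <= window


def classify_architecture(
    operons: list[OperonModel], divergence_window: int = 1000
) -> ArchitectureCall:
    """Classify the csg gene layout of one genome (see module docstring)."""
    csg_ops = [op for op in operons if op.labels]
    if not csg_ops:
        raise ValueError("no csg-labelled genes among the supplied operons")

    has_d = any("csgD" in op.labels for op in csg_ops)
    d_ops = [op for op in csg_ops if op.labels == {"csgD"}]
    if not has_d:
        d_loc = "absent"
    elif d_ops:
        d_loc = "detached"
    else:
        d_loc = "in_operon"

    ab_ops = [op for op in csg_ops if op.labels & AB_LABELS]
    efg_ops = [op for op in csg_ops if len(op.labels & EFG_LABELS) >= 2]

    def call(name: str) -> ArchitectureCall:
        return ArchitectureCall(name, csg_ops, d_loc)

    if len(csg_ops) == 1:
        return call("single_operon")

    if len(csg_ops) == 2:
        a, b = csg_ops
        if d_ops:
            main = a if b in d_ops else b
            d = b if main is a else a
            if main.labels & AB_LABELS and len(main.labels & EFG_LABELS) >= 2:
                if main.strand != d.strand and _adjacent(main, d, divergence_window):
                    return call("single_operon_csgD_divergent")
                return call("other")
            return call("other")
        ab = [op for op in (a, b) if op.labels & AB_LABELS and not op.labels & EFG_LABELS]
        efg = [op for op in (a, b) if len(op.labels & EFG_LABELS) >= 2]
        if len(ab) == 1 and len(efg) == 1 and ab[0] is not efg[0]:
            if _divergent(ab[0], efg[0], divergence_window):
                return call("divergent_two_operon")
            if ab[0].strand == efg[0].strand and _adjacent(ab[0], efg[0], divergence_window):
                return call("co_oriented_two_operon")
        return call("other")

    if len(csg_ops) == 3 and len(d_ops) == 1:
        rest = [op for op in csg_ops if op not in d_ops]
        ab = [op for op in rest if op.labels & AB_LABELS and not op.labels & EFG_LABELS]
        efg = [op for op in rest if len(op.labels & EFG_LABELS) >= 2]
        if len(ab) == 1 and len(efg) == 1 and _divergent(ab[0], efg[0], divergence_window):
            return call("divergent_csgD_detached")
    return call("other")


def content_profile(
    taxon: str, homolog_labels: dict[str, str]
) -> GeneContentProfile:
    """Gene-content flags for one genome.

    ``homolog_labels`` maps locus id -> csg family label (csgA, csgB,
    csgA/B, csgC..csgH).
    """
    labels = list(homolog_labels.values())
    n_ab = sum(1 for lab in labels if lab in AB_LABELS)
    return GeneContentProfile(
        taxon=taxon,
        csgAB=n_ab > 0,
        csgC="csgC" in labels,
        csgD="csgD" in labels,
        csgE="csgE" in labels,
        csgF="csgF" in labels,
        csgG="csgG" in labels,
        csgH="csgH" in labels,
        n_csgAB_paralogs=n_ab,
    )


def csgH_adjacency(
    features: list[GeneFeature],
    homolog_labels: dict[str, str],
    adjacency_window: int = 3,
) -> bool | None:
    """Whether a csgH gene lies within ``adjacency_window`` genes of a
    csgA/B gene on the same contig; ``None`` (not applicable) without csgH."""
    h_loci = {l for l, lab in homolog_labels.items() if lab == "csgH"}
    ab_loci = {l for l, lab in homolog_labels.items() if lab in AB_LABELS}
    if not h_loci:
        return None
    by_contig: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_contig.setdefault(f.contig, []).append(f)
    for contig, genes in by_contig.items():
        genes = sorted(genes, key=lambda g: g.start)
        index = {g.locus_id: i for i, g in enumerate(genes)}
        for h in h_loci:
            if h not in index:
                continue
            for ab in ab_loci:
                if ab in index and abs(index[h] - index[ab]) <= adjacency_window:
                    return True
    return False


def assign_csgAB_roles(
    operon: OperonModel,
    repeat_loci: set[str],
    taxon_class: str | None,
) -> dict[str, tuple[str, bool]]:
    """Distinguish the nucleator (CsgB) from the major subunit (CsgA).

    Only within the Gammaproteobacteria, and only with a csgBAC-like
    layout (>= 2 repeat-bearing genes in the operon), is the repeat gene
    proximal to the transcription start labelled csgB and the next csgA.
    Everything else is the ambiguous label csgA/B; the boolean marks a
    confident call.
    """
    genes = operon.labelled_genes() or (
        operon.genes if operon.strand == "+" else list(reversed(operon.genes))
    )
    ordered_repeat = [g.locus_id for g in genes if g.locus_id in repeat_loci]
    out: dict[str, tuple[str, bool]] = {}
    if taxon_class == "Gammaproteobacteria" and len(ordered_repeat) >= 2:
        out[ordered_repeat[0]] = ("csgB", True)
        out[ordered_repeat[1]] = ("csgA", True)
        for locus in ordered_repeat[2:]:
            out[locus] = ("csgA/B", False)
    else:
        for locus in ordered_repeat:
            out[locus] = ("csgA/B", False)
    return out
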