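import pytest

from curliscan.io_formats import GeneFeature
from curliscan.operons import (
    OperonModel,
    assign_csgAB_roles,
    call_operons,
    classify_architecture,
    content_profile,
    csgH_adjacency,
)


def _genes(spec, contig="c1"):
    """[(start, end, strand, locus, label), ...] -> features"""
    return [GeneFeature(contig, s, e, st, loc, lab) for s, e, st, loc, lab in spec]


class TestCallOperons:
    def test_small_gap_joins(self):
        ops = call_operons(_genes([(0, 300, "+", "g1", None),
                                   (350, 600, "+", "g2", None)]), max_gap=200)
        assert len(ops) == 1 and len(ops[0].genes) == 2

    def test_large_gap_splits(self):
        ops = call_operons(_genes([(0, 300, "+", "g1", None),
                                   (800, 1100, "+", "g2", None)]), max_gap=200)
        assert len(ops) == 2

    def test_strand_change_splits_regardless_of_gap(self):
        ops = call_operons(_genes([(0, 300, "+", "g1", None),
                                   (310, 600, "-", "g2", None)]), max_gap=200)
        assert len(ops) == 2

    def test_partition_is_exact(self):
        feats = _genes([(i * 400, i * 400 + 300, "+-"[i % 2], f"g{i}", None)
                        for i in range(8)])
        ops = call_operons(feats)
        loci = [g.locus_id for op in ops for g in op.genes]
        assert sorted(loci) == sorted(f.locus_id for f in feats)
        assert len(loci) == len(set(loci))


def _ecoli_layout():
    # <-GFED ... BAC->  divergent heads 300 bp apart
    return _genes([
        (0, 500, "-", "gG", "csgG"),
        (550, 900, "-", "gF", "csgF"),
        (950, 1250, "-", "gE", "csgE"),
        (1300, 1900, "-", "gD", "csgD"),
        (2200, 2600, "+", "gB", "csgB"),
        (2650, 3100, "+", "gA", "csgA"),
        (3150, 3500, "+", "gC", "csgC"),
    ])


def _translate(feats, offset):
    return [GeneFeature(f.contig, f.start + offset, f.end + offset, f.strand,
                        f.locus_id, f.label) for f in feats]


def _reverse_complement(feats, length=10_000):
    return [GeneFeature(f.contig, length - f.end, length - f.start,
                        "+" if f.strand == "-" else "-", f.locus_id, f.label)
            for f in feats]


class TestClassify:
    def test_divergent_two_operon(self):
        call = classify_architecture(call_operons(_ecoli_layout(), 200))
        assert call.architecture == "divergent_two_operon"
        assert call.csgD_location == "in_operon"

    def test_co_oriented_two_operon(self):
        feats = _genes([
            (0, 500, "+", "gD", "csgD"),
            (550, 900, "+", "gE", "csgE"),
            (950, 1250, "+", "gF", "csgF"),
            (1300, 1900, "+", "gG", "csgG"),
            (2200, 2600, "+", "gB", "csgB"),
            (2650, 3100, "+", "gA", "csgA"),
            (3150, 3500, "+", "gC", "csgC"),
        ])
        call = classify_architecture(call_operons(feats, 200))
        assert call.architecture == "co_oriented_two_operon"

    def test_csgD_detached(self):
        feats = _genes([
            (0, 500, "-", "gG", "csgG"),
            (550, 900, "-", "gF", "csgF"),
            (950, 1250, "-", "gE", "csgE"),
            (1550, 1950, "+", "gB", "csgB"),
            (2000, 2450, "+", "gA", "csgA"),
            (2500, 2850, "+", "gC", "csgC"),
            (8000, 8600, "+", "gD", "csgD"),
        ])
        call = classify_architecture(call_operons(feats, 200))
        assert call.architecture == "divergent_csgD_detached"
        assert call.csgD_location == "detached"

    def test_single_operon_csgD_divergent(self):
        feats = _genes([
            (0, 400, "+", "gB", "csgB"),
            (450, 900, "+", "gA", "csgA"),
            (950, 1250, "+", "gE", "csgE"),
            (1300, 1650, "+", "gF", "csgF"),
            (1700, 2250, "+", "gG", "csgG"),
            (2550, 3150, "-", "gD", "csgD"),
        ])
        call = classify_architecture(call_operons(feats, 200))
        assert call.architecture == "single_operon_csgD_divergent"

    def test_single_operon(self):
        feats = _genes([
            (0, 300, "+", "gH", "csgH"),
            (350, 750, "+", "gAB", "csgA/B"),
            (800, 1150, "+", "gF", "csgF"),
            (1200, 1750, "+", "gG", "csgG"),
        ])
        call = classify_architecture(call_operons(feats, 200))
        assert call.architecture == "single_operon"
        assert call.csgD_location == "absent"

    def test_no_csg_labels_is_error(self):
        ops = call_operons(_genes([(0, 300, "+", "g1", None)]))
        with pytest.raises(ValueError):
            classify_architecture(ops)

    @pytest.mark.parametrize("transform", [
        lambda f: _translate(f, 5000),
        _reverse_complement,
        lambda f: _reverse_complement(_translate(f, 1234), 20_000),
    ])
    def test_invariance_under_translation_and_reverse_complement(self, transform):
        base = classify_architecture(call_operons(_ecoli_layout(), 200))
        moved = classify_architecture(call_operons(transform(_ecoli_layout()), 200))
        assert moved.architecture == base.architecture
        assert moved.csgD_location == base.csgD_location


class TestContentAndAdjacency:
    def test_alpha_style_profile(self):
        labels = {"g1": "csgH", "g2": "csgA/B", "g3": "csgA/B",
                  "g4": "csgF", "g5": "csgG"}
        prof = content_profile("alpha", labels)
        assert (prof.csgC, prof.csgD, prof.csgE) == (False, False, False)
        assert prof.csgH and prof.csgAB and prof.csgF and prof.csgG
        assert prof.n_csgAB_paralogs == 2

    def test_six_paralogs_counted(self):
        labels = {f"g{i}": "csgA/B" for i in range(6)}
        assert content_profile("x", labels).n_csgAB_paralogs == 6

    def test_empty_homolog_set(self):
        prof = content_profile("x", {})
        assert not any([prof.csgAB, prof.csgC, prof.csgD, prof.csgE,
                        prof.csgF, prof.csgG, prof.csgH])

    def test_csgH_directly_beside_subunit(self):
        feats = _genes([(0, 300, "+", "gH", None), (350, 700, "+", "gAB", None)])
        assert csgH_adjacency(feats, {"gH": "csgH", "gAB": "csgA/B"}) is True

    def test_csgH_far_away(self):
        feats = _genes([(i * 400, i * 400 + 300, "+", f"g{i}", None)
                        for i in range(12)])
        labels = {"g0": "csgH", "g11": "csgA/B"}
        assert csgH_adjacency(feats, labels, adjacency_window=3) is False

    def test_no_csgH_not_applicable(self):
        feats = _genes([(0, 300, "+", "gAB", None)])
        assert csgH_adjacency(feats, {"gAB": "csgA/B"}) is None


class TestSubunitRoles:
    def _operon(self, strand="+"):
        spec = [(0, 400, strand, "gB", None), (450, 900, strand, "gA", None),
                (950, 1250, strand, "gC", None)]
        genes = _genes(spec)
        if strand == "-":
            genes = genes  # coordinates identical; strand drives orientation
        return OperonModel("c1", strand, genes)

    def test_enterobacterial_layout_assigns_B_then_A(self):
        roles = assign_csgAB_roles(self._operon("+"), {"gB", "gA"},
                                   "Gammaproteobacteria")
        assert roles["gB"] == ("csgB", True)
        assert roles["gA"] == ("csgA", True)

    def test_reverse_strand_uses_transcription_order(self):
        roles = assign_csgAB_roles(self._operon("-"), {"gB", "gA"},
                                   "Gammaproteobacteria")
        # on the minus strand the rightmost repeat gene is proximal to the
        # transcription start, so the role order flips
        assert roles["gA"] == ("csgB", True)
        assert roles["gB"] == ("csgA", True)

    def test_non_gamma_taxa_stay_ambiguous(self):
        roles = assign_csgAB_roles(self._operon("+"), {"gB", "gA"}, "Bacteroidetes")
        assert all(v == ("csgA/B", False) for v in roles.values())

    def test_single_repeat_gene_low_confidence(self):
        roles = assign_csgAB_roles(self._operon("+"), {"gB"},
                                   "Gammaproteobacteria")
        assert roles["gB"] == ("csgA/B", False)
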