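import numpy as np
import pytest

from curliscan.curation import (
    AB_FAMILY,
    CurationParams,
    curate_hits,
    iterate,
    repeat_statistics,
    validate,
)
from curliscan.io_formats import GeneFeature, Msa, ProteinRecord
from curliscan.phmm import HmmHit


def _hit(locus, score=30.0):
    return HmmHit(locus, score, 0, 10, (0, 10), 1e-3)


def _rank_index(n, contig="c"):
    return {f"g{i}": (contig, i) for i in range(n)}


class TestCurateHits:
    def test_subunit_accepted_on_repeats_alone(self):
        d, = curate_hits(AB_FAMILY, [_hit("g0")], _rank_index(1), {"g0": "G"},
                         csg_context=set(), repeat_counts={"g0": 3},
                         params=CurationParams())
        assert d.accepted and d.reason == "repeats"

    def test_accessory_accepted_on_neighborhood(self):
        d, = curate_hits("csgF", [_hit("g3")], _rank_index(10), {"g3": "G"},
                         csg_context={"g5"}, repeat_counts={},
                         params=CurationParams())
        assert d.accepted and d.reason == "neighborhood" and d.n_neighbors == 1

    def test_isolated_low_repeat_candidate_rejected(self):
        d, = curate_hits("csgF", [_hit("g0")], _rank_index(20), {"g0": "G"},
                         csg_context={"g15"}, repeat_counts={"g0": 1},
                         params=CurationParams())
        assert not d.accepted and d.reason == "rejected"

    def test_candidate_never_corroborates_itself(self):
        d, = curate_hits("csgF", [_hit("g0")], _rank_index(1), {"g0": "G"},
                         csg_context={"g0"}, repeat_counts={},
                         params=CurationParams())
        assert not d.accepted

    def test_unannotated_genome_held_not_dropped(self):
        d, = curate_hits("csgF", [_hit("orphan")], {}, {"orphan": "G"},
                         csg_context=set(), repeat_counts={},
                         params=CurationParams())
        assert d.accepted and d.unplaceable and d.reason == "unplaceable"


class TestValidate:
    def test_table_row_arithmetic(self):
        rep = validate(set("abcdefgh"), set("abcdefg") | {"x", "y", "z"}, "m")
        assert rep.row() == "8\t7/8 (88%)\t3/10 (30%)"

    def test_perfect_model_row(self):
        ids = {f"p{i}" for i in range(172)}
        rep = validate(ids, ids, "CsgF")
        assert rep.row() == "172\t172/172 (100%)\t0/172 (0%)"

    def test_disjoint_prediction(self):
        rep = validate({"a", "b"}, {"c", "d"}, "m")
        assert rep.correct_pct == 0 and rep.missing_pct == 100

    def test_empty_truth_is_error(self):
        with pytest.raises(ValueError):
            validate({"a"}, set(), "m")


class TestIterate:
    def _seed_msa(self):
        rows = [("seed_1", "MKQWENDYRAGH"), ("seed_2", "MKQWANDYRAGH"),
                ("seed_3", "MKQWGNDYRAGH")]
        return {"csgF": Msa(rows)}

    def _decoys(self, n=120):
        rng = np.random.default_rng(42)
        return [ProteinRecord(f"d{i}", "".join(
            rng.choice(list("ACDEFHIKLMPRSTVWY"), size=60))) for i in range(n)]

    def test_seed_only_proteome_is_a_fixed_point(self):
        seeds = self._seed_msa()
        proteome = {"gen": [ProteinRecord(rid, seeds["csgF"].records[i][1])
                            for i, (rid, _) in enumerate([("seed_1", None),
                                                          ("seed_2", None),
                                                          ("seed_3", None)])]}
        res = iterate(seeds, proteome, {}, self._decoys())
        assert res.n_iterations == 1 and res.converged
        assert res.homologs.family_ids("csgF") == {"seed_1", "seed_2", "seed_3"}

    def test_empty_proteome_converges_immediately(self):
        res = iterate(self._seed_msa(), {}, {}, self._decoys())
        assert res.n_iterations == 1 and res.converged
        # nothing beyond the seed database itself
        assert res.homologs.family_ids("csgF") == {"seed_1", "seed_2", "seed_3"}

    def test_homolog_set_is_monotone_and_remote_needs_a_second_round(
            self, bench, bench_run):
        it = bench_run.iteration
        tier = {t.locus_id: t.tier for t in bench.truth_proteins}
        accepted_rounds = {}
        for d in it.decisions:
            if d.accepted and d.locus in tier:
                accepted_rounds[d.locus] = d.iteration
        remote = [l for l, t in tier.items() if t == "remote"]
        near_or_mid = [l for l, t in tier.items() if t in ("near", "mid")]
        assert remote and all(accepted_rounds[l] >= 2 for l in remote)
        assert all(accepted_rounds[l] == 1 for l in near_or_mid)

    def test_iterate_is_deterministic(self, bench):
        sub_prot = {g: bench.proteomes[g] for g in list(bench.proteomes)[:2]}
        sub_ann = {g: bench.annotations[g] for g in sub_prot}
        r1 = iterate(bench.seed_msas, sub_prot, sub_ann,
                     bench.calibration_decoys[:120])
        r2 = iterate(bench.seed_msas, sub_prot, sub_ann,
                     bench.calibration_decoys[:120])
        assert {f: sorted(m) for f, m in r1.homologs.members.items()} == \
            {f: sorted(m) for f, m in r2.homologs.members.items()}
        assert r1.cutoffs == r2.cutoffs


class TestRepeatStatistics:
    def test_summary_arithmetic(self):
        pos = "AAAAAAQAGAANAAAAAAAAAA"
        proteins = {
            "two": pos + pos,          # functional
            "one": pos,                # single repeat
            "none": "MKLPMKLPMKLP",
        }
        stats = repeat_statistics(proteins)
        assert stats["n_proteins"] == 3
        assert stats["n_functional"] == 1
        assert stats["functional_pct"] == 33
        assert stats["max_length"] == 44
        assert stats["max_repeats"] == 2

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            repeat_statistics({})
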