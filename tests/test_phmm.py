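import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_hmm_scores, random_profile_hmm
from curliscan import phmm
from curliscan.io_formats import Msa, ProteinRecord
from curliscan.phmm import (
    ProfileHMM,
    build_profile,
    calibrate,
    forward,
    search,
    viterbi,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _single_state_model(residue="Q", p=0.999999999):
    em = np.full((1, 20), (1 - p) / 19)
    em[0, AA.index(residue)] = p
    tr = np.tile([1 / 3, 1 / 3, 1 / 3, 0.5, 0.5, 0.5, 0.5], (2, 1))
    return ProfileHMM("one", em, np.full(20, 0.05), tr, np.full(20, 0.05))


class TestBuildProfile:
    def test_pseudocount_estimator_hand_arithmetic(self):
        # column {Q,Q,N,N}, uniform background 0.05, weight 1:
        # P(Q) = (2 + 0.05) / 5 = 0.41
        msa = Msa([("a", "Q"), ("b", "Q"), ("c", "N"), ("d", "N")])
        hmm = build_profile(msa, pseudocount_weight=1.0)
        assert hmm.match_emissions[0, AA.index("Q")] == pytest.approx(0.41)
        assert hmm.match_emissions[0, AA.index("N")] == pytest.approx(0.41)

    def test_vanishing_weight_limit(self):
        msa = Msa([("a", "NQ")])
        hmm = build_profile(msa, pseudocount_weight=1e-9)
        assert hmm.match_emissions[0, AA.index("N")] == pytest.approx(1.0)
        assert hmm.match_emissions[1, AA.index("Q")] == pytest.approx(1.0)

    def test_majority_gap_column_is_not_a_match_state(self):
        msa = Msa([("a", "MQ"), ("b", "M-"), ("c", "M-"), ("d", "M-")])
        hmm = build_profile(msa)
        assert hmm.n_match == 1  # the 3/4-gap column became insert context

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(ValueError, match="consensus"):
            build_profile(Msa([("a", "-M"), ("b", "M-")]))

    def test_row_order_invariance(self):
        rows = [("a", "MKQW"), ("b", "MK-W"), ("c", "MRQW"), ("d", "AKQW")]
        h1 = build_profile(Msa(rows))
        h2 = build_profile(Msa(rows[::-1]))
        np.testing.assert_allclose(h1.match_emissions, h2.match_emissions)
        np.testing.assert_allclose(h1.transitions, h2.transitions)


class TestViterbiForward:
    def test_single_match_state_closed_form(self):
        hmm = _single_state_model("Q", p=1 - 1e-12)
        path, score = viterbi(hmm, "Q")
        assert path == [("M", 1, 0)]
        assert score == pytest.approx(math.log2(1 / 0.05), abs=1e-6)

    def test_single_path_degenerate_forward_equals_viterbi(self):
        hmm = _single_state_model("Q")
        _, v = viterbi(hmm, "Q")
        assert forward(hmm, "Q") == pytest.approx(v, abs=1e-6)

    def test_below_background_sequence_scores_nonpositive(self):
        em = np.full((2, 20), 1 / 20)
        em[:, AA.index("W")] = 1e-6
        em /= em.sum(axis=1, keepdims=True)
        tr = np.tile([1 / 3, 1 / 3, 1 / 3, 0.5, 0.5, 0.5, 0.5], (3, 1))
        hmm = ProfileHMM("w", em, np.full(20, 0.05), tr, np.full(20, 0.05))
        _, score = viterbi(hmm, "WWWWW")
        assert score <= 0

    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        k=st.integers(1, 3),
        length=st.integers(1, 6),
    )
    def test_scores_match_bruteforce_path_enumeration(self, seed, k, length):
        rng = np.random.default_rng(seed)
        hmm = random_profile_hmm(rng, k)
        seq = "".join(rng.choice(list(AA), size=length))
        bv, bf = brute_force_hmm_scores(hmm, seq)
        assert viterbi(hmm, seq, want_path=False)[1] == pytest.approx(bv, abs=1e-9)
        assert forward(hmm, seq) == pytest.approx(bf, abs=1e-9)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_forward_dominates_viterbi(self, seed):
        rng = np.random.default_rng(seed)
        hmm = random_profile_hmm(rng, int(rng.integers(1, 5)))
        seq = "".join(rng.choice(list(AA), size=rng.integers(1, 12)))
        assert forward(hmm, seq) >= viterbi(hmm, seq, want_path=False)[1] - 1e-9

    def test_hit_interval_within_target(self, rng):
        msa = Msa([("a", "MKQWENDY"), ("b", "MKQWANDY"), ("c", "MKQWGNDY")])
        hmm = build_profile(msa)
        seq = "AAAAAMKQWENDYAAAAA"
        path, score = viterbi(hmm, seq)
        emitted = [p for _, _, p in path if p is not None]
        assert 0 <= min(emitted) and max(emitted) < len(seq)
        assert seq[min(emitted):max(emitted) + 1] == "MKQWENDY"


class TestSearchCalibrate:
    def test_consensus_sequence_is_top_hit(self):
        msa = Msa([("a", "MKQWENDYRA"), ("b", "MKQWANDYRA"), ("c", "MKQWGNDYRA")])
        hmm = build_profile(msa)
        proteome = [
            ProteinRecord("target", "GGGG" + hmm.consensus() + "PPPP"),
            ProteinRecord("junk", "PLPLPLPLPLPLPL"),
        ]
        hits = search(hmm, proteome, cutoff_bits=5.0)
        assert hits and hits[0].target_id == "target"
        assert hits[0].evalue_surrogate == pytest.approx(
            2 * 2 ** (-hits[0].bit_score))

    def test_calibrate_quantile_arithmetic(self, monkeypatch):
        scores = iter(range(1, 101))
        monkeypatch.setattr(
            phmm, "viterbi", lambda h, s, want_path=True: (None, float(next(scores))))
        hmm = _single_state_model()
        decoys = [ProteinRecord(f"d{i}", "AAAA") for i in range(100)]
        assert calibrate(hmm, decoys, fpr=0.01) == 100.0

    def test_calibrate_fpr_zero_is_max(self, monkeypatch):
        vals = iter([5.0] * 99 + [17.0])
        monkeypatch.setattr(
            phmm, "viterbi", lambda h, s, want_path=True: (None, next(vals)))
        decoys = [ProteinRecord(f"d{i}", "AAAA") for i in range(100)]
        assert calibrate(_single_state_model(), decoys, fpr=0.0) == 17.0

    def test_calibrate_constant_scores(self, monkeypatch):
        monkeypatch.setattr(
            phmm, "viterbi", lambda h, s, want_path=True: (None, 3.5))
        decoys = [ProteinRecord(f"d{i}", "AAAA") for i in range(120)]
        assert calibrate(_single_state_model(), decoys, fpr=0.05) == 3.5

    def test_calibrate_requires_100_decoys(self):
        with pytest.raises(ValueError, match="100"):
            calibrate(_single_state_model(),
                      [ProteinRecord("d", "AAAA")] * 99, fpr=0.01)

    def test_decoy_false_positive_rate_at_calibrated_cutoff(self, bench):
        """A fresh decoy set should rarely exceed the calibrated cutoff."""
        from curliscan.synthetic import SimParams, sample_decoy

        hmm = build_profile(bench.seed_msas["csgF"])
        cutoff = calibrate(hmm, bench.calibration_decoys, fpr=0.01)
        rng = np.random.default_rng(777)
        fresh = [sample_decoy(SimParams(seed=0), rng, f"f{i}") for i in range(100)]
        hits = search(hmm, fresh, cutoff)
        assert len(hits) <= 3

    def test_planted_family_fully_recovered(self, bench):
        hmm = build_profile(bench.seed_msas["csgA/B"])
        cutoff = calibrate(hmm, bench.calibration_decoys, fpr=0.01)
        ab_truth = {t.locus_id for t in bench.truth_proteins if t.family == "csgA/B"}
        proteome = [r for recs in bench.proteomes.values() for r in recs]
        found = {h.target_id for h in search(hmm, proteome, cutoff)}
        assert ab_truth <= found
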