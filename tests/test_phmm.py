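"""Profile-HMM engine: format I/O, estimation, and Viterbi scoring.

The central check is an exhaustive path-enumeration oracle: for tiny
models (M <= 3) and short sequences (length <= 4) every legal local
alignment path is enumerated and its log2-odds summed directly; the
dynamic-programming score must match the best enumerated path exactly.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ice_scout import phmm
from ice_scout.phmm import (
    AMINO_ACIDS,
    BACKGROUND,
    CutoffError,
    HmmHit,
    Msa,
    ProfileHMM,
    ProfileParseError,
    build_profile,
    calibrate_gumbel_mu,
    call_presence,
    parse_profile,
    score_sequence,
    write_profile,
)


# ---------------------------------------------------------------------------
# oracle: exhaustive enumeration of all legal local alignment paths
# ---------------------------------------------------------------------------

def brute_force_best(hmm: ProfileHMM, seq: str) -> float:
    """Best log2-odds over every legal path, by direct enumeration.

    A legal path enters at some match state, moves through match /
    insert / delete states with the model's transitions, consumes a
    contiguous subsequence, and exits from a match state.
    """
    idx = phmm.seq_to_indices(seq)
    melo, ielo, tlog = hmm._scoring_arrays()
    M, L = hmm.M, len(idx)
    best = -np.inf

    def walk(state: str, node: int, pos: int, score: float) -> None:
        nonlocal best
        if state == "M":
            best = max(best, score)  # exit is free from any match state
        if pos > L:
            return
        if state == "M":
            if node + 1 < M and pos < L:
                walk("M", node + 1, pos + 1,
                     score + tlog[node, 0] + melo[node + 1, idx[pos]])
            if pos < L:
                walk("I", node, pos + 1,
                     score + tlog[node, 1] + ielo[node, idx[pos]])
            if node + 1 < M:
                walk("D", node + 1, pos, score + tlog[node, 2])
        elif state == "I":
            if node + 1 < M and pos < L:
                walk("M", node + 1, pos + 1,
                     score + tlog[node, 3] + melo[node + 1, idx[pos]])
            if pos < L:
                walk("I", node, pos + 1,
                     score + tlog[node, 4] + ielo[node, idx[pos]])
        elif state == "D":
            if node + 1 < M and pos < L:
                walk("M", node + 1, pos + 1,
                     score + tlog[node, 5] + melo[node + 1, idx[pos]])
            if node + 1 < M:
                walk("D", node + 1, pos, score + tlog[node, 6])

    for start_node in range(M):
        for start_pos in range(L):
            walk("M", start_node, start_pos + 1,
                 melo[start_node, idx[start_pos]])
    return best


def random_profile(rng: np.random.Generator, M: int) -> ProfileHMM:
    me = rng.dirichlet(np.ones(20), size=M)
    ie = rng.dirichlet(np.ones(20), size=M)
    tr = np.zeros((M, 7))
    tr[:, 0:3] = rng.dirichlet(np.ones(3), size=M)
    tr[:, 3:5] = rng.dirichlet(np.ones(2), size=M)
    tr[:, 5:7] = rng.dirichlet(np.ones(2), size=M)
    tr[-1] = [1, 0, 0, 1, 0, 1, 0]
    return ProfileHMM("rand", "", me, ie, tr)


class TestViterbiOracle:
    def test_matches_exhaustive_enumeration(self):
        """DP equals brute force on a randomized battery of tiny instances."""
        rng = np.random.default_rng(2024)
        checked = 0
        for M in (1, 2, 3):
            for L in (1, 2, 3, 4):
                for _ in range(12):
                    hmm = random_profile(rng, M)
                    seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
                    got = score_sequence(hmm, seq).bit_score
                    want = brute_force_best(hmm, seq)
                    assert got == pytest.approx(want, abs=1e-9), (M, L, seq)
                    checked += 1
        assert checked == 144

    def test_single_state_closed_form(self):
        """A one-state profile emitting only W scores log2(1/b_W) on 'W'."""
        me = np.zeros((1, 20))
        me[0, AMINO_ACIDS.index("W")] = 1.0
        tr = np.array([[1, 0, 0, 1, 0, 1, 0]], float)
        hmm = ProfileHMM("w", "", me, np.tile(BACKGROUND, (1, 1)), tr)
        hit = score_sequence(hmm, "W")
        b_w = BACKGROUND[AMINO_ACIDS.index("W")]
        assert hit.bit_score == pytest.approx(math.log2(1.0 / b_w))
        assert (hit.env_start, hit.env_end) == (0, 1)

    def test_local_score_monotone_under_padding(self):
        """Appending residues to the query can never lower a local score."""
        rng = np.random.default_rng(5)
        hmm = random_profile(rng, 3)
        for _ in range(10):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=6))
            s0 = score_sequence(hmm, seq).bit_score
            s1 = score_sequence(hmm, seq + "GGGG").bit_score
            assert s1 >= s0 - 1e-9

    def test_model_padding_invariance(self):
        """A trailing pass-through background match state changes nothing."""
        rng = np.random.default_rng(11)
        hmm = random_profile(rng, 3)
        me = np.vstack([hmm.match_emissions, BACKGROUND])
        ie = np.vstack([hmm.insert_emissions, BACKGROUND])
        tr = np.vstack([hmm.transitions, [[1, 0, 0, 1, 0, 1, 0]]])
        padded = ProfileHMM("pad", "", me, ie, tr)
        for _ in range(5):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=8))
            a = score_sequence(hmm, seq).bit_score
            b = score_sequence(padded, seq).bit_score
            assert b == pytest.approx(a, abs=1e-6) or b > a  # padding may only help

    def test_envelope_within_sequence(self):
        rng = np.random.default_rng(3)
        hmm = random_profile(rng, 3)
        seq = "ACDEFGHIKLMNP"
        hit = score_sequence(hmm, seq)
        assert 0 <= hit.env_start < hit.env_end <= len(seq)

    def test_empty_sequence_rejected(self):
        hmm = random_profile(np.random.default_rng(0), 2)
        with pytest.raises(ValueError):
            score_sequence(hmm, "")


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

class TestBuildProfile:
    def test_pseudocount_closed_form(self):
        """Two identical ungapped rows 'ACD' reproduce the mixture formula."""
        msa = Msa(["a", "b"], ["ACD", "ACD"])
        hmm = build_profile(msa, pseudocount_weight=0.1)
        assert hmm.M == 3
        b_a = BACKGROUND[AMINO_ACIDS.index("A")]
        want = (2 + 0.1 * 20 * b_a) / (2 + 0.1 * 20)
        assert hmm.match_emissions[0, AMINO_ACIDS.index("A")] == pytest.approx(want)
        hmm.validate()

    def test_all_gap_column_not_match_state(self):
        msa = Msa(["a", "b"], ["A-D", "A-D"])
        assert build_profile(msa).M == 2

    def test_majority_gap_column_dropped(self):
        msa = Msa(["a", "b", "c", "d"], ["AC", "A-", "A-", "A-"])
        assert build_profile(msa, match_gap_frac=0.5).M == 1

    def test_no_match_states_raises(self):
        with pytest.raises(ValueError, match="no match states"):
            build_profile(Msa(["a", "b"], ["-", "-"]))

    def test_training_rows_score_high(self):
        """Members of the training alignment score far above random decoys."""
        rng = np.random.default_rng(17)
        base = "".join(rng.choice(list(AMINO_ACIDS), size=80))
        rows = []
        for _ in range(4):
            chars = list(base)
            for i in rng.choice(80, size=8, replace=False):
                chars[i] = rng.choice(list(AMINO_ACIDS))
            rows.append("".join(chars))
        hmm = build_profile(Msa([f"s{i}" for i in range(4)], rows))
        member_scores = [score_sequence(hmm, r).bit_score for r in rows]
        decoy = "".join(rng.choice(list(AMINO_ACIDS), size=80))
        assert min(member_scores) > score_sequence(hmm, decoy).bit_score + 50


# ---------------------------------------------------------------------------
# HMMER3 text format
# ---------------------------------------------------------------------------

class TestProfileIO:
    def test_write_parse_round_trip(self):
        msa = Msa(["a", "b", "c"], ["ACDEF", "ACDEF", "ACDEW"])
        hmm = build_profile(msa, name="rt", cutoff_bits=25.0)
        back = parse_profile(write_profile(hmm))
        assert back.name == "rt"
        assert back.M == hmm.M
        assert back.cutoff_bits == 25.0
        np.testing.assert_allclose(back.match_emissions, hmm.match_emissions,
                                   rtol=1e-4)
        np.testing.assert_allclose(back.transitions, hmm.transitions, rtol=1e-4)

    def test_ga_line_maps_to_cutoff(self):
        hmm = build_profile(Msa(["a", "b"], ["ACD", "ACD"]), cutoff_bits=25.0)
        text = write_profile(hmm)
        assert "GA    25.00 25.00;" in text
        assert parse_profile(text).cutoff_bits == 25.0

    def test_zero_neglog_is_probability_one(self):
        """An emission stored as 0.0 negative-log decodes to probability 1."""
        me = np.zeros((1, 20))
        me[0, 0] = 1.0
        tr = np.array([[1, 0, 0, 1, 0, 1, 0]], float)
        hmm = ProfileHMM("p1", "", me, np.tile(BACKGROUND, (1, 1)), tr)
        text = write_profile(hmm)
        back = parse_profile(text)
        assert back.match_emissions[0, 0] == pytest.approx(1.0)

    def test_missing_header_field_raises(self):
        with pytest.raises(ProfileParseError, match="NAME"):
            parse_profile("HMMER3/f\nLENG  1\nALPH  amino\nHMM\n x\n//\n")

    def test_non_hmmer_text_raises(self):
        with pytest.raises(ProfileParseError):
            parse_profile(">fasta\nACDEF\n")


# ---------------------------------------------------------------------------
# presence calling and E-values
# ---------------------------------------------------------------------------

class TestPresence:
    @pytest.mark.parametrize(
        "bits,cutoff,expected",
        [(30.0, 25.0, True), (25.0, 25.0, True), (24.9, 25.0, False)],
    )
    def test_threshold_semantics(self, bits, cutoff, expected):
        hmm = build_profile(Msa(["a", "b"], ["ACD", "ACD"]), cutoff_bits=cutoff)
        hit = HmmHit("q", hmm.name, bits, float("nan"), 0, 3)
        assert call_presence(hit, hmm) is expected

    def test_override_takes_precedence(self):
        hmm = build_profile(Msa(["a", "b"], ["ACD", "ACD"]), cutoff_bits=100.0)
        hit = HmmHit("q", hmm.name, 30.0, float("nan"), 0, 3)
        assert call_presence(hit, hmm, override_bits=25.0) is True

    def test_no_cutoff_raises(self):
        hmm = build_profile(Msa(["a", "b"], ["ACD", "ACD"]))
        hit = HmmHit("q", hmm.name, 30.0, float("nan"), 0, 3)
        with pytest.raises(CutoffError, match="profile"):
            call_presence(hit, hmm)


class TestGumbel:
    def test_evalue_monotone_and_bounded(self):
        rng = np.random.default_rng(29)
        base = "".join(rng.choice(list(AMINO_ACIDS), size=60))
        hmm = build_profile(Msa(["a", "b"], [base, base]))
        mu = calibrate_gumbel_mu(hmm, [base], n_shuffles=40, seed=1, db_size=100)
        e_lo = phmm.evalue(mu + 50, mu, 100)
        e_hi = phmm.evalue(mu - 5, mu, 100)
        assert 0 < e_lo < e_hi <= 100 * 1.0 + 1e-9
        # a true member should get a tiny E-value after calibration
        hit = score_sequence(hmm, base)
        assert hit.e_value < 1e-6
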