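"""Coding-potential scorer: ORF search, Fickett statistic, hexamer bias,
logistic combination, and the strict-inequality consensus filter."""

import numpy as np
import pytest

from allolnc import coding
from allolnc.coding import (
    ConsensusError,
    CodingScores,
    LogisticModel,
    consensus_noncoding,
    fickett_score,
    find_longest_orf,
    hexamer_bias,
    train_hexamer_table,
    train_logistic,
)

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_orf_length(seq: str) -> int:
    """Exhaustive enumeration over all ATG positions (independent oracle)."""
    best = 0
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in STOPS:
                best = max(best, j + 3 - i)
                break
    return best


class TestORF:
    def test_minimal_orf(self):
        assert find_longest_orf("ATGAAATAA") == (9, 0, 0)

    def test_no_start_codon(self):
        assert find_longest_orf("CCCCCC")[0] == 0

    def test_empty_sequence(self):
        assert find_longest_orf("")[0] == 0

    def test_unterminated_orf_does_not_count(self):
        assert find_longest_orf("ATGAAAAAA")[0] == 0

    def test_matches_exhaustive_enumeration(self):
        """500 random sequences: longest ORF equals brute-force scan, and
        the reported (frame, start) locates a real ORF of that length."""
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        for _ in range(500):
            n = int(rng.integers(10, 400))
            seq = "".join(rng.choice(bases, size=n))
            length, frame, start = find_longest_orf(seq)
            assert length == brute_force_orf_length(seq)
            if length > 0:
                assert start % 3 == frame
                assert seq[start : start + 3] == "ATG"
                assert seq[start + length - 3 : start + length] in STOPS


class TestFickett:
    def test_deterministic(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert fickett_score(seq) == fickett_score(seq)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            fickett_score("ATG" * 50)

    def test_period3_bias_scores_high(self):
        """A perfectly periodic sequence outscores i.i.d.-uniform noise."""
        periodic = "ATG" * 100
        rng = np.random.default_rng(2)
        random_seq = "".join(rng.choice(list("ACGT"), size=300))
        assert fickett_score(periodic) > fickett_score(random_seq)

    def test_equal_position_counts_hit_minimum_bin(self):
        """ACGT-periodic sequence: every base occurs equally in all three
        codon positions, so each position value is max/(min+1) < 1.1 (the
        bottom lookup bin) and each content fraction is 0.25 (the 0.25
        bin). Expected score derived by hand from the published tables:
        position 0.26*0.22 + 0.18*0.23 + 0.31*0.08 + 0.33*0.09 = 0.1531,
        content 0.11*0.62 + 0.12*0.59 + 0.15*0.64 + 0.14*0.55 = 0.3120.
        """
        seq = "ACGT" * 50
        assert fickett_score(seq) == pytest.approx(0.1531 + 0.3120, abs=1e-9)


class TestHexamer:
    def test_uniform_table_gives_zero_bias(self):
        flat = np.full(4096, 1.0 / 4096)
        table = coding.HexamerTable(coding=flat, noncoding=flat.copy())
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=240))
        assert hexamer_bias(seq, table) == 0.0

    def test_single_hexamer_exact_log_ratio(self):
        flat = np.full(4096, 1.0 / 4096)
        biased = flat.copy()
        idx = coding._HEX_INDEX["AAAAAA"]
        biased[idx] *= 2
        biased /= biased.sum()
        table = coding.HexamerTable(coding=biased, noncoding=flat)
        # no ORF in AAAAAA: whole sequence in frame 0, single hexamer
        assert hexamer_bias("AAAAAA", table) == pytest.approx(
            float(np.log(biased[idx] / flat[idx]))
        )

    def test_coding_model_samples_have_positive_bias(self):
        """Monte-Carlo: sequences sampled from the coding hexamer model
        score positive expected bias on average."""
        rng = np.random.default_rng(4)
        coding_seqs = ["ATG" + "GCTGAA" * 40 + "TAA" for _ in range(10)]
        noncoding_seqs = ["".join(rng.choice(list("ACGT"), size=250)) for _ in range(10)]
        table = train_hexamer_table(coding_seqs, noncoding_seqs)
        biases = [
            hexamer_bias("ATG" + "GCTGAA" * 30 + "TAA", table) for _ in range(100)
        ]
        assert np.mean(biases) > 0

    def test_minimum_training_size_enforced(self):
        with pytest.raises(ValueError, match=">= 10"):
            train_hexamer_table(["ATGTAA"] * 5, ["AAAAAA"] * 20)


class TestLogistic:
    def test_all_zero_coefficients_give_half(self):
        model = LogisticModel(
            intercept=0.0, coef=np.zeros(4), mean=np.zeros(4), scale=np.ones(4)
        )
        p = model.predict_proba(np.array([500.0, 0.9, 1.0, 2.0]))
        assert p[0] == pytest.approx(0.5)

    def test_degenerate_labels_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        with pytest.raises(ValueError, match="degenerate"):
            train_logistic(X, np.ones(20))

    def test_separates_simple_classes(self):
        rng = np.random.default_rng(6)
        X0 = rng.normal(0, 1, size=(50, 4))
        X1 = rng.normal(3, 1, size=(50, 4))
        model = train_logistic(np.vstack([X0, X1]), np.array([0] * 50 + [1] * 50))
        p0 = model.predict_proba(X0).mean()
        p1 = model.predict_proba(X1).mean()
        assert p0 < 0.2 < 0.8 < p1


class TestConsensus:
    def _scores(self, prob, external):
        return CodingScores(
            transcript_id="t", orf_length=0, fickett=0.5, hexamer=0.0,
            coding_prob=prob, external=external,
        )

    def test_all_below_thresholds_is_noncoding(self):
        s = self._scores(0.20, {"CPC2": -0.5, "PLEK": -0.1, "CNCI": -2.0})
        assert consensus_noncoding(s) is True

    def test_cpat_boundary_is_coding(self):
        """Score exactly at 0.36 fails the strict '<' rule."""
        s = self._scores(0.36, {"CPC2": -1.0, "PLEK": -1.0, "CNCI": -1.0})
        assert consensus_noncoding(s) is False

    def test_one_tool_veto(self):
        s = self._scores(0.01, {"CPC2": 0.1, "PLEK": -5.0, "CNCI": -5.0})
        assert consensus_noncoding(s) is False

    def test_just_below_zero_contributes_noncoding(self):
        s = self._scores(0.01, {"CPC2": -0.0001, "PLEK": -0.0001, "CNCI": -0.0001})
        assert consensus_noncoding(s) is True

    def test_missing_required_tool_raises(self):
        s = self._scores(0.01, {})
        with pytest.raises(ConsensusError, match="CPC2"):
            consensus_noncoding(s, {"CPC2": 0.0, "CPAT": 0.36})

    def test_equals_set_intersection_of_per_tool_filters(self):
        """Consensus on a random score table equals intersecting the
        per-tool boolean filters (Venn semantics)."""
        rng = np.random.default_rng(9)
        thresholds = dict(coding.DEFAULT_THRESHOLDS)
        for _ in range(200):
            ext = {tool: float(rng.normal()) for tool in ("CPC2", "PLEK", "CNCI")}
            prob = float(rng.random())
            s = self._scores(prob, ext)
            per_tool = [ext[t] < thresholds[t] for t in ("CPC2", "PLEK", "CNCI")]
            per_tool.append(prob < thresholds["CPAT"])
            assert consensus_noncoding(s, thresholds) == all(per_tool)
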