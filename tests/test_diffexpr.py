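"""NB Wald test calibration, size factors, BH adjustment, additivity and
species-specific calls."""

import numpy as np
import pandas as pd
import pytest

from allolnc.diffexpr import (
    bh_adjust,
    classify_additivity,
    detect_species_specific,
    nb_test,
    size_factors,
)


def nb_draw(rng, mu, size, dispersion=0.05):
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu), size=size)


def null_blocks(seed, n_feat=1000, reps=3):
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(np.log(100), 1.0, n_feat))
    a = pd.DataFrame({f"a{i}": nb_draw(rng, mu, n_feat) for i in range(reps)})
    b = pd.DataFrame({f"b{i}": nb_draw(rng, mu, n_feat) for i in range(reps)})
    return a, b


class TestSizeFactors:
    def test_identical_samples_give_unity(self):
        counts = pd.DataFrame({"a": [10, 30, 5], "b": [10, 30, 5]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_exact_scaling_recovered(self):
        base = np.array([10, 30, 5, 100])
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        f = size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_fallback_warns_when_no_common_feature(self):
        counts = pd.DataFrame({"a": [10, 0], "b": [0, 10]})
        with pytest.warns(RuntimeWarning, match="total-count"):
            f = size_factors(counts)
        assert np.allclose(f, 1.0)

    def test_normalized_means_agree_on_random_nb(self):
        rng = np.random.default_rng(8)
        mu = np.exp(rng.normal(np.log(200), 1.0, 2000))
        lib = np.array([0.7, 1.0, 1.6])
        counts = pd.DataFrame(
            {f"s{i}": nb_draw(rng, mu * lib[i], 2000) for i in range(3)}
        )
        f = size_factors(counts)
        norm_means = (counts / f).mean(axis=0)
        assert norm_means.max() / norm_means.min() < 1.05


class TestBH:
    def test_hand_computed_step_up(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_all_ones_capped(self):
        assert np.allclose(bh_adjust(np.ones(5)), 1.0)

    def test_nan_passthrough_excluded_from_m(self):
        out = bh_adjust(np.array([0.01, np.nan, 0.02]))
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], [0.02, 0.02])

    def test_matches_reference_step_up(self):
        """Random p-vectors (10^4 values in total) agree with the
        statsmodels fdr_bh reference implementation."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        for _ in range(20):
            p = rng.random(500)
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), expected)


class TestNBTest:
    def test_identical_groups_are_ns(self):
        a = pd.DataFrame({"a1": [100, 50], "a2": [100, 50], "a3": [100, 50]})
        b = a.rename(columns=lambda c: c.replace("a", "b"))
        res = nb_test(a, b, ("A", "B")).table
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["call"] == "ns").all()

    def test_type_one_error_calibrated(self):
        """Seeded null: fraction of raw Wald p < 0.05 within 0.05 +/- 0.02."""
        for seed in (0, 1, 2):
            a, b = null_blocks(seed)
            res = nb_test(a, b, ("A", "B")).table
            frac = (res["wald_p"].dropna() < 0.05).mean()
            assert 0.03 <= frac <= 0.07, (seed, frac)

    def test_no_null_feature_reaches_strict_alpha(self):
        """FDR sanity: padj < 1e-4 occurs for zero features under the null."""
        for seed in (0, 1, 2, 3, 4):
            a, b = null_blocks(seed)
            res = nb_test(a, b, ("A", "B")).table
            assert (res["padj"].dropna() < 1e-4).sum() == 0

    def test_planted_fold_change_recovered(self):
        """|log2FC| = 3 at mean 100: recall >= 0.8 at the study thresholds."""
        rng = np.random.default_rng(7)
        lfc = np.zeros(1000)
        lfc[:200] = 3 * rng.choice([-1.0, 1.0], 200)
        mu_a = 100 * 2 ** (lfc / 2)
        mu_b = 100 * 2 ** (-lfc / 2)
        a = pd.DataFrame({f"a{i}": nb_draw(rng, mu_a, 1000) for i in range(3)})
        b = pd.DataFrame({f"b{i}": nb_draw(rng, mu_b, 1000) for i in range(3)})
        res = nb_test(a, b, ("A", "B")).table
        recall = (res["call"].iloc[:200] != "ns").mean()
        false_calls = (res["call"].iloc[200:] != "ns").sum()
        assert recall >= 0.8
        assert false_calls == 0

    def test_calls_antisymmetric(self):
        rng = np.random.default_rng(9)
        lfc = np.concatenate([np.full(50, 3.0), np.full(50, -3.0), np.zeros(100)])
        mu_a = 80 * 2 ** (lfc / 2)
        mu_b = 80 * 2 ** (-lfc / 2)
        a = pd.DataFrame({f"a{i}": nb_draw(rng, mu_a, 200) for i in range(3)})
        b = pd.DataFrame({f"b{i}": nb_draw(rng, mu_b, 200) for i in range(3)})
        ab = nb_test(a, b, ("A", "B")).table["call"]
        ba = nb_test(b, a, ("B", "A")).table["call"]
        flip = {"up_in_A": "down_in_A", "down_in_A": "up_in_A", "ns": "ns"}
        assert (ba == ab.map(flip)).all()

    def test_zero_in_both_groups_untestable(self):
        a = pd.DataFrame({"a1": [0, 10], "a2": [0, 12], "a3": [0, 9]})
        b = pd.DataFrame({"b1": [0, 11], "b2": [0, 10], "b3": [0, 13]})
        res = nb_test(a, b, ("A", "B")).table
        assert np.isnan(res.loc[0, "wald_p"])
        assert res.loc[0, "call"] == "ns"

    def test_contrast_needs_two_replicates(self):
        a = pd.DataFrame({"a1": [1]})
        b = pd.DataFrame({"b1": [1], "b2": [2]})
        with pytest.raises(ValueError, match="replicates"):
            nb_test(a, b, ("A", "B"))


class TestAdditivityAndSpeciesSpecific:
    def test_identical_progeny_and_mpv_additive(self):
        a = pd.DataFrame({"s1": [40, 7], "s2": [42, 8], "s3": [38, 6]})
        b = a.rename(columns=lambda c: c.replace("s", "m"))
        calls = classify_additivity(nb_test(a, b, ("S14", "MPV")))
        assert (calls == "additive").all()

    def test_planted_nonadditive_up_recovered(self):
        rng = np.random.default_rng(10)
        mpv_mu = np.full(300, 60.0)
        s14_mu = mpv_mu.copy()
        s14_mu[:30] *= 2**3  # Delta = +3
        s14 = pd.DataFrame({f"s{i}": nb_draw(rng, s14_mu, 300) for i in range(3)})
        mpv = pd.DataFrame({f"m{i}": nb_draw(rng, mpv_mu, 300) for i in range(3)})
        calls = classify_additivity(nb_test(s14, mpv, ("S14", "MPV")))
        assert (calls.iloc[:30] == "nonadditive_up").mean() >= 0.8
        assert (calls.iloc[30:] == "additive").all()

    def test_both_thresholds_required(self):
        """A feature above alpha-significance but below the fold-change
        floor stays additive (p and |lfc| must both pass)."""
        rng = np.random.default_rng(11)
        mpv_mu = np.full(400, 4000.0)
        s14_mu = mpv_mu.copy()
        s14_mu[:40] *= 2**1.5  # strong p, |lfc| < 2
        s14 = pd.DataFrame(
            {f"s{i}": nb_draw(rng, s14_mu, 400, dispersion=0.001) for i in range(3)}
        )
        mpv = pd.DataFrame(
            {f"m{i}": nb_draw(rng, mpv_mu, 400, dispersion=0.001) for i in range(3)}
        )
        det = nb_test(s14, mpv, ("S14", "MPV"))
        sub = det.table.iloc[:40]
        assert (sub["padj"] < 1e-4).all()
        assert (sub["call"] == "ns").all()

    def test_species_specific_flags(self):
        tpm_a = pd.DataFrame({"a1": [5.0, 5.0, 5.0], "a2": [5.0, 5.0, 5.0]})
        tpm_b = pd.DataFrame({"b1": [0.0, 0.0, 9.0], "b2": [0.0, 0.1, 9.0]})
        counts_a = pd.DataFrame({"a1": [50, 50, 50], "a2": [50, 50, 50]})
        counts_b = pd.DataFrame({"b1": [0, 0, 90], "b2": [0, 1, 90]})
        flags = detect_species_specific(tpm_a, tpm_b, counts_a, counts_b)
        assert flags[0] == "A_only"  # expressed in A, all-zero counts in B
        assert flags[1] == "none"  # one nonzero count in B breaks strict rule
        assert flags[2] == "none"

    def test_species_specific_planted_recovery(self):
        """Features with exactly-zero B means are flagged at 100%."""
        rng = np.random.default_rng(13)
        mu = np.full(100, 50.0)
        mu_b = mu.copy()
        mu_b[:20] = 0.0
        counts_a = pd.DataFrame({f"a{i}": nb_draw(rng, mu, 100) for i in range(3)})
        counts_b = pd.DataFrame({f"b{i}": nb_draw(rng, mu_b, 100) for i in range(3)})
        tpm_a = counts_a / 1.0
        tpm_b = counts_b / 1.0
        flags = detect_species_specific(tpm_a, tpm_b, counts_a, counts_b)
        assert (flags.iloc[:20] == "A_only").all()
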