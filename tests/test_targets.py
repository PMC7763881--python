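"""Cis-target windows, pair correlation, hypergeometric enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allolnc.intervals import AnnotationSet, GenomicInterval, TranscriptModel
from allolnc.targets import correlate_pairs, find_cis_targets, hypergeom_enrich


def tm(tid, gid, chrom, start, end, strand="+"):
    return TranscriptModel(tid, gid, (GenomicInterval(chrom, start, end, strand),))


@pytest.fixture(scope="module")
def pcgs():
    return AnnotationSet(
        [
            tm("near.t1", "near", "H01", 151_000, 153_000),  # 50 kb away
            tm("far.t1", "far", "H01", 251_000, 253_000),  # 150 kb away
            tm("inside.t1", "inside", "H01", 99_500, 100_200),  # overlapping
            tm("left.t1", "left", "H01", 20_000, 21_000),  # 79 kb upstream
            tm("otherchrom.t1", "oc", "C01", 100_000, 101_000),
        ]
    )


class TestWindow:
    def test_inclusion_by_distance(self, pcgs):
        spans = {"lnc1": GenomicInterval("H01", 100_000, 100_900, "+")}
        tab = find_cis_targets(spans, pcgs, window=100_000)
        assert set(tab["pcg"]) == {"near", "inside", "left"}
        by_pcg = tab.set_index("pcg")
        assert by_pcg.loc["inside", "distance"] == 0
        assert by_pcg.loc["inside", "relation"] == "overlapping"
        assert by_pcg.loc["near", "distance"] == 151_000 - 100_900 - 1
        assert by_pcg.loc["near", "relation"] == "downstream"
        assert by_pcg.loc["left", "distance"] == -(100_000 - 21_000 - 1)
        assert by_pcg.loc["left", "relation"] == "upstream"

    def test_chromosome_edge_truncates_quietly(self, pcgs):
        spans = {"edge": GenomicInterval("H01", 1, 400, "+")}
        tab = find_cis_targets(spans, pcgs, window=100_000)
        assert set(tab["pcg"]) == {"left", "inside"}

    def test_window_symmetry(self, pcgs):
        """A PCG is a target of the lncRNA iff the lncRNA lies within the
        PCG's own window (span-to-span distances are symmetric)."""
        rng = np.random.default_rng(41)
        for _ in range(50):
            s = int(rng.integers(1, 400_000))
            lnc_span = GenomicInterval("H01", s, s + int(rng.integers(200, 2000)), "+")
            forward = find_cis_targets({"l": lnc_span}, pcgs, window=100_000)
            for gid in pcgs.genes:
                g_span = pcgs.gene_span(gid)
                gap = max(
                    lnc_span.start - g_span.end, g_span.start - lnc_span.end, 0
                )
                same_chrom = g_span.seq_id == lnc_span.seq_id
                expected = same_chrom and (gap == 0 or gap - 1 <= 100_000)
                assert (gid in set(forward["pcg"])) == expected


class TestCorrelation:
    def _expr(self, rows):
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=[f"s{i}" for i in range(12)]
        ).astype(float)

    def test_identical_series_pass_with_r_one(self):
        x = list(range(12))
        expr = self._expr({"l": x, "g": x}).astype(float)
        pairs = pd.DataFrame({"lncrna_gene": ["l"], "pcg": ["g"]})
        out = correlate_pairs(pairs, expr)
        assert out["pearson_r"][0] == pytest.approx(1.0)
        assert bool(out["passes"][0])

    def test_negated_series_r_minus_one(self):
        x = np.arange(1.0, 13.0)
        expr = self._expr({"l": x, "g": -x})
        out = correlate_pairs(pd.DataFrame({"lncrna_gene": ["l"], "pcg": ["g"]}), expr)
        assert out["pearson_r"][0] == pytest.approx(-1.0)
        assert bool(out["passes"][0])

    def test_zero_variance_never_passes(self):
        expr = self._expr({"l": np.ones(12), "g": np.arange(12.0)})
        out = correlate_pairs(pd.DataFrame({"lncrna_gene": ["l"], "pcg": ["g"]}), expr)
        assert np.isnan(out["pearson_r"][0])
        assert not bool(out["passes"][0])

    def test_passing_pairs_exceed_critical_r(self):
        """With 12 samples the two-sided 5% critical |r| is ~0.576 (t
        quantile with 10 df), consistent with the study's observed floor
        of 0.62: every passing pair satisfies |r| >= 0.576."""
        t_crit = stats.t.ppf(0.975, 10)
        r_crit = float(np.sqrt(t_crit**2 / (t_crit**2 + 10)))
        assert r_crit == pytest.approx(0.576, abs=2e-3)
        rng = np.random.default_rng(44)
        rows = {f"l{i}": rng.normal(size=12) for i in range(30)}
        rows.update({f"g{i}": rng.normal(size=12) for i in range(30)})
        expr = self._expr(rows)
        pairs = pd.DataFrame(
            {"lncrna_gene": [f"l{i}" for i in range(30)], "pcg": [f"g{i}" for i in range(30)]}
        )
        out = correlate_pairs(pairs, expr)
        passing = out[out["passes"]]
        assert (passing["pearson_r"].abs() >= r_crit - 1e-9).all()


def exhaustive_upper_tail(N, K, n, k):
    """Enumerate all n-subsets of an N-set: fraction with >= k marked
    (exact oracle for small instances)."""
    items = list(range(N))
    marked = set(range(K))
    total = hits = 0
    for combo in itertools.combinations(items, n):
        total += 1
        if len(marked.intersection(combo)) >= k:
            hits += 1
    return hits / total


class TestEnrichment:
    def _term_map(self, background, term_genes):
        out = {g: ["GO:base"] for g in background}
        for g in term_genes:
            out[g] = out[g] + ["GO:mark"]
        return out

    def test_closed_form_all_marked(self):
        """N=10, K=5, n=5, k=5 -> p = C(5,5)C(5,0)/C(10,5) = 1/252."""
        background = [f"g{i}" for i in range(10)]
        term_map = self._term_map(background, background[:5])
        tab = hypergeom_enrich(background[:5], background, term_map)
        p = tab.set_index("term_id").loc["GO:mark", "p"]
        assert p == pytest.approx(1 / 252)

    def test_zero_overlap_gives_p_one(self):
        background = [f"g{i}" for i in range(10)]
        term_map = self._term_map(background, background[5:])
        tab = hypergeom_enrich(background[:3], background, term_map)
        assert tab.set_index("term_id").loc["GO:mark", "p"] == pytest.approx(1.0)

    def test_universal_term_gives_p_one(self):
        background = [f"g{i}" for i in range(12)]
        term_map = {g: ["GO:all"] for g in background}
        tab = hypergeom_enrich(background[:4], background, term_map)
        assert tab.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        """p-values equal subset enumeration on instances with N <= 20."""
        rng = np.random.default_rng(45)
        for _ in range(10):
            N = int(rng.integers(6, 13))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            background = [f"g{i}" for i in range(N)]
            term_map = self._term_map(background, background[:K])
            targets = background[:n]
            k = len(set(targets) & set(background[:K]))
            tab = hypergeom_enrich(targets, background, term_map)
            p = tab.set_index("term_id").loc["GO:mark", "p"]
            assert p == pytest.approx(exhaustive_upper_tail(N, K, n, k))

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hypergeom_enrich([], ["g1"], {"g1": ["GO:x"]})

    def test_targets_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeom_enrich(["gX"], ["g1"], {"g1": ["GO:x"]})

    def test_marker_term_ranks_first_on_planted_data(self, default_run, default_data):
        """DE lncRNAs are planted adjacent to marker-term genes, so the
        marker leads the enrichment ranking of predicted targets."""
        report, outdir, _ = default_run
        assert report.target_summary["top_term"] == default_data.config.marker_term
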