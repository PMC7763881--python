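"""Positional classification, TE flagging, subgenome assignment and
collinear homoeolog recovery."""

import numpy as np
import pytest

from allolnc.annotate import (
    annotate_lncrna_genes,
    assign_subgenome,
    build_te_index,
    classify_position,
    find_homoeologous_pairs,
    flag_te_derived,
    kmer_jaccard,
)
from allolnc.intervals import AnnotationSet, GenomicInterval, TranscriptModel


def tm(tid, gid, chrom, strand, *exon_pairs):
    return TranscriptModel(
        tid, gid, tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs)
    )


@pytest.fixture(scope="module")
def pcgs():
    return AnnotationSet(
        [
            tm("g1.t1", "g1", "H01", "+", (1000, 1500), (2500, 3000)),
            tm("g2.t1", "g2", "H01", "-", (10_000, 10_500), (11_000, 11_500)),
        ]
    )


class TestClassifyPosition:
    def test_same_strand_exon_overlap_is_sense(self, pcgs):
        lnc = tm("l", "l", "H01", "+", (1400, 1700), (1900, 2000))
        assert classify_position(lnc, pcgs) == "sense"

    def test_opposite_strand_exon_overlap_is_antisense(self, pcgs):
        lnc = tm("l", "l", "H01", "-", (1400, 1700), (1900, 2000))
        assert classify_position(lnc, pcgs) == "antisense"

    def test_intron_containment_is_intronic_either_strand(self, pcgs):
        for strand in "+-":
            lnc = tm("l", "l", "H01", strand, (1600, 1800), (2100, 2300))
            assert classify_position(lnc, pcgs) == "intronic"

    def test_distant_transcript_is_intergenic(self, pcgs):
        lnc = tm("l", "l", "H01", "+", (60_000, 60_400), (61_000, 61_300))
        assert classify_position(lnc, pcgs) == "intergenic"

    def test_sense_precedes_antisense(self, pcgs):
        # overlaps g1 (+) and g2 (-) exons; a + lnc is sense via g1
        lnc = tm("l", "l", "H01", "+", (2900, 3100), (10_400, 10_600))
        assert classify_position(lnc, pcgs) == "sense"


class TestTEFlag:
    def _index(self, *ivs):
        return build_te_index([GenomicInterval("H01", s, e, ".") for s, e in ivs])

    def test_boundary_ten_bp(self):
        lnc = tm("l", "l", "H01", "+", (100, 300), (500, 700))
        ov, derived = flag_te_derived(lnc, self._index((291, 320)))
        assert (ov, derived) == (10, True)

    def test_nine_bp_not_derived(self):
        lnc = tm("l", "l", "H01", "+", (100, 300), (500, 700))
        ov, derived = flag_te_derived(lnc, self._index((292, 320)))
        assert (ov, derived) == (9, False)

    def test_no_tes_on_chromosome(self):
        lnc = tm("l", "l", "H01", "+", (100, 300))
        assert flag_te_derived(lnc, build_te_index([])) == (0, False)

    def test_max_single_te_not_sum(self):
        lnc = tm("l", "l", "H01", "+", (100, 300))
        ov, _ = flag_te_derived(lnc, self._index((95, 104), (200, 207)))
        assert ov == 8  # largest single TE overlap, intron bases ignored


@pytest.mark.parametrize(
    "chrom,expected",
    [("H03", "subH"), ("C07", "subC"), ("scaffold_12", "unplaced")],
)
def test_subgenome_naming_rule(chrom, expected):
    assert assign_subgenome(chrom) == expected


def _mutate(rng, seq, rate=0.03):
    bases = np.array(list("ACGT"))
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = bases[rng.integers(4)]
    return "".join(out)


class TestHomoeologPairs:
    def _planted(self, seed=31, n_pairs=6):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        sequences, positions = {}, {}
        h_pos, c_pos = 1000, 1000
        for i in range(n_pairs):
            seq = "".join(rng.choice(bases, size=600))
            sequences[f"h{i}"] = seq
            sequences[f"c{i}"] = _mutate(rng, seq)
            positions[f"h{i}"] = GenomicInterval("H01", h_pos, h_pos + 599)
            positions[f"c{i}"] = GenomicInterval("C01", c_pos, c_pos + 599)
            h_pos += 5000
            c_pos += 5000
        return sequences, positions

    def test_planted_pairs_form_one_block(self):
        sequences, positions = self._planted()
        pairs, blocks = find_homoeologous_pairs(sequences, positions)
        assert sorted(pairs) == [(f"h{i}", f"c{i}") for i in range(6)]
        assert len(blocks) == 1 and len(blocks[0].pairs) == 6

    def test_shuffled_positions_destroy_blocks(self):
        """Permuting the planted C positions breaks monotone runs."""
        sequences, positions = self._planted()
        rng = np.random.default_rng(1)
        c_ids = [f"c{i}" for i in range(6)]
        perm = [c_ids[j] for j in [3, 0, 5, 1, 4, 2]]
        remapped = dict(positions)
        for orig, new in zip(c_ids, perm):
            remapped[orig] = positions[new]
        pairs, blocks = find_homoeologous_pairs(sequences, remapped)
        assert blocks == [] and pairs == []

    def test_chromosome_below_min_anchors_excluded(self):
        sequences, positions = self._planted(n_pairs=3)
        pairs, blocks = find_homoeologous_pairs(sequences, positions, min_anchors=4)
        assert pairs == [] and blocks == []

    def test_pairs_are_one_to_one(self, small_data, small_cfg):
        from allolnc.gtfio import transcript_sequence

        truth = small_data.truth
        lnc = truth[truth["is_lncrna"]]
        sequences, positions = {}, {}
        for tid in lnc.index:
            t = small_data.assembled.transcripts[tid]
            sequences[t.gene_id] = transcript_sequence(small_data.genome, t)
            positions[t.gene_id] = t.span
        pairs, _ = find_homoeologous_pairs(sequences, positions)
        flat = [g for pair in pairs for g in pair]
        assert len(flat) == len(set(flat))

    def test_planted_recovery_sensitivity(self, small_data, small_cfg):
        """>= 90% of generator-planted collinear lncRNA pairs recovered."""
        from allolnc.gtfio import transcript_sequence

        truth = small_data.truth
        lnc = truth[truth["is_lncrna"]]
        sequences, positions = {}, {}
        for tid in lnc.index:
            t = small_data.assembled.transcripts[tid]
            sequences[t.gene_id] = transcript_sequence(small_data.genome, t)
            positions[t.gene_id] = t.span
        pairs, _ = find_homoeologous_pairs(sequences, positions)
        found = {frozenset(p) for p in pairs}
        planted = {
            frozenset((row["gene_id"], row["homoeolog_partner"]))
            for _, row in lnc.iterrows()
            if row["homoeolog_partner"]
        }
        assert planted, "generator planted no pairs"
        recovered = sum(1 for p in planted if p in found)
        assert recovered / len(planted) >= 0.9


def test_kmer_jaccard_bounds():
    assert kmer_jaccard("ACGTACGTACGTACG", "ACGTACGTACGTACG") == 1.0
    assert kmer_jaccard("A" * 30, "C" * 30) == 0.0


def test_record_table_and_category_partition(small_data):
    """Category counts partition the identified set (the 983+827+345+51
    identity) and te_derived matches the >= 10 bp rule per record."""
    truth = small_data.truth
    lnc_reps = {}
    for tid in truth.index[truth["is_lncrna"]]:
        t = small_data.assembled.transcripts[tid]
        lnc_reps.setdefault(t.gene_id, t)
    table, _ = annotate_lncrna_genes(
        lnc_reps, small_data.reference, small_data.te_intervals
    )
    assert len(table) == len(lnc_reps)
    assert table["category"].isin(
        ["intergenic", "sense", "antisense", "intronic"]
    ).all()
    assert int(table["category"].value_counts().sum()) == len(table)
    assert (table["te_derived"] == (table["te_overlap_bp"] >= 10)).all()
    # positional classes agree with the generator's planted categories
    planted = truth[truth["is_lncrna"]].drop_duplicates("gene_id").set_index("gene_id")
    agree = (table["category"] == planted.loc[table.index, "category"]).mean()
    assert agree >= 0.9
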