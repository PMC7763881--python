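# Methods

This note documents the models and procedures implemented in `allolnc`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic validation shows.

## Coordinate conventions

All internal coordinates are 1-based and inclusive on both ends (the GTF
convention); BED input is 0-based half-open and converted at the I/O
boundary. "Transcript length" always means spliced (exonic) length —
assembled-transcript lengths are conventionally reported this way, and
the ≥ 200 nt lncRNA floor is applied to it. Overlap queries run through
an interval tree per chromosome; query results are property-tested
against a brute-force all-pairs scan.

## Identification cascade

Four ordered filters, each a per-transcript predicate, with a full audit
of the removing step:

1. **Novelty.** Class codes against the reference annotation: `u` (no
   overlap with any reference transcript span), `i` (span entirely
   within one reference intron, any strand), `x` (exon–exon overlap with
   a reference transcript on the opposite strand), `known_match` (exact
   intron-chain match; single-exon transcripts must match a single-exon
   reference exactly), everything else `other_overlap`. Only u/i/x
   transcripts of spliced length ≥ 200 nt continue. Precedence with
   multiple overlapping references: known_match > x > i > other_overlap.
   Only the three retained codes are modelled precisely; the remaining
   Cuffcompare taxonomy is collapsed into `other_overlap` because those
   transcripts are discarded either way.
2. **Coding potential.** A native CPAT-style scorer: longest
   forward-strand ATG…stop ORF across three frames (length includes the
   stop codon; unterminated reading frames do not count), the Fickett
   (1982) TESTCODE statistic from the published position-bias and
   composition lookup tables (hard-coded as data), and an in-frame
   hexamer log-ratio score, mean log(F_coding/F_noncoding) over the
   hexamers of the longest ORF (whole sequence in frame 0 if none),
   trained with add-one smoothing. The four features (ORF length, ORF
   coverage, Fickett, hexamer) feed a logistic model; because ORF length
   separates real training sets almost perfectly, the fit is
   ridge-penalized (scikit-learn, L2, standardized features), which
   keeps the probabilities well-defined under separation. Training data
   are taken from the input itself: reference mRNAs as the coding class
   and random length-matched intergenic fragments as the background.
   The consensus rule is an intersection: a transcript is noncoding only
   if *every* available tool score is strictly below its threshold
   (defaults CPC2 < 0, PLEK < 0, CNCI < 0, CPAT < 0.36; a score equal to
   its threshold is coding). External per-tool score tables are merged
   from TSV when provided; the internal probability always plays the
   CPAT role.
3. **Structure.** Exon number ≥ 2 (single-exon assemblies are the least
   reliable transcript models).
4. **Expression.** TPM is computed within the pipeline
   (counts/length-in-kb, normalized to 10⁶ per sample). The 0.3
   threshold is applied to the maximum of the four group means — the
   permissive reading that lets species-specific lncRNAs (expressed in
   only one group) survive; the source protocol does not specify the
   sample scope of this filter.

Surviving transcripts are collapsed to lncRNA-genes by `gene_id`
(counts summed per sample; the longest member represents the gene's
interval). Gene-level TPM uses the longest member's length.

## Positional classification and the sense-class tension

Positional categories are assigned against the coding annotation,
independent of the novelty class codes: **sense** = ≥ 1 bp exonic
overlap with a coding exon on the same strand; **antisense** = exonic
overlap on the opposite strand only; **intronic** = span inside one
intron with no exonic overlap; **intergenic** otherwise; precedence
sense > antisense > intronic > intergenic, with the largest-overlap gene
defining the relation (ties to the lexicographically smaller gene id).
Strict u/i/x extraction cannot by itself produce same-strand
exon-overlapping ("sense") lncRNAs; category tables in this field
nevertheless report them in quantity. The resolution implemented here
is that classification is a separate relation from extraction; the
synthetic generator accordingly plants its sense lncRNAs at convergent
gene pairs, where an opposite-strand overlap with one gene (class `x`)
carries them through extraction while a same-strand overlap with the
other gene makes them positionally sense. All planted overlaps fall in
UTR sequence, never CDS.

TE-derived flags use the maximum single-TE overlap with the lncRNA's
exons, strand-blind, at the ≥ 10 bp rule. Subgenome assignment keys on
the chromosome-name prefix (H…/C…; anything else is `unplaced`).

## Homoeologous collinearity

A two-stage procedure mirroring reciprocal-best BLAST plus MCScanX-style
chaining, at desk scale and deterministic: (1) reciprocal best match
between subH and subC lncRNA sequences by shared-k-mer Jaccard
similarity (k = 11, minimum similarity 0.2), keeping one-to-one optimal
matches; (2) anchors on each chromosome pair sorted by H position and
chained into runs with monotone C ranks (either orientation), rank gaps
≤ 25; blocks need ≥ 4 anchors (the `-s 4` convention). Exact
BLAST/MCScanX scoring is not reproduced; the contract — one-to-one
optimal matching, then collinear chaining — is. At 3% sequence
divergence an 11-mer survives with probability ≈ 0.97¹¹ ≈ 0.71, giving
pair similarities ≈ 0.5, comfortably above threshold, while unrelated
noncoding sequences share almost no 11-mers.

## Expression analysis

**TPM** per sample sums to 10⁶ (property-tested). **Replicate QC** is
the mean pairwise Pearson r of log₂(TPM+1) within each group;
zero-variance replicates are excluded pair-wise. **MPV
pseudo-replicates** pair parental replicates by index,
MPV_i = (CC_i + HH_i)/2, so the count-based test keeps three replicates
per side; count MPVs are rounded half-up to stay integral. The
replicate-pairing rule is a documented choice — protocols rarely state
how MPV enters a replicated NB test.

**NB Wald test.** Median-of-ratios size factors (total-count fallback
with a warning when no feature is everywhere-nonzero); per-feature
method-of-moments dispersion pooled within groups, shrunk halfway
(weight 0.5) toward a fitted mean–dispersion trend α(μ) = a₀ + a₁/μ;
Wald statistic log₂FC/SE with pseudo-count 0.5 on normalized means and
a delta-method SE; two-sided normal p; BH step-up across features
(features with zero counts in both groups are untestable: p = NA,
excluded from m). Calls require BH-adjusted p < 10⁻⁴ AND |log₂FC| > 2.
This is deliberately not a DESeq2 reimplementation (no GLM, no MAP
dispersion, no independent filtering); numeric equality with DESeq2 is
not claimed. The simplified test is validated by simulation instead:
type-I error 0.04–0.07 at nominal 0.05 on 1000-feature nulls (n = 3 per
side), recall 1.0 for |log₂FC| = 3 at mean 100, and zero null features
reaching the strict padj < 10⁻⁴ threshold in seeded runs.
**Species-specific expression** (mean TPM > 0.3 in one group, all
replicate counts exactly zero in the other) bypasses the Wald p — the
SE is undefined at zero — and is merged into the DE calls as its own
class. Additivity classes come from the progeny-vs-MPV contrast:
`nonadditive_up` / `nonadditive_down` where the DE thresholds are met,
`additive` otherwise.

The eight study contrasts are HH–CC, S₁₄–CC, S₁₄–HH, S₁₄–MPV, F₁–CC,
F₁–HH, F₁–MPV, and S₁₄–F₁.

## Trend profiles

T = 3 ordered stages (MPV, F₁, S₁₄) and unit-change bound c = 2 give
(2c+1)^(T−1) = 25 model profiles, enumerated lexicographically
(−c first, the all-flat profile is id 12); no greedy profile
subselection is needed at 25 ≤ 50 profiles, approximating the reference
tool's defaults. Genes enter as log₂(TPM+1) group means transformed to
differences from the first stage and are assigned to the
best-Pearson-correlated profile (flat genes to the flat profile; ties
to the lowest id) — assignment is property-tested against an exhaustive
argmax. Significance: every permutation shuffles each gene's stage
values independently and reassigns; the observed count per profile is
tested against Binomial(n_genes, π̂_p) on the upper tail with π̂_p the
permutation-expected proportion, BH across profiles, significant at
padj < 0.05. Significant profiles with shape correlation ≥ 0.7 are
grouped by single linkage (connected components). The "bins" reported
in this field are treated as a presentation grouping of significant
profiles, not a hard-coded count.

Correlation-based assignment is scale-free: genes with small noisy
wiggles still land on shaped profiles rather than the flat one. This is
authentic to the reference tool's behaviour and is why profile
*significance* (against the permutation null), not raw membership,
carries the inference.

## Cis targets and enrichment

The 100-kb window is measured span-to-span (not TSS-to-TSS — the
protocol wording does not distinguish, and span-to-span keeps the
relation symmetric, which is property-tested). Distances are signed by
genomic position (negative = upstream on the + axis), 0 for overlap.
Pair screening uses Pearson correlation of log₂(TPM+1) over all 12
replicate samples with a two-sided t test at n−2 = 10 df: the 5%
critical |r| is ≈ 0.576, which is why correlation floors near 0.6
appear in published target tables — a 4-group-mean correlation (2 df,
critical r ≈ 0.95) would be inconsistent with them. Enrichment is the
hypergeometric upper tail P(X ≥ k | N, K, n) against the full coding
background, BH-corrected, with the top 10 terms at p < 0.05 flagged.
GO annotation is a flat gene→terms table; no ontology-graph
propagation.

## Summary arithmetic

Report percentages are round-to-nearest with ties to even (banker's
rounding) at 1 decimal, ratios at 2 decimals — the convention that
reproduces the published worked examples exactly (352/1593 → 22.1%,
33/1593 → 2.1%, 153:16 → 9.56, 77:8 → 9.62; note 77/8 = 9.625 exactly,
so half-up rounding would print 9.63). Every percentage in the summary
report is recomputed from a stored numerator/denominator pair.

## The synthetic-data generator

The generator emulates the study conditions; its defaults are the
package's fixed reference conditions, not tuning knobs.

* **Genome**: 19 chromosomes (12 subH + 7 subC) of 500 kb, AT-rich
  background (32/18/18/32). Desk-scale — real chromosomes are three
  orders of magnitude longer; density-dependent statistics (TE overlap
  rates, targets per window) therefore do not transfer numerically.
* **Coding genes** (1500): ATG…stop ORFs of 112–251 codons from a
  stylized codon-usage table (wobble positions biased toward A/T),
  UTRs from background sequence, 2–5 exons. Homoeolog copies at 3%
  divergence are planted collinearly on paired chromosomes
  (H01↔C01 … H07↔C07) for 60% of standalone genes; CDS repairs keep
  mutated copies stop-free.
* **lncRNAs** (120 intergenic / 100 sense / 45 antisense / 15 intronic
  transcripts): background-composition sequences rejection-sampled to
  carry no ORF ≥ 100 codons; sense lncRNAs at convergent gene pairs,
  antisense over host 3′ UTRs, intronic inside enlarged introns; 20
  collinear lincRNA pairs (5 per chromosome pair on 4 pairs); a
  fraction of lincRNA loci carry a second isoform so gene collapsing is
  exercised.
* **Decoys** exercising each filter: 40 novel coding transcripts, 20
  single-exon noncoding, 20 expressed-below-threshold.
* **TEs**: 1200 intervals of 100–1000 bp, placed with triangular
  enrichment toward chromosome midpoints; interval placement only, no
  TE sequence model.
* **Expression**: per-transcript baselines are log-normal
  (σ = 1.8 in natural log) with NB dispersion 0.02 — calibrated so
  within-group replicate correlations of log TPM sit at 0.97–0.98,
  matching the replicate quality such studies report (0.98–0.99);
  planted features are floored at mean 8 so they clear the TPM filter.
  15% of features get a parental difference (|Δlog₂| ∈ [2.5, 4]), 3%
  are species-specific (zero mean in one parent), 22% of features are
  non-additive in F₁ (85% of them upward — hybridization activation)
  and 2.1% in S₁₄ (symmetric), with |Δ| ∈ [2.5, 4] against MPV.
  Library sizes vary uniformly ±15%. PCGs within 10 kb of a DE lncRNA
  inherit its relative group profile (cis-regulation emulation) and
  carry a marker GO term, so target prediction and enrichment have a
  planted positive control.
* **Determinism**: every artifact draws from its own stream spawned
  from the master seed; a seed fully determines every output byte.

What passing the synthetic checks does **not** show: robustness to
assembly artifacts (fragmented or chimeric transcripts), to
mismapping between near-identical homoeologs, to non-NB overdispersion,
to polyA-selection biases, or to real TE sequence homology. The
generator's truth labels are constructions, and recovery rates on them
are upper bounds on real-data performance.

## Numerical and degenerate-input choices

Add-one smoothing for hexamer tables; ridge (C = 1) for the logistic;
dispersion floor 10⁻⁸; pseudo-count 0.5 in fold changes; log₂(TPM+1)
for all correlation work; zero-variance series give undefined
correlations (excluded or never passing, per context); BH propagates
NaN without counting it in m; empty target sets and all-zero samples
raise errors rather than returning silently. Problem sizes in the test
suite and acceptance script (≈ 2k features, 1000-feature calibration
nulls, 1000 permutations) are the package's default desk-scale
conditions; all are configuration fields.
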