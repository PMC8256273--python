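# Methods

## The differentiation scan

For a biallelic SNP with alternate-allele frequencies p₁, p₂ in two
populations, the absolute allele frequency difference is AFD = |p₁ − p₂|;
the general multi-class form ½ Σᵢ |f₁ᵢ − f₂ᵢ| is provided for completeness
and reduces to it in the biallelic case. AFD is symmetric, bounded in
[0, 1], and — unlike Fst-type ratios — linear in the frequencies, which
makes the outlier tail easy to reason about.

Frequencies are computed from called genotypes: p = (alt allele count) /
(2 · n_called). A site is retained only when every population in the
comparison has at least `min_called = 5` non-missing individuals; this is
the genotype-level reading of a read-support rule (the pipeline consumes
VCFs, not reads, so "individuals with sequencing reads" becomes
"individuals with called genotypes"). The rule is applied per comparison
(only the populations being compared must satisfy it), which is the less
restrictive of the two possible readings; passing all populations of
interest to `allele_frequencies` gives the stricter one.

The outlier threshold is the empirical q-quantile (default q = 0.95,
type-7 linear interpolation — the quantile rule is recorded in the run
metadata) of the focal vs cultivated-reference AFD distribution. Outliers
are strict exceedances (ties at the threshold are not outliers). The same
threshold is reused for the focal vs reference-weedy comparison so that
the two comparisons are judged on one scale; `scan(...,
per_comparison_threshold=True)` derives a cutoff per comparison instead. A
candidate SNP must (i) exceed the threshold in both comparisons and (ii)
have one allele — either allele — whose frequency in the focal population
strictly exceeds its frequency in both references; an optional `margin`
(default 0) raises that bar. Either-allele logic is the permissive choice:
requiring the alternate allele specifically would make candidacy depend on
which strain happened to be the reference assembly.

## Variant-effect classification

A lightweight annotator stands in for a full effect predictor, since the
pipeline only needs the exon/UTR filter. One representative transcript per
gene (longest total CDS) keeps gene-level rollups well defined. GFF
1-based inclusive coordinates are converted to 0-based half-open exactly
once at parse time. Coding SNPs are re-translated through the spliced,
strand-adjusted codon (standard genetic code); the filter keeps
nonsynonymous, stop-gain, stop-loss (all amino-acid-changing) and both
UTRs, and drops synonymous, intronic and intergenic records. A SNP
overlapping several genes yields one record per gene, and only records
that pass the filter enter integration — so a SNP in one gene's UTR and
another's intron counts once, for the UTR gene. A stated REF allele that
contradicts the reference base produces an explicit `ref_mismatch` record,
never a silent reinterpretation. Genes whose spliced CDS length is not a
multiple of 3 are flagged and refused coding classification (their
UTR/intron intervals still classify).

## Differential expression

RPKM = counts · 10⁹ / (library_size · gene_length_bp). With one library
per condition, the two-library comparison uses the exact binomial
random-sampling model: conditional on the total c₁ + c₂, the count in
library 1 is Binomial(c₁ + c₂, n₁/(n₁+n₂)) under equal relative
expression. The two-sided p-value doubles the smaller tail with the
observed point mass included — slightly conservative, simple, and exactly
checkable against brute-force pmf summation. The log₂ ratio of normalized
expression adds a 0.5 pseudocount to both counts only when one count is
zero; the test itself never uses pseudocounts. Genes with c₁ + c₂ = 0 are
reported non-significant with p = 1.

P-values are corrected per comparison (per stage, per north-eastern
region) with the Benjamini–Yekutieli step-up (statsmodels), whose
harmonic-sum inflation c(m) = Σ 1/k keeps FDR control under arbitrary
dependence; per-comparison correction mirrors pairwise usage, and pooling
across comparisons would couple unrelated stage contrasts. A call requires
|log₂Ratio| ≥ 1 **and** q < 0.001. Region-specific sets intersect the two
north-eastern comparisons per stage; stage-persistent sets intersect
across all three stages.

## Integration, tracing, concordance

A candidate gene needs ≥ 1 candidate SNP surviving the exon/UTR filter and
membership in a `common_up` set at a pre-germination stage (default stages
1–2: four days after imbibition, and the day before radicle emergence;
configurable). Output is sorted by SNP count, then gene id.

Allele tracing reports the *elevated* allele's frequency (1 − p when the
reference allele is the elevated one) in each of the five panels. Presence
means an allele count of at least `presence_min_count` (default 1) among
called individuals; a panel with zero called individuals at a site is
absent *data* (NaN), never frequency zero — conflating the two would
misclassify origins. Classes: `standing_in_wild` (present in wild),
`cultivation_associated` (absent from wild, present in japonica or
indica), `weedy_private` (absent from all three); sites without wild data
are `unclassifiable`. Concordance between two frequency-estimation
platforms is a classical paired t-test on per-site differences
(`scipy.stats.ttest_rel`), with the degenerate zero-variance cases
reported (t = 0, p = 1 for all-zero differences; p = 0 for a constant
nonzero difference) rather than raised.

## The synthetic-data model

Panels scatter around a shared ancestral frequency (symmetric Beta(0.8,
0.8), U-shaped like a site-frequency spectrum) Balding–Nichols-style:
panel frequency ~ Beta(p(1−d)/d, (1−p)(1−d)/d) with dispersion d =
`background_divergence` (default 0.05, giving a genome-wide mean AFD of
~0.13 at 20 diploids — a low-differentiation background against which
planted signals must stand out). d = 0 collapses every panel onto the
ancestral frequency. Planted loci override this: the focal panel gets
`focal_freq` (default 0.97 — near fixation, as expected under strong local
selection in a selfer), the reference weedy panel draws uniformly below
`ref_freq_max` (0.2), and the wild/cultivated panels get the low standing
frequencies (0.05 / 0.08) that plant the standing-variation origin
pattern.

Genotypes are drawn with a heterozygote deficit parameterized by the
inbreeding coefficient F (default 0.95, reflecting predominant selfing):
P(het) = 2p(1−p)(1−F), homozygotes absorbing the remainder. F is used
instead of generational selfing because only the stationary genotype
frequencies matter downstream. Missingness is independent per sample ×
site (default 5%); no real missingness model is emulated because none is
identifiable from the inputs the pipeline consumes. Sites are independent
— no linkage, no demography; the generator's job is a tunable AFD
background, not population-genetic realism, so passing tests say nothing
about linked-selection or demographic confounding in real data.

Counts are negative-binomial (Poisson at overdispersion 0) with mean =
library_size × expression weight × fold; log-normal weights (σ = 1) give a
realistic dynamic range, and planted folds multiply both north-eastern
libraries at the specified stages. Default overdispersion 0.05 adds mild
biological noise; because the design has single libraries, a noisy draw in
the shared eastern reference library produces *correlated* false calls in
both comparisons — a faithful reproduction of the replicate-free design's
main weakness.

The end-to-end fixture (`simulate_joint_fixture`) writes a complete bundle
(toy genome FASTA + GFF3, VCF, population map, counts, truth tables) in
which 12 genes carry both a planted exon/UTR adaptive SNP and planted
4-fold pre-germination up-regulation, alongside decoys carrying only one
signal (including an up-regulated gene whose only adaptive SNP is
synonymous). Background differentiation sites are placed intergenic so the
gene-level ground truth is exactly the planted set; 200 genes keep the
planted fold changes a small fraction of each library, so composition
effects do not erode the log-ratios.

## Problem sizes and numerical choices

The test suite and the acceptance script run the scan at 50,000 sites ×
100 samples, the DEG calibration at 10,000 genes, the classifier oracle at
20 genes × 240 SNPs, and the joint fixture at 200 genes / ~620 SNPs —
sizes at which every stochastic check has comfortable statistical margin
while the whole suite completes in seconds. All generators take explicit
integer seeds and are exactly reproducible; quantiles are type-7;
threshold comparisons are strict; the BY step-up is validated against
hand-expanded formulas and dominates Benjamini–Hochberg elementwise.

## Known limitations

- Per-SNP statistics only: no windowed or haplotype-aware scans, so the
  method cannot separate a selected site from its linked neighbors.
- Genotype-based frequencies: no depth weighting or genotype likelihoods;
  low-coverage data should be filtered upstream.
- The DEG model assumes sampling noise only between libraries; with
  biological overdispersion the test is anticonservative, and the
  region-specific intersection only partially compensates (see above).
- The effect classifier handles biallelic SNPs against one transcript per
  gene; splice-site, indel and multi-isoform effects are out of scope.
- Origin tracing treats absence below the sampling depth as absence:
  with 20 diploids a 5% allele is missed ~12% of the time per panel, so
  some standing variants will class as private (the examples demonstrate
  this ascertainment limit).
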