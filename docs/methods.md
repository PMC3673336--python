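# Methods

This note documents the statistical procedures implemented in `methtrio`,
the defaults and why, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Data model and coordinates

All intervals are 0-based half-open (BED convention); VCF positions are
converted on read. Dosages are counts of the alternate allele in {0, 1, 2}
with NaN for missing. Methylation β is the proportion of methylated signal,
β = M/(M + U + ε) with ε = 0 by default (β is a pure proportion; the platform
offset sometimes added in other toolchains is not applied; ε is configurable
as a zero-total guard). Exon units are the per-gene union of exons of
protein-coding and lincRNA transcripts; the TSS is the 5′-most transcript
start (minimum start on +, maximum end on −). Cis windows are inclusive at
both edges (|anchor − target| ≤ window): 1 Mb around the TSS for eQTLs, 5 kb
around the CpG for mQTLs, 50 kb around the TSS for eQTMs. Promoters span
TSS − 1 kb to TSS + 2 kb, mirrored for − strand genes; a CGI promoter is a
promoter overlapping a CpG island.

## Genotype QC

SNPs are removed for missingness > 5%, MAF < 1%, or Hardy–Weinberg
chi-square (1 df, plug-in allele frequency) p < 10⁻⁶, attributed to the
first failing filter in that order; a separately counted second pass applies
the association-stage MAF ≥ 5% filter. An exact HWE test was considered and
left out: at the simulated sample sizes the chi-square approximation is
adequate and the filter only guards gross genotyping failure.

## Methylation array normalization

Two probe designs coexist on the array: type-1 probes read both signals in
one colour channel, type-2 probes read methylated in green and unmethylated
in red. Normalization proceeds in stages: (1) type-1 M and U are quantile
normalized across individuals per channel, then the two channels are
quantile normalized within each individual (M and U separately) to remove
colour bias; (2) type-2 M and U are quantile normalized across individuals,
then mapped per individual onto the corresponding normalized type-1
reference distribution; (3) β is formed; (4) type-1 and type-2 β are
quantile normalized together within each individual. Quantile normalization
targets the mean of the sorted vectors (the standard variant); mapping
between different-length vectors goes through interpolated empirical
quantile functions on a 2001-point grid, which leaves the two probe types'
per-individual β distributions equal to sup-norm ≲ 10⁻³ at 10⁴ sites.
Probes whose assayed dinucleotide overlaps a supplied SNP list are removed
(the MAF threshold on that list is the caller's).

## Expression processing

Samples under the exonic-read floor are dropped (default 5×10⁶ reads, the
scale of a real library; synthetic-cohort configs lower it since simulated
libraries are desk-sized). Libraries are scaled to 10⁷ total exonic reads,
using totals taken before exon filtering. Exons with zero counts in ≥ 10% of
samples are removed. Each exon is then regressed on mean GC content and
insert-size mode (continuous) with grouped intercepts for run date and
primer index, and the output is the residual plus the exon's grand mean, so
per-exon means are preserved exactly. The default estimator is the
fixed-effects projection (one matrix solve for all exons); a
`method="mixed"` variant fits the categorical factors as variance components
(statsmodels MixedLM). With a handful of run-date/primer groups the two
agree to numerical noise, and the projection vectorizes across thousands of
exons, so it is the default. RPKM is per gene: summed exon counts over
(summed exon kb × library exonic reads in millions).

## Cis association and permutation FDR

All scans are Spearman rank correlations (average ranks; two-sided p from
the t approximation on ρ). eQTL, mQTL and eQTM runs share one code path and
differ only in configuration (window, unit, matrices). The unit is the gene
for expression scans (minimum p over all the gene's exon×feature tests) and
the CpG for mQTLs. The null is built by permuting the y-variable's
individual labels — jointly for all of a unit's tests, preserving the cis LD
structure of the x side — 1000 times over a sample of units (all units when
fewer than the configured sample). The global threshold T is the largest
observed unit-minimum p such that

  FDR(T) = median over permutations of #{null units with min-p ≤ T},
           scaled to the full unit count, divided by #{observed ≤ T}

is at most the target (10%); candidate thresholds are the observed minimum
p-values themselves, and a mean-count variant sits behind a flag. Records
with nominal p ≤ T are flagged significant. Per-unit empirical p-values are
also emitted: from the unit's own permutation null when it was sampled,
otherwise from the pooled null (an approximation, since units differ in
test counts). Missing dosages are dropped pairwise in the scalar Spearman
test; inside the vectorized permutation engine missing values receive the
mean rank, which contributes zero to the correlation.

π0 is estimated from #{p > λ}/((1 − λ)n) on the grid λ = 0.05…0.95 (step
0.05) by a weighted cubic fit (weights from the binomial variance of each
point, which stabilizes the extrapolation at λ → 1), evaluated at the top of
the grid and clipped to [0, 1]; below 100 p-values the single-λ = 0.5
estimate is used. The estimator's Monte-Carlo sd is ≈ 0.02 at 10⁴ uniform
p-values, so calibration checks report means over replicate draws.
Q-values are the monotone step-up π0·n·p(j)/j, reducing to
Benjamini–Hochberg at π0 = 1.

## Differentiation metric and context enrichment

The differentiation score of a CpG is cv = sd(per-cell-type median β, n − 1
denominator) / mean(medians); a zero mean yields an undefined marker. Decile
enrichment ranks sites into 10 equal-count bins and compares flagged vs
unflagged scores by a two-sided rank-sum test. Feature enrichment of
significant pairs uses a matched null: null pairs are sampled from
non-significant units stratified on joint bins of MAF (5% bins), |distance|
(10 log-spaced bins) and phenotype level (deciles); empty strata fall back
to halved bin counts, then to the whole pool, with a log entry. The 2×2
Fisher exact test is (significant vs null) × (overlap vs not). The
pos/neg-eQTM context analysis compares each sign's overlap proportion
against non-eQTM sites. "Expressed genes" means at least one exonic read in
more than 90% of individuals; non-expressed genes are excluded from
promoter-methylation correlations rather than plotted at a floor. An
optional flag (default off) drops sites whose median β is outside the range
spanned by the per-cell-type medians, as a robustness check.

## Allele-specific expression

Assayable heterozygous site–individual pairs require 50-bp mapability = 1,
simulated-read mapping-bias difference ≤ 5%, and coverage ≥ 16 reads (counts
are assumed already restricted to mapping/base quality ≥ 10 upstream);
genotype verification requires both alleles observed in at least one cell
type, skipped in imprinted-gene mode. The expected reference ratio is
computed per individual and allele pair by pooling reads after down-sampling
sites above the individual's 75th coverage percentile to that percentile
(hypergeometric, seeded, never increasing coverage); combinations with zero
total fall back to the individual-wide ratio. Imbalance is the absolute
distance of a site's reference fraction from this expected ratio (≈ 0.5); a
strict-0.5 mode sits behind a flag. Simulated-read bias estimation from a
genome is out of scope: `sim_bias` is an input column the generator
fabricates. Group comparisons summarize per gene — mean imbalance across a
gene's assayable sites per individual, then the median across qualifying
individuals — and use two-sided rank-sum tests. Down-sampling is per
individual (pooled-across-individuals down-sampling would couple
individuals' corrections).

## Interactions and TF analyses

The interaction model is OLS of expression on {snp, meth, snp·meth} with the
inputs mean-centered before forming the product; centering reduces
collinearity and leaves the product-term t test unchanged (tested).
Triplets enter the scan when the exon has an eQTL with p < 10⁻⁴ (best SNP
per independent recombination interval — intervals are an input BED; the
generator emits an even partition) and an eQTM with p < 10⁻³, the SNP and
CpG are uncorrelated (Spearman p ≥ 0.05), and the SNP has at least four
minor-allele homozygotes. Enrichment is measured by π1 with a permutation
envelope: expression is permuted jointly across triplets per round, each
round yields a π1, and the empirical p is (1 + #{null ≥ observed})/(B + 1).
Inside the envelope the comparison statistic is the raw (unclipped)
fixed-λ = 0.5 π1 on both sides — clipping to [0, 1] would put an atom at
zero and break the uniformity of the empirical p under the null — while the
reported observed π1 uses the full smoother; a flag forces the smoother
everywhere. TF–methylation analysis correlates each TF exon's expression
with eQTM β at CpGs inside that TF's binding peaks, excluding CpGs within
1 Mb of the TF's own TSS, and reports per-TF π1 and q-value counts plus a
one-permutation expected distribution; TF expression is tested per exon (a
gene-level aggregation is a caller-side groupby). SNP×TF interactions take
the best significant mQTL SNP per CpG that falls in a TF peak whose CpG is
TF-correlated at 10% FDR, require SNP–TF independence (p ≥ 0.05) and ≥ 4
minor homozygotes, and fit methylation on {snp, tf, snp·tf}.

## Causal models

Each structure's log-likelihood is the sum of its two conditional nodes'
maximized Gaussian OLS log-likelihoods (MLE variance); the S root term is
identical across the three structures and omitted. S enters as a numeric
additive parent. The AIC books k = 5 parameters per network
(intercept + slope per modeled node, plus one shared-variance convention); a
k = 6 per-node-variance convention is selectable and cannot change the
ranking since k is equal across models. The BN call is the minimum-AIC
structure; relative likelihoods are exp((AIC_best − AIC_other)/2).

The CIT for S → mediator → outcome combines four p-values and takes their
maximum: p1 (marginal F of S on the outcome), p2 (F of S in
mediator ~ outcome + S), p3 (F of mediator in outcome ~ S + mediator), and a
conditional-independence component p4. For p4 the observed F of S in
outcome ~ mediator + S is located within its permutation distribution from
permuting S inside mediator-decile strata (strata under two members merge
left) — a reference that preserves the S–mediator association while
enforcing conditional independence — then mapped through the central-F
quantile back to an F scale and evaluated against a noncentral F whose
noncentrality is estimated from the marginal S→outcome F (the no-mediation
alternative). Small p4 therefore supports conditional independence with
real power; a raw permutation quantile would be uniform under true mediation
and leave the max-p omnibus nearly powerless. When the marginal signal is
absent the component falls back to the permutation quantile itself. The CIT
is run with M as mediator (supporting SME) and E as mediator (supporting
SEM); exactly one omnibus p < 0.05 calls that model, both calls none, and
neither calls INDEP. The eQTM sign is the sign of the marginal Spearman
correlation of M and E.

High confidence: SME/SEM when BN and CIT agree; INDEP additionally requires
the best-vs-second-best AIC margin to reach the median margin of the
high-confidence SME/SEM calls (when none exist the margin rule is undefined
and agreement alone suffices, recorded in the output). Triplet selection
builds three sets from the association results — best significant eQTM per
exon with that CpG's best significant mQTL; best significant eQTL and eQTM
per exon; best significant eQTL per exon where the SNP is also a best
significant mQTL — down-sampled to the smallest set's size (seeded) and
merged.

## Synthetic cohort: what it emulates, and what it does not

The generator mirrors the statistical structure of a three-cell-type newborn
cohort at desk scale: shared HWE genotypes with MAF ~ Uniform(0.1, 0.5);
β-values as the inverse logit of a bimodal per-site latent (means near ±2)
plus per-cell-type shifts for a configurable minority of sites
(differentiated fraction 0.2, shift sd 1.0), Gaussian individual noise
(sd 0.5), and planted mQTL effects (default 1.0 on the logit scale) through
dedicated SNPs placed within 5 kb; negative-binomial exon counts
(dispersion 0.1) with lognormal gene means, library-size factors, a GC-slope
covariate effect (2.0 on the log scale), planted eQTLs
(exp(β·dosage), β = 1.0) through SNPs within 1 Mb, and eQTMs coupling the
methylation latent into the gene mean with recorded sign; optional raw
fluorescence with probe-type/channel affine distortions (red gain 1.3 etc.)
so the normalization is testable; evenly spaced recombination intervals,
promoters/CGIs/peaks placed from the seed; binomial allelic counts with
negative-binomial coverage and per-individual bias offsets. Default effect
sizes are large enough that every planted effect is recoverable by its
matched estimator within 3 SE — the regime the analyses are validated in.

Not emulated: LD beyond the planted SNP–target couplings, probe chemistry
beyond affine distortion, read-level sequences, batch structure beyond the
four covariates, imprinting mechanics (imprinted-gene mode only relaxes a
filter), or trans effects. Passing tests therefore demonstrate correctness
of the procedures and calibration under the generator's assumptions, not
performance on real cohort data. Each generator stage derives its RNG from
(seed, stage name), so outputs are byte-identical per seed and adding a
generator never perturbs another's draws.

## Problem sizes and runtime

Tests and the acceptance script use scaled-down problems chosen as the
package's own validation conditions: null-FDR calibration on 100 individuals
× 500 genes × 2000 SNPs × 1000 permutations (×5 seeds), causal recovery on
200 triplets per structure at n = 200 with 200 CIT permutations,
normalization on 10⁴ sites × 20 individuals, envelope calibration on 100
replicate seeds of 100 triplets. The full test suite runs in about two
minutes and the acceptance script in under one on a single CPU.

## Known limitations

* The permutation engine mean-rank-imputes missing dosages (exact pairwise
  dropping is used in scalar tests); with post-QC missingness ≤ 5% the
  effect on thresholds is negligible.
* Per-unit empirical p-values for units outside the permutation sample come
  from the pooled null and ignore between-unit differences in test counts.
* The π0 smoother has Monte-Carlo sd ≈ 0.02 at 10⁴ p-values; single-draw
  estimates near a calibration boundary should be averaged over replicates.
* The CIT p4 noncentrality estimate is plug-in; very weak marginal signals
  make p4 conservative (it degrades toward the permutation quantile).
* No conditional/secondary signal mapping, no trans analysis, no
  beta-binomial overdispersion in ASE, no phasing.
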