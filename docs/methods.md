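# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `twinmeth`.

## Study design and inference unit

The cohort is a set of monozygotic twin pairs discordant for disease
status. Because co-twins are genetically identical and share early
environment, the within-pair difference of any molecular readout cancels
genetic and much of the shared-environment confounding. All inference in
the methylation arm therefore reduces to a one-sample problem on the
within-pair difference vector (affected − unaffected), which is
algebraically equivalent to a pair-blocked two-group linear model but
simpler to verify against a brute-force paired t-test. The default cohort
size is 7 pairs (14 samples), the size this design realistically reaches.

## Probe QC

Filters are applied in a fixed order so the report bins are well defined —
detection failure (detection p > 0.01, strict, in ≥ 1 sample), SNP
overlap, underperforming-probe mask, sex chromosomes — and each probe is
tallied in the first filter that removes it, so the bins always sum to the
input count. The order itself is a convention: the underlying filters are
defined probe-wise and commute.

Between-sample normalization is plain quantile normalization on β: the
k-th smallest value of each sample is replaced by the mean of the k-th
smallest values across samples, leaving every sample with the identical
sorted vector (all pairwise Kolmogorov–Smirnov distances exactly zero on
tie-free data). The stratified variant used with array data requires
probe-chemistry annotations that are deliberately out of scope; plain QN
preserves the property downstream stages rely on (identical marginals).
Ties receive the mean of the target values at their occupied ranks, making
the operation deterministic and idempotent (to 1 ulp; re-averaging
identical sorted columns can move a value by one rounding step).

## M values and the paired moderated test

Testing happens on M = log2(β/(1−β)) after clipping β to [ε, 1−ε]
(ε = 10⁻³): the M scale approximately stabilizes variance across the β
range, while effect sizes (Δβ) are reported back on the β scale where they
are interpretable. Sign consistency of Δβ and the M-scale effect holds
whenever β stays away from the clip boundaries.

**Surrogate covariates.** Unmodelled batch structure is estimated from the
data: each probe row of the difference matrix is centred, and the leading
right-singular vectors are retained while their singular values exceed the
(1−α) empirical quantile (conservative "higher" method, α = 0.05) of
singular values from 20 row-wise independently permuted copies (parallel
analysis). On pure noise this yields q = 0 in ≈ 95% of runs; a planted
batch split is recovered with |r| > 0.99 against the true pattern. The
number of surrogates is logged, never assumed. Because rows are centred,
surrogate columns are orthogonal to the intercept, so including them does
not bias the effect estimate — it only spends residual degrees of freedom
(d = n_pairs − 1 − q).

**Empirical-Bayes moderation.** With per-probe residual variance s²_g on d
df, the hyper-parameters of the scaled-inverse-χ² variance prior are
estimated by moment matching on z_g = log s²_g: writing
e_g = z_g − ψ(d/2) + log(d/2), the prior df solves
ψ′(d₀/2) = var(e) − ψ′(d/2) via Newton iteration on the trigamma inverse
(tolerance 10⁻⁸), with d₀ = ∞ when the right-hand side is non-positive,
and log s₀² = mean(e) + ψ(d₀/2) − log(d₀/2). The posterior variance is the
df-weighted blend, the moderated t uses d + d₀ df (standard normal when
d₀ = ∞). This reproduces limma's `lmFit`/`eBayes` one-sample path exactly
(agreement to 10 significant digits on a frozen fixture, computed with
R limma 3.58.1). One consequence worth noting: when all probes share the
same s², the estimator returns d₀ = ∞ with s₀² equal to the χ²
bias-corrected pooled variance, which exceeds s² by the factor
exp(log(d/2) − ψ(d/2)) (≈ 1.19 at d = 6) — the "no-moderation" intuition
s̃² = s² holds only up to that constant.

**DMP calling.** Significance uses strict p < 0.005 — a deliberately
suggestive threshold for a 7-pair cohort; the epigenome-wide level
3.6×10⁻⁸ is surfaced as a constant for context but never applied as a
filter. BH q-values are computed over all tested probes.

## Region chaining and concordance

"At least two DMPs within 1 kb" is implemented transitively: sort
significant probes per chromosome, extend a chain while the gap between
consecutive CpGs is ≤ max_gap (1000 bp, inclusive at the boundary), emit
chains with ≥ min_probes (2) members. The transitive reading is the only
one consistent with regions holding more than two probes; boundary
inclusivity is a convention and documented as such. The operation is a
partition — every significant probe lands in exactly one (possibly
dropped) chain — and is verified against an O(n²) transitive-closure
oracle. Duplicate CpG coordinates are rejected at manifest validation, so
ties cannot arise.

Concordance is a strict all-same-sign rule on member Δβ; a Δβ of exactly
zero classifies the region as mixed and flags it. Promoter windows default
to −1500/+500 around the TSS, strand-aware, approximating vendor promoter
classes; promoter takes precedence over gene body, and the first gene in
the model wins at equal priority.

## Co-expression arm

**Normalization.** Median-of-ratios size factors (median over
all-positive genes of the sample count over the gene's geometric mean,
rescaled to geometric mean 1), falling back to total counts with a warning
when no gene is positive everywhere.

**CLR.** Counts are divided by size factors, pseudocounted (+1, the
smallest standard choice; CLR is undefined at zero), renormalized to a
per-gene composition across samples, and log-centred so every gene row
sums to zero. An all-zero gene maps to the simplex centre and is flagged.

**Mixture model.** A diagonal-covariance Gaussian mixture is fitted by EM
over K = 2…25 (configurable), 5 restarts per K from k-means++ seedings,
convergence when the log-likelihood changes by < tol·(1+|LL|) with
tol = 10⁻⁶ (relative, so the criterion is meaningful at any sample size),
cap 300 iterations. The log-likelihood trace is asserted non-decreasing on
every fit. A restart that empties a component or drives a variance below
10⁻⁸ is re-initialized (up to 3 attempts); a K whose restarts all collapse
is skipped. Model selection minimizes ICL = BIC + 2·Σ entropy, which
penalizes fuzzy assignments and resists the overfitting BIC alone allows
on small samples. Membership requires responsibility strictly > 0.9, so a
gene can remain unassigned.

**Contrast.** Per cluster, A_g (B_g) is gene g's mean normalized
expression over affected (unaffected) samples; the cluster ratio is
mean(A)/mean(B) and the test is a two-sided Wilcoxon rank-sum comparing
{A_g} with {B_g}. With hundreds of member genes this comparison has the
resolution to produce the extreme p-values this analysis style reports,
which a 7-vs-7 sample-level comparison cannot. The rank-sum is exact by
full enumeration of splits (correct under ties) when the pooled sample has
≤ 50 observations and at most 2×10⁵ splits, and a tie-corrected normal
approximation without continuity correction otherwise. The ratio is
computed on size-factor-normalized counts (the scale is not fixed by
convention; this choice is flagged in the interface docs).

**DE stand-in.** The paired differential-expression table uses a
moderated paired t on log-CPM (log2((y+0.5)/(lib+1)·10⁶)) rather than a
negative-binomial GLM: it is calibrated (null p-values KS-uniform in the
test suite), reuses verified machinery, and its role downstream is only to
supply nominal-p gene lists. It is labelled a stand-in in the outputs.
Known property: because CPM divides by the library total, a group shift
affecting a large fraction of the transcriptome is partially absorbed into
the normalization (at 25% spiked genes, ~0.17 of a 0.585 log2 effect).

**Enrichment.** One-sided Fisher exact tests on the 2×2 overlap table per
gene set, BH across sets. The universe defaults to the genes present in
the input, not the genome, to avoid selection bias.

## Bench calculators

2^−ΔCt relative expression with replicate-scatter propagation on the Ct
scale (flagged unreliable above 1 cycle SD, still computed); MeDIP
percent-of-input with dilution-adjusted input Ct
(Ct* = Ct_input − log2(fraction)) and amplification efficiency fixed at
2.0, over-recovery flagged; two-sided one-sample t.

## Synthetic cohorts

The methylation generator draws per-probe baselines from a three-component
M-scale mixture (low ≈ β 0.1, high ≈ β 0.9, intermediate; 40/40/20 by
default) so the marginal β histogram is bimodal as on real arrays; adds a
shared pair effect (σ = 1.0) giving strong within-pair correlation; adds
technical noise (σ = 0.3); and spikes additive disease effects
(delta_m = 0.8) at isolated probes and at probes clustered into
sub-kilobase regions (one shared sign per region unless discordant regions
are requested). Manifest positions keep region probes within the region
span and all other neighbours ≥ 2 kb apart so chaining cannot bridge
unrelated probes. Detection p-values are U(0, 0.01) with sporadic failures
U(0.011, 1) at rate 0.001.

The batch effect deserves its own paragraph. The M-scale offset (0.5) is
applied to one member per pair — affected member in half the pairs,
unaffected in an equal number, both members in an odd leftover pair — and
to a random half of probes. Both choices are forced by the design: a
sample-wide shift is a monotone per-sample transform that quantile
normalization removes exactly (leaving nothing for the surrogate stage to
find), and an unbalanced carrier pattern across an odd number of pairs
leaves a nonzero mean in the within-pair differences that is
mathematically confounded with the disease contrast — no covariate could
remove it. Real scan-batch artefacts are probe-specific and not aligned
with case status, which is what this scheme emulates.

The count generator assigns each gene a latent cluster; a cluster template
gives every *pair* a log-normal multiplier (σ = 0.7) shared by both twins
(expression has a strong familial component), affected-sample means are
multiplied by the cluster's group ratio, library factors are jittered
U(0.7, 1.3), and counts are negative binomial
(var = μ + 0.05·μ²). Genes within a cluster share the cluster's base mean
(log-uniform on [50, 500] across clusters): with a common base, per-gene
group summaries of different genes are exchangeable under a unit ratio, so
the cluster contrast's null p-values are honestly uniform. This is the one
place the generator is deliberately cleaner than real data, where
within-cluster expression magnitudes vary and gene-level summaries are
correlated through them; passing null-calibration tests here demonstrates
the machinery is correct, not that real-data cluster p-values are exact.

What the generator does not emulate: probe type I/II chemistry, cell-type
composition, age/sex structure, copy-number artefacts, count outliers and
transcript-length effects. Recovery results on these cohorts are
best-case; on real data the same stages face additional nuisance structure
the simulation omits.

## Problem sizes and determinism

The default test and acceptance problem sizes — 20,000 probes × 7 pairs
for calibration, 5,000 probes for prior recovery, 500 genes over a K grid
of 2–25 for clustering recovery, 8,000 genes / 20 clusters for the
contrast — are chosen as the smallest sizes at which the Monte-Carlo
noise of each property is comfortably below its acceptance margin. Every
random draw flows from `numpy.random.default_rng` seeded per stage via a
CRC32 hash of the stage name and the global seed (stable, < 2³¹), so runs
are byte-reproducible and toggling one stage does not shift another's
stream. Tables are written with 17 significant digits and read back with
round-trip float parsing, making write/read cycles bit exact.

## Known limitations

- Plain (not stratified) quantile normalization; no background/dye-bias
  correction; no cell-composition or age/sex covariates.
- The surrogate estimator is residual SVD + parallel analysis, not
  iteratively reweighted SVA; with 7 pairs there are at most 6 residual df
  to spend.
- The DE stand-in is not dispersion-aware and should not be used where a
  count GLM is required.
- Gene-level cluster contrasts treat genes as exchangeable units; on real
  data their correlation makes the printed p-values optimistic.
- The GMM assumes diagonal covariance on CLR profiles; strongly
  correlated sample axes within a cluster are not modelled.
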