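# Methods

This note records the statistical models, the numerical choices, and the
design decisions behind `sarcotype`, in the spirit of a package vignette:
what is computed, under which assumptions, and what the tests do and do not
demonstrate.

## Synthetic cohorts

The generator emulates a bulk RNA-seq cohort of high-grade soft-tissue
sarcomas with planted transcriptomic subtypes. It exists so that every
downstream stage has a ground truth to be tested against; it is first-class,
tested code, not a fixture.

**Expression.** Gene g in sample s is negative-binomial with mean
μ_gs = L_s · b_g · f_g(subtype(s)) and variance μ + φμ² (gamma–Poisson
mixture), the standard RNA-seq parameterization. Baseline relative
abundances b_g are log-normal (σ = 1.2 on the natural-log scale, roughly
the spread of log-expression seen in bulk panels) and normalized to sum to
one; library sizes L_s are log-normal (median 2×10⁵, σ = 0.3), matching a
targeted expression panel rather than whole-transcriptome depth. Each
subtype owns two disjoint marker blocks of 40 genes (over / under), whose
means are shifted multiplicatively by 2^±2 by default. Marker effects are
applied before any per-sample renormalization so that the realized
marker-to-baseline fold change is exactly 2^log2_effect in expectation —
a property the tests verify from raw CPMs. Defaults: 120 samples, 4
subtypes in equal proportions, 1500 genes, dispersion φ = 0.1.

**Survival.** Death times are exponential with per-subtype monthly hazards
(0.010, 0.030, 0.028, 0.035 by default: one favorable subtype, median OS
≈ 69 months, against three unfavorable ones, 20–25 months). Censoring is
the minimum of an administrative horizon (120 months) and exponential
dropout (0.005/month). Disease-free survival is min(recurrence, death)
with recurrence hazard 1.6× the death hazard, under the same censoring;
the factor makes DFS events outnumber OS events, as in real cohorts, and
guarantees dfs ≤ os per sample. Event indicators are independent of
expression given the subtype, by construction.

**Clinical covariates and external scores.** Age ~ N(66, 12²) truncated to
[25, 92]; histotype drawn with subtype-specific frequencies (one
liposarcoma-dominated subtype, the rest dominated by undifferentiated
pleomorphic sarcoma); all samples grade 3; a treatment flag with rate 0.6.
The external risk score emulates a clinical nomogram's predicted 5-year
overall survival on the probability scale — exp(−60·λ_subtype) plus
N(0, 0.05²) noise, clipped to [0, 1] — so the conventional 60% threshold
rule can be applied verbatim. Comparator gene lists (a published
67-gene-signature stand-in) are assembled with a controlled fraction of
one planted marker block, the rest drawn from non-marker genes.

All randomness flows from a single integer seed through one
`numpy.random.Generator`; identical configurations are byte-identical.

**What the generator does not emulate:** FFPE degradation and QC failure,
batch effects, fusion events, correlated co-expression modules beyond the
marker blocks, or non-proportional hazards. Passing tests therefore
demonstrate the pipeline's correctness and its behavior under clean planted
structure — not robustness to those real-data pathologies.

## Preprocessing

Filtering retains a gene iff CPM ≥ `min_cpm` (default 1.0) in at least
⌈`min_fraction`·n⌉ samples (default 0.2). The thresholds concretize the
common "filter by expression" heuristic and are config-exposed. Library
sizes are fixed when the count matrix is constructed and are *not*
recomputed after gene filtering, so CPM values remain comparable across
filter settings.

The variance-stabilizing transform is log₂((count + 0.5)/(libsize + 1)·10⁶);
the offsets bound the transform at zero counts. Per-observation precision
weights come from a fitted mean–variance trend: gene-wise residual SDs from
an intercept-only fit, lowess of √SD against mean log₂ count (span 0.5,
2 robustness iterations), evaluated at each observation's fitted log-count
and raised to the −4th power. Outside the fitted range the trend is
extended flat, bounding weights on extreme genes. With the quantile flag,
columns are quantile-normalized positionally (each column's order
statistics replaced by their across-column mean) before the trend fit —
used for external cohorts scored by rank-based enrichment, where only
within-sample ranks matter.

The MAD filter keeps the ⌈0.55·G⌉ genes of largest median absolute
deviation; ⌈·⌉ (not ⌊·⌋) fixes the count deterministically and ties at the
cut break by lexicographic gene id, so the "top 55%" is reproducible.

## Consensus clustering and the number of clusters

Each of `n_resamples` resamples draws ⌊0.8·n⌋ samples without replacement
and clusters them by average-linkage hierarchical clustering on
1 − Pearson correlation (the consensus-clustering default; Euclidean
distance is config-exposed). One set of draws is made per seed and each
resample's linkage tree is cut at every k in the range, so co-sampling
counts are shared across k and the procedure is deterministic given the
seed. Consensus M_k(i,j) is the co-clustering fraction among resamples
where both samples were drawn; never-co-drawn pairs score 0 and are
flagged via the co-sampling counts. Feature subsampling is off by default.

The stability summary is A(k) = ∫₀¹ ECDF(x) dx over the off-diagonal
upper-triangle entries of M_k, computed as an exact step integral
(equivalently A = 1 − mean consensus). An all-ones matrix gives A = 0, an
all-zeros matrix A = 1.

**Elbow rule.** With the curve anchored at A(1) := 0, k\* is the interior k
whose point (k, A(k)) lies furthest (vertically) above the chord joining
(1, 0) to (k_max, A(k_max)); ties go to the smallest k. This is the
classical knee criterion: A(k) rises while genuine structure is being
resolved and plateaus once k exceeds the true cluster count. A
second-difference variant (argmax of gain drops m(k) − m(k+1)) was
considered and rejected: for c balanced, well-separated clusters the
merges below c are near-uniformly random, making the marginal gains decay
in exact arithmetic ratio (for c = 4: 3 : 2 : 1) so that all second
differences tie and the selection degenerates; the chord criterion has no
such degeneracy and selects the planted k across all seeds tried. PAC
(proportion of consensus entries in an ambiguity band, default
(0.1, 0.9)) is available behind a flag as an alternative selector.

Final labels cluster the consensus matrix itself (average linkage on
1 − M, cut at k\*) and are renumbered 1..k\* by decreasing cluster size,
ties by smallest member sample id — output is invariant to seed-induced
label permutations. Note that the renumbering is by size, so discovered
"C1" corresponds to a planted subtype only up to the mapping given by the
discovery cross-table.

**Limitation.** Subtypes holding fewer than ~10% of samples (for example
the smallest of the four clusters reported in real STS cohorts, 9 of 74
samples) are genuinely unstable under 0.8-item resampling at n ≈ 120: the
consensus matrix tends to absorb the small block and the elbow then
prefers k − 1. The defaults use balanced proportions; strongly unbalanced
designs need more resamples and larger cohorts than the defaults model.

## Differential expression and signatures

For each cluster pair (a, b), every gene is fitted by weighted least
squares on the full cluster-indicator design (so residual variance pools
over all clusters, d_g = n − k), with the precision weights from
normalization. The contrast estimate is the difference of weighted cluster
means; its unscaled variance is 1/W_a + 1/W_b with W_c the summed weights
in cluster c.

Empirical-Bayes moderation shrinks gene variances toward a prior:
s̃²_g = (d₀·s₀² + d_g·s²_g)/(d₀ + d_g), with (d₀, s₀²) estimated by moment
matching on log s²_g — the digamma/trigamma system solved by Newton
iteration on the trigamma inverse. If the observed log-variances are
under-dispersed (no positive solution), the prior df falls back to d₀ = 10
with a logged warning. The moderated t = logFC/√(s̃²·v) is referred to a
Student t with d₀ + d_g df. On unit-weight fixtures with heterogeneous
variances the whole path (d₀, s₀², t, p) agrees with Bioconductor limma to
about 1e-6, which the test suite checks through `Rscript`.

BH adjustment is applied per contrast across genes (pooled-across-contrast
mode is a flag). A gene joins C_c_over iff in *every* contrast (c vs j) it
has q < 0.05 and logFC > 0 (C_c_under mirrored); the all-contrasts reading
of "intersection" is the strict one, and the log-fold-change threshold
defaults to 0 (direction only), both config-exposed. Provenance (the
qualifying contrasts and q-values per member gene) is recorded.

Under the default generator conditions roughly one null gene per cohort
enters some signature: a ±3σ fluctuation of one cluster's mean passes all
three contrasts at BH q < 0.05 with consistent sign. This is the expected
false-discovery behavior of the rule at its thresholds (the per-gene
entry rate, ~0.1%, is far below the nominal FDR), not an implementation
artifact — the naive intersection oracle admits the same genes.

## Single-sample enrichment and classification

Genes are ranked by descending expression (ties by gene id). With rank
weights w_r = (N − r + 1)^α (α = 0.25 by default; α = 0 gives a pure,
monotone-invariant rank statistic), the enrichment score is
ES = Σ_i [P_hit(i) − P_miss(i)], where P_hit is the weighted cumulative
hit fraction and P_miss the uniform cumulative miss fraction. Sets
concentrated at the top of the ranking score positive, at the bottom
negative.

The null standardization draws `n_perm` random gene sets of the same size
(default 1000): NES = (ES − mean)/sd, p = 2(1 − Φ(|NES|)). Because ranks
within a sample are always 1..N and the weights depend only on N and α,
the permutation null depends only on (N, set size, α) — it is computed
once per set size and shared across samples, which both accelerates
scoring and removes a source of between-sample noise. Calibration is
verified empirically: random sets yield P(p < 0.05) within 0.05 ± 0.02.

Classification per sample: BH across *all* scored sets (signatures plus
any user-supplied context pathway sets — the package ships no pathway
database), context sets are then discarded, and the signature set with the
smallest q wins if q < 0.05; otherwise the sample is UNASSIGNED. Ties
break on ascending set name. The literal most-significant-set rule can
assign a sample to a cluster through a significant *anti*-signature (an
_under set with positive NES); a sign-concordance flag (off by default, to
match the literal rule; on is recommended) restricts winners to sets whose
NES sign matches their direction, and every call records whether the
winner was concordant. Sets shrinking below 5 genes after intersection
with the cohort's genes are skipped with a warning.

## Survival machinery

Kaplan–Meier is the product-limit estimator with censored times reducing
the risk set only. The k-group log-rank test sums observed-minus-expected
counts over pooled event times with hypergeometric variance; the statistic
is rank-based and invariant to monotone time transforms.

The Cox model maximizes the Efron partial likelihood by Newton–Raphson
(Breslow available; Efron is the better tie approximation and the de facto
standard). Convergence: max |score| < 1e-9 or relative log-likelihood
change < 1e-12, with step-halving on any likelihood decrease; failure
after 50 iterations, a singular information matrix, or a diverged
coefficient (|β| > 15, the signature of perfect separation) raise explicit
errors rather than returning silently. Standard errors come from the
observed information; 95% CIs are Wald on the log-hazard scale. Factors
are reference-coded with the first sorted level as reference,
deterministically. Against lifelines' `CoxPHFitter` on the same data,
coefficients agree to ~1e-6.

Proportional-hazards diagnostics use the Grambsch–Therneau score test on
scaled Schoenfeld residuals r\*_k = d·V̄⁻¹s_k + β̂, with the averaged
risk-set covariance V̄ (the `cox.zph` approximation) and the identity time
transform by default (a Kaplan–Meier transform is a flag). Per-covariate
χ²_j = (Σ ĝ_k s_kj)²/(Σĝ² · V̄_jj) with ĝ the centered transform; the
global test uses the corresponding p-dimensional quadratic form. The test
is calibration-validated (type-I error within [0.01, 0.10] at α = 0.05
under proportional hazards) and detects a sign-reversing effect at
p < 0.01. Covariates violating proportionality are *reported*; the
package never drops them automatically — exclusion is an explicit user
decision.

The sequential ANOVA fits nested covariate blocks left to right and
reports per-block likelihood-ratio χ² with df equal to the design columns
added; block χ² telescopes to the full-model LRT by construction.

Harrell's C is computed over comparable pairs (i usable against j iff
t_i < t_j and subject i had the event), with 0.5 credit for tied scores,
returning the pair counts alongside C.

## Benchmarking

Model specifications name covariate lists (cluster labels as an unordered
factor with cluster 1 the reference; age; an external risk probability; a
comparator two-class label consumed as a plain column — no re-training of
external classifiers). Each spec is fitted by Cox PH on the full cohort
and ranked by the apparent Harrell's C of its fitted linear predictor —
apparent, i.e. trained and evaluated on the same cohort, matching
single-cohort comparison practice; a k-fold cross-validated C is available
and labeled separately, since apparent C of nested models is not monotone
in general (the tests assert log-likelihood monotonicity instead).

Sub-stratification splits the cohort at predicted 5-year OS > 60%
(favorable) versus ≤ 60% (unfavorable; the boundary value is unfavorable),
then runs per-cluster (or cluster-1-versus-rest) Kaplan–Meier and log-rank
within each stratum. Gene-set overlap reports 100·|A∩B|/|A| with the
comparator list as the denominator set, alongside Jaccard; NES correlation
is Spearman's rank correlation with average-rank ties.

## Problem sizes used by the tests

The pipeline-level checks run the generator at its default size (1500
genes × 120 samples) with 250 consensus resamples and 1000-permutation
enrichment nulls; module tests use compact instances (hundreds of genes,
tens of samples) chosen so each statistic's behavior is already
asymptotically visible. Calibration checks use 50 replicates (Schoenfeld
type-I), 200 replicates (ANOVA null uniformity), and 500 random sets
(enrichment null), sizes at which the binomial standard errors are well
inside the asserted bands.
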