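# Methods

## The synthetic cohort generator

Counts are gamma-Poisson (negative binomial with `Var = µ + φµ²`, default
φ = 0.1) on a log2 mean that stacks a per-gene baseline
(log2 of 200 ± 1.5 sd across genes), planted effects, a hidden batch factor
and per-sample log-normal library-size variation (sd 0.3 natural-log
units). The NB noise model matches what the precision-weighting step
assumes about bulk RNA-seq.

Gene geography defaults to 90% autosomal (cycled over chr1–22), 6% X, 2%
PAR (carried on X with `par_flag`), 2% Y. Non-PAR X genes draw an XCI class
with probabilities 0.157 / 0.160 / 0.683 (escape / variable / inactive),
matching the published XCI catalogue's 99/101/431 proportions in a 631-gene
universe; PAR genes are labeled escape, since pseudoautosomal loci are not
silenced.

Sex rules: male X genes sit at the female inactive-gene baseline (dosage
compensated); female escape genes are up-shifted +0.4 log2 by default
(+0.2 for variable escape), encoding biallelic escape expression; Y genes
are silenced in females (mean × 1e-4); PAR genes are expressed equally in
both sexes. A configurable fraction of autosomal genes (default 5%) gets a
sex log-fold-change of ±1; diagnosis effects are planted per region as
shared, female-only and male-only gene sets; `rxe_factor` multiplies the
non-PAR X means of one (sex, diagnosis, region) cell to plant a
chromosome-wide dosage shift. Donors are shared across regions (one sample
per donor per region), ages are uniform on 17–80 (matching the usual
adult-cohort inclusion rule), and quality covariates are independent
normals.

What the generator does *not* emulate: transcript/exon/junction features,
count outliers and GC/length biases, ancestry structure in the SNP PCs,
age-dependent effects, or correlated quality covariates. Tests that pass on
this generator certify the statistical machinery, not robustness to those
real-data pathologies.

## Normalization

* Effective length `gene_length − mean_fragment_length + 1`; genes at ≤ 1
  are masked (they cannot be quantified at the given fragment length).
* TPM per Eq. above with columns summing to 1e6 over retained genes.
* The low-expression filter counts samples at ≥ 10 CPM across the whole
  cohort against a quota of ⌈0.7 × smallest group⌉ — the quota derives from
  the smallest sex group but qualifying samples are counted cohort-wide.
  Ceiling is the conservative rounding choice.
* TMM with the canonical trims (30% on M, 5% on A), delta-method precision
  weights, reference = sample whose 75th-percentile CPM is closest to the
  mean, factors rescaled to geometric mean 1. Genes zero in either member
  of a pair are excluded from that pair.
* log-CPM uses a prior count of 0.5 on TMM-effective library sizes.
* Precision weights: per-gene OLS on the design, lowess (span 0.5) of
  √(residual sd) on mean log-CPM, evaluated at each observation's fitted
  value with clamping to the trend's endpoints, weight = trend⁻⁴. The
  trend is fit on log-CPM abundance rather than raw log-counts; on
  NB-simulated data the downstream moderated-t type-I error at p < 0.05
  lands inside [0.035, 0.065] (verified in the acceptance tests).

## Linear models and moderation

Designs are treatment-coded with intercept; female, CTL and the
alphabetically first region are the reference levels, so the sex
coefficient is log2(male/female) — male-bias positive. Interaction models
include main effects plus product terms, and the product terms are the test
target (a joint moderated F when there are several). The diagnosis-by-sex
model demands single-sex input and errors otherwise. Rank deficiency is
detected before fitting and reported with the aliased columns.

Two named null designs support residualization: `null_with_diagnosis`
(diagnosis + age + covariates + SNP PCs, no sex, no hidden factors) and
`null_minimal` (age + covariates + SNP PCs + hidden factors, no sex, no
diagnosis). Residualization is per-gene OLS followed by a z-score across
samples; zero-variance genes are flagged and excluded.

Variance moderation follows the standard empirical-Bayes recipe: fit a
scaled-F prior to the per-gene residual variances by moment-matching on
log s² (digamma/trigamma identities; the trigamma inverse by Newton), then
use the posterior `(d₀s₀² + d·s²)/(d₀ + d)` and `d + d₀` df for the t.
`d₀ = 0` reproduces ordinary WLS exactly; `d₀ = ∞` pins every gene at s₀².
The robust (outlier-tolerant) prior variant is not implemented.

Repeated donors across regions in the sex × region model are handled with
CR1 donor-clustered sandwich standard errors and `n_clusters − 1` df,
replacing a random-effect fit: the inferential target (a valid SE for the
interaction under within-donor correlation) is the same, at closed form
and without a mixed-model dependency. Moderation is skipped on the robust
path because shrinking a sandwich variance with a model-based prior mixes
incompatible estimands.

Hidden factors are the leading PCs of the null-design residuals, with rank
chosen by parallel analysis: keep PC k while its variance exceeds the 95th
percentile of the k-th PC variance under independent within-gene
permutation (20 permutations), stopping at the first failure. This
approximates surrogate-variable analysis without the iterative
reweighting. Covariate screening correlates candidates with the top 10
expression PCs within each sex, Bonferroni over all tests, after collapsing
candidate pairs with |r| > 0.95 to the first member.

## X dosage and XCI enrichment

RXE drops genes with TPM > 0 in fewer than 20% of samples ("present" means
strictly positive TPM), then takes log2 of the mean TPM over non-PAR X
genes minus log2 of the mean over chr1–22. PAR genes and chrY are excluded
by default (both flags are configurable) because neither is informative
about X-inactivation dosage; `restrict_xci_class` limits the X set to one
inactivation class. The log-of-mean form is the default; a mean-of-log
variant (log2(TPM+1) averaged within each set) is provided. RXE is
invariant to rescaling a sample's TPM, so group shifts reflect the X:
autosome rate ratio only — a planted 0.8× factor appears as
log2(0.8) = −0.322 exactly, up to sampling noise.

Mann-Whitney U uses exact enumeration when both groups have ≤ 8
observations and the pooled values are tie-free, otherwise the
tie-corrected normal approximation with continuity correction. Fisher
tests are two-sided by the minimum-likelihood rule. XCI enrichment builds
one 2×2 table per (class × direction stratum) over the tested X universe
and Bonferroni-corrects across all tables computed.

## Sex-specific procedures

The stringent filter's opposite-sex Mann-Whitney runs on residuals from
the `null_minimal` design — diagnosis is deliberately left out of the null
so a diagnosis difference remains visible in the residuals. Stages are
strictly nested and every removed gene carries a reason
(`shared` / `opposite-sex signal`).

The subsampling null draws B simple random male subsets (no stratification
by default; a `stratify` option balances diagnosis) and reruns the
diagnosis DE pipeline per draw. With `reuse_normalization` (default) the
filter, TMM, log-CPM and weights come from the full male cohort and only
the model refits per draw; the faithful-but-expensive alternative reruns
everything including hidden-factor estimation. The empirical p is add-one
and two-sided, `min(1, 2·min((1+#{≤obs})/(B+1), (1+#{≥obs})/(B+1)))` —
never zero, and approximately uniform under exchangeability provided the
DEG count varies across draws. The calibration test therefore uses a
cohort with an intermediate-power diagnosis signal: with no signal the
count is almost always a handful of tied values and the uniformity check
degenerates into a test of discreteness rather than of calibration.

## Replication statistics

π0(λ) = #{p > λ}/(n(1−λ)) on the grid 0.05…0.95 (step 0.05). The smoother
is a precision-weighted cubic fit — the stiff (~4 effective df) limit of a
natural cubic smoothing spline, weights ∝ √(1−λ) to downweight the
increasingly noisy tail — evaluated at the largest λ and clamped to [0,1].
A data-driven (GCV) spline was rejected: on a 19-point grid it tracks the
binomial noise of the tail estimates and inflates the null π1. Below 20
p-values the single-λ estimate at λ = 0.5 is used. Selection in dataset A
defaults to nominal p < 0.05 (configurable). Spearman concordance uses
average ranks; the overlap Fisher table is
[[|A∩B|, |A\B|], [|B\A|, |U\(A∪B)|]].

## Problem sizes and determinism

The test suite and acceptance script use desk-scale cohorts — 1000–2000
genes and 100–400 samples, 3–25 replicates per stochastic check, B = 99
subsampling draws against the study-scale 1000 — chosen so each check has
adequate Monte-Carlo resolution for the property it asserts. Every random
stage takes an explicit seed; a fixed configuration reproduces counts and
pipeline outputs byte-for-byte. Degenerate inputs (all-zero samples,
constant genes, empty groups, rank-deficient designs, samples sharing no
expressed genes with the TMM reference) raise errors naming the offending
row or column rather than propagating NaN.
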