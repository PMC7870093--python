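# Methods

This note records the models the package implements, the assumptions behind
each formula, what the synthetic-data generators do and do not emulate, and
the numerical and design choices that were genuinely open.

## Distance model and asymptotics

For a data matrix X with m instances and p attributes, the L_q distance is
D_ij = (Σ_a |X_ia − X_ja|^q)^{1/q}. Under the null model — entries iid
within each attribute, attributes independent — the per-attribute
projections Z_a = |X_ia − X_ja|^q are iid, so D_ij^q is asymptotically
normal by the CLT and D_ij is asymptotically normal by the delta method
applied to z ↦ z^{1/q}:

    D_ij ≈ N( (μ_z p)^{1/q},  σ²_z p / (q² (μ_z p)^{2(1−1/q)}) ).

For standard normal data Z_a is generalized gamma with
μ_z = 2^q Γ((q+1)/2)/√π and σ²_z = 4^q[Γ(q+1/2)/√π − Γ²((q+1)/2)/π]; for
standard uniform data Z_a is Kumaraswamy with μ_z = 2/((q+2)(q+1)) and
σ²_z = 1/((q+1)(2q+1)) − μ_z². Gamma factors are evaluated through
log-gamma, so large q cannot overflow.

For q = 2 the squared distance is itself the CLT sum, which gives the
second-order mean estimate E D = √(μ_z p − σ²_z/(4μ_z)) (e.g. √(2p−1) for
normal data). This estimate is accurate at both low and high p and is the
package default for q = 2; the plain first-order mean is available via the
`improved=False` flag.

Two facts worth keeping in mind when choosing a metric: on N(0,1) data the
Manhattan variance grows like p while the Euclidean variance is exactly 1 in
the limit, so Euclidean distances concentrate in a thin shell in high
dimension while Manhattan distances stay dispersed.

## Range (max-min) normalization and extreme values

Relief divides each attribute diff by the attribute's observed range
max(a) − min(a) to bound scores. Treating the range as approximately
independent of the numerator, the normalized-distance moments follow from
the moments of sample extremes:

* normal data: the sample maximum is asymptotically Gumbel. The Gumbel-limit
  *median*, log(log 2)/Φ⁻¹(1/m) − Φ⁻¹(1/m), estimates the expected maximum
  more accurately than the Gumbel mean (the mean overestimates; the unit
  test `test_median_closer_than_gumbel_mean` checks this against exact
  quadrature), so the median is the default and the Gumbel mean sits behind
  a flag. Range variance: π²/(6 log m).
* uniform data: exact beta moments, E max = m/(m+1), E min = 1/(m+1), and
  E[range²] = (m³−m+2)/((m+2)(m+1)²). The E[range²] form embeds the
  approximation E[max·min] ≈ E[max]·E[min]; it is kept exactly as written
  (the exact value at m = 2 is 1/6, not 2/9), hence the m ≥ 2 precondition —
  the approximation is part of the model, not replaced by the exact
  small-m value.

Consequences reproduced by the tests: the normalized Euclidean variance on
uniform data tends to 7/120·(m+2)(m+1)²/(m³−m+2) → 7/120, and on normal
data vanishes like 1/log m (another curse of dimensionality — normalized
Euclidean distances become indistinguishable at large m).

## Genotype metrics

Genotypes are minor-allele counts X ~ Binomial(2, f_a), loci independent.
The three diff metrics are genotype mismatch (GM, support {0,1}), allele
mismatch (AM = |Δ|/2, support {0,1/2,1}), and the transition/transversion
weighted TiTv with support {0, 1/4, 1/2, 3/4, 1}: a mismatch at a
transition locus (PuPu or PyPy nucleotide pair) scores 1/4 (|Δ|=1) or 3/4
(|Δ|=2); at a transversion locus (PuPy) it scores 1/2 or 1 — transversions
are the more disruptive substitution and carry the larger weight. Whether a
locus is Ti or Tv is determined solely by its encoding label; per-nucleotide
allele identities are not modeled.

The encoding probabilities γ0, γ1, γ2 (PuPu, PuPy, PyPy) satisfy
γ1 = 1/(η+1) and γ0 + γ2 = η/(η+1) for Ti/Tv ratio η (≈ 2 in human data).
Every moment formula depends on the γ's only through γ1 and γ0+γ2, so the
split of the transition mass between PuPu and PyPy is arbitrary; the
sampler draws γ0 uniform on (ε, η/(η+1) − ε) and theoretical curves use the
even split. All pmfs and closed-form moments are verified against an
exhaustive 3×3 genotype-pair enumeration to 1e-12 across a MAF grid.

The mean TiTv distance as a function of a common MAF f̄ is maximized at
f̄ = 0.5 and symmetric about it (f ↔ 1−f leaves both polynomial building
blocks invariant), and decreases in η at fixed f̄.

Distance variances use the independent-loci sums; deviations under linkage
or imposed correlation are measured by the validation module, not corrected
analytically.

## Correlation-stack (ROI) metric

For correlation data derived from time series, each subject contributes a
p×p correlation matrix. Off-diagonals are Fisher r-to-z transformed,
stacked into a p(p−1) × m matrix whose ROI-k block holds that ROI's
correlations with every other ROI (each unordered pair therefore appears
twice per column), and columns are standardized to zero mean, unit
variance. The ROI diff is the L1 difference over an ROI's block; the
distance is the sum over ROIs, i.e. Manhattan on the stack columns.

Since stack entries are approximately standard normal, the mean is
2p(p−1)/√π. The entrywise-independence variance 2(π−2)p(p−1)/π
underestimates the within-dataset sample variance of stack distances: the
pair duplication and the sharing of each ROI across p−1 rows induce
cross-covariances. Empirically the discrepancy grows like β1·p² + β0·p with
fitted β1 ≈ 0.08; folding a proportional correction into the formula gives
the default corrected variance 9p(π−2)(p−1)/(4π), whose correction term
corresponds algebraically to β1 = −β0 = (π−2)/(4π) ≈ 0.0908. The package
reproduces the simulation fit (`fit_variance_correction`) rather than
explaining the ≈ 0.08 vs 0.0908 gap; note the *marginal* variance of a
single stack distance is roughly twice the independence formula (duplicated
pairs are perfectly dependent), so the ≈ 1.12 ratio is specifically a
property of the within-dataset sample variance over the m(m−1)/2 distances,
which is the statistic both the correction and its fit use. The fitted β0
is small but not exactly −β1 under this generator; only β1 is treated as
the meaningful coefficient.

The single-ROI diff keeps the independence variance 2(π−2)(p−1)/π (a fixed
ROI sees negligible cross-covariance; the alternative scaled-down corrected
form is behind a flag and is farther from simulation). The range-normalized
stack metric applies the normal extreme-value formulas with effective
sample size m(p−1) — the number of values in an ROI's block, which is the
sample its range is taken over.

## Synthetic data: what is and is not emulated

* `gen_continuous`, `gen_gwas`, `gen_fmri_stack` implement the null models
  above exactly; every generator is a deterministic function of
  (seed, parameters).
* Null stacks are built from independent Gaussian time series of length
  T = 4p per subject (T configurable). T controls the pre-standardization
  variance of the Fisher-z entries (≈ 1/(T−3)); after column
  standardization its main residual effect is on finite-T dependence among
  correlations sharing an ROI. No generative process for "random" stacks is
  canonical; this one yields the approximately-normal margins the
  derivations assume.
* Correlated variants impose a target correlation R via X·U with U the
  upper-triangular Cholesky factor (UᵀU = R). Targets come from an
  Erdős–Rényi graph: hi on edges, lo elsewhere. Dense high-correlation
  targets are indefinite; they are repaired by eigenvalue clipping at 1e-6
  and unit-diagonal renormalization, which *attenuates* the requested
  correlations — so the achieved mean absolute pairwise correlation
  (r̄_abs) is always measured on the output, and graph density is the dial
  used to sweep r̄_abs levels rather than a calibrated mapping.
* Correlated genotypes: correlated Gaussians → Φ → inverse Binomial(2, f_a)
  cdf. Margins are exact; Pearson correlation survives only approximately
  (as rank correlation through a discretization).
* The feature-selection benchmark is a deliberately simple surrogate for
  interaction-network simulators: m=100 instances (50/50 case-control),
  p=1000 attributes, 100 functional by default — main effects as
  between-group mean shifts (default 0.8 SD), interactions as
  case-only equicorrelation (default 0.75) with zero marginal shift. It
  does not model LD structure, population stratification, scanner noise,
  or realistic interaction-network topologies.

Because all generators are null or stylized, passing tests demonstrate the
correctness of the formulas under their stated assumptions — not
performance on real data, where correlation between attributes (main
effects, interactions) skews distance distributions positively and inflates
variances while leaving means roughly intact (the package demonstrates this
direction on its own correlated generators).

## Neighborhoods

The MultiSURF radius is R_i = mean_j(D_ij) − α·SD_j(D_ij) with α = 0.5,
row statistics excluding the self-distance, sample SD (ddof=1). Under
approximate normality of distances, the inclusion probability for such a
radius is Φ(−α) ≈ 0.309 at α = 1/2, and simulated radius neighborhoods on
null data match (m−1)·Φ(−α) closely — this is what `radius_inclusion_prob`
returns and what the radius-neighborhood test asserts.

The published informed-k anchor, however, is q_{1/2} ≈ 0.154 with
k̄ = ⌊0.154(m−1)⌋ = 15 at m = 100 — consistent with the empirical
MultiSURF-equivalent k = ⌊m/6⌋ = 16 but about half of Φ(−1/2)·(m−1).
`informed_k` follows the published anchor, implementing
q_α = (1 − erf(α√2))/2 = Φ(−2α), which reproduces ⌊(m−1)q_{1/2}⌋ = 15 and
q_0 = 1/2. The factor-of-two tension between the direct probability and the
published evaluation is documented here and left unresolved; both forms are
exposed so users can pick deliberately.

The Relief scorer uses range-normalized diffs (the Relief convention)
regardless of the metric used to find neighbors, averages
(miss diffs − hit diffs) per instance and then over instances, and breaks
distance ties by ascending index for determinism.

## Numerical choices

* Quadrature: `scipy.integrate.quad`, absolute tolerance 1e-10, limit 200;
  infinite domains via the library's standard transformation. The numeric
  projection-density path raises if the error estimate is not far below the
  value.
* Dense m×m distance matrices (scipy `pdist`), double precision, no
  rounding; intended for m up to a few thousand, no sparse or metric-tree
  path.
* Degenerate attributes (zero range) under normalization raise by default;
  a "drop" policy removes them with a warning. The TiTv distance is
  computed vectorized as Σ|Δ|/2 − (1/4)·#{mismatching Ti loci}, which is
  exactly the diff table.
* Shapiro-Wilk normality screens subsample to 5000 distances with a fixed
  seed (the test statistic degrades above its size cap).
* Internal indexing is 0-based half-open everywhere; the 1-based inclusive
  block formulas start_k = (k−1)(p−1)+1, end_k = k(p−1) are preserved in
  `roi_block_indices`' public contract.
* Fisher z clamps |r| at 0.999999; stacks exclude diagonals so this only
  fires on degenerate inputs.

## Problem sizes used in the test suite

Simulation-backed tests use the regimes the formulas target where that is
cheap (m=100 with p up to 5000 for the Manhattan theory-vs-simulation grid;
m=p=500 for the normalized-Euclidean limit; p up to 100 with 20 replicates
for the stack variance fit) and smaller replicate counts or dimensions for
auxiliary sanity checks (noted per test). Monte-Carlo comparisons use
3-standard-error bands over replicates unless a wider tolerance is stated
inline.

## Known limitations

* All closed forms assume independent attributes and instances; under
  correlation only the means remain accurate.
* The TiTv distance SD and the stack-metric variance are approximations
  even under the null (the former's cross-term cancellation is verified
  numerically rather than re-derived; the latter's correction is an
  empirical fit).
* Non-integer q is not supported; the stack metric is q = 1 only.
* No missing-genotype handling, VCF/PLINK parsing, or neuroimaging-format
  input: genotype matrices and correlation matrices are the entry points.
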