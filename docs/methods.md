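# Methods

## Model and estimator

`ebprs` treats each SNP's association z-score as a noisy observation of a
standardized effect, `Zᵢ | μᵢ ~ N(μᵢ, 1)` with `μᵢ = βᵢ / se(β̂ᵢ)`, where
`βᵢ` is the allelic log-odds-ratio and the null-variance standard error is
`se(β̂ᵢ) = sqrt(2 / (Nₑ fᵢ (1 − fᵢ)))` with `Nₑ = 4n₀n₁/(n₀+n₁)` and `fᵢ` the
pooled reference-allele frequency. The pooled frequency is used because it
makes `z = β̂/se` coincide with the standard allelic test; which frequency
enters the variance is a genuinely open convention, and control-only
frequencies would change `se` by O(β̂) terms only.

The prior on standardized effects is a spike-and-slab Gaussian mixture,
`μ ~ π₀δ₀ + Σⱼ πⱼ N(0, Nₑσⱼ²)`. Scaling the slab variances by `Nₑ` makes the
`σⱼ²` portable across studies of different size: the marginal z-variance of
component j is `vⱼ = 1 + Nₑσⱼ²`, and refitting the same z-vector at a
different nominal `Nₑ` changes only the reported `σⱼ²`, exactly inversely —
a property the test suite asserts at 1% and that holds to machine precision.

The PRS weight is the posterior-mean log-OR
`E(βᵢ|zᵢ) = Σⱼ ltdrᵢⱼ · [Nₑσⱼ²/(1+Nₑσⱼ²)] · β̂ᵢ`, the Bayes-risk-minimizing
estimate under the fitted prior. It is validated against an adaptive-
quadrature evaluation of the mixture posterior to 1e-6. Classification uses
the zero-one-loss-optimal threshold
`−log(κ/(1−κ)) − 2Σᵢ log((1−fᵢ₁)/(1−fᵢ₀))`; on enumerable instances (≤5
SNPs, known frequencies) no grid perturbation of this threshold attains lower
exact risk.

## Fitting

Parameters are fitted by MAP-EM on the (K+1)-component z mixture with the
null component's variance fixed at 1. A Dirichlet-style pseudo-count of `α`
extra null observations enters the M-step (`π₀ ∝ N₀ + α`), encoding that the
null proportion dominates in GWAS; a literal Dirichlet MAP with zero
concentrations on the slab components would be degenerate. Defaults:

* `K = 3` non-null components. More components add flexibility but past a
  point only split existing components without predictive benefit.
* `α = m/20` as the preliminary pseudo-count. Optionally, `select_alpha`
  simulates parametric-bootstrap z-vectors from the preliminary fit, refits
  every grid value (`m/100, m/50, m/20, m/10, m/5` by default, 20
  replicates), and picks the `α` minimizing the mean relative error of
  `(π, σ²)` against the preliminary values. Both the proportions and the
  variances are refit in each bootstrap fit. The error norm (mean relative
  error over all parameters) is a documented choice; no canonical definition
  exists.
* Initialization: `π₀ = 0.95`, remaining mass split equally; `vⱼ`
  geometrically spaced between 1.5 and `max(4, q₀.₉₉(z²))`. Deterministic,
  covers the observed z² range.
* Convergence: relative penalized log-likelihood change `< 1e-6`, cap of
  10,000 iterations; variance floor `vⱼ ≥ 1 + 1e-8` keeps `σⱼ² > 0`.
  Components are sorted by `σ²` after fitting to resolve label switching.
* The penalized log-likelihood is non-decreasing by construction (MAP-EM);
  the implementation asserts this every iteration and exposes the path.

The pseudo-count is a deliberate bias toward the null: with `α = m/20` the
MAP `π̂₀` overshoots a true `π₀ = 0.9` by ~0.06 and inflates the slab
variance. Parameter-*recovery* experiments therefore use the plain maximum-
likelihood fit (`α = 0`) with a tight tolerance (`1e-9`), which recovers
`π₀` to well under 0.02 and the slab variance to a few percent at
m = 50,000. Prediction always uses the MAP path, where the extra shrinkage
is the point.

## Comparators

All comparators emit the same `(snp_id, weight)` table, so scoring and
evaluation are method-agnostic.

* **Unadjusted PRS**: observed `β̂`.
* **P+T**: greedy clumping retains the most significant SNP and discards
  remaining SNPs with dosage `r² > 0.1`; p-value ties break lexicographically
  on snp_id so runs are deterministic. The cutoff grid
  `{1, 5e-1, …, 5e-6}` is tuned on labelled data, ties toward the more
  inclusive cutoff.
* **LDpred-inf**: ridge posterior mean `(m/(nh²)·I + D)⁻¹ β̂_std` on the
  standardized-genotype scale, solved as a positive-definite system. When
  `h²` is not supplied it is estimated from the aggregate z² inflation
  `m(mean(z²)−1)/n`, clipped to [0.01, 0.9], keeping the comparator
  self-contained. Weights are rescaled by per-SNP dosage standard deviations
  at scoring time (the evaluation metrics are affine-invariant).
* **So & Sham**: Tweedie-corrected standardized effects
  `E(μ|z) = z + f′(z)/f(z)` with `f` estimated by Lindsey's method —
  histogram counts (120 equal-width bins over the data range padded 10%)
  fitted by a Poisson log-linear model with a degree-7 polynomial basis.
  The corrected effect is converted to per-SNP observed-scale variance
  explained `4·E(μ|z)²/Nₑ`, transformed to the liability scale with
  prevalence κ and study case fraction P via
  `κ²(1−κ)² / (φ(Φ⁻¹(1−κ))² P(1−P))`, and the weight is
  `ltdr_total · sqrt(V_liab) · sign(z)`. The explained-liability functional
  is a reconstruction of the method's published structure (ltdr × square
  root of explained liability); the ltdr comes from the parametric mixture
  fit for comparability across methods.
* **Mak et al.**: `ltdr_total · β̂`, with the same parametric ltdr.

A consequence of sharing the parametric ltdr: when the generative slab has a
single component, Mak's weights are proportional to the EB posterior means
(the per-component shrink factor is then constant), so the two methods give
identical r²/AUC up to fitting noise in that regime. They separate when the
effect-size distribution genuinely has multiple scales.

Nonparametric accuracy of the Tweedie step is limited in the sparse
`|z| ≈ 3–4` transition region: against the closed-form mixture posterior
mean the estimate is uniformly accurate where data are dense (`|z| ≤ 2.5`)
and its maximum error grows to ~0.1–0.3 in the transition zone regardless of
basis (polynomials degree 5–15, B-splines, natural splines) or sample size
up to 10⁶ — an inherent bias/variance limit of density-derivative
estimation, not a fitting defect. The tests bound the dense-region error at
0.15 and the RMS over [−4, 4] at 0.1.

## Simulation designs

**Independent SNPs.** Reference-allele frequencies are drawn from
U(0.05, 0.95) or a scaled Beta(a, b) on (0.05, 0.95) (default a = b = 0.8,
mimicking the excess of low-MAF variants). A fraction (default 10%) of SNPs
is causal with `μ ~ N(0, c·Nₑ)`, default `c = 0.001`; `β = μ·se`. Sampling
is retrospective — genotype given status — with `X|y=0 ~ Bin(2, f₀)` and
`X|y=1 ~ Bin(2, f₁)` where `logit f₁ = logit f₀ + β`; the population
frequency is identified with the control frequency under the default 1%
prevalence (low-prevalence approximation). Prevalence enters only the
decision threshold and liability conversion, as in a retrospective design.
Defaults: m = 10,000 SNPs, balanced training cohort, a 100 + 100 test set.
Optional train/test divergence redraws test frequencies from a different
distribution and/or shifts effects by `N(0, 0.0005·Nₑ)` on the standardized
scale (converted per SNP through its se).

**Phenotypes on genotypes.** For benchmarking on an existing genotype
matrix, a sparse causal set (default 0.1%) receives `β ~ N(0, 0.04)` and
`y ~ Bernoulli(expit(Σ βᵢxᵢ + b))`, with the intercept b solved by bisection
to hit a target case fraction (default 0.5). The realized observed-scale
heritability diagnostic `var(g)/(var(g)+π²/3)` is reported.

**Correlated genotypes.** Since real LD panels are access-restricted, a
synthetic stand-in generates exchangeable-correlation blocks via a Gaussian
copula on the two allele draws (block size and ρ configurable). This
exercises clumping and LDpred-inf but does not reproduce realistic LD decay,
allele-frequency–LD coupling, or long-range structure; benchmark results on
it say nothing about fine-mapping-grade LD handling.

What passing these simulations shows — and does not. The generators match
the modeled sampling process exactly (binomial genotypes, independent SNPs,
logistic phenotypes), so they validate the estimator math, the method
ordering under the modeled conditions, and the plumbing. Real data add LD,
stratification, imputation error, case-control ascertainment quirks and
cross-population shifts that these tests do not probe.

## Numerical and interface choices

* Missing dosages are excluded per SNP from frequency computation and
  mean-imputed at scoring time (deterministic, standard PRS practice).
* Zero allele-count cells get a Haldane–Anscombe +0.5 correction per cell,
  flagged per SNP, keeping `β̂` finite without dropping SNPs.
* Harmonization matches SNPs by identifier; dosages whose declared reference
  allele equals the training alternate allele are recoded `2 − x`;
  strand-ambiguous palindromic SNPs (A/T, C/G) are dropped by default with
  an override.
* When classification needs per-group frequencies that summary statistics
  lack, `(f₀, f₁)` are reconstructed from the pooled frequency, `β̂` and the
  case fraction by a monotone root solve in `logit f₀`.
* All stochastic routines take explicit seeds; identical seeds give
  byte-identical output files. Scores are reported raw (r² and AUC are
  affine-invariant); a z-standardization flag exists for plotting.
* ΔAUC comparison uses a stratified paired bootstrap with a normal
  approximation on the replicates (percentile CI also reported);
  cross-validation folds are stratified by phenotype so small cohorts cannot
  produce single-class folds.
* Problem sizes in the test and acceptance runs (m = 10,000 benchmark with
  10 replicates, m = 50,000 recovery fits, 10⁵ null z for the Tweedie
  check) are the package's reference experiment sizes; the benchmark uses
  the preliminary `α = m/20` rather than bootstrap α selection, which is the
  default training path.

## Known limitations

* The mixture prior is symmetric around zero and exchangeable across SNPs;
  no annotation or LD information enters the EB weights.
* LDpred with an MCMC point-normal prior is not implemented; the
  infinitesimal closed form is.
* Predictive r² is computed on the observed 0/1 scale, not the liability
  scale.
* The So-method explained-liability step is an interpretive reconstruction
  of the published principle; its nonparametric density derivative is
  tail-noisy as described above.
* PLINK I/O covers bed/bim/fam (SNP-major) and plain TSV; no VCF, dosage
  (BGEN) formats, imputation or liftover.
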