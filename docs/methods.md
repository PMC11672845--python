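# Methods

## The statistical model

All analyses are linear mixed models over one record per individual with
the overall mean as the sole fixed effect — the cohort this package
emulates is a single-hatch, single-sex, single-farm group of individually
fed broilers, so no other systematic effect is identifiable.  The random
structure is defined entirely by individual-by-individual similarity
kernels:

* the genomic relationship matrix **G** = ZZ′ / 2Σpᵢ(1−pᵢ), with
  Z the dosage matrix centred by twice the sample allele frequencies.
  Monomorphic markers contribute nothing and are excluded from the
  denominator.  E[diag G] = 1 under Hardy–Weinberg proportions, which the
  test suite checks on simulated cohorts (mean diagonal within [0.95, 1.05]).
* the microbial similarity matrix **O** = MM′/(m−1), where M is the
  rarefied ASV table after log₁₀(x+1), per-feature centring and scaling
  (SD with n−1), oriented samples × features so that O is an n×n
  covariance usable as a random-effect kernel.  With that scaling the mean
  diagonal is exactly m(n−1)/(n(m−1)), which a test asserts as an algebraic
  identity.

GBLUP uses G alone, MBLUP O alone, MGBLUP both.  The bivariate model
stacks two traits sharing G, with unstructured 2×2 genetic and residual
blocks; its covariance is K_u ⊗ G + K_e ⊗ I.

Derived parameters: h² = σ²ᵤ/(σ²ᵤ+σ²ₑ) and m² = σ²ₘ/(σ²ₘ+σ²ₑ) from the
single-kernel fits; h̄² and m̄² with denominator σ²ᵤ+σ²ₘ+σ²ₑ from the
joint fit; r_g = σ_u₁u₂/√(σ²_u₁σ²_u₂) from the bivariate fit.

## AI-REML

The REML log-likelihood −½[log|V| + log|X′V⁻¹X| + y′Py] is maximised by
average-information updates: score s_k = −½[tr(PK_k) − y′PK_kPy], AI
matrix A_ij = ½ y′PK_iPK_jPy, Newton step δ = A⁻¹s.  Numerical policy:

* **Starting values** — Var(y)/(#components+1) per component; the bivariate
  covariances start at 0.
* **Step control** — a trust region caps any component's proposed change at
  5× its scale (a near-singular AI matrix otherwise proposes steps of
  arbitrary magnitude); the step is then halved up to 30 times until the
  likelihood does not decrease.  If no AI step is acceptable, one EM-REML
  step (σ² ← σ² + 2σ⁴ s/n) is tried for the variance parameters, then a
  scaled-gradient step that can also move covariances.
* **Constraints** — variances are floored at 10⁻⁶·Var(y); the bivariate
  2×2 blocks are projected to the PSD cone (eigenvalue clip) after every
  proposal.  Components that sit on the floor with the score pushing them
  further down for two consecutive iterations are pinned and dropped from
  the AI system.
* **Convergence** — |Δ log-likelihood| < 10⁻⁸ between accepted iterations,
  or a stationary stall: if no feasible direction (AI, EM, gradient, each
  with 30 halvings) improves the likelihood by more than 10⁻¹², the point
  is a constrained optimum within numerical precision and is reported as
  converged.  This matters at the r_g = ±1 boundary, where the genetic
  block becomes singular: such boundary maxima are legitimate REML
  estimates, and treating them as failures would censor exactly the
  high-|r_g| replicates and bias recovery experiments downward.  Only
  exhausting `max_iter` (default 200) yields a non-converged fit, which
  carries no ratio estimates (rendered as "—" in reports).
* **Uncertainty** — the asymptotic covariance of the components is the
  inverse of the final AI matrix.  SEs of ratio parameters (h², m², h̄²,
  m̄², r_g) are Monte-Carlo: draw component vectors from N(θ̂, A⁻¹),
  truncate negative variance draws at 0, evaluate the ratio per draw,
  report the sample SD.  A delta-method closed form agrees within a few
  percent when the asymptotic covariance is small (tested); the Monte-Carlo
  route also behaves sensibly near boundaries where the delta method does
  not.

### Solving in the eigenbasis

Single-kernel and bivariate models are solved after rotating by the
eigenvectors of the (jittered) kernel: with G = EΛE′, the transform
y → E′y is orthogonal, leaves the REML likelihood unchanged, and makes V
diagonal (univariate) or block-diagonal in n independent 2×2 blocks
(bivariate).  Likelihood, score and AI evaluations are then O(n) instead
of O(n³), which is what makes 20-replicate recovery experiments at n = 400
run in seconds.  The dense-matrix path is kept for the two-kernel MGBLUP
fit (G and O share no eigenbasis) and doubles as the exactness oracle: a
test asserts dense and rotated likelihoods agree to 10⁻⁸ on both model
shapes.  Small diagonal jitter (10⁻⁸) is added to kernels only at
decomposition time, never stored.

## Phenotype derivation

From weekly body weight and feed intake (grams, weeks 4–10):

* ADG over an interval = (BW_end − BW_start)/(7·weeks); FCR = interval
  feed / interval gain, with non-positive gains set missing and logged.
* RFI is the residual of the OLS regression AFI = a + b·ADG + c·MBW^0.75,
  where AFI is total interval feed divided by interval days and MBW is the
  arithmetic mean of the weekly body weights inside the interval (the most
  literal reading of "average BW during the interval"; the alternative
  mean-of-weekly-FI definition is identical when weeks are complete).
* Outliers: each trait is screened once against mean ± 3.5 SD computed on
  the unscreened vector — a single pass, not iterated.  Traits are screened
  independently, so per-trait record counts differ.  The RFI regression is
  fitted on inputs that passed their own screens; its residuals are then
  screened themselves.
* All intervals are anchored at week 4 and named by end week (6, 9, 10);
  days per week fixed at 7.

## Quality control

**SNPs** — call rate ≥ 0.9, MAF ≥ 0.05, and a 1-df chi-square
Hardy–Weinberg test at p ≥ 10⁻⁸, applied jointly in one pass (hence
order-independent and idempotent).  The chi-square test is dependency-free
and at these thresholds and n ≈ 400 decides identically to an exact test
except at tiny expected counts.  Missing genotypes are then imputed by the
marker mean 2p̂ — an expectation imputation, sufficient because the GRM
needs unbiased dosages, not phased haplotypes.  Summary statistics:
MAF; per-site nucleotide diversity π = n_chr/(n_chr−1)·2p̂(1−p̂); LD decay
as composite genotypic r² (squared dosage correlation, the standard
unphased surrogate) binned by physical distance; classical MDS
(double-centring + eigendecomposition) on the 1−IBS distance,
IBS = mean(1 − |xᵢ−xⱼ|/2).

**ASV table** — samples with library size < mean − 3 SD removed (single
pass, strict inequality, so equal sizes remove nothing); features present
in fewer than ⌈0.10·n⌉ samples removed ("less than 10%" is strict, so a
feature in exactly 10% stays); rarefaction to the smallest remaining
library by multivariate-hypergeometric subsampling (without replacement,
seeded, column sums exactly equal to depth); then log₁₀(x+1) with
per-feature centring/scaling.  Alpha diversity (observed features, Chao1,
inverse Simpson, Shannon, Camargo evenness) is computed on the rarefied
table by default; the pre-rarefaction route is available.  Chao1 uses the
bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)) (no division by zero at
F₂ = 0); the classic F₁²/2F₂ variant can be selected.  Shannon uses the
natural log by default with a configurable base.  The n−1 scaling
convention affects O only by a scalar absorbed into σ²ₘ.

## Synthetic cohorts

The generator reproduces the study conditions at desk scale — 400
individuals, 2,000 SNPs, 300 ASVs by default (marker count shrunk from
~48K; REML accuracy depends on markers only through the precision of G) —
and controls the ground truth of every estimand:

* **Genotypes** — two haplotypes per individual, each a latent AR(1)
  Gaussian process across markers (lag-one correlation `ld_rho`, default
  0.95 at 2.5 Kb spacing) thresholded at the allele-frequency quantile
  (MAF ~ U(0.05, 0.5)).  Marginally each marker is in Hardy–Weinberg
  proportions; adjacent markers are in LD that decays geometrically, falling
  below r² = 0.1 within ~100 Kb at the defaults.  Thresholding attenuates
  the latent correlation, so realised genotype r² is lower than ld_rho².
* **ASV counts** — community log-abundance profile fixed at the quantiles
  of a lognormal whose SD is calibrated at generation time (bisection
  against probe draws) so the realised zero fraction tracks
  `sparsity_target` (default 0.5); per-sample lognormal perturbation
  (SD 1.0) and multinomial sampling at a library size ~ N(20000, 5000²)
  truncated at 100 reads.  Fixing the profile shape to quantiles rather
  than drawing it keeps realised sparsity within ~±0.01 across seeds at
  the default size.
* **Phenotypes** — y = μ + u + m + e with u, m drawn through
  eigendecomposition square roots of G and O (negative eigenvalues clipped
  at zero: kernels are rank-deficient when markers < individuals, so
  Cholesky is unusable) and σ²ᵤ = h²·Var_total, σ²ₘ = m²·Var_total.  The
  bivariate draw uses a matrix-normal construction giving cov(vec U) =
  K ⊗ G exactly.  A guard warns when a kernel is numerically proportional
  to the identity (its component would be confounded with the residual).
* **Growth records** — logistic body-weight curves (asymptote 3,600 g,
  rate 0.064/day, inflection day 49.3 — chosen to hit the observed means of
  ~735 g at week 4, ~1,408 g at week 6 and ~2,845 g at week 10) with an
  individual asymptote whose variation (CV 0.12) has genetic fraction 0.15
  drawn from G; weekly feed intake a + b·ADG + c·MBW^0.75 + δ with
  a = −7.6 g/day, b = 0.5, c = 0.45, tuned so the derived FCR at six weeks
  averages ≈ 2.12; the intake deviation δ (SD 6 g/day, matching the
  observed RFI spread) has a controllable genetic fraction, so the true
  RFI heritability is known.

What the generator does **not** emulate: family/line structure (the cohort
is homogeneous, consistent with the absence of stratification in the
population this mirrors), genotyping error, compositional coupling between
the microbiome and the genome (O and G are independent under the null),
and any genuine microbiome→phenotype pathway beyond the linear kernel
term.  Passing recovery tests therefore demonstrate estimator correctness
under the assumed model, not robustness to model misspecification.

## Recovery experiments and their precision

`scripts/acceptance.py` (and the mirror tests) simulate 20 replicates per
target with the true parameter set to the published point estimate for
this population, and compare the mean estimate with truth within two
Monte-Carlo SEs of the mean.  At n = 400 the per-replicate SD of ĥ² is
≈ 0.05–0.07, so 20-replicate means resolve ≈ ±0.03.  Bivariate r̂_g is
much noisier when both heritabilities are low (per-replicate SD ≈ 0.7 for
the h² ≈ 0.16/0.11, r_g ≈ 0.3 regime, with pile-up at ±1): that imprecision
is a property of the design, mirrored in the large published SEs for the
same cells, and the acceptance tolerance is the replicate-based SE for
exactly that reason.  Problem sizes (400×2,000, 20 replicates) were chosen
as the smallest design that keeps those Monte-Carlo errors informative.

## Known limitations

* Only biallelic SNPs and GT-field VCFs are read; no phasing, pedigree or
  sex-chromosome handling.
* The bivariate model handles two traits; larger multi-trait systems and
  pedigree (A-matrix) models are out of scope.
* Microbial kernels are covariance-based only; distance-based alternatives
  (Bray–Curtis, UniFrac) are not provided.
* Complete-case analysis per fit; no phenotype imputation.
* The AI-matrix inverse underestimates uncertainty for components at or
  near boundaries; the Monte-Carlo ratio SEs inherit that.
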