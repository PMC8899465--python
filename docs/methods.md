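# Methods

## Model

For *n* subjects, a gene region holding *L* SNPs on the normalized position
interval [0, 1] and a trait measured on a shared grid of Q+1 time points
(also normalized to [0, 1] internally; raw time labels are retained for
reporting), the model is

    y_i(t) = mu(t) + ∫ x_i(s) β(s, t) ds + ε_i(t).

Genotypes are additively coded (0/1/2 copies of the minor-tagged allele).
Both sides are centered across subjects, which removes mu(t) from the
estimation problem; the per-time phenotype mean is kept as the estimate of
mu(t) for prediction.

**Genotype function.**  x_i(s) is taken to be a step function: the value
x_il holds from the midpoint between SNP l−1 and l to the midpoint between
l and l+1 (boundary intervals clipped to the domain).  This is the
deterministic, interpolation-free reading of "marker information as a
continuum variable"; the inner products ∫ x_i(s) φ_j(s) ds then reduce to
exact integrals of B-splines over intervals (computed analytically).  A
per-SNP point-mass quadrature is available as an option
(`genotype_function="point"`).

**Surface basis.**  β(s, t) = Σ_jk b_jk φ_j(s) φ_k(t) with marginal cubic
B-spline bases (order 4), default 15 functions per direction, equally
spaced interior knots and full-multiplicity boundary knots.  The
coefficient count is K = m_s·m_t = 225 by default.

**Estimation.**  Stacking subjects (subject-major, time-minor; the order is
fixed so coefficient vectors are bit-reproducible), b solves

    (Ψ'Ψ + λ1 R1 + λ2 R2) b = Ψ'y,

with R1 = P_s ⊗ M_t and R2 = M_s ⊗ P_t, P the marginal second-derivative
penalty ∫φ''φ''ᵀ and M the marginal Gram matrix ∫φφᵀ, both exact via
per-span Gauss–Legendre quadrature.  The solver is a Cholesky solve with a
single jitter retry (1e-10·trace/K) and an explicit singularity error
naming the remedy; the unpenalized path (λ1 = λ2 = 0) additionally rejects
rank-deficient systems rather than returning one of infinitely many
solutions.

**Smoothing selection.**  Leave-one-*subject*-out cross-validation (all
Q+1 rows of a subject leave together, since rows within a subject are
correlated) over the Cartesian product of the grid {1e2, …, 1e6} for
(λ1, λ2), computed exactly through the block hat-matrix identity
e_loo,i = (I − H_ii)⁻¹ e_i; ties go to the smoother pair (larger λ1+λ2).
The experiment runners default to a "pilot" policy — CV on the first
replicate, λ then held fixed across replicates — recorded in the result
metadata; per-replicate CV is available.

## Hypothesis test

H0: β(s, t) ≡ 0 is examined per time point:

    F(t) = [(RSS0(t) − RSS1(t))/K] / [RSS1(t)/(n − K − 1)],

with RSS0 the centered-phenotype sum of squares and RSS1 the model residual
sum of squares at that time, referred to F(K, n−K−1).  Two conventions
matter:

* **K in the degrees of freedom** is the *nominal* number of bivariate
  basis functions, `k_test` (default 15), not the 225 estimated
  coefficients.  The F reference with K = 225 would make the per-time test
  blind (power ≈ 0 at realistic samples) because the penalized fit has far
  fewer effective degrees of freedom than coefficients; with K = 15 the
  test shows the intended behaviour — conservative under the null, high
  power under strong effects.  `k_test` is exposed on the model.
* The reference distribution ignores the within-subject time correlation
  ρ; together with the penalization this makes the per-time test
  *conservative* (null rejection rates well below nominal).  This is a
  property of the method, not corrected here.

When the fit at some time is worse than the null (possible because the
surface is smoothed jointly across times), F is negative and p = 1 — this
is exactly what happens at gene-off time points when the surrounding times
carry strong effects, and it is why the test never flags switched-off
times.

A pooled "global" statistic (RSS summed over all times, same df) is
reported as a clearly labelled aggregate of the per-time quantities.

In the special case of an unpenalized fit whose smoothed design has rank
equal to `k_test` and independent errors, the per-time statistic is exactly
F(k_test, n−k_test−1); the test suite verifies the resulting uniformity of
null p-values.

## Comparator: single-time smoothed FLM

For each time point separately, the centered phenotype vector is regressed
on Z = X_c W, the B-spline representation of the genotype signal, with an
optional second-derivative ridge penalty chosen by leave-one-out CV.  The
F test uses df1 = rank(Z): with the default λ = 0 the statistic is then
*exactly* F-distributed under the null, which reproduces the comparator's
near-nominal behaviour (it rejects at ≈ α even where the gene is switched
off — the contrast the longitudinal test is built to expose).  With fewer
SNPs than basis functions, using the nominal basis size in the df instead
would silently deflate the rejection rate several-fold.  A nonzero ridge
grid makes the comparator conservative; it is off by default.

## Evaluation metrics

On the discrete SNP-by-time grid, with S0/S1 the null/causal SNP sets and
Γ the time grid:

    ISE0 = Σ_{S0×Γ} (β̂ − β)² / [(|Γ|−1)(|S0|−1)]
    ISE1 = Σ_{S1×Γ} (β̂ − β)² / [(|Γ|−1)(|S1|−1)]
    PMSE = Σ_{test×Γ} (y − ŷ)² / (N−1)

The (·−1) denominators are deliberate conventions of these definitions and
are kept even though they are not plain means.  When only one causal SNP exists the
ISE1 denominator degenerates; `metric_report` then divides by (|Γ|−1)
alone.  PMSE uses a fresh seeded 80/20 subject split per replicate (the
split ratio is configurable; no canonical choice exists for it).

## Synthetic data

The generators emulate the simulation designs used to characterize the
method:

* **MAF classes**: rare U(0.0005, 0.01), low-frequency U(0.01, 0.05),
  common U(0.05, 0.5); mixtures draw each SNP's class (20/80 or 80/20
  common/rare).  The drawn (population) MAF is stored alongside the sample
  MAF and is used for effect sizes, so η(s) does not inherit genotype
  sampling noise (configurable).
* **Linkage equilibrium**: genotypes Binomial(2, MAF) independent across
  SNPs and subjects; positions equally spaced in the region.
* **Linkage disequilibrium**: two haplotypes per subject from a
  first-order Gaussian-copula chain.  Each adjacent pair targets an
  allelic correlation r = +√(r²) with r² ~ U(lo, hi) (study bands
  (0.01, 0.25) and (0.25, 0.64)); r is converted to a latent Gaussian
  correlation by bisection on the bivariate-normal orthant probability
  (Owen's-T closed form).  Draws beyond the Fréchet feasibility bound for
  the current MAF pair resample the downstream MAF (logged), with a final
  clip if resampling keeps failing.  Only positive-sign LD is generated,
  and only adjacent-pair correlation is targeted; real LD blocks are
  denser and signed, so LD results here speak to the adjacent-chain
  topology only.
* **Phenotypes**: y = mu + Σ_{l∈A} x_l · sign_l · η_l · θ(t) + ε with
  μ = 1, η(s) = ln(c)|log10 MAF_s|/2, θ(t) = 2+2sin(πt/12) (case 1) or
  2+2sin(πt/2) (case 2), θ evaluated at the *raw* time labels 1..9 (only
  that scale puts the case-2 zeros at t = 3 and t = 7); ε multivariate
  normal, unit variance, pairwise correlation ρ = 0.5 under compound
  symmetry (AR(1) optional — the single-ρ phrasing is ambiguous, and
  compound symmetry is the literal reading).  The causal set A is a
  uniform random subset of size max(1, round(causal_prop·L)) excluding
  monomorphic SNPs; round(neg_prop·|A|) effects are flipped negative.

**SNP density.**  The test region is 1 kb with L = 10 SNPs by default.
Density is a free design parameter of the study conditions: with ~15
marginal basis functions the genotype smoother resolves individual loci
only up to L ≈ m_s, and the characteristic behaviour of this class of
tests (near-complete power at n = 2000 with a lone causal variant, and
single-time comparators matching the longitudinal test's power) lives in
that regime.  At L = 100 per kb the basis captures ~15% of a lone SNP's
signal and power collapses to ~0.3 — a different regime entirely.  Ten
variants per kb is also a realistic array-era density.  L is configurable
everywhere.

What passing the simulation suite does *not* show: robustness to
population structure, covariates, missing visits, signed/dense LD,
variant-weighting schemes, or non-Gaussian traits — none of which the
generator emulates.

## Numerical choices

* Domains normalized to unit intervals (removes the scale dependence of the
  λ grid); positions are 1-based bp on input, mapped affinely.
* Exact basis integrals (Gauss–Legendre per knot span; antiderivatives for
  step-interval weights), no numeric quadrature error in the design or the
  penalties.
* All generators and runners are bit-reproducible: every replicate's seed
  is spawned from the master seed; identical invocations produce identical
  outputs.
* Degenerate inputs produce explicit errors: fewer than 2 subjects
  (centering), n ≤ K+1 (test df), |S| < 2 (ISE denominators), non-PSD
  compound symmetry (ρ ≤ −1/Q), empty regions, singular unpenalized
  systems.

## Known limitations

* The per-time F test is conservative by construction (penalization +
  ignored time correlation); it trades type-I inflation for a lower null
  rejection rate than nominal.
* The LD generator's adjacent-pair chain understates long-range LD.
* No covariates, random subject effects or population-structure
  correction; the model assumes a homogeneous population.
* Replicate counts in the shipped runners (200 power / 500 null) carry
  binomial Monte-Carlo error √(p(1−p)/reps); comparisons in the test suite
  use ~3·SE bands.
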