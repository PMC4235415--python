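# Methods

## Model

For a quantitative trait measured on pedigreed families the package fits the
additive polygenic ("animal") model

    y = Xβ + ρ + ε,   ρ ~ N(0, σ²g A),   ε ~ N(0, σ²e I_n),

with A = 2K the additive genetic relationship matrix from the pedigree.
Since pedigrees of distinct families share no ancestors, A is
block-diagonal when individuals are ordered family-contiguously, and the
phenotypic covariance is Var(y) = σ²g A + σ²e I.  Narrow-sense heritability
is h² = σ²g/(σ²g + σ²e).

All inference routes use the same reparameterization: each family block is
factored by a symmetric eigendecomposition A_f = U_f S_f U_fᵀ (identical to
the SVD for a symmetric PSD matrix, and numerically more robust), the
loading matrix is G_f = U_f S_f^{1/2}, and the model is rewritten as
y = Xβ + Gu + ε with u ~ N(0, σ²g I) independent.  The factorization is done
once, per family (cost Σ n_f³ rather than n³); only the identity
G_f G_fᵀ = A_f is contractual — eigenvector order and sign are not.
Eigenvalues in [−10⁻⁸, 0) are treated as floating-point noise and clamped to
zero; anything below −10⁻⁸ is an error, because a pedigree-derived A is
exactly PSD.

## Kinship

Kinship is computed by the classic tabular recursion over a topologically
sorted pedigree: founders are unrelated and non-inbred (φ_ii = ½), and for
individual i with parents f, m: φ_ii = ½(1 + φ_fm), φ_ij = ½(φ_fj + φ_mj)
for any j listed before i.  The numeric kernel refuses unsorted input rather
than silently re-sorting.  Sex codes are carried but unused (autosomal
model).  Married-in spouses without recorded parents are founders with zero
kinship to everyone but their descendants.  A gene-dropping Monte Carlo
estimator (unique founder alleles, random transmissions, IBD counted over
the four allele comparisons per pair) is included as an independent oracle;
the recursion is validated against it in the test suite.

Pedigrees may contain *phantom* connecting ancestors (`sampled=False`),
e.g. the ungenotyped grandparents that make two trio-parents full siblings.
Phantoms participate in the recursion and are then dropped; because the
recursion is exact this equals taking the corresponding submatrix of the
full-kinship matrix.

## Gibbs sampler (Gaussian trait)

Priors follow common BUGS practice: β_j ~ N(0, precision 0.001),
τ_e = 1/σ²e ~ Gamma(1, 1), τ_g = 1/σ²g ~ Gamma(1, 1) (shape, rate).  All
full conditionals are conjugate; the fixed cycle β → u → τ_e → τ_g is

* β | · — multivariate normal, precision τ_e XᵀX + 0.001·I;
* u_f | · — per family, precision τ_e G_fᵀG_f + τ_g I (families of equal
  block size are updated in one batched Cholesky call);
* τ_e | · — Gamma(1 + n/2, 1 + RSS/2), RSS = ‖y − Xβ − Gu‖²;
* τ_g | · — Gamma(1 + n/2, 1 + uᵀu/2).

Defaults are 11,000 iterations with 1,000 burn-in and no thinning, a single
chain, initialization at the OLS β with u = 0 and unit precisions.  Draws
are bit-reproducible given the seed.  Point estimate = posterior mean,
SE = posterior SD, 95% CI = equal-tailed percentiles; the per-draw identity
h² = σ²g/(σ²g+σ²e) holds exactly by construction.

## Bernoulli-logit extension

For a binary trait, y_j | u ~ Bernoulli(expit(x_jᵀβ + (Gu)_j)) with the same
priors on β and τ_g; the dispersion is fixed at 1 and there is no residual
variance.  The sampler is adaptive random-walk Metropolis-within-Gibbs:

* β moves in a joint random-walk step whose proposal covariance is the
  ordinary logistic-MLE covariance (scale adapted around 2.38/√p); three
  proposals per sweep, since each costs only O(n);
* u is updated componentwise within family blocks, vectorized across
  families of equal size;
* τ_g alternates a conjugate Gamma draw (centered step) with an interwoven
  non-centered move: holding the whitened effects u·√τ_g fixed, τ_g is
  proposed on the log scale and u and the linear predictor are rescaled
  deterministically.  Without this joint move the strong u–τ_g coupling
  makes σ²g mix far too slowly in logit models; with it the chain explores
  the full (heavy-tailed) σ²g posterior.

Proposal scales adapt toward 20–50% acceptance during burn-in only and are
frozen afterwards, so the retained draws come from a fixed-kernel chain.
The chain starts at the logistic MLE of β (zeros, with a warning, under
separation), which markedly shortens burn-in.

Identification caveat: with one random effect per individual, σ²g in the
logit model is informed only through within-family covariance; in small
samples of small families its posterior is heavy-tailed (the Gamma(1,1)
precision prior implies an infinite-mean inverse-gamma on σ²g).  Fixed
effects remain well calibrated, which is what the coverage test checks; a
liability-scale heritability is deliberately not reported.

## REML reference

The frequentist cross-check rotates each block by the eigenvectors of A_f,
making the covariance diagonal: Var(y*_i) = σ²e(1 + γ d_i) with
γ = σ²g/σ²e.  β then has a weighted-least-squares closed form, σ²e profiles
out analytically, and the (restricted) likelihood is maximized over
log γ ∈ [−10, 10] by bounded scalar search (tolerance 10⁻⁸ on log γ).
Solutions at the box edge are flagged as boundary (h² effectively 0 or 1);
A = I makes the two components confounded and is flagged non-identifiable.
SEs for β come from the inverse expected information at the optimum; no SEs
are produced for the variance components, mirroring classical mixed-model
printouts.  On small instances the rotated likelihood is verified against a
dense multivariate-normal evaluation to 10⁻⁸.

## Simulators

Four benchmark structures, each replicated `n_fam` times (defaults chosen to
give 400/600/1500/1400 sampled individuals at `n_fam = 100`):

* nuclear — couple + 2 offspring (4 sampled);
* two_trios — two parent-offspring trios whose non-spouse parents are full
  siblings via two phantom founder grandparents (6 sampled);
* asymmetric — the same linkage with 1 and 10 offspring (15 sampled),
  containing first-, second- and third-degree sampled pairs;
* combination — nuclear families plus extended two-trio families with 3
  offspring per trio (4 + 10 sampled).  The 3-offspring split is this
  package's choice of a simple composition matching the 1,400 total.

Gaussian traits are drawn exactly from the model covariance: per family,
V_f = σ²e I + 2σ²g K_f is eigendecomposed as U diag(d) Uᵀ and
y_f = X_fβ + U d^{1/2} z with z standard normal, so Var(y) = V by
construction (no approximation error for the covariance oracle tests to
absorb).  Binary traits draw u ~ N(0, σ²g I) and Bernoulli outcomes through
the logit link.  Where generating variances are needed and not otherwise
specified, the labeled defaults are (σ²g, σ²e) = (1, 1) and (2, 1) —
assumptions, chosen as round values bracketing heritabilities of 0.5 and
0.67.  Pedigree construction is deterministic; all trait randomness flows
from one seeded generator per call.

What the simulators do *not* emulate: ascertainment (families selected for a
trait), missing phenotypes, genotyping error, shared-environment variance,
and real covariate distributions (age is uniform, sex is assigned
deterministically by position).  Passing tests therefore demonstrate
correctness of the algebra and samplers under the stated model, not
robustness to those real-data features.

## Validation design and problem sizes

The test suite validates each layer against an independent route: kinship
vs gene dropping (10⁶ drops on the 15-member asymmetric family; 3 binomial
SEs), the loading identity GGᵀ = A (< 10⁻⁸ on every scenario), the Gibbs
posterior vs dense 2-D quadrature of the exact marginal posterior on an
8-individual toy (within 0.02, with β integrated analytically), Bayesian
posterior means vs REML on all four scenarios at 100 families (within
0.05), parameter recovery on two-trios (within 3 posterior SDs), and
frequentist 95%-CI coverage of the fixed effects in the logit model over
100 replicates of 200 nuclear families (binomial 3-SE tolerance; smaller
replicates leave the intercept posterior too skewed for nominal coverage,
a property of the design rather than the sampler).  These
sizes keep the full suite to a few minutes while leaving the Monte Carlo
tolerances meaningful.

## BUGS export

`io_bugs` writes the model in BUGS syntax — likelihood looping over families
and individuals with the offset-sliced `inprod(G[j, …], u[…])`, univariate
normal u, `dnorm(0, 0.001)` fixed-effect priors, `dgamma(1, 1)` precisions
and the derived `herit` node — plus R-dump data (`N`, `n.fam`, `offset`,
`y`, covariates, `G`) and initial values.  Matrices are serialized
column-major with an explicit `.Dim`, as the R-dump format defines, so the
parsed G reproduces A to the serialized precision (10 significant digits).
The exporter emits syntactically balanced code and rejects covariate names
that collide with reserved node names.

## Known limitations

* Kinship is dense O(n²) in the number of pedigree records; fine for
  thousands of individuals, not for biobank-scale cohorts.
* One genetic variance component; no dominance, X-linkage, GxE or
  marker-based (genomic) relationship matrices.
* Binary traits: logit link only; no liability-scale heritability.
* Single-chain defaults; users wanting formal convergence diagnostics can
  run multiple seeds and compare summaries.
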