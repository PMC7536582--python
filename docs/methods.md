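# Methods

## Model

`lemma-gxe` fits the whole-genome regression

    y = C α + X β + (E w ⊙ X) γ + ε,        ε ~ N(0, σe² I)

for a centered, scaled quantitative phenotype `y` (N samples), standardized
genotypes `X` (N × M), covariates `C` (N × L′) and standardized environmental
variables `E` (N × L). The length-N vector η = E w — the **environmental
score (ES)** — is a single learned linear combination of environments that
multiplies genotypes in interaction terms genome wide. Main effects β and
interaction effects γ carry independent two-component mixture-of-Gaussians
(slab + spike) priors whose variances are scaled by σe²; covariate effects
get a flat Gaussian prior N(0, σα²) with σα² = 100 held fixed; the weights w
get N(0, I_L).

The fixed unit prior variance on `w` is what identifies the scale split
between `w` and `γ` (any rescaling of one can be absorbed by the other in the
likelihood). A consequence worth knowing: rescaling the columns of `E` does
not rescale the fitted `ŵ` inversely — the posterior keeps ‖ŵ‖ near the
prior scale and pushes the change into the learned γ-variances. The *direction*
of the ES is invariant; its magnitude is a convention. Environments should be
standardized (the preprocessing pipeline and the ES itself assume this).

Every environmental column must also appear among the covariates, so the
interaction term is identified net of environmental main effects;
`align_and_complete_cases` enforces this, appending missing columns with a
warning.

## Variational inference

The posterior over θ = {α, β, γ, w} is approximated by a fully factorized
distribution (per covariate, per SNP-effect pair, per weight) optimized by
coordinate ascent on the evidence lower bound (ELBO). All updates are closed
form. For a SNP main effect the update is a two-component Bayesian regression
on the current residual: component k has posterior variance
σe²/(xᵀx + 1/σβ,k²) and mean xᵀr/(xᵀx + 1/σβ,k²), with slab responsibility
given by a softmax over component log-evidence. Interaction effects use the
same form with the expected squared interaction column Σᵢ E_q[ηᵢ²] xᵢⱼ² in
place of xᵀx (the ES enters through its first two posterior moments, as
mean-field independence requires). Weight updates are Gaussian with prior
precision 1. Update order in a pass: covariates, then (βj, γj) pairs in
genome order, then w. Running caches (linear-predictor residual, X γ̄, ES
moments) are maintained incrementally; `VariationalState.check_cache`
verifies them against from-scratch recomputation at 1e-6.

The seven free hyper-parameters (σe², two variance scales and a mixture
weight per effect type) are updated by a closed-form variational M-step:
σe² ← E_q‖y − Cα − Xβ − η⊙Xγ‖²/N, mixture weights ← mean slab
responsibility (clamped to [1e-6, 1−1e-6]), variance scales ←
responsibility-weighted second moments over σe². Because the scales are
profiled jointly with σe², this step never lowers the ELBO. Slab/spike labels
are kept ordered (slab ≥ spike) by swapping components — in the
hyper-parameters and the state simultaneously, which leaves the ELBO
unchanged.

### SQUAREM acceleration

The (λ, σ²) mixture hyper-parameters move along a slow, nearly linear ridge
under plain variational EM, so the fit uses squared extrapolation (SQUAREM)
on the log/logit-transformed hyper-parameter vector: two EM steps open a
cycle, the three iterates are extrapolated with step
v = min(−1, −‖Δφ‖²/‖Δ²φ‖²), and one stabilizing EM step is run from the
extrapolated point. If the extrapolation leaves the representable domain, or
the stabilized ELBO falls below the last recorded value, the step is halved
toward v = −1 (at which the scheme reduces to plain EM) up to a small number
of retries, with full state rollback on failure. Accepted states therefore
never lower the ELBO. Convergence is declared when a full pass changes the
ELBO by less than 0.01 in absolute value (`elbo_tol`); `max_passes` defaults
to 200.

Initialization: SNP-effect means zero with prior variances; λβ = λγ = 0.1;
slab scales sized so expected explained variance is 10% (main) and 1% (GxE)
with spikes 100× smaller; σe² = 1; w drawn N(0, 1/L) from the seeded
generator to break the sign symmetry of the bilinear term, with initial
variances 1/L. Everything is deterministic given the seed; in serial mode
identical seeds give bit-identical ELBO traces. The per-SNP sweep is
JIT-compiled with numba (a plain-numpy fallback with the same update order is
used if numba is absent; the two agree to round-off).

Covariates can either be modeled inside the variational approximation
(default) or residualized out of the phenotype once before fitting
(`covariate_mode="project-out"`).

## Association testing

After the fit, per-chromosome leave-one-chromosome-out (LOCO) residuals
exclude each chromosome's fitted main and interaction contributions, so a
test SNP is never conditioned on its own chromosome. Each variant is then
tested in the two-column regression residual ~ [x, η̂⊙x]: the main effect by
a plain t test (N − 2 df), the interaction by a Wald χ²₁ statistic with
heteroskedasticity-consistent (sandwich) variance using the small-sample
leverage adjustment Σ̂ii = ε̂ᵢ²/(1 − hᵢᵢ)², with leverage taken from the
two-column design. Genome-wide GxE at other loci makes the residual variance
depend on the ES, which inflates the homoskedastic variant of this test; the
sandwich variant stays calibrated as long as the test SNP is independent of
the environments. Test SNPs are standardized, so effects are per genotype SD.
Rank-deficient designs (e.g. η̂⊙x ∝ x) and numerically exact fits produce a
flagged row rather than aborting a scan.

Comparison tests fit y ~ [1, C, E, x, x⊙E] by OLS (via statsmodels) and test
all L interaction coefficients: the F-test with the homoskedastic covariance
(null F(L, N−d₁)) and the robust F-test as a Wald statistic with HC3
covariance referred to χ²_L.

Squared-environment screening regresses y on [1, C, E_l²] per environment and
flags environments at the Bonferroni threshold 0.01/L; flagged squared
columns (centered) are appended to the covariates. This guards the GxE scan
against a heritable environment entering the trait non-linearly, which
otherwise inflates interaction statistics at SNPs that are causal for the
environment.

SNP-specific interaction profiles (least-squares weights of y ~
[1, C, x, x⊙E]) give a per-locus η_LS = E w_LS whose squared correlation with
the genome-wide ES measures how well the shared-ES assumption captures that
locus. ES weights can be re-expressed in any same-span recoding E₁ of the
environments by least squares, with the projection residual reported.

## Heritability estimation

With the fitted ES treated as a known fixed effect, variance components for
K = XXᵀ/M and V = diag(η̂) K diag(η̂) are estimated by Haseman-Elston
regression: a method-of-moments linear system in {tr(K²), tr(KV), tr(V²),
tr(K), tr(V)} and the quadratic forms yᵀKy, yᵀVy. Fixed effects (intercept,
covariates, η̂) are projected out of y, X and Z = diag(η̂)X; after projecting
k columns the identity-block entry uses tr(P) = N − k rather than N, and all
trace-over-N normalizers use the same N − k. At small N the system is solved
with explicit matrices (`exact_rhe`); at scale all traces involving products
of kinships are estimated with B Hutchinson probe vectors (default B = 50) in
O(NMB) time without forming any N × N matrix. Probe noise in the
heritability scale is ~1e-3 at B = 50 and the surrogate scale below —
negligible against sampling noise. Negative method-of-moments estimates are
reported and flagged, never truncated.

MAF/LD-stratified (LDMS) estimation assigns each SNP to one of 5 MAF bins
((0, 0.1], ..., (0.4, 0.5], right-inclusive) × 4 in-sample LD-score
quantiles, with one additive and one GxE component per bin solved jointly by
least squares. LD scores are unadjusted sums of r² over a fixed window of
100 SNPs each side within a chromosome (window and estimator are package
defaults; the stratification literature leaves them open).

Standard errors come from a delete-one-block jackknife over 100 contiguous
SNP blocks (default). Because every per-component quantity in the moment
system is a sum over that component's SNPs, each delete-block system is
obtained by subtracting the block's contribution from cached probe images —
the whole jackknife costs about one extra pass over the genotypes, and the
decomposition is exact (verified against rebuilding the system without the
block).

**Jackknife coverage caveat.** At aspect ratio N/M ≈ 0.5 with a known ES,
the SNP-block jackknife matches the empirical replicate scatter of ĥ²_G
almost exactly, but captures only part of the scatter of ĥ²_GxE: the GxE
moment equation is sensitive to the realized fourth moments of the ES across
samples, which deleting SNP blocks cannot resample. The exact-trace solver
shows the same scatter, so this is a property of the estimator, not of the
randomization. Accordingly, the acceptance suite checks ĥ²_G per replicate
against its jackknife SE but assesses ĥ²_GxE recovery on the mean across
replicates with a Monte-Carlo SE.

## Synthetic data

The generator emulates the evaluation design end to end. Genotypes are hard
calls Binomial(2, f_j) with f_j ~ U(0.05, 0.5), split evenly across
pseudo-chromosomes (22 by default). Optional LD uses a Gaussian-copula AR(1)
haplotype model: two latent AR(1) Gaussian processes per chromosome are
thresholded at each SNP's frequency, so marginals stay exactly
Binomial(2, f_j) at any LD level. (A dosage-copying Markov scheme was
rejected: it homogenizes allele frequencies, emptying the low-MAF tail that
the stratified-heritability scenario needs.) The latent autocorrelation
attenuates at the dosage level — `ld_rho = 0.9` yields mean adjacent-SNP
r² ≈ 0.35.

Environments are i.i.d. standard Gaussian, standardized. Phenotypes are
y = Xβ + (Ew)⊙(Xγ) + c₁·PC1 + ε with: causal SNPs drawn from the first half
of each chromosome (second halves stay null for calibration), optionally
restricted to a MAF ceiling; equal weights 1/√(n_active) on the active
environments; a block of SNPs with standardized (equal-magnitude,
random-sign) main and interaction effects for power measurement; PC1 the
leading left singular vector of standardized X; and every component rescaled
empirically so realized variance fractions equal their targets exactly
(recorded in `SimTruth` along with all effects and index sets). The final
phenotype is scaled to unit variance. Defaults follow the full-scale
evaluation design (N = 25,000, M = 100,000, L = 30 with 6 active, 2,500 main
/ 1,250 interaction causal SNPs at 20%/5% of variance, 60 standardized-effect
SNPs at 1%+1%, 1% on PC1).

What the generator does *not* emulate: realistic human LD beyond first-order
decay, population structure beyond the single PC1 effect, frequency-dependent
effect-size architecture, non-Gaussian or dependent environments, and
missing-data patterns. Tests passing on this generator show the estimators
are correct and calibrated under the stated model; they do not certify
behavior under real-cohort confounding.

The model-misspecification design draws a heritable environment
S = Xτ + ε_s (spike-and-slab τ with slab variance h²_τ/(M λ_τ), so
Var(S) ≈ 1) and a trait Y = aS² + Xβ + ε. Testing SNPs that are causal for S
with S as the environment inflates GxE statistics; including the detected
squared environment among covariates restores calibration — both directions
are exercised in tests.

## Problem sizes used in the shipped experiments

Chosen as scaled-down analogues of the full design that preserve the
relevant signal-to-noise quantities:

* **RHE recovery surrogate**: N = 10,000, M = 20,000, L = 30 (6 active),
  2,000 + 2,000 causal SNPs at 20%/5%, known ES, 20 replicates sharing one
  genotype matrix (the estimand — bias over phenotype/environment draws —
  does not require redrawing genotypes). Mean ĥ²_GxE runs slightly above 5%,
  the direction the method is known to drift at reduced N.
* **Power comparison**: N = 5,000, M = 20,000, L = 10 (6 active). The
  standardized-effect GxE budget is set to 5% so that the per-SNP
  noncentrality N·(var/SNP) matches the full design (25,000 × 0.01/60);
  at the full design's per-SNP variance, N = 5,000 gives both tests ~zero
  power and no comparison is possible.
* **Low-MAF LDMS scenario**: N = 4,000, M = 8,000, `ld_rho = 0.9`, causal
  SNPs restricted to MAF ≤ 0.1.
* **Calibration suites**: 5,000 null SNPs at N = 2,000 (single-SNP tests);
  1,500–2,000 replicates at N = 500 (F-tests).

## Numerical choices

* Sample SD uses the n−1 denominator everywhere; standardized columns are
  mean 0, variance 1 to 1e-8.
* Missing genotypes are mean-imputed per column before standardization.
* Mixture weights clamped to [1e-6, 1−1e-6]; variance scales floored at
  1e-10 with a warning when a component loses all responsibility mass.
* SQUAREM extrapolations whose transformed coordinates exceed ±50 are treated
  as out of domain.
* Degenerate single-SNP designs (condition number > 1e12, non-positive
  leverage complement, or residual numerically in the design span) yield
  flagged results with missing p-values.
* The GxE p-value is χ²₁ survival; no genomic control is applied.
* Bonferroni threshold for squared-environment inclusion is 0.01/L.
* Dosages count the first .bim allele; MAF is folded; positions are 1-based;
  chromosome labels compare as strings; info scores default to 1.0 for hard
  calls.

## Known limitations

* A single ES: interactions driven by environment combinations orthogonal to
  the learned score are invisible to the single-df test (the SNP-specific
  interaction profile quantifies this per locus).
* Mean-field variational inference underestimates posterior variances, which
  is why heritability is estimated by moment matching with the ES as a fixed
  effect rather than from the fitted hyper-parameters.
* Testing SNPs that participated in ES estimation is mildly anti-conservative
  at small N (a two-stage effect); the shipped calibration checks quantify
  this regime's behavior with an independently generated ES.
* The ELBO surface of the bilinear (w, γ) term is multi-modal; with very weak
  interaction signal the fit can settle in a no-GxE mode. Seeded
  initialization keeps runs reproducible; restarting with different seeds is
  the pragmatic check.
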