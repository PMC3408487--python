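# Methods

This note records the statistical models implemented in `gmatools`, the
assumptions behind them, the defaults of the synthetic-data generator, and
the numerical choices that matter when reproducing or extending results.

## 1. The multivariate mixed model

### Model

Each surviving plant contributes a k-vector of traits (k = 4: nodule
number, herbivory proportion, root biomass, shoot biomass), treated as
repeated measures on the plant.  The mean structure is trait crossed with
environment, population, population×environment, and block nested in
environment (treatment-contrast coding, intercept plus reference levels).
The covariance structure is

* an among-family random effect u_{f,e} ~ N(0, G_e), drawn independently
  per family×environment — families are near-isogenic selfed lines, so
  G_e is broad-sense genetic (co)variance in environment e;
* a within-plant residual e ~ N(0, R_e) across the k traits.

With `grouping="by_env"` both matrices are estimated separately per
environment (2×10 + 2×10 = 40 covariance parameters for k = 4);
`grouping="none"` pools them (20).  An optional constraint ties one
family covariance element (by default herbivory–nodulation) across
environments, removing one parameter.  There is no cross-environment
family covariance: the grouped model treats the same family's effects in
sun and shade as independent draws, and the generator's default matches
this structure (a `shared_family_effects` switch exists for robustness
studies; it routes one standard-normal draw per family through both
environments' G factors, giving perfectly correlated effects with the
correct per-environment marginals).

### REML computation

Because every plant belongs to exactly one family×environment cell, the
marginal covariance is block diagonal with V_cell = J_n⊗G_e + I_n⊗R_e.
All computations use the identities

    V_cell⁻¹ = I⊗R⁻¹ − J⊗M_n,  M_n = (R⁻¹ − H_n)/n,  H_n = (R + nG)⁻¹,
    log|V_cell| = (n−1)·log|R| + log|R + nG|,

which reduce the restricted log-likelihood (fixed effects profiled out)
and its analytic gradient to k×k operations on per-(environment,
cell-size) data aggregates computed once.  A fit therefore costs the same
whether the design has 50 or 5000 plants per environment, apart from the
one-time aggregation.

Parameterisation: residual matrices use a log-Cholesky factorisation
(always positive definite); family matrices are unconstrained symmetric
(vech) by default, because unconstrained-structure REML legitimately
returns boundary solutions — zero variances with nonzero covariances —
and forcing PSD would change the estimator.  A strict-PSD mode
(`family_structure="psd"`) swaps in a log-Cholesky family
parameterisation.

Numerical choices:

* Traits are standardised internally per trait (by the sample SD) and all
  reported quantities transformed back; this conditions the optimisation
  and makes fits exactly invariant to the input's measurement scale.
* The likelihood requires R + nG positive definite for every cell size n.
  Instead of a hard feasibility wall, eigenvalues below 1e-8·tr(R)/k are
  floored for evaluation and a C¹ quadratic penalty (scaled to the
  typical-eigenvalue magnitude so line searches can interpolate across
  it) pushes the optimiser back; y'Py is clamped at its mathematical
  lower bound 0 to suppress cancellation noise, and the log-diagonal
  Cholesky parameters are box-bounded to ±12.
* Optimiser: L-BFGS-B with the analytic gradient, followed by a dense
  BFGS polish and repeated fresh restarts until no further progress is
  achievable; "converged" means exactly that no restart improves the
  objective beyond 1e-7 relative.  Starting values are method-of-moments
  (family-mean covariance minus the attenuation term for G, pooled
  within-family covariance for R); in a balanced design these already sit
  at the REML optimum, which is why no EM warm-start stage is needed.
* Aliased fixed-effect columns are dropped deterministically in
  left-to-right order by a sequential Gram–Schmidt rank filter, with a
  warning naming them.

Validation: on a balanced single-trait design the fit reproduces the
closed-form ANOVA moment estimators exactly, and the REML log-likelihood
matches statsmodels `MixedLM` to ~1e-10 on the same model.

### Likelihood-ratio tests

`lrt` compares two REML fits on identical data with identical fixed
effects (both checked via a data fingerprint), referring 2Δll to a plain
χ² with df equal to the covariance-parameter difference.  No boundary
mixture correction is applied — variance-component tests at the boundary
are conservative under the plain χ² reference, which is the convention
this package follows deliberately.

### Least-squares means

Population×environment lsmeans come from the fixed-effect solution,
averaging over block effects with equal weight per block within the focal
environment and over no other terms.  They feed the population-level
correlation and path analyses; with 8 populations the per-group sample is
very small and the pipeline's report says so.

## 2. Matrix comparison

**Random skewers.**  Selection gradients β are iid standard normal
vectors normalised to unit length (uniform on the sphere).  The
per-skewer statistic is the cosine of the angle between the response
vectors G₁β and G₂β — not the centred Pearson correlation, which would
discard the response's mean component; a zero-length response (possible
for singular matrices) contributes 0.  The statistic is symmetric and
invariant to a common positive rescaling of both matrices; at 1000
skewers its Monte-Carlo SE is small enough that independent runs agree
within 0.02 on the built-in example matrices.

The equality test pools individuals across the two environments and
reassigns them at random to the original environment×family cells (cell
sizes preserved), so both matrices are re-estimated from a common
population — the matrix-equality null.  It is one-tailed, rejecting for
*low* similarity: p = (1 + #{null r ≤ observed}) / (n_null + 1).  The
same skewer set is reused across replicates so replicate variation
reflects only the reassignment.  The null scheme is pluggable via the
`estimator` argument.  Under the null this construction is exact: with
n_null = 199 the rejection rate at α = 0.05 is 5% up to binomial error,
which the test suite verifies over 200 null simulations.

**Flury hierarchy.**  Sample matrices enter with Wishart df n_i =
(number of families − 1).  Fits per level: equality — the df-weighted
pooled matrix; proportionality — alternating updates of the common shape
and the proportionality constants; full CPC — the FG pairwise-rotation
algorithm (converged when successive bases differ by < 1e-10 in maximum
column angle, or when the objective has stabilised to 1e-12 relative for
three sweeps, which matters when near-degenerate eigenvalues leave flat
rotational directions; the objective is asserted non-increasing every
sweep); partial CPC(q) — numerical ML over the common q-frame via a
matrix-exponential parameterisation, started from every q-subset of the
FG basis.  The LR statistic vs the unrelated model is
Σ n_i [log|Σ̂_i| − log|S_i| + tr(Σ̂_i⁻¹S_i) − p], with the trace term
equal to p at every exact ML solution.  χ² reference df are reported for
bookkeeping (10, 9, 6, 5, 3 for k = 2 groups, p = 4); inference uses the
jump-up randomisation: under the null a family's sun and shade data are
exchangeable, so each replicate swaps the environment labels of a random
subset of families and recomputes all LR statistics.  Randomisation loops
default to the headline levels (equality, proportionality, full CPC);
partial-CPC fits are much slower and are computed for the observed
matrices only unless requested.

Non-PD inputs (boundary REML estimates, family-mean matrices of small
samples) are "bent" by flooring eigenvalues at 1e-6·trace/p before any
log-det likelihood; bending inflates the LR statistics of
boundary-adjacent matrices and is the reason CPC statistics on such
matrices should be read comparatively, not absolutely.

## 3. Two-group path analysis

The canonical diagram: herbivory (exogenous) → root, shoot, nodules;
root, shoot → nodules; root~~shoot error covariance, constrained equal
across the two light-treatment groups.  For recursive models the implied
covariance is Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ.  Fitting minimises the pooled ML
discrepancy F = Σ_g (n_g/N)[log|Σ_g| + tr(S_gΣ_g⁻¹) − log|S_g| − p] with
an analytic gradient, OLS starting values per structural equation, and
BFGS to gradient norm 1e-9; χ² = (N − G)·F_min, the (N − G) multiplier
being one of several conventions in circulation (it affects the third
decimal at these sample sizes) and the one adopted here.  Means are not
modelled.  Standard errors come from the observed information (Hessian of
(N−G)F/2 by central differences of the analytic gradient); critical
ratios for cross-group parameter differences use
z = (b₁−b₂)/√(SE₁²+SE₂²) with two-sided normal p-values reported raw (no
multiplicity correction).  Standardised coefficients use model-implied
SDs; total effects are (I−B_std)⁻¹ − I, which equals the sum over all
directed paths of products of standardised coefficients.  CFI uses the
per-group independence baseline; multi-group RMSEA includes the √G
factor.  Inadmissible iterates (non-PD implied covariance) are handled
with the same floored-eigenvalue-plus-C¹-penalty device as the REML
engine.  Non-significant paths are never pruned.

With df = 0 (saturated models) RMSEA is reported as not applicable.  The
`simulate_group` helper draws data from the structural equations in
topological order and serves as the independent oracle for the implied
covariance and for recovery studies.

## 4. The synthetic-data generator

`generate_experiment` composes, per plant, mu_env + population effect
(from P_pop, once per population) + family effect (from G_env, once per
family×environment) + block effect (diagonal, SD sigma_block per trait) +
residual (from R_env), then applies independent Bernoulli survival per
plant with environment-specific probability, clips herbivory to [0, 1]
and floors the remaining traits at 0.  Randomness uses one master seed
with deterministic sub-streams per population / family / block / plant
(`SeedSequence` spawn keys), so enlarging the design or switching off
thinning never changes the draws of existing units — thinning only
removes rows.  Clipping fractions are reported in the table's `attrs`.

`study_config` emulates the motivating field experiment: 8 populations ×
7 inbred families × 15 replicates per treatment (1680 planted), 15 blocks
per treatment, survival 26% (sun) / 30% (shade) for ~28% overall; trait
means per treatment are the observed ones (nodules 2.5/12.7, herbivory
0.45/0.29, root 0.16/0.23 g, shoot 1.32/2.0 g).  The family-level
covariance is the published mean-scaled G pair projected to the nearest
PSD matrix (the published boundary estimates are not valid simulation
inputs as printed) and rescaled to original units by the grand trait
means.  Residual and among-population covariances are not published;
they were chosen once to reproduce the study's qualitative signature and
then frozen: residual correlations pair herbivory negatively with all
three size/nodulation traits (−0.45 with nodules, −0.30/−0.35 with
biomass) and the sizes positively with each other (+0.35…+0.60), strong
enough that within-environment phenotypic herbivory–nodulation
correlations come out negative even though the family-level and
population-level herbivory–nodulation covariances are positive — the
study's central pattern.  Residual SDs are proportional to trait means
(CV 1.0 for nodule counts, 0.45 for herbivory, 0.55 for biomass), block
SD is 15% of the trait mean.

`scaled_architecture_config` strips the design to its genetic core for
estimator studies: the same mean-scaled G pair, no population or block
variance, trait means placed ≥ 3 residual SDs from the clipping bounds
(so truncation cannot bias recovery), survival 0.9, 5 replicates per
family×environment.  `equal_G=True` gives both environments the shade
matrix — the matrix-equality null condition used for calibration.

What the generator does **not** emulate: spatial autocorrelation within
blocks, family- or genotype-biased mortality, leaf-count-based herbivory
(the proportion is drawn directly with Gaussian noise and clipped, per
the untransformed-analysis convention), non-Gaussian trait distributions
(real nodule counts are overdispersed integers), and any behavioural
model of insect choice.  Passing tests therefore demonstrate correctness
of the estimators and tests under a Gaussian, independently-thinned
version of the design — not robustness to those real-data features.

## 5. Problem sizes used by the test and acceptance suites

Chosen as the package's own defaults for a single-CPU run:

* REML parameter recovery: 100 simulated experiments at 275 families
  (5 populations × 55), 5 replicates per family×environment, survival
  0.9 (~2470 plants each); coverage of ±2 Monte-Carlo SDs around truth
  across the 20 distinct G elements, checked against the ~95% nominal
  rate with allowance for the binomial Monte-Carlo error of the coverage
  estimate itself; element-wise RMSE additionally compared against 30
  runs at 55 families.
* SEM recovery: 200 replicates of two groups × 600 individuals.
* Skewers calibration: 200 null simulations (40 families, 6 replicates,
  survival 1), 199 reassignments each, 100 skewers.
* The acceptance script fits the full study design (~450–500 survivors)
  three times and evaluates 100 000 skewers.

## 6. Known limitations

* The χ² reference for boundary-adjacent variance LRTs is deliberately
  uncorrected (no 50:50 mixture), so those tests are conservative.
* Partial-CPC ML uses a general-purpose optimiser over the orthogonal
  group; with near-degenerate eigenvalues the common-frame estimate is
  well-defined only up to rotations the likelihood cannot distinguish.
* The population-level SEM rests on as few samples per group as there are
  populations; its χ² is reported with an explicit small-sample caveat.
* Critical ratios treat the two groups' estimates as independent, which
  is exact only without cross-group constraints; with the single error-
  covariance constraint the approximation error is negligible but
  nonzero.
* Only two environments are supported throughout; the CPC machinery is
  written for k = 2 groups.
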