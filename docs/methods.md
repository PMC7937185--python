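# Methods

## The problem

Workers of the ant *Myrmica rubra* differ consistently in behaviour:
some are more active, explorative or aggressive than others, and beyond
differences in their *mean* behaviour they differ in how *variable* they
are around that mean (residual intraindividual variation, rIIV — the
inverse of predictability).  Colonies, in turn, differ in collective
traits such as how quickly they relocate their brood after nest
destruction.  This package implements the full statistical pipeline for
analysing such data — repeated assays (activity in cm travelled,
meandering in degrees/cm, exploration as grid squares entered, an
ordinal 0–3 aggression score) on workers nested in colonies from two
habitat types, plus colony-level nest-displacement times and brood
counts — together with a hierarchical simulator so every estimator can
be verified by parameter recovery.

## Double-hierarchical Gaussian model (`antvar.dhglm`)

For trial *i* on individual *j* in colony *k*:

    y_ijk   = β0 + β1·worker size + β2·colony size + β3·Myrmica nests
              + β4·allospecific nests + β5·habitat + β6·repeat
              + u_j + v_k + ε_ijk
    log σ(ε_ij) = γ0 + γ1·worker size + ... + γ5·habitat + s_j
    (u_j, s_j) ~ MVN(0, Ω),   v_k ~ N(0, σ²_colony)

Ω carries the among-individual variance of behavioural types (σ²_IDμ),
of log residual SDs (σ²_IDσ), and their covariance; the derived
correlation r_Int,rIIV = cov/√(σ²_IDμ·σ²_IDσ) measures whether
behavioural type predicts predictability.  A colony-level variant (used
for the three nest-displacement repeats) puts both intercept pairs at
the colony level; its residual is then within-colony variation.

Sampling is Metropolis-within-Gibbs.  β, v and u have conjugate
Gaussian full conditionals (exact, vectorised); s_j uses a vectorised
adaptive random-walk step exploiting the closed form of its conditional
log-likelihood (−n_j·s − ½·e^(−2s)·Σ e²·e^(−2w'γ)); γ, the Ω
parameters (parameterised as two SDs plus a correlation) and the colony
SD use componentwise adaptive random walks tuned to ~44% acceptance
during burn-in.  Priors: Normal(0, 10²) on β and γ, half-Normal(0, 1)
on all random-effect SDs, Uniform(−1, 1) on the Ω correlation — diffuse
relative to signal because all inputs are standardized.  Parameterising
Ω through its correlation makes every stored draw positive
semidefinite and bounds every r_Int,rIIV draw in [−1, 1] by
construction.

Defaults are 4 chains × 10,000 iterations (5,000 burn-in, thin 5);
tests and the pipeline default to 2 chains at a few thousand
iterations, which suffices at these data sizes (split-R̂ ≲ 1.05 on the
main parameters).  Summaries are posterior means with equal-tailed
credible intervals; `summary()` refuses (unless forced) when any
split-R̂ exceeds 1.1 or any effective sample size falls below 200.
Covariates enter z-scored over the analysis rows, colony size on the
log scale (worker counts span 219–5964 and are strongly right-skewed);
habitat is coded 0 = seminatural, 1 = invaded.

The homogeneous-variance limit of the model is an ordinary
random-intercept LMM, which provides two independent cross-checks: the
ML fixed-effect estimates from `statsmodels` must match DHGLM posterior
means (verified within 3 Monte Carlo SEs at a design of 80 colonies × 8
workers, large enough that prior influence is negligible), and
likelihood-ratio tests for the random intercepts use the boundary-
corrected ½χ²₀+½χ²₁ mixture.

## Syndrome decomposition (`antvar.syndrome`)

A behavioural syndrome is an among-unit correlation between distinct
traits.  The multivariate Gaussian mixed model splits the phenotypic
covariance of the trait vector into colony, individual and residual
components, y_i = μ + b·habitat + c_k + u_j + e_i, each component with
its own covariance matrix.  Random and fixed effects have exact
Gaussian Gibbs updates; the individual effects are *hierarchically
centred* on their colony effect (w_j = c_k + u_j), which removes the
severe mixing problem of the uncentred parameterisation when colony
effects are weakly identified.

Covariance matrices use a separation-strategy prior: SDs half-Normal(0,
1), the correlation matrix uniform over its positive-definite region,
updated with adaptive Metropolis steps (proposals failing a Cholesky
are rejected).  This choice is deliberate: a conjugate inverse-Wishart
update with a small scale matrix looks innocuous but its density spikes
at singular matrices, and on weakly identified components (23–40
colonies) it drags correlations toward ±1 — we confirmed this against
an exact numerically-integrated marginal posterior on a two-trait test
problem before discarding it.  With the separation prior the same exact
marginal is reproduced and simulation coverage is nominal at all three
levels.

Two model forms: four individual traits with colony + individual random
effects (one row per individual and trial series), and a five-trait
form adding repeat-level nest displacement with a colony random effect
only.  In the five-trait form the unobserved cells (displacement on
worker rows, worker traits on displacement rows) are completed by
conditional-normal data augmentation, and only the among-colony
component is interpretable — the residual mixes variation measured on
different units and is flagged accordingly.  pMCMC for a fixed effect
is the two-tailed posterior sign probability 2·min(P(>0), P(<0)) with a
(1+count)/(1+n) floor.

## Repeatability (`antvar.repeatability`)

R = σ²_group/(σ²_group+σ²_residual) from the Gaussian random-intercept
model, fitted by ML with the mean and residual variance profiled out so
the optimisation is one-dimensional in the variance ratio — this makes
each fit ~0.2 ms and the 1000-fold parametric bootstrap (percentile
95% CI) and 1000-fold randomization test cheap.  The default
randomization permutes group labels at the observation level; a block
mode permutes whole individuals (preserving within-individual
correlation) for colony-level tests, since either reading of
"randomization test" is defensible.  Variance components hitting the
zero boundary are truncated and flagged.  The estimator was verified
against `statsmodels.MixedLM` ML components to four digits.

## Productivity regressions (`antvar.productivity`)

Colony level: brood counts (total production and its worker / gyne /
male components, related by exact integer identities) are regressed on
habitat plus the per-colony mean and SD of each standardized trait.
Overdispersion is operationalised as Poisson-first: the NB2 family
replaces Poisson when the Pearson dispersion statistic exceeds 1.5.
The NB-GLM is `statsmodels.NegativeBinomial` (joint ML of coefficients
and dispersion, Wald CIs on the link scale).

Individual level: the colony's count is attached to each of its trial
rows and modelled with trait fixed effects and an individual random
intercept.  No NB mixed model exists in statsmodels, so the
Laplace-approximation ML is implemented here: per-individual posterior
modes by damped Newton steps on the closed-form η-derivatives of the
NB2 log-likelihood, a log-curvature correction, and BFGS over (β, log
α, log σ).  Standard errors come from a numerical Hessian evaluated
with a frozen inner warm start (warm-start hysteresis otherwise
corrupts finite differences).  On NB non-convergence the documented
fallback is a Gaussian LMM.  The male-production model is skipped with
a message when fewer than five colonies produced males.

Model selection is bidirectional stepwise AIC or exhaustive all-subsets
AICc (AIC + 2k(k+1)/(n−k−1)), random effects always retained, ties
broken toward fewer parameters, full path logged, with a combinatorial
guard above 20 candidate terms.

## The synthetic-data generator (`antvar.simulate`)

The generator reproduces the field design as its defaults: 12
seminatural + 11 invaded colonies, 12 focal foragers each, 3 repeats
per assay (828 trials per trait, 276 individuals), colony sizes
log-uniform over 219–5964 (matching the reported median/min/max skew),
*Myrmica* nest counts Poisson(1.5) truncated to 0–9 and allospecific
counts Poisson(1) truncated to 0–3, three displacement trials per
colony, and negative-binomial production counts.  Generating
coefficients default to the published activity estimates for the mean
and dispersion submodels (e.g. repeat effect −0.17, σ²_IDμ = 0.58,
σ²_colony = 0.43, σ²_IDσ = 0.26, r_Int,rIIV = 0.21), the published
level-specific among-trait correlation matrices (all three are already
positive definite as printed), the published colony-size slope (−0.49)
and allospecific-nest slope (−0.32) for displacement, and the published
total-production coefficient set (exploration +0.73, SD meandering
−0.95, ...).  The NB size parameter defaults to 5 (moderate
overdispersion; the source reports none).  Worker head widths are
Normal(1000, 60) µm clipped positive — a placeholder scale, as no
distribution is reported.

Traits are generated on the standardized latent scale that the models
assume, then mapped to observation units by fixed affine/log1p scales,
so the pipeline's own transform-and-standardize step recovers the
latent values exactly; boundary clipping (negative distances, >3
aggression) is counted and negligible at the default scales.
Displacement times are generated on the log scale, making positivity
structural.  Aggression is continuous-latent by default (the analysis
models log-transformed scores as Gaussian) with an optional {0,1,2,3}
discretisation by fixed thresholds for ordinal realism.  True
random-effect draws are stored in a tidy truth table; because the
analysis standardizes the response, `analysis_scale_truth` maps
generating parameters onto the fitted scale exactly (slopes and SDs
divide by the realized total SD, the dispersion intercept shifts by its
log, correlations are unchanged).  One shared seed drives per-stage
deterministic substreams, so identical configurations are byte-identical.

What the generator does *not* emulate: ordinal measurement of
aggression (by default), missing trials (attrition is imposed by tests
where needed), spatial structure among nests, any trait-specific fixed
effects (one coefficient vector is shared across the four traits), and
movement paths themselves.  Passing recovery tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to ordinal data or model misspecification.

## Problem sizes and numerical choices

Recovery tests run at the smallest sizes where the checked property is
sharply identified: field scale (23×12×3) for DHGLM interval coverage
(10 replicates), 200 individuals × 6 repeats for the mean–rIIV
correlation, 200 individuals × 5 repeats for the syndrome
decomposition, 200 colonies / 300 individuals for the productivity
coefficients, 200×10 for the closed-form ICC check.  MCMC tests use 2
chains × 1,500–4,000 iterations.  Equal-tailed quantile intervals are
used throughout (not HPD).  Spearman screening uses average ranks for
ties and the t approximation for p (scipy), with S = (n³−n)(1−ρ)/6
reported.  The log transform for aggression, meandering and
displacement is log1p, one consistent rule that is defined at the
ordinal zero.  Standardization statistics are computed on the analysis
subset actually fed to each model and stored with the table.

## Known limitations

Three repeats per individual make individual rIIV estimates imprecise
by design (the field design's constraint); the model is correct but
posterior intervals for σ²_IDσ are wide at field scale.  The Laplace
approximation for the NB-GLMM is accurate here because counts are
large; for sparse counts adaptive quadrature would be preferable.  The
five-trait syndrome model treats displacement repeats as exchangeable
with worker trial series within a colony, one of several defensible
alignments of traits measured at different levels.
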