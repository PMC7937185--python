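# antvar

Multi-level behavioural variance analysis for social-insect colonies.

Repeated behavioural assays on ant workers — activity (distance
travelled, cm), meandering (°/cm), exploration (grid squares entered)
and an ordinal aggression score — carry information at three levels:
colonies differ, individuals within colonies differ, and individuals
differ in how variable they are around their own mean (residual
intraindividual variation, rIIV; its inverse is *predictability*).
`antvar` is for behavioural ecologists who want to analyse such designs
end to end: it fits the paired mean/dispersion hierarchical model,
decomposes trait–trait correlations by level (behavioural syndromes),
estimates repeatability with resampling inference, and relates colony
productivity (brood counts) to behaviour — plus a matching hierarchical
simulator so every estimator is verifiable by parameter recovery.

## The models

**Double-hierarchical Gaussian mixed model.**  For trial *i* on
individual *j* in colony *k*,

    y_ijk = x'β + u_j + v_k + ε_ijk,          ε_ijk ~ N(0, σ²_ij)
    log σ_ij = w'γ + s_j,
    (u_j, s_j) ~ MVN(0, Ω),   v_k ~ N(0, σ²_colony)

with covariates worker size, colony size, conspecific and allospecific
nest density, habitat and repeat number.  u_j is the individual's
behavioural type, s_j its rIIV on the log-SD scale, and
r_Int,rIIV = cov(u,s)/√(σ²_IDμ σ²_IDσ) couples the two.  Fitted by an
adaptive Metropolis-within-Gibbs sampler (`antvar.dhglm`).

**Syndrome decomposition.**  A multivariate Gaussian mixed model splits
the trait covariance into Σ_colony + Σ_individual + Σ_residual; the
correlation from each component is the syndrome at that level
(`antvar.syndrome`).

**Repeatability.**  R = σ²_group/(σ²_group+σ²_residual) from a
profiled-ML random-intercept model, with parametric-bootstrap CIs and
randomization-test p-values (`antvar.repeatability`).

**Productivity.**  Negative-binomial GLMs of colony brood counts on
trait means/SDs, and NB mixed models (Laplace ML, Gaussian LMM
fallback) of production on trial-level traits, with stepwise-AIC or
all-subsets-AICc selection (`antvar.productivity`).

## Worked example

```python
from antvar import (SimulationConfig, generate_study, DHGLM,
                    transform_and_standardize, estimate_repeatability)

study = generate_study(SimulationConfig(seed=1))     # 23 colonies, 276 workers
fit = DHGLM.from_tables(study.trials, study.colonies, "activity").fit(
    chains=2, iterations=3000, burn_in=1500, thin=3, seed=1)
print(fit.summary(force=True))
```

```
DHGLM posterior summary (95% CrI, 2 chains x 3000 iterations)
  beta_repeat_index              -0.159 (-0.189 to -0.130) *
  gamma_colony_size              -0.162 (-0.243 to -0.083) *
  sigma2_id_mu                    0.398 (0.317 to 0.496) *
  sigma2_id_sigma                 0.185 (0.119 to 0.266) *
  r_int_riiv                      0.186 (-0.062 to 0.431)
  sigma2_colony                   0.337 (0.148 to 0.683) *
  ...
```

Activity declines across trial repeats (β_repeat < 0), individuals and
colonies both carry substantial mean variance (σ²_IDμ, σ²_colony), and
individuals genuinely differ in predictability (σ²_IDσ > 0); the
mean–rIIV correlation is positive but its interval spans zero.  The
generating values behind this dataset are the defaults of
`SimulationConfig`, so each starred estimate can be compared with the
truth table the simulator also returns.

```python
tz = transform_and_standardize(study.trials)
print(estimate_repeatability(tz, "activity", "individual",
                             1000, 1000, seed=1).summary())
# repeatability of activity at the individual level:
#   R = 0.626 (95% CI 0.561-0.680), permutation p = 0.000999
```

The same pipeline runs from the shell:

```bash
antvar simulate --out-dir data --seed 1
antvar fit-dhglm --trials data/trials.csv --colonies data/colonies.csv \
    --trait activity --seed 1 --out fit.json
antvar run-all --out-dir results --seed 1        # everything, one command
```

CSV schemas: `trials.csv` has one row per behavioural trial
(`colony_id, individual_id, habitat, assay, repeat_index, raw_value`,
plus optional `worker_size`); `colonies.csv` has one row per colony
(habitat, `colony_size`, queen/brood counts, `myrmica_nests`,
`allo_nests`, `mean_worker_size`, `displacement_1..3` and the derived
production components).

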