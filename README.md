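# copulagm

Bayesian Gaussian copula graphical model with an adaptive
graphical-lasso prior and cluster random effects, for multilevel
mixed-type data.

## What problem this solves

Survey and questionnaire studies routinely collect a hundred or more
variables of mixed type — continuous measurements, Likert scales,
yes/no items — from respondents nested in clusters (schools, clinics,
sites), with plenty of missing answers.  Three questions recur:

* which variables are *conditionally* associated, after controlling for
  everything else and for cluster effects (a sparse graphical model);
* how do cohorts (groups of clusters, e.g. survey waves) differ on each
  item;
* can the joint model score individuals for a rare binary outcome
  (e.g. an under-diagnosed disease) from their other answers?

`copulagm` answers all three from a single MCMC fit of the model

```
y_icl = F_l^{-1}( Phi(z_icl) )          observed response, variable l
z_ic  ~ N_p( b_c, Omega^{-1} )          latent Gaussian scores
b_c   ~ N_p( 0, Psi )                   cluster (school) effects
```

where the marginals `F_l` are never specified: inference uses the
extended rank likelihood, which conditions only on the event that the
latent scores share the observed ordering within each column, so
continuous, ordinal and binary variables are handled uniformly and
missing-at-random cells are integrated out.  Conditional dependence
lives in the precision matrix `Omega`, which carries an adaptive
graphical-lasso prior — element-wise double-exponential shrinkage with
rates `lambda_ij ~ Gamma(s, t)` — so weak conditional associations are
pulled to zero while strong ones are left alone.  Everything is sampled
by a block Gibbs sampler with conjugate updates (see
`docs/methods.md`).

## Worked example

Simulate one replicate of the built-in 4-variable multilevel benchmark
(20 schools, Poisson(50) sizes, known truth), fit two chains, and read
off the summaries:

```python
import numpy as np
import copulagm as cg
from copulagm.model_core import Hyperparameters

rng = np.random.default_rng(42)
data = cg.benchmark_dataset(rng)          # N = 1004, p = 4, m = 20

hp = Hyperparameters(n_iter=2000, burn_frac=0.5, thin=5, n_chains=2, seed=7)
draws_list, report = cg.run_chains(data, hp)
print(report.attrs["frac_above"])         # {'Omega': 0.0, 'Psi': 0.0}

pooled = np.concatenate([d.Omega for d in draws_list])
print(pooled.mean(axis=0).round(3))
```

```
[[ 2.38  -0.834  0.007  0.882]
 [-0.834  1.474 -0.016 -0.42 ]
 [ 0.007 -0.016  1.556 -0.005]
 [ 0.882 -0.42  -0.005  2.095]]
```

No parameter's scale-reduction factor exceeds 1.05, and the posterior
mean precision recovers the generating structure: the strong entries
(true `omega_12 = -0.918`, `omega_14 = 1.209`) come out clearly nonzero
with the right signs, while the near-zero entries (true `omega_13 =
0.067`, `omega_34 = 0.046`) are shrunk to ~0 by the adaptive prior at
the default `t = 1e-4`.

Conditional (regression-type) coefficients of the other variables on
`v1`, with 95% highest-density regions:

```python
pooled_G = np.concatenate([d.Gamma for d in draws_list])
print(cg.conditional_association_report(pooled_G, 0, columns=data.columns))
```

```
predictor   mean  hdr_lo  hdr_hi  significant
       v2  0.353   0.293   0.408         True
       v3 -0.003  -0.027   0.018        False
       v4 -0.373  -0.456  -0.298         True
```

`v2` and `v4` are flagged (their HDRs exclude 0), matching the
generating precision pattern.

The same workflow is scriptable from the shell:

```bash
copulagm simulate --kind benchmark --out data.csv --meta meta.yaml --seed 42
copulagm fit --data data.csv --meta meta.yaml --out draws.h5 --iters 2000 --chains 2
copulagm summarize --archive draws.h5 --out-prefix report --response v1
copulagm predict --archive draws.h5 --data data.csv --meta meta.yaml \
    --outcome <binary-column> --out scores.csv     # needs fit --store-z
copulagm coverage --replicates 40 --out coverage.csv
```

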