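# skm — rate-constant inference for stochastic kinetic models

`skm` infers the kinetic rate constants of a discrete stochastic
biochemical reaction network (a Markov jump process on molecule counts)
from time-course observations of some or all species, by maximum
likelihood.  It is aimed at systems-biology models in the
gene-regulation regime — low copy numbers, where deterministic rate
equations misrepresent the dynamics and the chemical master equation is
the right description but its likelihood is intractable.

## Method in brief

For a network `U S → V S` with net-effect matrix `A = V − U` and
mass-action hazards `h_r(X) = θ_r ∏_a C(x_a, u_ra)`, the missing data
between observations is the reaction path Ξ (types and times of all
latent firings).  The gradient of the observed-data log-likelihood is an
expectation of complete-data sufficient statistics,

    ∂ log L/∂θ_r = E[n_r]/θ_r − E[G_r],      G_r = ∫ h_r(X(t))/θ_r dt,

conditioned on the observations.  `skm` estimates it by reversible-jump
MCMC over paths — proposals add or delete whole *elementary modes*
(reaction multisets invisible to the observed species, computed from the
integer null space of the observed stoichiometry) or redraw event times —
and feeds the estimate to an adaptive stochastic gradient ascent.
Partially observed systems use correlated moves on interval pairs with a
complementary move that restores the hidden state at the pair's end.
Initial paths come from integer programming; small-system correctness is
pinned by exact truncated-master-equation oracles.

## Worked example

```python
import numpy as np, skm

# simulate a birth-death dataset: R1: A -> 0 (k1*nA), R2: 0 -> A (k2)
spec = skm.BenchmarkSpec(model="birth_death", theta=(0.03, 0.6),
                         m=21, dt=2.0, seed=11)
obs, _ = skm.generate_benchmark(spec)

net = skm.birth_death_network()
theta_hat, trace = skm.infer_parameters(
    net, obs,
    theta0=np.array([5.0, 0.5]),                       # deliberately far off
    sgd_config=skm.SGDConfig(seed=42),
    mcmc_config=skm.MCMCConfig(n_samples=1000, burn_in=100),
)
print(np.round(theta_hat, 4), trace.n_iters, trace.converged)
```

Output:

    [0.0255 0.3233] 9 True

The run converged in 9 gradient evaluations.  The estimate is the
maximum-likelihood point *of this particular 21-observation dataset*:
an exact master-equation computation puts its MLE at
(0.0258, 0.329), so the sampler-based ascent lands on it to within
Monte-Carlo resolution; across replicate datasets the estimates scatter
around the simulation truth (0.03, 0.6).  With 21 sparse observations
the production rate is the harder parameter — the same behavior the
benchmark tables show.

The same call infers the 8 rate constants of the bundled auto-regulatory
gene network (promoter binding/unbinding, transcription, translation,
dimerization, degradation), fully observed or with only mRNA, P and P2
observed (the DNA total is then treated as known).

## Command line

    skm simulate --preset birth_death --m 21 --dt 2 --seed 1 --out data.csv
    skm nullset  --model model.json --observed mRNA,P,P2
    skm infer    --model model.json --obs data.csv --samples 1000 --burnin 100
    skm validate --model model.json --x-start 20 --x-end 22 --tau 2

`skm infer` writes `results.json`, `trace.csv`, `diagnostics.csv` and a
run manifest (config, seeds, input digests) sufficient to reproduce the
run.  Model files are JSON/YAML (species, reactions with integer
stoichiometries, rate-law tags, θ values, optional conserved totals);
observations are CSV with a `time` column and one column per observed
species.

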