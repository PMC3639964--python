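# cjshet — survival estimation under individual capture heterogeneity

`cjshet` is a Python package for studying, and correcting, the bias that
individual heterogeneity in detection (capture/resighting) probability causes
in survival estimates from open-population capture–mark–recapture data.  It
is aimed at quantitative ecologists and biostatisticians who fit
Cormack–Jolly–Seber (CJS) models and want to know when the added complexity
of individual random effects on detection is worth it.

## The model

The CJS model is written in state-space form, conditioning on first capture.
For individual *i* at occasion *t*:

- state process: z<sub>i,t+1</sub> | z<sub>i,t</sub> ~ Bernoulli(z<sub>i,t</sub> · φ) — alive/dead with
  apparent survival φ (constant over time and individuals);
- observation process: y<sub>i,t</sub> | z<sub>i,t</sub> ~ Bernoulli(z<sub>i,t</sub> · p<sub>i</sub>) — detection
  only while alive, with an individual detection probability p<sub>i</sub>.

Heterogeneity in detection is modelled with a logit-normal random effect,

logit(p<sub>i</sub>) = μ + ε<sub>i</sub>,  ε<sub>i</sub> ~ Normal(0, σ²),

and the likelihood marginalises ε<sub>i</sub> by Gauss–Hermite quadrature over the
forward algorithm of the two-state hidden Markov chain.  The package
provides:

- **scenario simulation** (`cjshet.scenarios`): four generating regimes for
  p<sub>i</sub> — symmetric beta (mean 0.4, SD 0.148), right-skewed beta (0.2, 0.163),
  left-skewed beta (0.8, 0.163), and a two-group 0.2/0.8 mixture — with
  φ = 0.7, 15 annual occasions and 50 newly marked animals per occasion by
  default, plus a homogeneous regime for null checks;
- **likelihoods** (`cjshet.likelihood`): constant, time-varying (fixed
  per-occasion effects) and logit-normal random-effects detection;
- **inference** (`cjshet.inference`): adaptive random-walk Metropolis MCMC
  with U(0,1) priors on φ and the mean detection probability and U(0,10) on
  σ, Brooks–Gelman–Rubin convergence diagnostics, and a fast
  maximum-likelihood path with observed-information standard errors;
- **goodness of fit** (`cjshet.gof`): the classical m-array and the
  U-CARE-style component tests TEST3.SR, TEST3.SM, TEST2.CT, TEST2.CL with
  directional z tests for transience and trap-dependence, and the
  overdispersion factor ĉ = χ²/df;
- **replicate studies** (`cjshet.evaluation`): bias and precision of survival
  estimates across scenarios and models, with Monte-Carlo standard errors;
- **I/O and CLI** (`cjshet.io`, `cjshet.cli`): CSV and MARK-style `.inp`
  capture histories, YAML/JSON study configs, run manifests, and the
  `cjshet simulate|fit|gof|study` commands.

## Worked example

Simulate one two-group dataset (750 individuals × 15 occasions), fit both
detection models by maximum likelihood, and run the GOF suite:

```python
from cjshet import default_scenarios, simulate_dataset, fit_mle, overall_gof

spec = default_scenarios()["two_group"]      # p = 0.2 or 0.8, phi = 0.7
data = simulate_dataset(spec, rng_seed=42)

fit_mle(data, "constant_p").params.round(3)
#             mean     sd   q2.5    q50  q97.5
# phi        0.666  0.013  0.641  0.666  0.692
# p          0.589  0.019  0.551  0.589  0.627

fit = fit_mle(data, "re_p")
fit.params.round(3)
#             mean     sd   q2.5    q50  q97.5
# phi        0.722  0.016  0.692  0.722  0.752
# p_mean     0.465  0.044  0.379  0.465  0.551
# sigma      2.021  0.246  1.538  2.021  2.504
fit.implied_detection_sd()                 # 0.315 (generating SD: 0.3)
```

Ignoring the heterogeneity biases survival low (0.666 vs the generating
0.7, well outside its confidence interval); the random-effects model covers
the truth and recovers the probability-scale detection SD.  The GOF suite
flags the heterogeneity as apparent transience and trap-dependence:

```python
r = overall_gof(data)
# TEST3.SR: chi2=24.75 df=13 p=0.0249 z=+3.88   (transience direction)
# TEST3.SM: chi2=40.01 df=17 p=0.0013
# TEST2.CT: chi2=58.60 df=11 p<0.0001 z=+5.76   (trap-happiness direction)
# TEST2.CL: chi2=11.29 df=11 p=0.4196
# overall : chi2=134.64 df=52 p=3.0e-09 c_hat=2.589
```

The same pipeline runs from the shell:

```bash
cjshet simulate --scenario two_group --replicates 1 --seed 42 --out sim/
cjshet gof --input sim/two_group_rep000.csv --out gof/
cjshet study --config study.yaml          # full replicate bias/precision study
```

## Acceptance script

`scripts/acceptance.py` recomputes the headline quantities of the simulation
study from scratch — the cross-scenario minimum/maximum of the relative bias
of the estimated probability-scale detection SD under the random-effects
model (20 ML-fitted replicates per scenario), the maximum ĉ over five GOF'd
datasets per scenario, and the maximum Brooks–Gelman–Rubin statistic for a
3-chain × 10000-iteration fit of the random-effects model — and writes them
as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It takes well under a minute on one CPU.
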