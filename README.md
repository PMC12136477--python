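# softmix

Bayesian soft-tree ensembles for multipollutant mixture–health analysis.

Environmental health studies routinely measure a *mixture* of correlated
exposures — for example the constituents of fine particulate matter
(Br, Ca, Cu, Fe, Mn, Ni, S, Se, Si, Ti, V, Zn) — together with a continuous
health outcome and confounders. Two questions dominate: *which* components
of the mixture drive the outcome, and *what shape* does the joint
exposure–response take, including nonlinearities and interactions?
`softmix` answers both with one model, at a computational cost that scales
to cohort-sized datasets where Gaussian-process approaches (e.g. BKMR)
become impractical.

## The model

For outcome $Y_i$, exposures $Z_i \in \mathbb{R}^M$ and confounders
$X_i \in \mathbb{R}^d$:

$$Y_i = h(Z_i) + X_i^\top \beta + \varepsilon_i, \qquad
\varepsilon_i \sim N(0, \sigma^2),$$

with a **SoftBart** prior (Linero & Yang, 2018) on the surface:
$h(z) = \sum_{t=1}^{T} \mathrm{Tree}(z;\mathcal{T}_t,\mathcal{M}_t)$, where
each tree routes an input through logistic gates
$\psi\big((C_b - z_{j_b})/\tau\big)$ rather than hard indicators, so $h$ is
smooth, and hard BART is the $\tau \to 0$ limit. Sparsity comes from a
Dirichlet prior on the split-variable probabilities
$s \sim \mathrm{Dir}(a/M,\dots,a/M)$, $a/(a+M)\sim\mathrm{Beta}(0.5,1)$:
exposures that do not earn splits are starved of them, and the posterior
inclusion probability (PIP) of exposure $m$ — the fraction of MCMC draws in
which $m$ appears in at least one split — drives selection at the usual 0.5
threshold. Effects are reported as partial-dependence curves and surfaces
with pointwise credible intervals and sup-norm simultaneous credible bands.

Posterior computation is Bayesian backfitting MCMC with leaf values
integrated out analytically in every tree move; hot loops are
numba-compiled, and a full 20,000-draw chain at $n=1000$, $M=3$, $T=30$
takes on the order of a minute on one core. See `docs/methods.md` for the
complete prior and sampler specification.

## Worked example

Simulate a three-exposure mixture (case 2 of the built-in simulation
designs: all three exposures active, correlations 0.1/0.3/0.7, two
confounders, residual variance 0.5), fit, and summarize:

```bash
softmix simulate --case 2 --n 200 --seed 7 --out mix.csv
softmix fit --data mix.csv --exposures Z1,Z2,Z3 --confounders X1,X2 \
        --config cfg.yaml --seed 17 --out draws.json   # cfg: total_draws: 4000
softmix summarize --draws draws.json --effect pip  --out pip.csv
softmix summarize --draws draws.json --effect main --vars Z1 --out eff.csv
```

The fit reports

```
retained 500 draws; structure acceptance 0.105; posterior mean sigma2 0.5756
```

— the posterior mean of $\sigma^2$ (0.58) is close to the generating value
0.5. `pip.csv` shows every exposure correctly selected in this dense case:

```
exposure,pip,selected
Z1,1.0,True
Z2,1.0,True
Z3,1.0,True
```

and `eff.csv` tabulates the centered main effect of Z1 on a 50-point
quantile grid with its interval and band, e.g. at $z_1 \approx -2.0$ the
posterior mean is $-1.21$ with 95% pointwise interval $(-2.12, -0.58)$ and
simultaneous band $(-2.36, -0.06)$ — the band is wider than the interval,
as it must be. The same library calls are available in Python
(`run_mcmc`, `main_effect`, `interaction_effect`, `conditional_effect`,
`compute_pip`), and `softmix study` runs the full replicate
simulation-study harness (`run_simulation_study`) that scores estimation
accuracy, interval/band lengths, band coverage and PIPs against the known
truth.

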