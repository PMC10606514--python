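# itc-uq

Uncertainty quantification for 1:1 binding parameters estimated from
isothermal titration calorimetry (ITC) integrated-heat curves.

ITC experiments titrate a ligand solution (syringe concentration [L]s) into
a cell containing a receptor (concentration [R]0) and record the heat of
each injection. Nonlinear regression of the resulting heat curve yields the
binding free energy ΔG and enthalpy ΔH — but how trustworthy are the error
bars? The widely used asymptotic standard error (ASE) from least squares
treats the titrant concentration as exactly known, even though
inter-laboratory titrant errors of 5–20% are common, and so it can
understate the uncertainty dramatically.

This package implements and compares three interval procedures:

* **BCI** — Bayesian credible intervals: the shortest interval containing
  X% of MCMC samples from the posterior p(θ|D) ∝ p(D|θ) p(θ), with
  θ = (ΔG, ΔH, ΔH0, [R]0, [L]s, σ), uniform priors on the energies,
  lognormal priors on both concentrations (relative scale δ), and a
  Jeffreys prior p(σ) ∝ 1/σ;
* **ASE** — normal-theory intervals θ̂ ± z·s from the maximum-likelihood
  fit, with s from the inverse observed Fisher information;
* **ASE+EP** — the ASE inflated by first-order error propagation of the
  titrant-concentration error,
  (s_θ/θ)² = (s_ASE/θ)² + (s_[L]s/[L]s)², applied to ΔG and ΔH.

It also ships the simulation machinery to *test* these procedures: a
generator of synthetic heat curves with lognormal concentration error and
Gaussian heat noise, and coverage analysis (nominal level vs. observed
fraction of intervals containing the truth, with bootstrap error bars).
Calibrated procedures lie on the diagonal of the coverage plot; on the
reference design the BCI does, the ASE falls far below it for ΔH, and
ASE+EP overshoots for ΔG.

## The model

For injections n = 1..N with volumes v_n into a cell of volume V0, the
cumulative dilution is d_n = Π_{i≤n}(1 − v_i/V0), giving total
concentrations R_n = [R]0·d_n and L_n = [L]s·(1 − d_n). With
Ka = exp(−ΔG/RT), the 1:1 complex concentration [RL]_n solves the
mass-action quadratic (evaluated in a cancellation-safe form), and the
expected injection heat is

    q_n* = Q_n − (1 − v_n/V0)·Q_{n−1} + ΔH0,   Q_n = V0·ΔH·[RL]_n,  Q_0 = 0.

Observed heats are q_n ~ N(q_n*(θ), σ²).

## Worked example

```python
import numpy as np
from itc_uq import (SimulationDesign, simulate_dataset, fit_mle, EpSpec,
                    propagate_error, PriorSpec, McmcConfig, sample_posterior)

design = SimulationDesign(n_curves=1, seed=7)     # ΔG=-10, ΔH=-5 kcal/mol,
ds = simulate_dataset(design)                     # 10% concentration error
curve, truth = ds.curves[0], ds.truths[0]

fit = fit_mle(curve)
se = fit.ase("dH")
se_ep = propagate_error(fit.theta_hat.dH, se, EpSpec(rel_err_Ls=0.10))
print(f"dH_hat = {fit.theta_hat.dH:.3f}  ASE = {se:.3f}  ASE+EP = {se_ep:.3f}")

prior = PriorSpec(stated_R0=0.1, stated_Ls=1.0, conc_rel_uncertainty=0.10)
cfg = McmcConfig(n_warmup=500, n_samples=1000, n_chains=4, thin=5, seed=3)
samples = sample_posterior(curve, prior, cfg)
iv = samples.credible_interval("dH", 0.95)
print(f"true dH = {truth.dH:.3f}  95% BCI = ({iv.lower:.3f}, {iv.upper:.3f})")
```

prints

```
dH_hat = -5.717  ASE = 0.041  ASE+EP = 0.573
true dH = -5.000  95% BCI = (-5.829, -4.527)
```

The realized true titrant concentration here is ~15% above its stated value,
so the least-squares ΔH estimate is off by ~0.7 kcal/mol — seventeen times
its asymptotic standard error (the ASE interval misses the truth badly).
Error propagation widens the 95% band to ±1.1 kcal/mol, and the Bayesian
credible interval, which carries the concentration uncertainty through the
priors, contains the truth.

A command-line interface wraps the same functionality
(`itc-uq simulate | fit-mle | fit-bayes | coverage | compare-figure |
pipeline`); run `itc-uq --help`.

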