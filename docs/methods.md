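# Methods

## Observation model

An integrated heat curve is D = (q_1, …, q_N), one heat per injection, in
cal (displayed as µcal). The deterministic forward model maps
θ = (ΔG, ΔH, ΔH0, [R]0, [L]s, σ) and an injection schedule to expected
heats q_n*(θ) for simple 1:1 binding:

* cumulative dilution d_n = Π_{i≤n}(1 − v_i/V0) for injection volumes v_i
  into a cell of volume V0 (constant-volume cell: each injection displaces
  its own volume);
* total concentrations R_n = [R]0 d_n, L_n = [L]s (1 − d_n);
* complex concentration [RL]_n from mass action,
  Ka([R]_tot − RL)([L]_tot − RL) = RL with Ka = exp(−ΔG/RT), evaluated as
  2RL/(S + √(S² − 4RL_tot-product)) with S = R + L + 1/Ka to avoid the
  catastrophic cancellation of the textbook quadratic root at high affinity
  (verified against a bracketed bisection oracle to 1e−10 relative across
  six orders of magnitude in Ka);
* injection heat q_n* = Q_n − (1 − v_n/V0) Q_{n−1} + ΔH0 with
  Q_n = V0 ΔH [RL]_n and Q_0 = 0; the carryover term accounts to first
  order for bound material displaced from the cell.

Observed heats are independent N(q_n*, σ²); the stoichiometry is fixed at
1:1 (no free site-number parameter).

Units are converted at exactly one place (inside the forward model):
energies kcal/mol, concentrations mM, volumes mL/µL, heats cal,
R = 1.9872×10⁻³ kcal/(mol·K). Default instrument geometry is a MicroCal
VP-ITC-style cell, V0 = 1.43 mL, 24 × 10 µL injections, 298.15 K — all
configurable. No special treatment of the first injection (a discard flag
can be emulated by editing the curve; none is applied by default).

## Synthetic data

The simulator emulates the calibration study the package is built to run:
fixed thermodynamic truth (ΔG = −10 kcal/mol, ΔH = −5 kcal/mol,
ΔH0 = 0.5 µcal), *true* concentrations drawn per curve from lognormal
distributions whose arithmetic mean equals the stated values (0.1 mM cell,
1.0 mM syringe) and whose coefficient of variation is the concentration
error level (5% or 10%, the range reported for inter-laboratory titrant
errors), and i.i.d. Gaussian heat noise (σ = 1 µcal) on every injection
including the first. The lognormal is parameterized by moment inversion:
s² = log(1 + cv²), µ = log(mean) − s²/2.

Fitters only ever see the *stated* concentrations; realized truths are kept
on a parallel structure used solely for coverage scoring. A master seed
spawns one child stream per curve, so datasets are bit-reproducible and
single curves can be regenerated in isolation.

What the simulator does **not** emulate: baseline/integration error in the
raw power trace, correlated or heteroscedastic injection noise, systematic
concentration bias (the lognormal is centered on the stated value), and
active-site fractions ≠ 1. Passing coverage tests therefore demonstrate
calibration *under the stated error model*, not robustness to these
real-data effects.

## Bayesian regression

Priors (independent): uniform on ΔG ∈ [−40, 0], ΔH ∈ [−100, 100] kcal/mol,
ΔH0 ∈ [−1, 1] cal — wide enough to be uninformative at the scale of real
titrations while keeping the sampler bounded; lognormal on both
concentrations, centered on the stated values with relative scale δ (the
analyst's concentration uncertainty, matching the simulator's
parameterization); Jeffreys p(σ) ∝ 1/σ, made proper as a flat density on
log σ over [log 10⁻⁸, 0] (σ in cal). σ0 = 1 cal only fixes units.

Sampling runs in the unconstrained space (ΔG, ΔH, ΔH0, ln[R]0, ln[L]s,
ln σ), where the concentration priors are Gaussian and the Jeffreys prior is
flat. The sampler is the affine-invariant ensemble method (emcee) with
differential-evolution and snooker moves (80/20 mix), which mix markedly
faster here than the default stretch move (integrated autocorrelation ~30
vs. ~90 ensemble iterations on the prior). A "chain" is an independent
16-walker ensemble: `n_warmup` whole-ensemble moves are discarded, then
`n_samples` draws per chain are stored (optionally thinned by whole
iterations). Defaults are 2000 warm-up moves and 10,000 stored draws from
each of four chains. Posterior runs initialize the walkers around a quick
maximum-likelihood fit with the unidentified syringe-concentration direction
dispersed over its full prior; prior-only runs (a test hook that switches
the likelihood off) start from exact prior draws.

Credible intervals pool all chains and return the *shortest* contiguous
window containing ⌈level·M⌉ sorted draws (the sample HPD interval; verified
against exhaustive window enumeration). Convergence is summarized by
split-R̂ per parameter (threshold 1.01) plus running 2.5/50/97.5 percentile
traces versus fraction of draws used. Because the data identify only the
titrant:titrand ratio, the marginal posterior of [L]s is set by the two
concentration priors alone; its SD is prior_SD/√2 (the ratio constraint
pools the two iid priors), a useful sanity check that the sampler has not
invented information.

## Maximum likelihood, ASE, and error propagation

The MLE maximizes the same Gaussian log-likelihood. Because of the ratio
degeneracy, the default fit follows the standard procedure's assumption:
[L]s is fixed at its stated value and (ΔG, ΔH, ΔH0, [R]0, σ) are fit
(`fix_Ls=False` frees it, accepting the flat direction). The mean
parameters are solved by least squares (two-stage, tight tolerances); σ
then has the closed-form profile maximizer σ̂² = SSR/N, making the joint
optimum exact. Starts: concentrations at stated values, ΔH0 from the
post-saturation tail, ΔH from the total heat, ΔG at −9 kcal/mol.

The ASE covariance is the inverse of the negative log-likelihood Hessian at
the maximizer, by symmetrized central finite differences with relative step
10⁻⁴ and an absolute floor of 10⁻⁶ *per parameter scale* (energies
1 kcal/mol; concentrations the stated values; ΔH0 and σ the fitted σ). A
single absolute floor would be larger than the cal-scale parameters
themselves and push σ negative. A positive-definiteness check names the
offending parameter directions on failure. A `strict_printed_form` flag
additionally divides the Hessian by N before inversion (scaling the
covariance by N) for comparison with that alternative convention; the
standard observed-information form is the default and is what reproduces
classical nonlinear-least-squares standard errors.

Error propagation applies (s_θ/θ)² = (s_ASE/θ)² + (s_Ls/Ls)² to ΔG and ΔH
only, using |θ̂| in the relative terms (the estimates are negative); an
optional receptor term adds (s_R0/R0)² in quadrature. The result is clamped
to ≥ s_ASE so rounding can never undercut the plain ASE. Normal-theory
intervals are θ̂ ± z·s with z the standard-normal quantile at (1+level)/2.

## Coverage validation

For each method, parameter, and nominal level, observed coverage is the
fraction of curves whose interval contains the per-curve realized truth
(simulated data) or a proxy truth (for replicate experimental datasets: the
pooled median of per-curve posterior medians, configurable). Bootstrap SDs
resample curves — not injections — with replacement (coverage is a
per-curve Bernoulli outcome; 100 resamples by default). The default level
grid is 10–95% in 5% steps. Figures: per-method 95%-interval panels with
the proxy truth marked, and nominal-vs-observed coverage plots with the
diagonal as the calibration reference.

## Study sizes and numerical choices in the test suite

The shipped calibration study uses 100 simulated curves at the 10%
concentration-error design with 4 chains × 1000 stored draws (thin 5,
500 warm-up moves) per curve — sizes chosen so the whole suite runs in a
few minutes while keeping the binomial noise on a 95% coverage estimate at
±2.2 points (1 SE). At these sizes the 95% BCI coverage of ΔG and ΔH sits
within ±6.5 points of nominal, the ASE under-covers ΔH at every level
≥ 50%, and ASE+EP never covers less than ASE.

Known limitations:

* The MLE σ̂ = √(SSR/N) carries the standard small-sample bias
  E[σ̂] ≈ σ·√((N−p)/N); at N = 24 with p = 4 mean parameters the
  Monte-Carlo mean of σ̂ is ~0.90 µcal for σ = 1 µcal. The package reports
  the MLE as defined rather than a bias-corrected variant.
* Mid-level (30–70%) BCI coverage runs a few points below the diagonal at
  the shipped run sizes for fixed-truth energies; the 95% level and the
  method ordering are unaffected.
* Heats are stored in files in µcal; the display-unit conversion costs at
  most 1 ulp on a round trip.
* Only 1:1 stoichiometry; no competitive or multi-site models; no raw
  power-trace processing.
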