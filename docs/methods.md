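# Methods

## The model

Each breeding population is described by a scalar stochastic
exponential-growth (lognormal diffusion) state process on annual time steps,

    log N[t+1] = log N[t] + r[t],        r[t] ~ Normal(rbar, sigma_r^2),

with `rbar` the mean growth rate and `sigma_r` the process (temporal)
variation in growth — the biological year-to-year variability that survives
after survey sampling error is accounted for.  The observation model links
the latent abundance to the detection-adjusted aerial estimate `y[t]`, whose
sampling SE `se[t]` is treated as known data:

    constant detection:    y[t] ~ Normal(N[t],        se[t])
    latent VCF variants:   y[t] ~ Normal(N[t] / d[t], se[t])

The visibility-correction-factor (VCF) deviation `d[t]` captures unmeasured
year-to-year variation in aerial detectability, with

    log d[t] ~ Normal(x[t] * log(beta), sigma_d),
    sigma_d ~ Gamma(1, 10),      (beta - 1) ~ Gamma(15.5, 9),

where `x[t]` flags the single YKD year surveyed by a new observer (2015) and
`beta` is that observer's multiplicative undercount ratio.  Years without a
usable survey (YKD 2011; 2015 in the masked configuration) carry no
observation term; the state process still propagates through them, so their
abundance is estimated with appropriately wider uncertainty.

Conventions worth stating because the source material for this analysis is
ambiguous about them:

- **Division convention for `d[t]`.**  The observation mean is `N[t]/d[t]`,
  so a *positive* log-deviation means *fewer* birds were seen than were
  present.  A multiplicative rendering is recovered by negating `log d[t]`.
- **Observer effect on the ratio scale.**  `beta` is the natural-scale
  nest-to-aerial abundance ratio (prior mean ≈ 2.72, calibrated from the
  2015 nest census 15,584 ± 2,472 against the aerial estimate 5,714 ± 494,
  ratio 2.73 ± 0.49 by first-order error propagation), and the 2015
  log-deviation mean is `log(beta)`.  Placing `beta` itself on the log scale
  would imply an implausible ~15-fold undercount.
- **Priors on standard deviations.**  The Gamma(shape, rate) priors for
  `sigma_r` and `sigma_d` are on the SDs, not variances.
- The observation density is an untruncated Normal on the natural scale;
  estimates are far from zero relative to their SEs, so truncation is
  immaterial.

Six stock configurations are provided: ACP1/YKD1 (constant detection,
informative priors: log N_2007 ~ Normal(8.78 or 9.43, 0.1), rbar ~
Normal(0, 0.1), sigma_r ~ Gamma(3, 20)); YKD2 (diffuse: SDs 0.5, 0.5 and
sigma_r ~ Gamma(3, 2)); YKD3 (informative, 2015 masked); ACP2 (latent VCF);
YKD4 (latent VCF plus observer effect).

Under the division convention the latent-VCF configurations converge to
posteriors close to the masked-2015 configuration (the observer effect
absorbs the 2015 anomaly), with small `sigma_d`.  Published analyses of
this system report wider intervals for these two configurations; because
the algebraic placement of `d[t]` and `beta` admits more than one reading,
results for ACP2/YKD4 should be interpreted qualitatively (direction of the
risk comparison), not as point reproductions.  The constant-detection
configurations are unambiguous.

## Sampling

Posteriors are drawn by an adaptive Metropolis-within-Gibbs sampler written
directly on the model's log-density, vectorized across chains:

- single-site Gaussian random-walk updates of each `log N[t]`, scheduled as
  an even/odd checkerboard so all sites of one parity update simultaneously;
- two global moves that decorrelate the latent path from `rbar`: a level
  shift (all `log N[t]` plus a common δ) and a trend tilt
  (`log N[t] += δ·t`, which shifts every growth increment by δ);
- a conjugate Gibbs draw for `rbar` (Normal prior × Normal increments);
- log-scale random-walk updates for `sigma_r` and `sigma_d` (with Jacobian),
  and for `beta` on `log(beta - 1)`;
- Metropolis updates of `log d[t]` at surveyed years; at unsurveyed years the
  full conditional is the prior, which is drawn exactly.

Proposal scales adapt by Robbins–Monro (step `k^-0.6`) toward 44%
acceptance during a dedicated adaptation phase (default 5,000 iterations,
all discarded) and are frozen afterwards, so the retained chain is a valid
time-homogeneous Markov chain.  Default run lengths are the study settings:
3 chains × 100,000 iterations, 70,000 burn-in, thinning 2 (15,000 retained
draws per chain).  Chains initialize at the log of the observed estimates
(linearly interpolated across gaps), `rbar` at its prior mean and the scale
parameters at theirs, with a small per-chain jitter so the Gelman–Rubin
diagnostic starts from distinct states.  All chains advance in lock-step
from a single seeded generator; runs are reproducible bit-for-bit.

Convergence is monitored with the classic (non-split) Gelman–Rubin
statistic, computed on pooled post-burn-in retained draws per chain; a
warning is emitted whenever any monitored parameter has R̂ ≥ 1.01.  At the
default settings all six configurations reach R̂ < 1.01.  Credible
intervals are equal-tailed 2.5/97.5 percentiles with linear interpolation
between order statistics (numpy's default convention), fixed and documented
here so summaries are stable across versions.

The sampler was checked three ways: the joint density agrees with an
independent term-by-term computation to 1e-10; posterior summaries for the
constant-detection configurations reproduce independently published fits of
the same data; and simulation-based calibration on synthetic data (below)
yields nominal coverage and uniform rank statistics.

## Projection and decision analysis

Extinction risk as a function of the unknown mean growth rate `rs` is
estimated by Monte Carlo: for each of 81 grid values on [-0.4, 0.4] (step
0.01, resolving the curve's sigmoid), 10,000 replicates each draw an
initial abundance (final observed year) and `sigma_r` from the posterior —
jointly, from the same posterior iteration, preserving their correlation; a
switch allows independent draws — then project

    log N[t+1] = log N[t] + r',      r' ~ Normal(rs, sigma_r)

for 50 years.  A replicate is quasi-extinct if N drops below 250 breeding
birds in any projected year; the starting state itself is not checked, so a
population below 250 at t=0 is not automatically extinct.  Trajectories are
continuous (no demographic stochasticity or rounding) and the annual shocks
are independent — a pure lognormal random walk.

The underprotection loss (cost of delisting a declining population) equals
the quasi-extinction probability at `rs` for `rs < 0` and is exactly zero
for `rs >= 0`; the overprotection loss is its mirror image, `over(r) =
under(-r)`.  The hard zero at `r = 0` follows the recovery-plan definition
and creates a deliberate discontinuity: extinction risk just above zero
growth is small but not zero, and that residual risk is not charged to
either action.  Expected loss (misclassification risk) for each action is
the Monte-Carlo average of the loss over posterior draws of `rbar`, with
linear interpolation between grid points and clamping beyond the grid ends;
draws exactly at 0 fall in the overprotection region.  Averaging over draws
evaluates the same integral as discretizing the posterior into bins, without
a binning convention.

The delisting recommendation requires both criteria: lower 95% CRI of
final-year abundance ≥ 12,000 breeding birds (6,000 pairs; 1 pair = 2
birds throughout) and overprotection risk strictly exceeding
underprotection risk (ties fail).  The alternative abundance-only criteria
set (≥ 10,000 pairs at the lower CRI in ≥ 3 surveys, or ≥ 25,000 pairs in
any survey, both inclusive) is evaluated separately.  Reclassification to
endangered is represented as an action but carries no loss function.

## Synthetic data

The generator simulates exactly the generative model above: lognormal
growth, Normal observation error with known SE, optional latent detection
deviations and a one-year observer ratio, 13-year span by default with
defaults of the magnitude seen in the study system (initial abundance
12,000, observation SE 1,100, `sigma_r` 0.15, stable trend).  A
non-positive observation draw is redrawn and logged, keeping fixtures valid
at a negligible distortion for realistic SEs.  What the generator does not
emulate: spatial structure, survey-design effects, autocorrelated
detection, density dependence, or non-Normal observation error — so passing
recovery tests demonstrate correctness of the inference machinery under the
model's own assumptions, not robustness of the model to real-world
violations of them.

Calibration testing draws generating parameters from the fitting priors,
simulates, refits, and checks (i) that the truth lies within two posterior
SDs of the posterior mean at roughly the nominal rate and (ii) that the
rank of the truth among thinned posterior draws is uniform
(Kolmogorov–Smirnov).  One hundred replicates are used at shortened chain
lengths (2 chains × 3,000 iterations); the replicate count, not the chain
length, dominates the stability of the coverage estimate.

## Numerical and design choices

- Sampler engine: any correct MCMC is acceptable by contract; correctness is
  pinned by the density oracle, prior-recovery, calibration and
  reproducibility tests rather than by the engine's identity.
- Degenerate inputs: non-positive scale parameters passed to the density are
  coding errors and raise, rather than returning -inf (which would silently
  masquerade as a rejected proposal).
- `sigma_r -> 0` with unequal increments drives the density to -inf
  naturally; the Gamma priors keep the sampler away from the boundary.
- The rs grid and loss grids are symmetric about 0 by construction so the
  mirror identity is exact, grid point by grid point.
- The prior for `sigma_d` implies a median absolute log-deviation of about
  0.038 (reported as 0.04 at two decimals) and a 98th-percentile near 0.44,
  by both Monte Carlo and direct quadrature of
  P(|log d| < c) = E_sigma[2 Phi(c/sigma) - 1].
- Problem sizes: the full assessment (13 annual observations, ≤ 20 free
  parameters per model) fits in seconds per chain; the projection grid
  evaluates 81 × 10,000 × 50 lognormal steps vectorized.  Tests that refit
  repeatedly use shortened chains; all headline reproductions run at the
  full study settings.

## Known limitations

- The latent-VCF observation algebra is a documented interpretation (see
  above); alternative placements of `d[t]`/`beta` would change ACP2/YKD4
  point estimates though not the qualitative decision outcome.
- The classic Gelman–Rubin statistic is used (not split-R̂); with 15,000
  retained draws per chain and these small models the distinction is
  immaterial, but slowly-mixing halves of a single chain would not be
  detected.
- Expected-loss integrals inherit Monte-Carlo error from both the extinction
  curve (binomial, ≤ 0.005 per grid point at 10,000 replicates) and the
  posterior draws; reported risks are stable to about ±0.01 across seeds.
- No model selection is performed; the six configurations are compared
  descriptively.
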