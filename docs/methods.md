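# Methods

## The scientific problem

Accelerometer studies of clinical cohorts typically summarize activity as
weekly averages, discarding the day-to-day structure of the repeated
measurements. This package models that structure directly for two
complementary movement behaviors — daily sedentary behavior (SB) and
physical activity (PA) minutes — asking (i) whether a person's deviation
from their own typical level on one day predicts their deviation the next
day (autoregression), (ii) whether yesterday's PA predicts today's SB and
vice versa (cross-lagged effects), and (iii) whether person-level symptom
burden (pain, fatigue, well-being on a 0–10 numeric rating scale)
moderates any of these person-specific dynamics.

## Accelerometer preprocessing

Vertical-axis counts recorded in 10 s epochs are summed to 60 s epochs
(counts per minute, cpm). Non-wear time is any window of at least 60
minutes in which every count is ≤ 100 cpm and at most 2 minutes carry
counts in (0, 100]; any count above 100 terminates all windows through
it. Formally, a minute is non-wear iff it lies inside *some* qualifying
window — this is the only reading under which a 60+ minute low run with
three interior low-count minutes correctly splits into two sub-threshold
runs and stays wear. The allowance minutes count toward window length and
toward non-wear time. Wear minutes below 100 cpm are classified SB, at or
above 100 cpm PA; daily totals are minutes of each. A day is valid at
≥ 500 wear minutes; a participant enters the analysis with ≥ 4 valid days
of which at least one is a Saturday or Sunday. Days are bounded by local
calendar midnight; leading/trailing partial days are processed as-is and
handled by the validity rule; trailing partial minutes are dropped, never
zero-padded. All thresholds are parameters with these values as defaults.

## The model

For person *i* on day *t*, observed minutes decompose into a latent
person mean and a within-person deviation:

    SB_it = mu_sb,i + w_sb,it        PA_it = mu_pa,i + w_pa,it

The deviations follow a person-specific bivariate VAR(1),

    w_sb,it = phi_sb,i w_sb,i,t-1 + beta_sb,i w_pa,i,t-1 + zeta_sb,it
    w_pa,it = phi_pa,i w_pa,i,t-1 + beta_pa,i w_sb,i,t-1 + zeta_pa,it

with independent Gaussian innovations of person-specific variances
psi_u,i = exp(lambda_u,i). beta_sb is the coefficient *in the SB
equation* (previous-day PA → next-day SB). The eight person effects
u_i = (mu_sb, mu_pa, phi_sb, phi_pa, beta_sb, beta_pa, lambda_sb,
lambda_pa) are random at the between level:

    u_i = gamma0 + gamma1 (P_i - Pbar) + residual

with the predictor P_i grand-mean centered, residuals independent across
effects except for one covariance sigma_mu between the two person means,
and residual variances tau_u. The innovation covariance is diagonal
within person (no within-level residual covariance is modeled), and only
the (mu_sb, mu_pa) between-level covariance is carried. The first
observed day of each person follows the person-specific stationary
distribution of the VAR (the discrete-Lyapunov solution
V = A V A' + Psi); when a draw is non-stationary the initial law falls
back to a diffuse N(0, 1e6 I). Missing days are missing-at-random and
imputed as latent states.

## Estimation

Metropolis-within-Gibbs MCMC; defaults are 50,000 iterations per chain,
the first half burn-in, thinning 10, two chains. The sweep:

1. **Person dynamics** (phi, beta per equation): a conjugate Gaussian
   regression of deviations on lagged deviations is the proposal; it is
   accepted under the conditional with the person's bivariate mean
   integrated out analytically (the initial-state density depends on the
   dynamics, and at T = 7 the mean and the autoregression lie on a
   curved ridge — collapsing the mean is what lets the chain cross it).
2. **Person means**: the mean-block regression coefficients are drawn
   from their Gaussian conditional with *all* person means integrated
   out, then each person's (mu_sb, mu_pa) from its exact bivariate full
   conditional. Everything here is jointly Gaussian given the dynamics.
3. **Log innovation variances**: coordinate-wise adaptive random-walk
   Metropolis (step tuned toward 30–50% acceptance during burn-in, then
   frozen to preserve detailed balance), target including the
   initial-state term.
4. **Missing-day states**: Gaussian full conditionals, refreshed in two
   day-parity blocks so adjacent missing days never update together.
5. **Between level**: conjugate Gaussian draws of (gamma0, gamma1) per
   effect; conjugate variance draws (see priors); the mean-block
   residual covariance by conjugate inverse-Wishart.
6. **Interweaving and ridge moves** (all exact MCMC for the same
   posterior; Metropolis corrections use the exact initial-state and
   between-level ratios): a collapsed redraw of the dynamics fixed
   effects with person effects integrated out of the transition
   likelihood; rescaling draws of the dynamics random-effect SDs in the
   non-centered parameterization; intercept-shift, slope-shift and
   SD-rescale moves for the log-variance effects; a joint shift of all
   person autoregressions with compensating log-variance adjustment
   that walks the population-level persistence/variance trade-off (two
   step scales); and a random-walk update of the person-mean covariance
   with the person means integrated out (log-variance/atanh-correlation
   coordinates, parameterization Jacobian included), after which the
   means are redrawn exactly. Without these moves, chains on 41 × 7
   panels stall in the classic tau → 0 funnel, on the persistence ridge,
   and in a bistable trade-off between person-mean variance and
   persistence (potential scale reductions of 1.4–4); with them, all
   fixed effects converge within a few thousand iterations on every
   tested replicate.

**Priors** (all configurable): N(0, 1e6) on regression coefficients,
N(0, 1e8) for the min/day-scaled mean intercepts; flat-on-SD priors on
the scalar random-effect variances (conjugate inverse-gamma((N−1)/2,
SSE/2) update) and the Jeffreys prior on the person-mean covariance
block (conjugate inverse-Wishart(R, N) update). The often-used
IG(0.001, 0.001) / IW(I, p+1) pair is available as an option but is not
the default: in recovery experiments at N = 41, T = 7 it under-estimates
the person-mean variances by roughly 40% and biases the autoregressive
fixed effects upward by ~0.15 — over-shrunk person means leak into the
deviations as common offsets that masquerade as persistence. With the
default priors, pooled 95%-interval coverage of the eight fixed effects
in 20-replicate recovery runs is ≈ 0.92.

**Single-cluster oracle mode.** `FitConfig(random_effects=False)` ties
all person effects to the between-level intercepts (the tau → 0 limit)
and updates them by pooled conjugate regression; with a long single
series its posterior means of phi and beta agree with conditional least
squares to ±0.02, which the test suite checks.

**Convergence** is monitored by the potential scale reduction
sqrt((W + B)/W), W the mean within-chain variance and B the variance of
chain means — identically equal to 1 for identical chains — with a
split-chain fallback for single-chain runs; flag threshold 1.1.

**DIC** uses the conditional deviance: D(theta) = −2 log p(observed days
t ≥ 2 | person effects, latent states), DIC = D̄ + pD, pD = D̄ − D(thetâ)
at the posterior means of person effects and states. The first observed
day is conditioned on rather than scored, so DIC values are comparable
across models fit to the same panel but are not on the same scale as
implementations using other deviance definitions.

## Reporting and standardization

Point estimates are posterior medians (means also emitted); intervals
are 95% equal-tail; one-tailed p = min(share of draws below 0, above 0);
"significant" means the interval excludes 0. Standardization uses
model-implied stationary moments rather than 7-day sample moments (which
are noise-dominated): per draw and person, V_i solves the discrete
Lyapunov equation and

    std phi = phi,  std beta_sb = beta_sb sqrt(V_pa/V_sb),
    std beta_pa = beta_pa sqrt(V_sb/V_pa),
    std zeta_u = psi_u / V_u,  within R^2_u = 1 − std zeta_u,

averaged across persons per draw; non-stationary person-draws are
excluded from that draw's average and the exclusion rate is reported.
Note std phi is the raw phi (the lagged variable shares the outcome's
stationary SD); for a bivariate system a stable draw can therefore carry
std phi slightly outside (−1, 1) through cross-lag compensation — such
draws are retained, not clipped. Between-level effects are standardized
as gamma1 SD(P)/SD(u) with SD(u)^2 = gamma1^2 Var(P) + tau_u; the
person-mean covariance is reported as the residual correlation
sigma_mu / sqrt(tau_mu_sb tau_mu_pa); between R^2_u =
gamma1^2 Var(P)/SD(u)^2. Antipersistence is the share of persons whose
posterior-mean standardized autoregression is negative. Day-wise
descriptives report across-person mean ± SD of wear/SB/PA minutes, the
SB share of wear both as mean of person ratios and as ratio of means
(the two differ and neither is canonical), and the day-wise SB–PA
Spearman correlation (average ranks; two-sided t-approximation p).

## The synthetic cohort

Because the underlying participant data are not public, a generative
stand-in defines the study conditions. The epoch simulator emits Poisson
counts (level/6 per 10 s epoch) inside configured wear bouts and exact
zeros elsewhere, with ground-truth wear labels, so non-wear detection
can be scored exactly. The panel simulator draws person effects from the
between model (rejecting non-stationary lag matrices — at the default
truth the rejection rate is ~0.06%, so the induced truncation is
negligible), starts each person at their stationary distribution, and
iterates the within equations. Defaults are 41 persons × 7 days with
fixed effects near plausible cohort values (means 460/245 min/d,
phi 0.18/0.05, beta −0.01/−0.02, log psi 9.10/8.12), random-effect
variances of similar magnitude to those a cohort of this size exhibits,
person-mean residual correlation −0.56, and a pain-like predictor
N(1.9, 2.4) clipped to the 0–10 scale (slopes default to zero, so
clipping cannot distort recovery checks). Simulated minutes are
real-valued Gaussian draws and deliberately not truncated to [0, 1440]:
the fitted model is Gaussian and truncation would bias recovery.

What the generator does *not* emulate: day-of-week structure, wear-time
heterogeneity correlated with activity, non-Gaussian day totals, device
artifacts, or informative missingness. Passing recovery tests therefore
demonstrates correctness of the estimator under the model's own
assumptions, not robustness to their violation in real cohorts.

## Problem sizes and numerical choices

The test suite runs recovery at the study's own scale (41 × 7) over 20
replicates with 5,000 iterations thinned by 5 per chain, two chains —
chosen so the full calibration completes in minutes while every fixed
effect still passes the 1.1 PSR threshold; production analyses use the
50,000/10 defaults. The long-series oracle checks use T = 2,000 with
dynamics well inside the stationary region. Lyapunov systems are solved
by the symmetric 3×3 reduction in closed form (residuals < 1e-10);
2×2 conditionals use explicit inverses and Cholesky factors. Ties in
Spearman ranks use average ranks; correlations are reported as undefined
(NaN) for days with fewer than 3 observed persons or zero variance.
All randomness flows from a single seed through spawned generators, so
identical inputs, configuration and seed reproduce every output file
byte-for-byte (manifests contain no timestamps).

## Known limitations

* Seven days per person identify within-person dynamics weakly; the
  posterior for phi is wide and its small-sample skew, though greatly
  reduced by the default priors, does not vanish entirely.
* The DIC definition is conditional; comparisons with other software's
  deviance values are not meaningful.
* One lag, two outcome series, time-invariant predictors, no
  measurement-error layer — by design.
* The wear-protocol allowance is counted cumulatively per window (the
  protocol literature does not fix cumulative vs consecutive); this is
  configurable.
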