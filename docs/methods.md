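# Methods

## Task generative model

A session is 201 two-stage trials. Stage-1 action *k* leads to stage-2
state *k* ("common", probability `p_common = 0.7`) or to the other
state ("uncommon"); the common mapping is fixed to the identity —
arbitrary, but constant and documented. Each of the four stage-2
options pays 0/1 reward with a probability evolving as an independent
Gaussian random walk (step SD 0.025) folded into [0.25, 0.75] by exact
boundary reflection (`lo + fold((x − lo) mod 2w)`, which equals the
single-reflection rule `2·hi − x` whenever a step crosses one boundary
once, and remains correct for arbitrarily large steps). Walk initial
values default to a uniform draw in the band and can be pinned for
deterministic tests. Missed trials are generated by an independent
Bernoulli(`miss_rate`, default 0), carry no choices, trigger no
learning update and are excluded from every downstream analysis;
response deadlines (2 s) and monetary magnitude (0.2 per reward) are
presentation-level constants that never enter the model. Trials are
0-based internally and in the CSV interchange format; sessions are
1-based.

The second stage is modelled Daw-style as a genuine choice between two
options per state (four independent walks). The instructed transition
probabilities are used directly by the model-based valuation and are
not learned; a transition-learning agent was considered out of scope
for the likelihood but the valuation routine accepts any `p_common`.

## Hybrid agent

Stage-1 logits: `bMB·Q_MB(a) + bMF·Q_TD(a) + p·1[a = prev]`, with the
perseveration indicator coded {0, 1} on the previous valid trial's
stage-1 action (absent on the first trial). Stage-2: softmax over
`β₂·Q₂(s, ·)`. Updates (SARSA(λ)):

```
δ₁ = Q₂(s₂, c₂) − Q₁(c₁)        (pre-update Q₂)
Q₁(c₁) += α₁·δ₁
δ₂ = r − Q₂(s₂, c₂)
Q₂(s₂, c₂) += α₂·δ₂
Q₁(c₁) += α₁·λ·δ₂
```

The ordering (δ₁ from the pre-update stage-2 value) follows the
canonical implementation. Q values start at zero at the beginning of
every subject × session unit; nothing carries over between sessions.
Reward is coded 0/1 in the likelihood.

The variant family reduces every member to the full natural
parameterisation (bMB, bMF, β₂, α₁, α₂, λ, p): the ω-weighted original
maps through `bMB = β₁ω`, `bMF = β₁(1−ω)` (an exact algebraic
identity, verified numerically in the tests); a shared learning rate
sets α₁ = α₂; a missing eligibility trace sets λ = 0; missing
perseveration sets p = 0. Eight variants are registered — the
two named anchors plus six toggles of {two-beta vs ω, shared α, λ, p}.
The composition of the six non-anchor variants is a package choice;
only the two anchors are claimed to match their published definitions.
Transform/inverse-transform (exp/log, logistic/logit, identity) round
trip to 1e−10.

The session log-likelihood is a numba-compiled kernel (~30 µs per
201-trial evaluation), which is what makes the hierarchical fit and
the Monte-Carlo iBIC integral tractable on one CPU.

## Hierarchical empirical-Bayes fit

Units share a diagonal Gaussian prior on the unconstrained scale
(full covariance deliberately omitted: with ≤ a few hundred units and
seven parameters the diagonal model is the robust default).
EM initialisation: mean 0, variance 6.25 per parameter — weakly
informative, covering learning rates over ~(0.01, 0.99) and betas over
about two orders of magnitude.

* **E-step.** Per unit, MAP by L-BFGS from the prior mean plus 4 prior
  draws (first iteration; warm-started from the previous MAP
  afterwards), objective tolerance 1e−6; curvature by central finite
  differences (relative step 1e−3). Posterior moments are then
  *importance-sampling corrected*: 400 draws from a Gaussian proposal
  at the MAP with twice the Laplace covariance (eigenvalue-floored),
  self-normalised weights, falling back to the raw Laplace moments if
  the effective sample size drops below 1/25 of the draws. The common
  random numbers per unit are frozen across iterations so the EM map
  is deterministic. The correction matters: along the weakly
  identified, curved bMF ↔ α₁ ridge the raw MAP/curvature moments are
  systematically off-centre, and a pure Laplace E-step converges to a
  group mean several standard errors from the truth even though the
  exact marginal likelihood peaks at the truth (we verified this by
  direct Monte-Carlo scans of the marginal likelihood); the reweighted
  moments remove that bias for a few hundred extra likelihood
  evaluations per unit.
* **M-step.** Prior mean = mean of posterior means; prior variance =
  mean of (posterior variance + squared deviation), floored at 1e−3.
* **Stopping.** Largest hyperparameter change < 5e−3 (the residual
  Monte-Carlo jitter floor of the E-step) or 40 iterations; the
  Laplace approximation of the marginal likelihood is logged per
  iteration, and non-convergence is flagged, never silent.
* **Uncertainty.** The standard error of the fitted prior mean uses
  the Fisher identity: the per-unit score for the mean is
  `(E[θᵢ|data] − μ)/σ²`, so the observed information is approximated
  by the score outer product. For weakly identified parameters this is
  properly larger than `sqrt(σ²/n)` — shrunk posterior means carry
  little information — and recovery z-scores computed against it are
  calibrated (checked across seeds in development).

**iBIC.** `−2·Σᵢ log[(1/K)·Σₖ exp ℓᵢ(θₖ)] + h·log(total choices)` with
θₖ fresh prior draws per unit (K = 2000 by default, log-sum-exp
accumulation), `h` = 2 per free parameter (a mean and a variance) and
choices counted as 2 per valid trial (both stage decisions; the
convention is a package choice). Per-unit BIC uses the MAP
log-likelihood with `d·log(2·valid trials)`.

Hessians use an in-package finite-difference routine.

## Synthetic reference population

The generator's default prior (`REFERENCE_PRIOR`, unconstrained scale)
is anchored once to canonical fits of this task: stage-1 weights
bMB ≈ 2.2 and bMF ≈ 2.0 (ratio ≈ 1.07, slightly model-based-dominant),
β₂ ≈ 3, learning rates ≈ 0.55/0.45, eligibility ≈ 0.57, mild
perseveration (0.15 on the logit scale). Between-unit variances are
set so the natural-scale coefficients of variation match the
dispersions reported for this task (≈ 71% bMB, 47% bMF, 33% β₂,
49% α₁, 47% α₂, 36% λ); the perseveration SD is 0.5. What the
generator does *not* emulate: within-session non-stationarity,
lapse/attention states, response-time–choice coupling (synthetic RTs
are i.i.d. log-normal, deadline-truncated) and any true session-order
effects — so passing recovery tests demonstrates correctness of the
fitting machinery under the model, not robustness to real-data
violations of it.

## Stay/switch regression

Design rows exist for trials whose predecessor in the same session is
valid. Codings: stay ∈ {0, 1}; previous reward, transition and
"correct" ∈ {+1, −1}. "Correct" marks whether the previous stage-1
choice commonly led to the stage-2 state with the higher current
maximum reward probability — computed from the true generative walks
for synthetic data, or from a decaying running mean of observed
rewards (rate 0.1) when walks are unavailable; it enters as fixed
effect plus random slope when requested (off by default so the fixed
part matches the 20-term reward × transition × session expansion).
Sessions use treatment coding against the first session.

The logistic model with per-subject random intercept and
reward/transition/interaction slopes is fitted by `lme4::glmer`
(Laplace, bobyqa) through an Rscript bridge — the field-standard
estimator for this analysis; convergence failures walk a fallback
ladder (unstructured → diagonal → intercept-only) and singular fits
are flagged. Per-term Wald F statistics are computed in-package from
the fixed-effects covariance (χ²/q against F(q, n−p)). The linear
variant for continuous responses uses statsmodels MixedLM (REML), with
`lme4::lmer` as an independent oracle in the tests; continuous
responses are z-scored within subject by default. In the parameter
sweep (below) all agents within a grid point share identical
parameters, so there is no true between-subject heterogeneity and a
pooled logistic GLM targets the same coefficients; it is the sweep
default (~50× faster), with the hierarchical fit available via
`method="mixed"`.

## Parameter → regression mapping

Each parameter is swept over a five-point grid (betas
{0.25, 0.5, 1, 2, 4}; rates and λ {0.1, …, 0.9}; p
{−0.5, −0.15, 0, 0.15, 0.5}) with the other six clamped at the grid
centres; 1000 agents × 201 trials per parameter (200 per grid point),
single session. MF_CI/MB_CI are the Pearson correlations between grid
values and the fitted 'reward' / 'reward × transition' coefficients —
scale-free, hence robust to the pooled-vs-mixed choice. Grids are
swept on the natural scale and are fully configurable. The
reconstruction utility multiplies indices by per-session parameter
means ({bMF, α₁, λ} for the MF pattern, {bMB, β₂, α₂} for MB), summed
and reported relative to the first session. The mapping is one-way by
construction; no inverse is provided.

## Reliability and power

ICC(2,k) (two-way random effects, absolute agreement, mean of k
ratings) comes from pingouin's ANOVA decomposition, with an exact
early return for the degenerate zero-error case; the
poor/moderate/excellent labels cut at 0.4 and 0.75. CV is computed per
subject across sessions (sample SD over |mean|), averaged over
subjects and bootstrapped over subjects for its CI — the aggregation
is a package choice. The repeated-measures ANOVA (pingouin) adds
Bonferroni pairwise tests and orthonormal polynomial contrasts
(QR-orthogonalised, linear term ascending) tested by one-sample
t tests of per-subject contrast scores; no sphericity correction is
applied by default.

The power simulation draws per-subject trajectories with the
between/within variance split implied by the assumed test-retest
reliability, imposes a linear fractional mean change across the five
sessions, tests the linear contrast per replicate (two-sided t,
α = 0.05) and reports the rejection rate; the minimal detectable
change inverts the (monotone) power curve by bisection with frozen
replicate noise. The default parameter distribution is the log-normal
implied by the package's reference population, so the printed
detectable-change percentages characterise *this* synthetic
population, not any empirical cohort.

## fNIRS chain

The modified Beer–Lambert law is solved per sample and channel as a
2×2 system `ΔOD(λ) = ε(λ, chrom)·Δc·d·DPF(λ)` with the standard
coefficient set (μₐ 1486/2526 for O₂Hb, 3843/1798 for HHb at
760/850 nm; DPF 7.25/6.38) used verbatim as dimensionless defaults —
concentrations are in arbitrary units. ΔtHb = ΔO₂Hb + ΔHHb holds
sample-wise by construction. Preprocessing: first-sample baseline
subtraction, linear detrend, zero-phase Butterworth band-pass
(default 0.01–0.2 Hz, order 3; cutoffs configurable since no standard
is fixed). Trial amplitudes come from a least-squares GLM with one
stick-convolved double-gamma HRF regressor per stage-1 choice (peak
5 s, 35% undershoot, configurable) plus polynomial drift; a
rank-deficient design raises with a hint about inter-trial spacing.
The forward generator injects HRF-shaped O₂Hb responses (HHb as a
−0.3-scaled mirror), Mayer-wave and respiratory sinusoids and white
noise on the optical side. Short-channel (or any other) nuisance
signals can be supplied as extra GLM regressors; none are used by
default.

## Numerical and testing choices

All randomness flows through numpy Generators; cohort units derive
their streams from (master seed, subject, session), so simulation is
bit-reproducible and invariant to unit order. Test problem sizes are
scaled to single-CPU runs: the full seven-parameter sweep uses 1000
agents per parameter (~15 s), recovery and model-recovery suites 100
units × 201 trials (~1–3 min each), the null calibrations 500
replicates of small cohorts batched into a single R session. Ties in
model comparison break toward fewer parameters; undefined correlation
indices are reported as NaN rather than 0; degenerate inputs
(all-missed cohorts, zero-variance responses, empty trial files,
out-of-range codes) raise or warn explicitly with the offending row
named.

## Known limitations

* The E-step importance correction assumes the Laplace proposal covers
  the posterior; for pathological units it falls back to Laplace
  moments (logged), which can re-introduce local bias.
* Absolute iBIC values depend on the Monte-Carlo sample count and the
  prior parameterisation; only differences between variants fitted
  under the same settings are meaningful.
* The glmer bridge serialises data through CSV; very large designs pay
  I/O overhead, and R (with lme4) must be installed.
* ICC/CV and the power analysis operate on natural-scale parameter
  values; heavy-tailed distributions (large-beta units) make the CV
  estimate itself high-variance, mirroring the instability of that
  statistic on real fits.
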