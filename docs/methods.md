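# Methods

## The estimand and the multistate model

CGRFS is the probability of occupying one of the "alive and free of
moderate-to-severe chronic GVHD" states at time *t* after transplant.
The event history is a progressive ten-state model: state 0 (initial
remission) → state 2 (first chronic GVHD) → state 4 (first recovery) →
state 6 (second episode) → state 8 (second recovery), with each
transient state k having its own absorbing death/relapse companion
k+1. Two GVHD episodes are modelled; a third episode is outside the
model's state space and rejected at validation.

CGRFS = P00 + P04 + P08 equals the signed sum
S1 + S2 − S3 + S4 − S5 of five composite-endpoint survival functions.
The identity is purely set-theoretic: each S_k is the probability of
occupying a down-closed union of transient states (e.g. S3 = P00 + P02,
S2 = P00 + P02 + P04), and the alternating sum telescopes to the three
favorable states. Each endpoint is right-censored by the common
censoring time Z, giving the nested observations
X1 ≤ X3 ≤ X2 ≤ X5 ≤ X4.

## Estimation

Each Ŝ_k is the Kaplan–Meier product over distinct observed event
times of `1 − dN̄_k(u)/Ȳ_k(u)`, with the at-risk convention
`Ȳ_k(t) = #{X_ik ≥ t}` (a subject censored exactly at an event time is
still at risk there — events are processed before tied censorings).
Ĉ is evaluated by exact step-function arithmetic on the pooled grid of
distinct event times of all five endpoints; there is no interpolation.
Ĉ is reported raw: in finite samples it may locally leave [0, 1], and
clamping before inference would bias the variance, band and test
machinery (clamp for plotting only).

## Variance and pointwise intervals

The estimator admits the i.i.d. representation
`√n(Ĉ − C) ≈ n^{-1/2} Σ_i W_i(t)` with

```
W_i(t) = − Σ_k s_k S_k(t) ∫_0^t dM_ik(u) / y_k(u),   s = (+1,+1,−1,+1,−1)
```

where M_ik is the k-th endpoint's counting-process martingale for
subject i. The five martingales share events and are therefore
correlated; instead of a martingale variation process with covariance
terms, the moment estimator `σ̂²(t) = n^{-1} Σ_i Ŵ_i(t)²` is used, with
Ŵ_i obtained by plugging in Ŝ_k, Ȳ_k and the compensated increments
`dN_ik − Y_ik dN̄_k/Ȳ_k`. The influence values are exactly centred
(Σ_i Ŵ_i(t) = 0 algebraically), which the tests assert, and in the
degenerate no-GVHD case the variance collapses to the closed form
`n Ŝ4² Σ_{u≤t} (dN̄4/Ȳ4²)(1 − dN̄4/Ȳ4)` — the exact square-sum of KM
influence values, whose leading term is the familiar `Σ dN̄4/Ȳ4²`
expression.

Pointwise intervals: linear `Ĉ ± z_{1−α/2} σ̂/√n`, and the log-log
transform `[Ĉ^{1/θ}, Ĉ^θ]`, `θ = exp(z_{1−α/2} σ̂ / (√n Ĉ ln Ĉ))`,
which respects (0,1) but is undefined when Ĉ ∈ {0,1} (callers fall
back to the linear form there). Default α = 0.05.

## Multiplier bands and the supremum test

Band critical values come from realizable Gaussian processes in which
martingale increments are replaced by normal-weighted jumps of the
observed counting processes. Two schemes are exposed:

* **subject** (default): one draw G_i per subject multiplies Ŵ_i(t);
  the realized process `n^{-1/2} Σ_i G_i Ŵ_i(t)` has conditional
  variance exactly σ̂²(t), so it inherits the cross-endpoint covariance
  the moment variance captures.
* **endpoint**: independent draws G_ik per (subject, endpoint) weight
  each endpoint's jumps separately. This treats the five endpoint
  martingales as orthogonal; since they are positively dependent
  through shared death/relapse events, its second moment can differ
  substantially from σ̂² (empirically about twice σ̂ under the
  benchmark model). It is retained for comparison; the subject scheme
  is the default because its second moment matches the variance
  estimator by construction.

A G_ik "process" is a single time-constant draw — inside `∫ G dN_ik`
only its value at the subject's one jump matters.

The (1−α) band on [t1, t2] is `Ĉ ± n^{-1/2} q̃_α σ̂(t)` with q̃_α the
empirical (1−α) quantile (order statistic ⌈(1−α)B⌉) of
`sup_t |W̃_b(t)/σ̂(t)|`; grid points with σ̂ = 0 are excluded from the
sup, and step processes attain their supremum on the grid, so only grid
points are scanned. Defaults: B = 1000, [t1, t2] from the smallest to
the largest event time.

Two samples: the difference and its resampled analogues are
standardized on the probability scale by
`SE(t) = sqrt(σ̂1²/n1 + σ̂2²/n2)`, with each sample's realized process
scaled by 1/√n_i before differencing; for n1 = n2 this reproduces the
single-√n standardization exactly, and it extends cleanly to unequal
arms. K̂ is the observed standardized supremum; the p-value is the
proportion of resampled suprema ≥ K̂. The default window takes t1 as
the larger of the two samples' first event times and t2 as the largest
event time; the calibration experiments additionally truncate t2 at
4 years, where the benchmark cohorts' risk sets thin out and the
standardized tails become unstable.

## State occupation and functionals

Transient states: P0 = Ŝ1, P2 = Ŝ3 − Ŝ1, P4 = Ŝ2 − Ŝ3, P6 = Ŝ5 − Ŝ2,
P8 = Ŝ4 − Ŝ5 (raw KM differences; may be slightly negative in small
samples — the Aalen–Johansen route is the nonnegative alternative and
both are exposed). Absorbing states are cumulative incidences,
estimated by the Aalen–Johansen product integral with left-limit
at-risk counts under the same tie convention as the KM module.
Within-subject simultaneous transitions (a failure tied with a GVHD
event — validation permits exactly this tie) are processed as ordered
sub-steps in path order, so failure dominates and conservation
(Σ_i P̂_0i = 1) holds factor by factor. Ŝ1 = P̂00 is an exact identity
asserted to machine precision; all other cross-route agreements are
asymptotic only.

Functionals: GVHD prevalence among leukemia-free patients
`(P2 + P6)/Ŝ4` (KM-difference route) and the failure-odds contrast
`P5/P4 − P1/P0` (Aalen–Johansen route for all four terms, keeping the
ratio internally consistent and nonnegative). Where a denominator is
zero the functional is *undefined*, never a sentinel value — 0/0 has no
estimand. Intervals by nonparametric subject-level bootstrap,
percentile method (no stronger correction is warranted by the
asymptotics used); resamples where the functional is undefined are
dropped, and >50% undefined aborts with a diagnostic.

## The simulator and its oracles

Cohorts are drawn from a time-homogeneous Markov process on the nine
allowed transitions, with exponential sojourns and independent
right-censoring (exponential, uniform, or administrative). Constant
intensities are deliberate: they make the exact occupation
probabilities available as `P(0,t) = exp(tQ)`, the oracle for every
calibration claim. The benchmark specification (time unit: years)

```
λ01=0.25  λ02=0.35  λ23=0.15  λ24=0.20  λ45=0.08
λ46=0.10  λ67=0.15  λ68=0.25  λ89=0.05   censoring ~ U[2, 6]
```

was chosen once to mimic a transplant cohort qualitatively —
substantial first-episode onset and resolution, modest second episodes,
staggered accrual giving 2–6 years of follow-up — and is documented as
an arbitrary default, not an estimate of any real cohort. What the
generator does **not** emulate: non-Markov (duration-dependent) sojourn
times, time-varying intensities, covariate heterogeneity, informative
censoring, and interval-censored onset assessment. Passing calibration
here therefore validates the *inferential machinery* under a correctly
specified independent-censoring model, not robustness to those
departures.

Calibration experiments (replication r uses seed + r; two-sample
designs use seed + 2r and seed + 2r + 1) evaluate on [0, 4] years and
at the interior time t = 2: CI coverage, band coverage over the middle
80% of the pooled event times, test size/power at n = 200 per arm with
B = 500, variance ratio at n = 500, estimator agreement over
n ∈ {200, 500, 2000}. These sizes keep each experiment's Monte-Carlo
error near one percentage point while the full battery completes in
about a minute.

## Numerical choices and degenerate inputs

* All step functions are right-continuous; evaluation is a binary
  search over jump times.
* Zero-duration GVHD episodes (onset = resolution) are rejected as
  invalid input: zero-length sojourns make state membership ambiguous.
  A failure tied with a GVHD time is accepted, failure dominating.
* Empirical quantiles for critical values use the ⌈(1−α)B⌉ order
  statistic, the defining equation of the resampling percentile.
* A dataset with no events at all yields Ĉ ≡ 1, σ̂ ≡ 0 and an empty
  grid; bands and tests raise a degenerate-band error rather than
  returning a zero-width band.
* Ȳ_k = 0 at an event time is impossible by construction (the event's
  own subject is at risk) but guarded with an explicit error.

## Known limitations

Only two GVHD episodes; no left truncation, interval censoring,
covariate regression or more-than-two-sample comparisons. The KM
difference estimates of transient states are not constrained
nonnegative. The endpoint-level multiplier scheme is approximate by
construction (see above); its bands are wider than subject-scheme bands
under shared-event dependence. Variants that treat relapse as curable
or restart the clock at GVHD onset fit the same machinery after
relabelling states but are not implemented.
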