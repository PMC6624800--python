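# Methods

## Survival curves and step-function conventions

All curve logic operates on `StepCurve`, a right-continuous step function:
the survival value attached to a listed time holds from that time until the
next listed time. The grid lists *every* distinct observed time, so
censoring-only times appear as flat steps and carry their at-risk count;
this is what makes the plateau detector's at-risk lookup well defined
without storing raw data. Time is in months throughout; year-denominated
landmarks convert at 12 months/year.

Estimation from raw (duration, event) pairs delegates to the standard
product-limit estimator (lifelines); digitized curves load from 3-column
TSVs (`time_months  survival  at_risk`) and are validated, never repaired —
a non-monotone digitization is an error, because silently fixing it would
change award decisions.

Queries beyond the observed follow-up return the sentinel `NOT_REPORTED`
rather than an extrapolation. This is a substantive choice, not a
convenience: the TOC rule's second criterion ("data reported at twice the
control median") is exactly the question "is t2 within follow-up?", and the
LTP landmarks at 5/7 years are routinely beyond the follow-up of
registration trials — the rule must then fail, not guess. Similarly,
`median_survival` returns `NOT_REACHED` when the curve never falls to 0.5;
the median is taken at the *first* time with S ≤ 0.5, inclusive at exactly
0.5.

RMST is the exact rectangle sum of the step function up to τ, with τ
required to lie within follow-up (no tail extrapolation). It is
cross-checked in the tests against lifelines' implementation on fitted
curves and against naive numerical integration on arbitrary step curves.

Inclusive threshold comparisons (ratio ≥ 1.5, floor ≥ 0.20, gain ≥ 0.10,
median ≤ 6 or ≤ 12 months) use an absolute guard of 1e-9 so that
arithmetically exact boundary cases (e.g. 0.30/0.20) are not lost to float
rounding. The guard is far below any probability resolvable from trial
data.

## Plateau detection

The frameworks' "long-term plateau" is qualitative in practice (the
assessments this package models were made by human reviewers, with reported
inter-reviewer κ ≈ 0.72). The operational rule here declares the trailing
`window_frac` of follow-up a plateau when the total KM drop inside the
window is below `drop_tol` **and** at least `min_at_risk` patients are at
risk when the window opens. Defaults: `window_frac = 0.2`,
`drop_tol = 0.05` (absolute), `min_at_risk = 10`.

These defaults are this package's own conservative operationalization of "a
flat tail with meaningful support": a 5-point drop over the last fifth of
follow-up is within digitization noise of flat, and ten at-risk patients is
the smallest count at which a flat tail is more than anecdote (the same
imprecision concern that motivates the 20% control floor in the TOC rule).
All three are configurable, the detector is provably monotone in
`drop_tol`, and trial records can carry manual per-endpoint overrides so
published reviewer or field-testing verdicts can be injected without
re-derivation.

The plateau is assessed on the **test-arm** curve: the long-term-survivor
claim the adjustment credits concerns the experimental regimen. When the
control median is never reached within follow-up, the landmark branch
routes to the longer horizon (7 years OS / 2 years PFS), since the median
demonstrably exceeds the cutoff whenever follow-up passes it; with very
short follow-up the landmark is then unreachable and the rule fails on the
data criterion, which is the appropriate outcome for immature data.

## Award rules

**TOC bonus.** `evaluate_toc` forms t2 = 2 × control median of the same
endpoint, reads both milestones with the step convention, and records all
four criteria; every failure mode (median not reached, follow-up short of
t2, zero control survival) is a recorded verdict, never an exception. The
"≥ 50% improvement" criterion is read **relatively** (S_test ≥ 1.5·S_ctrl):
an absolute 50-point reading would be nearly unsatisfiable at a milestone
where only ≥ 20% of controls survive, contradicting the rule's intent.
`award_toc` evaluates OS when reported and not crossover-obscured, awards
20 points on success, and otherwise evaluates PFS (16 points). When OS is
evaluable but fails, PFS is still evaluated by default — the single-bonus
constraint presupposes both can be checked — and `os_strict=True` disables
that fallback for sensitivity analysis, since published practice is
ambiguous on this point.

**LTP adjustments.** One endpoint per trial, following the primary
endpoint; coprimary OS+PFS routes to OS by default (OS is the stronger
endpoint and the OS-form adjustment the stronger award), configurable per
call. The PFS gain is an **absolute** difference (≥ 0.10), consistent with
that framework's usage and in deliberate contrast to the relative TOC
criterion; the OS condition is any strict advantage at the landmark, with
no significance requirement imposed. Internal names are endpoint-based
(OS form / PFS form) rather than form numbers. Downstream grade arithmetic
(what "scored with form 1" or "upgrade one level" does to a final grade) is
out of scope; the award decision is terminal.

## Agreement statistics

Cohen κ is the unweighted 2×2 statistic (p_o − p_e)/(1 − p_e), with the
Fleiss–Cohen–Everitt large-sample variance for the CI and the null
(chance-agreement) variance for the test of κ = 0; degenerate margins
(p_e = 1) make κ undefined and are reported as such, not as 0 or 1. The
point estimate is cross-checked against scikit-learn on random tables.
McNemar's χ² = (b − c)²/(b + c) uses only the discordant cells
(statsmodels), uncorrected by default with the continuity correction behind
a flag. Risk differences use the unpooled Wald standard error for both CI
and test — the variant that reproduces the published intervals
(0.14, 95% CI −0.14 to 0.42; 0.07, 95% CI −0.09 to 0.23) — with a
pooled-variance test available. No multiple-testing adjustment is applied
anywhere.

Concordance tables are built over **dual-eligible** trials only (those the
plateau-adjustment framework actually assessed); subgroup tables are
emitted by therapy class, assessed endpoint, and disease site.

Computed from the published dual-eligible counts (both = 1, one-sided
disagreements 37 and 1, neither = 39), κ = 4/2968 ≈ 0.0013: agreement is
chance-level despite 51.3% raw agreement, because one framework awards
48.7% of trials and the other 2.6%.

## The mixture-cure simulator

Each arm draws from S(t) = π + (1 − π)·exp(−(λt)^k): a fraction π is cured
(infinite latent event time — the plateau), the rest draw Weibull latency
(k = 1 exponential). Censoring is purely administrative: end of study at
`followup_months` plus a uniform accrual offset in [0, accrual]; there is
no dropout process. PFS is simulated as an independent endpoint (default:
OS configuration with doubled event rates); joint OS/PFS modeling is out of
scope. The trial-level significance flag is not asserted but computed by a
log-rank test on the simulated primary endpoint, so null trials are
"significant" only at the type-I rate.

Reproducibility: arm- and endpoint-level generators derive from the config
seed via disjoint substreams, and cohorts assign each trial the substream
`SeedSequence(master_seed, spawn_key=(i,))`, so trial *i*'s data is
invariant to cohort size and composition.

Presets (all with a control median of 8 months, accrual 12 months,
follow-up 36 months, n = 500/arm by default — a realistic large
registration trial):

* `ici_like` — cure fractions 0.25 → 0.40, shared Weibull k = 3 latency.
  The sharp latency is spent well before t2 = 2 × median, so milestone
  reads at t2 see the plateaus themselves: asymptotic ratio
  0.40/0.25 = 1.6 against the 1.5 threshold, control floor 0.25 against
  0.20.
* `non_ici_like` — proportional hazards (HR 0.65), π = 0 in both arms,
  Weibull k = 1.5, which places the control tail at t2 at
  exp(−2^1.5·ln 2) ≈ 0.14, below the 20% floor. (With exponential latency
  the control tail at t2 is exactly 0.25 and the floor passes marginally;
  the k > 1 shape is what makes this preset a clean "durable-benefit-free"
  contrast.)
* `null` — identical exponential arms.

With 36-month follow-up the 5-year OS landmark is unreachable, so simulated
OS-primary trials cannot earn the OS-form plateau adjustment — deliberately
reproducing the short-follow-up asymmetry between the two frameworks that
registration-trial cohorts exhibit.

### Power analysis for the discrimination experiment

The designed end-to-end check asks that an `ici_like` effect be awarded the
TOC bonus in ≥ 95% of seeds and a `null` cohort in ≤ 5%. The binding margin
is the milestone ratio: 1.6 asymptotically vs the 1.5 threshold. With
administrative censoring only (no censoring before t2), the KM milestones
at t2 are binomial proportions, and the delta method gives

SE(ratio) ≈ 1.6 · sqrt[(0.24/0.16 + 0.1875/0.0625)/n] = 3.39/√n,

so the per-trial award probability is Φ(0.1·√n/3.39): ≈ 75% at n = 500/arm,
≈ 98% at n = 5000, ≈ 99.6% at n = 8000. The discrimination experiment in
the acceptance checks therefore uses n = 8000/arm — a designed simulation
experiment sized for a reliable ≥ 95% award rate, not a realistic trial
size — while cohort emulation keeps the realistic default of 500/arm. The
null design sits ~10 SE below the threshold at any of these sizes and is
effectively never awarded.

### What the simulator does and does not emulate

It reproduces the features the award rules actually read: plateau height
and separation, latency shape, control median, follow-up maturity,
administrative censoring, endpoint mix, eligibility flags. It does not
model dropout, non-proportional crossover contamination, interval-censored
assessment schedules, correlated OS/PFS, or cohort heterogeneity beyond the
preset mixture — so passing tests demonstrate that the rules behave as
specified on clean data with known truth, not that either framework is
well calibrated on real registration trials.

## Problem sizes in the test suite

Simulation-backed tests use the smallest sizes at which the assertions are
comfortably outside Monte-Carlo noise: n = 5000/arm and 20 seeds for
cure-fraction recovery within 0.03 (SE of the tail height ≈ 0.0065, so the
band is ~4.6 SE); n = 5000 for the closed-form median (ln 2/λ) and RMST
integral checks with tolerances ≈ 3.5 SE; 500 random trials for exact
oracle-equivalence of both scorers; 40 seeds at n = 8000/arm for the
discrimination experiment (expected failures per run < 0.2).

## Known limitations

* The plateau detector is an operationalization; its defaults are choices
  of this package, and nothing here claims they reproduce any particular
  human reviewer's qualitative calls beyond the override mechanism.
* Digitized-curve input trusts the at-risk column for the detector's
  support guard; files without faithful at-risk counts will gate plateaus
  incorrectly.
* The κ confidence interval is asymptotic and the published comparison
  values were computed with unstated interval methods; only the κ point
  estimate should be compared across implementations.
* `rmst` and the milestone queries refuse to extrapolate; analyses that
  need a common τ across trials must choose τ within every trial's
  follow-up.
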