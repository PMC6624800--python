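# tailcredit

Executable long-term-survival award rules for oncology value frameworks,
with the agreement statistics to compare them and a mixture-cure trial
simulator to validate them.

## The problem

Immune checkpoint inhibitors (ICIs) can produce durable benefit in a subset
of patients, visible as a plateau at the tail of the Kaplan-Meier survival
curve. Two major value frameworks try to credit that benefit with explicit
add-ons to their scores:

* **ASCO-VF v2 tail-of-the-curve (TOC) bonus** — 20 points (OS) or 16 points
  (PFS), awarded when, at *t2* = twice the control-arm median, the curves
  are still reported, survival in the test arm is at least 50% better
  relatively (S_test(t2) ≥ 1.5 · S_ctrl(t2)), and at least 20% of the
  control arm is still alive or progression-free (S_ctrl(t2) ≥ 0.20). One
  bonus per trial; OS has priority; PFS substitutes when OS is unreported or
  obscured by crossover.
* **ESMO-MCBS v1.1 immunotherapy-triggered long-term-plateau (LTP)
  adjustments** — a one-level grade upgrade (PFS form: plateau plus an
  absolute gain ≥ 10 points at 1 or 2 years, branching on whether the
  control median PFS is ≤ 6 months) or curative-potential scoring (OS form:
  plateau plus any test-arm advantage at 5 or 7 years, branching on whether
  the control median OS is ≤ 12 months). One endpoint per trial, following
  the primary endpoint; trials without a significant primary endpoint or
  with hematological agents are not assessed.

Whether these two rules agree on which trials deserve long-term-survival
credit is an empirical question. This package implements both rules as
deterministic decision procedures over step curves, the inter-rater
statistics used to compare them (Cohen κ, McNemar χ², Wald risk
differences), and a mixture-cure-model simulator
S(t) = π + (1 − π)·exp(−(λt)^k) whose known cure fraction π (the plateau
height) provides ground truth for validating either rule.

It is aimed at methodologists studying value frameworks and trial
statisticians who want an operational, reproducible reading of "tail of the
curve" criteria.

## Worked example

```python
from tailcredit import (award_toc, award_ltp, simulate_trial, cohen_kappa,
                        ConcordanceTable, percent_agreement)
from tailcredit.synthetic import ici_like

# a trial whose test arm raises the cure fraction 0.25 -> 0.40
trial = simulate_trial("demo", ici_like(n_per_arm=2000, seed=42),
                       therapy_class="ICI", therapy_subclass="ICI",
                       disease_site="skin", primary_endpoint="PFS")

toc = award_toc(trial)
crit = toc.criteria_detail["OS"]
print(f"TOC bonus: awarded={toc.awarded}, endpoint={toc.endpoint_used}, "
      f"points={toc.points}")
print(f"  t2 = {crit.t2:.1f} mo, S_test(t2) = {crit.s_test_t2:.3f}, "
      f"S_ctrl(t2) = {crit.s_ctrl_t2:.3f}, ratio = {crit.improvement_ratio:.2f}")

ltp = award_ltp(trial)
lcrit = ltp.criteria_detail["PFS"]
print(f"LTP adjustment: awarded={ltp.awarded}, kind={ltp.adjustment}")
print(f"  landmark = {lcrit.t_eval:.0f} mo, delta = {lcrit.delta:.3f}, "
      f"plateau = {lcrit.plateau.is_plateau}")

# agreement over 78 dual-eligible trials: both=1, ASCO-only=37, ESMO-only=1
table = ConcordanceTable(both=1, asco_only=37, esmo_only=1, neither=39)
res = cohen_kappa(table)
print(f"kappa = {res.kappa:.4f}, percent agreement = {percent_agreement(table):.1f}%")
```

prints

```
TOC bonus: awarded=True, endpoint=OS, points=20
  t2 = 16.1 mo, S_test(t2) = 0.395, S_ctrl(t2) = 0.262, ratio = 1.51
LTP adjustment: awarded=True, kind=pfs_upgrade
  landmark = 12 mo, delta = 0.157, plateau = True
kappa = 0.0013, percent agreement = 51.3%
```

The simulated trial earns the OS bonus (the milestone ratio 1.51 clears the
1.5 threshold and 26% of controls are alive at t2) and, on its primary PFS
endpoint, the plateau-based grade upgrade (15.7-point gain at 1 year with a
flat tail). The κ near zero says the two frameworks' award decisions across
a trial cohort can agree no better than chance even when their raw percent
agreement is 51%.

## Analysis workflow

Numbered drivers under `analysis/` run the full narrative on a simulated
cohort and write tables under `results/`:

1. `01_simulate_cohort.py` — 100 mixture-cure trials (14% ICI-like);
2. `02_score_frameworks.py` — both award rules, per-trial verdicts;
3. `03_concordance.py` — the 2×2 table, κ, McNemar, risk differences;
4. `04_threshold_sweep.py` — award counts as the 20% control floor varies.

The same operations are available from the `tailcredit` command line
(`simulate`, `score asco`, `score esmo`, `concordance`).

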