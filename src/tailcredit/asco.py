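"""ASCO-VF v2 tail-of-the-curve (TOC) bonus rule.

The bonus credits durable benefit read off the Kaplan-Meier curves at twice
the control-arm median ("time point 2", t2).  Four criteria must all hold for
an endpoint: the endpoint is reported; both curves extend to t2; survival in
the test arm at t2 is at least 50% better than control, read as the relative
condition S_test(t2) >= 1.5 * S_ctrl(t2); and at least 20% of the control arm
is still alive (or progression-free) at t2.  A single bonus per trial: OS
wins 20 points when it qualifies, otherwise PFS wins 16.  When OS
interpretation is obscured by crossover, PFS is evaluated instead.

All failure modes are recorded verdicts, never exceptions — a trial whose
control median is not reached simply cannot form t2 and fails the criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .awards import ASCO_TOC, AwardResult
from .curves import (NOT_REACHED, NOT_REPORTED, MaybeMonths, MaybeProbability,
                     StepCurve, Unobserved, _ge, median_survival, survival_at)
from .registry import Cohort, TrialRecord

DEFAULT_RATIO_THRESHOLD = 1.5
DEFAULT_FLOOR_THRESHOLD = 0.20

OS_BONUS_POINTS = 20
PFS_BONUS_POINTS = 16


@dataclass(frozen=True)
class TocCriteria:
    """Per-criterion breakdown of one endpoint's TOC evaluation."""

    endpoint: str
    t2: MaybeMonths              # 2 x control median, NOT_REACHED if unformable
    data_extends_to_t2: bool
    s_test_t2: MaybeProbability
    s_ctrl_t2: MaybeProbability
    improvement_ratio: float | None  # s_test / s_ctrl where defined
    ratio_ok: bool
    ctrl_floor_ok: bool
    met: bool


def evaluate_toc(test: StepCurve, control: StepCurve, *, endpoint: str = "OS",
                 ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
                 floor_threshold: float = DEFAULT_FLOOR_THRESHOLD) -> TocCriteria:
    """Evaluate the four TOC criteria for one endpoint's pair of curves."""
    ctrl_median = median_survival(control)
    if ctrl_median is NOT_REACHED:
        return TocCriteria(endpoint=endpoint, t2=NOT_REACHED,
                           data_extends_to_t2=False,
                           s_test_t2=NOT_REPORTED, s_ctrl_t2=NOT_REPORTED,
                           improvement_ratio=None, ratio_ok=False,
                           ctrl_floor_ok=False, met=False)
    t2 = 2.0 * ctrl_median
    s_test = survival_at(test, t2)
    s_ctrl = survival_at(control, t2)
    data_extends = not (isinstance(s_test, Unobserved) or isinstance(s_ctrl, Unobserved))
    ratio = None
    if data_extends and s_ctrl > 0:
        ratio = s_test / s_ctrl
    ratio_ok = ratio is not None and _ge(ratio, ratio_threshold)
    ctrl_floor_ok = data_extends and _ge(s_ctrl, floor_threshold)
    met = data_extends and ratio_ok and ctrl_floor_ok
    return TocCriteria(endpoint=endpoint, t2=t2, data_extends_to_t2=data_extends,
                       s_test_t2=s_test, s_ctrl_t2=s_ctrl,
                       improvement_ratio=ratio, ratio_ok=ratio_ok,
                       ctrl_floor_ok=ctrl_floor_ok, met=met)


def award_toc(trial: TrialRecord, *,
              ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
              floor_threshold: float = DEFAULT_FLOOR_THRESHOLD,
              os_strict: bool = False) -> AwardResult:
    """Apply the single-bonus rule to one trial.

    OS is evaluated when reported and not obscured by crossover; when OS
    qualifies, only the 20-point OS bonus is awarded.  PFS is evaluated when
    reported and OS is absent, obscured, or (unless ``os_strict``) evaluated
    but unmet.  ``os_strict=True`` disables the PFS fallback after a failed
    OS evaluation, for sensitivity analysis.
    """
    detail: dict[str, TocCriteria] = {}
    os_evaluable = trial.os_reported and not trial.os_obscured_by_crossover
    if os_evaluable:
        verdict = evaluate_toc(trial.curve("OS", "test"), trial.curve("OS", "control"),
                               endpoint="OS", ratio_threshold=ratio_threshold,
                               floor_threshold=floor_threshold)
        detail["OS"] = verdict
        if verdict.met:
            return AwardResult(framework=ASCO_TOC, trial_id=trial.trial_id,
                               awarded=True, endpoint_used="OS",
                               points=OS_BONUS_POINTS, criteria_detail=detail)
    pfs_evaluable = trial.pfs_reported and (not os_evaluable or not os_strict)
    if pfs_evaluable:
        verdict = evaluate_toc(trial.curve("PFS", "test"), trial.curve("PFS", "control"),
                               endpoint="PFS", ratio_threshold=ratio_threshold,
                               floor_threshold=floor_threshold)
        detail["PFS"] = verdict
        if verdict.met:
            return AwardResult(framework=ASCO_TOC, trial_id=trial.trial_id,
                               awarded=True, endpoint_used="PFS",
                               points=PFS_BONUS_POINTS, criteria_detail=detail)
    return AwardResult(framework=ASCO_TOC, trial_id=trial.trial_id,
                       awarded=False, endpoint_used="none", points=0,
                       criteria_detail=detail)


def threshold_sweep(cohort: Cohort, floor_grid, *,
                    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
                    os_strict: bool = False) -> pd.DataFrame:
    """Re-run the full award pass at each control-survival floor in the grid.

    Returns one row per floor with award counts split by therapy class —
    the sensitivity analysis behind proposals to relax the 20% floor.
    """
    floor_grid = list(floor_grid)
    if not floor_grid:
        raise ValueError("floor_grid must be non-empty")
    for value in floor_grid:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"floor threshold {value} outside [0, 1]")
    rows = []
    for floor in floor_grid:
        results = [award_toc(t, ratio_threshold=ratio_threshold,
                             floor_threshold=floor, os_strict=os_strict)
                   for t in cohort]
        awarded = [r for r, t in zip(results, cohort) if r.awarded]
        ici = sum(1 for r, t in zip(results, cohort)
                  if r.awarded and t.therapy_class == "ICI")
        rows.append({"floor_threshold": floor,
                     "awards_total": len(awarded),
                     "awards_ici": ici,
                     "awards_non_ici": len(awarded) - ici})
    return pd.DataFrame(rows)
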