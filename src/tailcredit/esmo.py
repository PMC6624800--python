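"""ESMO-MCBS v1.1 immunotherapy-triggered long-term-plateau (LTP) adjustments.

Two adjustment kinds exist and are mutually exclusive per trial: a PFS-based
grade upgrade and an OS-based switch to curative-potential scoring.  The
endpoint follows the trial's primary endpoint (coprimary OS+PFS routes to OS
by default).  Both kinds require (1) a long-term plateau of the selected
endpoint's curve and (2) a milestone condition whose landmark depends on the
control median:

* OS: test-arm advantage at 5 years when the control median is <= 12 months,
  at 7 years otherwise;
* PFS: an absolute improvement of >= 10 percentage points at 1 year when the
  control median is <= 6 months, at 2 years otherwise.

Trials without a statistically significant primary endpoint, or examining
hematological agents, are not assessed at all.  The plateau verdict comes
from the operational detector unless a manual override (e.g. a published
field-testing call) is attached to the trial.
"""

from __future__ import annotations

from dataclasses import dataclass

from .awards import (ADJUSTMENT_NONE, ESMO_LTP, OS_CURATIVE_SCORING,
                     PFS_UPGRADE, AwardResult)
from .curves import (NOT_REACHED, MaybeMonths, MaybeProbability, PlateauVerdict,
                     StepCurve, Unobserved, _ge, _le, detect_plateau,
                     median_survival, survival_at)
from .registry import TrialRecord, esmo_eligible

DEFAULT_DELTA_THRESHOLD = 0.10

MONTHS_PER_YEAR = 12.0
#: landmark (months) by endpoint: (short-median cutoff, early landmark, late landmark)
_LANDMARKS = {"OS": (12.0, 5 * MONTHS_PER_YEAR, 7 * MONTHS_PER_YEAR),
              "PFS": (6.0, 1 * MONTHS_PER_YEAR, 2 * MONTHS_PER_YEAR)}


@dataclass(frozen=True)
class LtpCriteria:
    """Per-criterion breakdown of one endpoint's LTP evaluation."""

    endpoint: str
    control_median: MaybeMonths
    t_eval: float                 # landmark in months
    plateau: PlateauVerdict
    data_extends_to_t_eval: bool
    s_test: MaybeProbability
    s_ctrl: MaybeProbability
    delta: float | None           # s_test - s_ctrl where both defined
    criterion2_ok: bool
    met: bool


def landmark_months(endpoint: str, control_median: MaybeMonths) -> float:
    """Landmark time for the milestone criterion, branching on control median.

    A control median that is never reached within follow-up routes to the
    longer-horizon branch (the median exceeds any short cutoff it did reach).
    """
    cutoff, early, late = _LANDMARKS[endpoint]
    if control_median is NOT_REACHED:
        return late
    return early if _le(control_median, cutoff) else late


def select_ltp_endpoint(trial: TrialRecord, coprimary_to: str = "OS") -> str:
    """The single endpoint a trial is assessed on (OS and PFS are mutually
    exclusive).  Coprimary OS+PFS trials route to ``coprimary_to``."""
    if not esmo_eligible(trial):
        raise ValueError(
            f"trial {trial.trial_id} is not eligible for LTP assessment; "
            "callers must gate on esmo_eligible")
    if trial.primary_endpoint in ("OS", "PFS"):
        return trial.primary_endpoint
    if coprimary_to not in ("OS", "PFS"):
        raise ValueError(f"coprimary_to must be OS or PFS, got {coprimary_to!r}")
    return coprimary_to


def _evaluate(endpoint: str, test: StepCurve, control: StepCurve,
              plateau: PlateauVerdict, delta_threshold: float) -> LtpCriteria:
    ctrl_median = median_survival(control)
    t_eval = landmark_months(endpoint, ctrl_median)
    s_test = survival_at(test, t_eval)
    s_ctrl = survival_at(control, t_eval)
    data_extends = not (isinstance(s_test, Unobserved) or isinstance(s_ctrl, Unobserved))
    delta = (s_test - s_ctrl) if data_extends else None
    if not data_extends:
        criterion2_ok = False
    elif endpoint == "OS":
        criterion2_ok = delta > 0  # strict advantage, no significance imposed
    else:
        criterion2_ok = _ge(delta, delta_threshold)
    met = plateau.is_plateau and data_extends and criterion2_ok
    return LtpCriteria(endpoint=endpoint, control_median=ctrl_median,
                       t_eval=t_eval, plateau=plateau,
                       data_extends_to_t_eval=data_extends,
                       s_test=s_test, s_ctrl=s_ctrl, delta=delta,
                       criterion2_ok=criterion2_ok, met=met)


def evaluate_ltp_os(test: StepCurve, control: StepCurve,
                    plateau: PlateauVerdict) -> LtpCriteria:
    """OS form: plateau plus any test-arm survival advantage at 5 or 7 years."""
    return _evaluate("OS", test, control, plateau, DEFAULT_DELTA_THRESHOLD)


def evaluate_ltp_pfs(test: StepCurve, control: StepCurve,
                     plateau: PlateauVerdict,
                     delta_threshold: float = DEFAULT_DELTA_THRESHOLD) -> LtpCriteria:
    """PFS form: plateau plus >= 10-point absolute gain at 1 or 2 years."""
    return _evaluate("PFS", test, control, plateau, delta_threshold)


def award_ltp(trial: TrialRecord, *,
              delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
              window_frac: float = 0.2, drop_tol: float = 0.05,
              min_at_risk: int = 10, coprimary_to: str = "OS") -> AwardResult:
    """Apply the LTP adjustment rule to one trial.

    Ineligible trials are returned unassessed with a reason.  The plateau
    verdict is taken from ``trial.plateau_override`` when present (reviewer
    or field-testing call), otherwise from :func:`detect_plateau` on the
    test-arm curve with the given detector settings.
    """
    if not esmo_eligible(trial):
        reason = ("hematological" if trial.hematological
                  else "primary_not_significant")
        return AwardResult(framework=ESMO_LTP, trial_id=trial.trial_id,
                           awarded=False, endpoint_used="none",
                           adjustment=ADJUSTMENT_NONE, ineligible_reason=reason)
    endpoint = select_ltp_endpoint(trial, coprimary_to=coprimary_to)
    reported = trial.os_reported if endpoint == "OS" else trial.pfs_reported
    if not reported:
        return AwardResult(framework=ESMO_LTP, trial_id=trial.trial_id,
                           awarded=False, endpoint_used="none",
                           adjustment=ADJUSTMENT_NONE,
                           ineligible_reason="curves_unavailable")
    test = trial.curve(endpoint, "test")
    control = trial.curve(endpoint, "control")
    if trial.plateau_override and endpoint in trial.plateau_override:
        plateau = PlateauVerdict.manual(trial.plateau_override[endpoint])
    else:
        plateau = detect_plateau(test, window_frac=window_frac,
                                 drop_tol=drop_tol, min_at_risk=min_at_risk)
    verdict = _evaluate(endpoint, test, control, plateau, delta_threshold)
    adjustment = ADJUSTMENT_NONE
    if verdict.met:
        adjustment = OS_CURATIVE_SCORING if endpoint == "OS" else PFS_UPGRADE
    return AwardResult(framework=ESMO_LTP, trial_id=trial.trial_id,
                       awarded=verdict.met, endpoint_used=endpoint,
                       adjustment=adjustment,
                       criteria_detail={endpoint: verdict})
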