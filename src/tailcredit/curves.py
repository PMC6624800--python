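"""Kaplan-Meier step curves and the queries the award rules are built on.

The central container is :class:`StepCurve`, a right-continuous survival step
function with at-risk counts, either estimated from raw event/censoring times
(:func:`km_estimate`, backed by lifelines) or loaded from a digitized
three-column TSV (:func:`read_curve_tsv`).  On top of it live the primitives
every framework criterion needs: milestone survival (:func:`survival_at`),
median survival (:func:`median_survival`), restricted mean survival time
(:func:`rmst`) and an operational plateau detector (:func:`detect_plateau`).

Time is measured in months throughout; year-denominated milestones convert at
12 months/year.  Queries beyond the observed follow-up return the sentinel
``NOT_REPORTED`` rather than extrapolating — a survival curve says nothing
about times it does not reach.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter


class Unobserved(enum.Enum):
    """Distinguished non-numeric outcomes of curve queries."""

    NOT_REPORTED = "not_reported"  # query time beyond observed follow-up
    NOT_REACHED = "not_reached"    # curve never crosses the queried level


NOT_REPORTED = Unobserved.NOT_REPORTED
NOT_REACHED = Unobserved.NOT_REACHED

Months = float
Probability = float
MaybeProbability = Union[float, Unobserved]
MaybeMonths = Union[float, Unobserved]

CURVE_TSV_COLUMNS = ["time_months", "survival", "at_risk"]
RAW_TSV_COLUMNS = ["time_months", "event"]

#: absolute guard for inclusive threshold comparisons on floats
_EPS = 1e-9


def _ge(a: float, b: float) -> bool:
    """a >= b up to a float guard (inclusive thresholds like >=20%)."""
    return a >= b - _EPS


def _le(a: float, b: float) -> bool:
    return a <= b + _EPS


@dataclass(frozen=True)
class StepCurve:
    """A right-continuous survival step function.

    ``times`` lists every distinct observed time (event or censoring);
    ``surv[i]`` is the survival probability holding from ``times[i]`` until
    the next listed time (censoring-only times carry a flat step), and
    ``at_risk[i]`` is the number at risk just before ``times[i]``.
    ``max_followup`` is the largest observed time; the curve is undefined
    beyond it.
    """

    times: np.ndarray
    surv: np.ndarray
    at_risk: np.ndarray
    max_followup: Months
    n_enrolled: int

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        surv = np.asarray(self.surv, dtype=float)
        at_risk = np.asarray(self.at_risk, dtype=int)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "surv", surv)
        object.__setattr__(self, "at_risk", at_risk)
        if not (len(times) == len(surv) == len(at_risk)):
            raise ValueError("times, surv and at_risk must have equal length")
        if len(times):
            if np.any(times < 0):
                raise ValueError("negative time in survival curve")
            if np.any(np.diff(times) <= 0):
                raise ValueError("times must be strictly increasing")
            if np.any(surv < -_EPS) or np.any(surv > 1 + _EPS):
                raise ValueError("survival probabilities must lie in [0, 1]")
            if np.any(np.diff(surv) > _EPS):
                raise ValueError("survival must be non-increasing")
            if np.any(np.diff(at_risk) > 0):
                raise ValueError("at-risk counts must be non-increasing")
            if np.any(at_risk <= 0):
                raise ValueError("at-risk counts must be positive")
            if self.max_followup < times[-1] - _EPS:
                raise ValueError("max_followup must cover the last listed time")
        if self.max_followup < 0:
            raise ValueError("max_followup must be non-negative")
        if self.n_enrolled < 1:
            raise ValueError("n_enrolled must be at least 1")

    @property
    def tail_height(self) -> Probability:
        """Survival at the end of follow-up (1.0 for an event-free curve)."""
        return float(self.surv[-1]) if len(self.surv) else 1.0


@dataclass(frozen=True)
class PlateauVerdict:
    """Outcome of a long-term-plateau assessment of one curve.

    ``source`` is ``"detector"`` for the operational rule of
    :func:`detect_plateau` and ``"manual_override"`` for verdicts injected
    from reviewer or field-testing calls; diagnostics are ``None`` for
    overrides.
    """

    is_plateau: bool
    window_start: Months | None
    drop_in_window: Probability | None
    at_risk_at_window: int | None
    source: str = "detector"

    def __post_init__(self) -> None:
        if self.source not in ("detector", "manual_override"):
            raise ValueError(f"unknown plateau source {self.source!r}")
        if self.drop_in_window is not None and self.drop_in_window < -_EPS:
            raise ValueError("drop_in_window must be non-negative")

    @classmethod
    def manual(cls, is_plateau: bool) -> "PlateauVerdict":
        return cls(is_plateau=bool(is_plateau), window_start=None,
                   drop_in_window=None, at_risk_at_window=None,
                   source="manual_override")


def km_estimate(event_times, event_flags) -> StepCurve:
    """Product-limit estimate from raw durations and event indicators.

    ``event_flags[i]`` is truthy when subject ``i`` had the event at
    ``event_times[i]`` and falsy when censored then.  Every distinct observed
    time appears in the output grid, so censoring-only times carry a flat
    step; a censored-only sample yields a curve flat at 1.0.
    """
    durations = np.asarray(event_times, dtype=float)
    observed = np.asarray(event_flags, dtype=bool)
    if durations.ndim != 1 or durations.size == 0:
        raise ValueError("at least one subject is required")
    if durations.shape != observed.shape:
        raise ValueError("event_times and event_flags must have equal length")
    if np.any(durations < 0) or np.any(~np.isfinite(durations)):
        raise ValueError("event times must be finite and non-negative")

    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    table = kmf.event_table  # indexed by distinct times, plus a t=0 row
    grid = table.index.values.astype(float)
    # lifelines always lists a t=0 row; keep it only if someone was observed at 0
    if grid.size and grid[0] == 0 and not np.any(durations == 0):
        grid = grid[1:]
    surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    at_risk = table["at_risk"].loc[grid].to_numpy(dtype=int)
    return StepCurve(times=grid, surv=surv, at_risk=at_risk,
                     max_followup=float(durations.max()),
                     n_enrolled=int(durations.size))


def survival_at(curve: StepCurve, t: Months) -> MaybeProbability:
    """S(t) under the right-continuous step convention.

    Returns ``NOT_REPORTED`` when ``t`` exceeds the observed follow-up —
    the curve does not extend that far and is never extrapolated.
    """
    if t < 0:
        raise ValueError("survival query time must be non-negative")
    if t > curve.max_followup + _EPS:
        return NOT_REPORTED
    idx = np.searchsorted(curve.times, t + _EPS) - 1
    if idx < 0:
        return 1.0
    return float(curve.surv[idx])


def median_survival(curve: StepCurve) -> MaybeMonths:
    """Smallest time with S(t) <= 0.5; ``NOT_REACHED`` if never within follow-up."""
    below = np.nonzero(curve.surv <= 0.5 + _EPS)[0]
    if below.size == 0:
        return NOT_REACHED
    return float(curve.times[below[0]])


def rmst(curve: StepCurve, tau: Months) -> Months:
    """Restricted mean survival time: area under the step curve on [0, tau]."""
    if not tau > 0:
        raise ValueError("tau must be positive")
    if tau > curve.max_followup + _EPS:
        raise ValueError("tau must lie within the observed follow-up")
    mask = curve.times < tau
    edges = np.concatenate([[0.0], curve.times[mask], [tau]])
    values = np.concatenate([[1.0], curve.surv[mask]])
    return float(np.sum(np.diff(edges) * values))


def detect_plateau(curve: StepCurve, window_frac: float = 0.2,
                   drop_tol: Probability = 0.05,
                   min_at_risk: int = 10) -> PlateauVerdict:
    """Operational long-term-plateau rule on the trailing end of a curve.

    The trailing ``window_frac`` of the follow-up is a plateau when the total
    Kaplan-Meier drop within it is below ``drop_tol`` and at least
    ``min_at_risk`` patients are still at risk when the window opens.  The
    at-risk guard mirrors the imprecision concern behind milestone rules:
    a flat tail supported by a handful of patients is not credited.
    """
    if not 0 < window_frac < 1:
        raise ValueError("window_frac must lie strictly between 0 and 1")
    if drop_tol < 0:
        raise ValueError("drop_tol must be non-negative")
    if min_at_risk < 1:
        raise ValueError("min_at_risk must be at least 1")
    if curve.max_followup <= 0:
        raise ValueError("degenerate curve: zero follow-up")

    window_start = (1.0 - window_frac) * curve.max_followup
    s_start = survival_at(curve, window_start)
    s_end = survival_at(curve, curve.max_followup)
    drop = float(s_start) - float(s_end)
    idx = np.searchsorted(curve.times, window_start)
    if idx < len(curve.times):
        at_risk_at_window = int(curve.at_risk[idx])
    elif len(curve.at_risk):
        # no listed time inside the window: last known count is an upper bound
        at_risk_at_window = int(curve.at_risk[-1])
    else:
        at_risk_at_window = curve.n_enrolled
    is_plateau = (drop < drop_tol - _EPS) and (at_risk_at_window >= min_at_risk)
    return PlateauVerdict(is_plateau=is_plateau, window_start=window_start,
                          drop_in_window=max(drop, 0.0),
                          at_risk_at_window=at_risk_at_window,
                          source="detector")


# ---------------------------------------------------------------------------
# text formats


def read_curve_tsv(path) -> StepCurve:
    """Load a digitized step curve from a 3-column TSV.

    Columns (exact header): ``time_months  survival  at_risk``.  The file is
    taken as-is after invariant validation — monotonicity violations are
    errors, never repaired.  The last row marks the end of follow-up and the
    first row's at-risk count is the enrolled number.
    """
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(frame.columns) != CURVE_TSV_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {CURVE_TSV_COLUMNS}, got {list(frame.columns)}")
    if frame.empty:
        raise ValueError(f"{path}: empty curve file")
    return StepCurve(times=frame["time_months"].to_numpy(dtype=float),
                     surv=frame["survival"].to_numpy(dtype=float),
                     at_risk=frame["at_risk"].to_numpy(dtype=int),
                     max_followup=float(frame["time_months"].iloc[-1]),
                     n_enrolled=int(frame["at_risk"].iloc[0]))


def write_curve_tsv(curve: StepCurve, path) -> None:
    frame = pd.DataFrame({"time_months": curve.times,
                          "survival": curve.surv,
                          "at_risk": curve.at_risk})
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_raw_times_tsv(path):
    """Load raw durations: 2-column TSV ``time_months  event`` with event in {0,1}."""
    frame = pd.read_csv(path, sep="\t")
    if list(frame.columns) != RAW_TSV_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {RAW_TSV_COLUMNS}, got {list(frame.columns)}")
    events = frame["event"].to_numpy()
    if not np.isin(events, (0, 1)).all():
        raise ValueError(f"{path}: event column must be 0/1")
    return frame["time_months"].to_numpy(dtype=float), events.astype(bool)
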