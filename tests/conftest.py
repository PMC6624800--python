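"""Shared fixtures: tiny hand-checkable curves and random trial generators."""

from __future__ import annotations

import numpy as np
import pytest

from tailcredit import StepCurve, TrialRecord


def make_curve(times, surv, at_risk=None, max_followup=None, n_enrolled=None):
    times = np.asarray(times, dtype=float)
    surv = np.asarray(surv, dtype=float)
    if at_risk is None:
        # any valid non-increasing positive sequence works for award logic
        at_risk = np.arange(len(times), 0, -1) + 50
    if max_followup is None:
        max_followup = float(times[-1]) if len(times) else 0.0
    if n_enrolled is None:
        n_enrolled = int(at_risk[0]) if len(np.atleast_1d(at_risk)) else 60
    return StepCurve(times=times, surv=surv, at_risk=np.asarray(at_risk),
                     max_followup=max_followup, n_enrolled=n_enrolled)


def random_step_curve(rng: np.random.Generator) -> StepCurve:
    """A random but valid step curve spanning a wide range of regimes."""
    n_steps = int(rng.integers(1, 13))
    times = np.sort(rng.uniform(0.5, rng.choice([20.0, 40.0, 90.0]), n_steps))
    times = np.unique(np.round(times, 3))
    # random non-increasing survival; sometimes plateaus, sometimes reaches 0
    drops = rng.dirichlet(np.ones(len(times))) * rng.uniform(0.3, 1.0)
    surv = np.clip(1.0 - np.cumsum(drops), 0.0, 1.0)
    if rng.random() < 0.3:  # force a flat tail
        k = max(1, len(surv) - int(rng.integers(1, 3)))
        surv[k:] = surv[k - 1]
    n = int(rng.integers(20, 400))
    at_risk = np.maximum.accumulate(
        rng.integers(1, n + 1, len(times))[::-1])[::-1]
    max_followup = float(times[-1]) + float(rng.choice([0.0, 0.0, 5.0, 30.0]))
    return StepCurve(times=times, surv=surv, at_risk=at_risk,
                     max_followup=max_followup, n_enrolled=n)


def random_trial(rng: np.random.Generator, trial_id: str) -> TrialRecord:
    """A random trial record exercising every branch of both award rules."""
    os_reported = bool(rng.random() < 0.9)
    pfs_reported = bool(rng.random() < 0.9) or not os_reported
    curves = {}
    for endpoint, reported in (("OS", os_reported), ("PFS", pfs_reported)):
        if reported:
            curves[(endpoint, "test")] = random_step_curve(rng)
            curves[(endpoint, "control")] = random_step_curve(rng)
    override = None
    if rng.random() < 0.2:
        override = {str(rng.choice(["OS", "PFS"])): bool(rng.random() < 0.5)}
    is_ici = bool(rng.random() < 0.2)
    return TrialRecord(
        trial_id=trial_id,
        therapy_class="ICI" if is_ici else "non-ICI",
        therapy_subclass="ICI" if is_ici else str(rng.choice(
            ["targeted", "chemotherapy", "hormone"])),
        disease_site=str(rng.choice(["lung", "skin", "breast", "hematologic"])),
        hematological=bool(rng.random() < 0.2),
        primary_endpoint=str(rng.choice(["OS", "PFS", "OS+PFS"])),
        primary_significant=bool(rng.random() < 0.8),
        os_reported=os_reported,
        os_obscured_by_crossover=bool(os_reported and rng.random() < 0.15),
        pfs_reported=pfs_reported,
        curves=curves,
        plateau_override=override,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def flat_curve():
    """Event-free curve: S = 1 throughout 10 months of follow-up."""
    return make_curve([10.0], [1.0], at_risk=[40], max_followup=10.0,
                      n_enrolled=40)


@pytest.fixture
def single_step_curve():
    """One step 1.0 -> 0.5 at t = 1, follow-up to 10 months."""
    return make_curve([1.0], [0.5], at_risk=[20], max_followup=10.0,
                      n_enrolled=20)
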