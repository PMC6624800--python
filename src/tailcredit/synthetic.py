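"""Mixture-cure-model trial simulator.

Each arm's survival follows S(t) = pi + (1 - pi) * exp(-(lambda t)^k): a
cured fraction ``pi`` never experiences the event (the curve's plateau) and
the rest draw Weibull(k, rate lambda) latency times (k = 1 is exponential).
Cure is modeled as an infinite event time; administrative censoring at the
end of study (``followup_months`` plus the subject's remaining uniform
accrual offset) guarantees finite observed times.  There is no dropout
process.

Three named presets span the behaviors of interest:

* ``ici_like`` — a genuine cure-fraction gain in the test arm (plateau
  separation), sharp Weibull latency so the plateau is established well
  before twice the control median;
* ``non_ici_like`` — proportional-hazards benefit with zero cure fraction
  in both arms and Weibull shape > 1, so the control tail falls below 20%
  at twice its median;
* ``null`` — identical exponential arms, no benefit of any kind.

Cohorts are reproducible: trial substreams derive from the master seed by
counter-based spawning, so changing cohort composition never shifts another
trial's draws.  The trial-level significance flag is not asserted by the
preset but computed from a log-rank test on the simulated primary endpoint.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from lifelines.statistics import logrank_test

from .curves import km_estimate
from .registry import Cohort, TrialRecord

_ARM_INDEX = {"test": 0, "control": 1}
_ENDPOINT_INDEX = {"OS": 0, "PFS": 1}
MAX_SEED = 2 ** 31


@dataclass(frozen=True)
class CureModelConfig:
    """Generative parameters for one simulated two-arm endpoint.

    Rates are per month; ``weibull_shape`` = 1 gives exponential latency.
    ``seed`` determines every draw; test/control arms and OS/PFS endpoints
    use disjoint substreams of it.
    """

    n_per_arm: int
    cure_fraction_test: float
    cure_fraction_control: float
    event_rate_test: float
    event_rate_control: float
    weibull_shape_test: float = 1.0
    weibull_shape_control: float = 1.0
    accrual_months: float = 12.0
    followup_months: float = 36.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be at least 1")
        for name in ("cure_fraction_test", "cure_fraction_control"):
            value = getattr(self, name)
            if not 0.0 <= value < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        for name in ("event_rate_test", "event_rate_control",
                     "weibull_shape_test", "weibull_shape_control",
                     "followup_months"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.accrual_months < 0:
            raise ValueError("accrual_months must be non-negative")


def simulate_arm(config: CureModelConfig, arm: str, endpoint: str = "OS"):
    """Draw observed (duration, event) pairs for one arm.

    Cured subjects have infinite latent event times and are always censored;
    censoring happens at end of study, ``followup_months`` plus a uniform
    accrual offset in [0, accrual_months].
    """
    if arm not in _ARM_INDEX:
        raise ValueError(f"arm must be 'test' or 'control', got {arm!r}")
    rng = np.random.default_rng(
        [config.seed, _ENDPOINT_INDEX[endpoint], _ARM_INDEX[arm]])
    n = config.n_per_arm
    if arm == "test":
        pi, lam, k = (config.cure_fraction_test, config.event_rate_test,
                      config.weibull_shape_test)
    else:
        pi, lam, k = (config.cure_fraction_control, config.event_rate_control,
                      config.weibull_shape_control)
    cured = rng.random(n) < pi
    latent = rng.exponential(1.0, n) ** (1.0 / k) / lam
    latent[cured] = np.inf
    censor = config.followup_months + rng.uniform(0.0, config.accrual_months, n)
    durations = np.minimum(latent, censor)
    events = latent < censor
    return durations, events


def true_survival(config: CureModelConfig, arm: str, t) -> np.ndarray:
    """Closed-form S(t) = pi + (1 - pi) exp(-(lambda t)^k) for one arm."""
    if arm == "test":
        pi, lam, k = (config.cure_fraction_test, config.event_rate_test,
                      config.weibull_shape_test)
    else:
        pi, lam, k = (config.cure_fraction_control, config.event_rate_control,
                      config.weibull_shape_control)
    t = np.asarray(t, dtype=float)
    return pi + (1 - pi) * np.exp(-((lam * t) ** k))


def derived_pfs_config(os_config: CureModelConfig) -> CureModelConfig:
    """Default PFS endpoint: same cure structure, twice the event rates.

    PFS is simulated as an independent endpoint (no joint model with OS).
    """
    return replace(os_config,
                   event_rate_test=2 * os_config.event_rate_test,
                   event_rate_control=2 * os_config.event_rate_control)


def simulate_trial(trial_id: str, os_config: CureModelConfig,
                   pfs_config: CureModelConfig | None = None, *,
                   therapy_class: str = "non-ICI",
                   therapy_subclass: str = "targeted",
                   disease_site: str = "lung",
                   hematological: bool = False,
                   primary_endpoint: str = "PFS",
                   os_obscured_by_crossover: bool = False,
                   plateau_override: dict[str, bool] | None = None,
                   alpha: float = 0.05) -> TrialRecord:
    """Simulate both endpoints of a two-arm trial and assemble the record.

    ``primary_significant`` is determined by a log-rank test on the simulated
    primary endpoint (for coprimary OS+PFS, on OS), so null trials are
    significant only at the type-I rate.
    """
    if pfs_config is None:
        pfs_config = derived_pfs_config(os_config)
    curves = {}
    raw = {}
    for endpoint, config in (("OS", os_config), ("PFS", pfs_config)):
        for arm in ("test", "control"):
            durations, events = simulate_arm(config, arm, endpoint=endpoint)
            raw[(endpoint, arm)] = (durations, events)
            curves[(endpoint, arm)] = km_estimate(durations, events)
    test_endpoint = "OS" if primary_endpoint in ("OS", "OS+PFS") else "PFS"
    td, te = raw[(test_endpoint, "test")]
    cd, ce = raw[(test_endpoint, "control")]
    lr = logrank_test(td, cd, event_observed_A=te, event_observed_B=ce)
    return TrialRecord(
        trial_id=trial_id,
        therapy_class=therapy_class,
        therapy_subclass=therapy_subclass,
        disease_site=disease_site,
        hematological=hematological,
        primary_endpoint=primary_endpoint,
        primary_significant=bool(lr.p_value < alpha),
        os_reported=True,
        os_obscured_by_crossover=os_obscured_by_crossover,
        pfs_reported=True,
        curves=curves,
        plateau_override=plateau_override,
    )


# ---------------------------------------------------------------------------
# named presets


def ici_like(n_per_arm: int = 500, seed: int = 0, *,
             cure_fraction_test: float = 0.40,
             cure_fraction_control: float = 0.25) -> CureModelConfig:
    """Plateau-separation benefit: cure-fraction gain, shared sharp latency.

    Weibull shape 3 with a control OS median of 8 months means the latency
    distribution is spent well before twice the control median, so milestone
    reads at t2 see the plateaus themselves (asymptotic ratio 0.40/0.25 = 1.6).
    """
    lam = np.log(3.0) ** (1 / 3) / 8.0  # control median 8 mo given pi = 0.25
    return CureModelConfig(n_per_arm=n_per_arm,
                           cure_fraction_test=cure_fraction_test,
                           cure_fraction_control=cure_fraction_control,
                           event_rate_test=lam, event_rate_control=lam,
                           weibull_shape_test=3.0, weibull_shape_control=3.0,
                           accrual_months=12.0, followup_months=36.0,
                           seed=seed)


def non_ici_like(n_per_arm: int = 500, seed: int = 0, *,
                 hazard_ratio: float = 0.65) -> CureModelConfig:
    """Proportional-hazards benefit, no cure fraction in either arm.

    Weibull shape 1.5 pushes the control tail at twice its median to
    exp(-2^1.5 ln 2) = 0.14, below the 20% control-survival floor.
    """
    shape = 1.5
    lam_control = np.log(2.0) ** (1 / shape) / 8.0  # control median 8 mo
    lam_test = lam_control * hazard_ratio ** (1 / shape)
    return CureModelConfig(n_per_arm=n_per_arm,
                           cure_fraction_test=0.0, cure_fraction_control=0.0,
                           event_rate_test=lam_test, event_rate_control=lam_control,
                           weibull_shape_test=shape, weibull_shape_control=shape,
                           accrual_months=12.0, followup_months=36.0,
                           seed=seed)


def null_preset(n_per_arm: int = 500, seed: int = 0) -> CureModelConfig:
    """Identical exponential arms: no benefit of any kind."""
    lam = np.log(2.0) / 8.0  # median 8 mo
    return CureModelConfig(n_per_arm=n_per_arm,
                           cure_fraction_test=0.0, cure_fraction_control=0.0,
                           event_rate_test=lam, event_rate_control=lam,
                           accrual_months=12.0, followup_months=36.0,
                           seed=seed)


PRESETS = {"ici_like": ici_like, "non_ici_like": non_ici_like,
           "null": null_preset}

#: primary-endpoint mix of FDA-approval trial cohorts (OS / PFS / coprimary)
ENDPOINT_WEIGHTS = {"OS": 0.33, "PFS": 0.58, "OS+PFS": 0.09}

_SITES = {"ici_like": ["skin", "lung", "genitourinary"],
          "non_ici_like": ["lung", "breast", "gastrointestinal",
                           "genitourinary", "hematologic"],
          "null": ["lung", "breast", "gastrointestinal", "hematologic"]}


@dataclass(frozen=True)
class CohortRecipe:
    """Sampling plan for a simulated trial cohort.

    ``weights`` assigns each named preset its mixture probability (the 14%
    ICI / 86% non-ICI composition of FDA-approval cohorts is the natural
    default at weight 0.14 on ``ici_like``).
    """

    n_trials: int
    weights: dict[str, float] = field(
        default_factory=lambda: {"ici_like": 0.14, "non_ici_like": 0.66,
                                 "null": 0.20})
    master_seed: int = 0
    n_per_arm: int = 500

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        if not self.weights:
            raise ValueError("weights must be non-empty")
        unknown = set(self.weights) - set(PRESETS)
        if unknown:
            raise ValueError(f"unknown presets {sorted(unknown)}")
        if abs(sum(self.weights.values()) - 1.0) > 1e-9:
            raise ValueError("preset weights must sum to 1")


def simulate_cohort(recipe: CohortRecipe) -> Cohort:
    """Draw a full cohort; deterministic under the master seed.

    Each trial gets its own counter-based substream
    (``SeedSequence(master_seed, spawn_key=(i,))``), so the i-th trial's data
    does not depend on how many trials precede it or which presets they drew.
    """
    names = sorted(recipe.weights)
    probs = np.array([recipe.weights[name] for name in names])
    trials = []
    for i in range(recipe.n_trials):
        ss = np.random.SeedSequence(recipe.master_seed, spawn_key=(i,))
        rng = np.random.default_rng(ss)
        preset = rng.choice(names, p=probs)
        trial_seed = int(ss.generate_state(1, dtype=np.uint32)[0] % MAX_SEED)
        config = PRESETS[preset](n_per_arm=recipe.n_per_arm, seed=trial_seed)
        is_ici = preset == "ici_like"
        endpoints = sorted(ENDPOINT_WEIGHTS)
        primary = rng.choice(endpoints,
                             p=[ENDPOINT_WEIGHTS[e] for e in endpoints])
        site = rng.choice(_SITES[preset])
        subclass = "ICI" if is_ici else rng.choice(
            ["targeted", "chemotherapy", "hormone", "radiopharmaceutical"],
            p=[0.86, 0.09, 0.04, 0.01])
        trials.append(simulate_trial(
            f"T{i:04d}", config,
            therapy_class="ICI" if is_ici else "non-ICI",
            therapy_subclass=str(subclass),
            disease_site=str(site),
            hematological=bool(site == "hematologic"),
            primary_endpoint=str(primary),
            os_obscured_by_crossover=bool(rng.random() < 0.10),
        ))
    return Cohort(trials=trials)


def recipe_from_yaml(path) -> CohortRecipe:
    """Load a cohort recipe from YAML (keys mirror :class:`CohortRecipe`)."""
    with open(path) as handle:
        data = yaml.safe_load(handle)
    known = {f.name for f in dataclasses.fields(CohortRecipe)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown recipe keys {sorted(unknown)}")
    return CohortRecipe(**data)


def recipe_to_yaml(recipe: CohortRecipe, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(recipe)))
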