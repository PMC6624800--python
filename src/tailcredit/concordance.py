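"""Agreement statistics between the two frameworks' award decisions.

The unit of analysis is the 2x2 cross-classification of dual-eligible trials
(award/withhold by each framework): Cohen's unweighted kappa with a Fleiss
asymptotic confidence interval and a null-variance test, the McNemar chi-square
test on the discordant cells, raw percent agreement, and Wald risk differences
for comparing award frequency between trial groups (ICI vs non-ICI).

Risk-difference confidence intervals use the unpooled Wald standard error;
a pooled-variance z test is available behind a flag.  No multiple-testing
adjustment is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .awards import AwardResult
from .registry import Cohort


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 award/withhold cross-classification of the two frameworks."""

    both: int
    asco_only: int
    esmo_only: int
    neither: int

    def __post_init__(self) -> None:
        for name in ("both", "asco_only", "esmo_only", "neither"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.both + self.asco_only + self.esmo_only + self.neither

    def as_matrix(self) -> np.ndarray:
        """Rows: first framework award/withhold; columns: second framework."""
        return np.array([[self.both, self.asco_only],
                         [self.esmo_only, self.neither]], dtype=float)


@dataclass(frozen=True)
class TwoProportions:
    """Awarded/total counts in two trial groups (e.g. ICI vs non-ICI)."""

    x1: int
    n1: int
    x2: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be at least 1")
        if not (0 <= self.x1 <= self.n1 and 0 <= self.x2 <= self.n2):
            raise ValueError("award counts must lie within group sizes")


@dataclass(frozen=True)
class RiskDifferenceResult:
    rd: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float


@dataclass(frozen=True)
class KappaResult:
    kappa: float | None  # None when chance agreement is degenerate (pe = 1)
    se: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None


@dataclass(frozen=True)
class McNemarResult:
    chi2: float | None  # None when there are no discordant pairs
    p_value: float | None


def risk_difference(p: TwoProportions, alpha: float = 0.05,
                    pooled_test: bool = False) -> RiskDifferenceResult:
    """p1 - p2 with an unpooled Wald CI and a two-sided normal test."""
    p1, p2 = p.x1 / p.n1, p.x2 / p.n2
    rd = p1 - p2
    se_unpooled = np.sqrt(p1 * (1 - p1) / p.n1 + p2 * (1 - p2) / p.n2)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    ci_low = rd - zcrit * se_unpooled
    ci_high = rd + zcrit * se_unpooled
    if pooled_test:
        pool = (p.x1 + p.x2) / (p.n1 + p.n2)
        se_test = np.sqrt(pool * (1 - pool) * (1 / p.n1 + 1 / p.n2))
    else:
        se_test = se_unpooled
    if se_test == 0:
        z = 0.0 if rd == 0 else np.inf * np.sign(rd)
    else:
        z = rd / se_test
    p_value = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return RiskDifferenceResult(rd=float(rd), ci_low=float(ci_low),
                                ci_high=float(ci_high), z=float(z),
                                p_value=float(p_value))


def cohen_kappa(t: ConcordanceTable, alpha: float = 0.05) -> KappaResult:
    """Unweighted Cohen kappa from the 2x2 table.

    The CI uses the Fleiss-Cohen-Everitt large-sample variance; the two-sided
    test of kappa = 0 uses the null (chance-agreement) variance.  With
    degenerate margins (chance agreement 1) kappa is undefined and every
    field is None.
    """
    if t.n < 1:
        raise ValueError("table must contain at least one trial")
    n = t.n
    p = t.as_matrix() / n  # p[i][j]: row rater i, col rater j (0=award, 1=withhold)
    po = p[0, 0] + p[1, 1]
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    pe = float(row @ col)
    if 1 - pe < 1e-12:
        return KappaResult(kappa=None, se=None, ci_low=None, ci_high=None,
                           p_value=None)
    kappa = (po - pe) / (1 - pe)

    # Fleiss-Cohen-Everitt asymptotic variance of kappa-hat
    term1 = sum(p[i, i] * ((1 - pe) - (row[i] + col[i]) * (1 - po)) ** 2
                for i in range(2))
    term2 = (1 - po) ** 2 * sum(p[i, j] * (col[i] + row[j]) ** 2
                                for i in range(2) for j in range(2) if i != j)
    term3 = (po * pe - 2 * pe + po) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    zcrit = stats.norm.ppf(1 - alpha / 2)

    # null variance for H0: kappa = 0
    var0 = (pe + pe ** 2 - sum(row[i] * col[i] * (row[i] + col[i])
                               for i in range(2))) / (n * (1 - pe) ** 2)
    se0 = float(np.sqrt(max(var0, 0.0)))
    if se0 > 0:
        p_value = float(2 * stats.norm.sf(abs(kappa) / se0))
    else:
        p_value = 1.0 if kappa == 0 else 0.0
    return KappaResult(kappa=float(kappa), se=se,
                       ci_low=float(kappa - zcrit * se),
                       ci_high=float(kappa + zcrit * se),
                       p_value=p_value)


def mcnemar(t: ConcordanceTable, continuity_correction: bool = False) -> McNemarResult:
    """McNemar chi-square on the discordant cells, 1 df, two-sided.

    Undefined (all-None result) when there are no discordant pairs.
    """
    if t.asco_only + t.esmo_only == 0:
        return McNemarResult(chi2=None, p_value=None)
    table = [[t.both, t.asco_only], [t.esmo_only, t.neither]]
    result = _sm_mcnemar(table, exact=False, correction=continuity_correction)
    return McNemarResult(chi2=float(result.statistic), p_value=float(result.pvalue))


def percent_agreement(t: ConcordanceTable) -> float:
    """Raw agreement (both award or both withhold), in percent."""
    if t.n == 0:
        raise ValueError("empty table")
    return 100.0 * (t.both + t.neither) / t.n


def build_concordance(cohort: Cohort, asco_results, esmo_results,
                      ) -> tuple[ConcordanceTable, dict[str, ConcordanceTable]]:
    """Tabulate award agreement over the dual-eligible trials of a cohort.

    ``asco_results`` and ``esmo_results`` are sequences of
    :class:`AwardResult` covering exactly the cohort's trials; trials whose
    ESMO result carries an ``ineligible_reason`` are excluded (they were
    never assessed by that framework).  Returns the main table plus subgroup
    tables keyed ``therapy_class=...``, ``esmo_endpoint=...`` and
    ``disease_site=...``.
    """
    asco_by_id = _index_results(asco_results, "asco_results")
    esmo_by_id = _index_results(esmo_results, "esmo_results")
    cohort_ids = {t.trial_id for t in cohort}
    for name, index in (("asco_results", asco_by_id), ("esmo_results", esmo_by_id)):
        if set(index) != cohort_ids:
            raise ValueError(f"{name} do not cover exactly the cohort's trials")

    cells: dict[str, list] = {}

    def _tally(key: str, asco_awarded: bool, esmo_awarded: bool) -> None:
        counts = cells.setdefault(key, [0, 0, 0, 0])
        idx = (0 if asco_awarded and esmo_awarded else
               1 if asco_awarded else
               2 if esmo_awarded else 3)
        counts[idx] += 1

    for trial in cohort:
        esmo_res = esmo_by_id[trial.trial_id]
        if esmo_res.ineligible_reason is not None:
            continue
        asco_res = asco_by_id[trial.trial_id]
        a, e = asco_res.awarded, esmo_res.awarded
        _tally("all", a, e)
        _tally(f"therapy_class={trial.therapy_class}", a, e)
        _tally(f"esmo_endpoint={esmo_res.endpoint_used}", a, e)
        _tally(f"disease_site={trial.disease_site}", a, e)

    main = ConcordanceTable(*cells.get("all", [0, 0, 0, 0]))
    subgroups = {key: ConcordanceTable(*counts)
                 for key, counts in cells.items() if key != "all"}
    return main, subgroups


def _index_results(results, name: str) -> dict[str, AwardResult]:
    index: dict[str, AwardResult] = {}
    for result in results:
        if result.trial_id in index:
            raise ValueError(f"{name}: duplicate result for {result.trial_id}")
        index[result.trial_id] = result
    return index
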