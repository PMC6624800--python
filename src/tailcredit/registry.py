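"""Trial-level data model and cohort I/O.

A :class:`TrialRecord` is one two-arm randomized trial carrying the flags the
award rules need (therapy class, primary endpoint, significance, crossover,
hematological indication) plus the per-endpoint, per-arm survival curves.
Cohorts round-trip through a documented CSV/JSON table plus one curve TSV per
arm per endpoint, named ``<trial_id>__<endpoint>__<arm>.tsv``.

ESMO-style eligibility (statistically significant primary endpoint, and not a
hematological anticancer agent) is a predicate here because it gates only one
framework's assessment path; the ASCO-style rule has no eligibility gate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .curves import StepCurve, read_curve_tsv, write_curve_tsv

ENDPOINTS = ("OS", "PFS")
ARMS = ("test", "control")
THERAPY_CLASSES = ("ICI", "non-ICI")
THERAPY_SUBCLASSES = ("chemotherapy", "targeted", "hormone",
                      "radiopharmaceutical", "ICI")
PRIMARY_ENDPOINTS = ("OS", "PFS", "OS+PFS")

#: required trial-table columns, in order
TRIAL_COLUMNS = [
    "trial_id", "therapy_class", "therapy_subclass", "disease_site",
    "hematological", "primary_endpoint", "primary_significant",
    "os_reported", "os_obscured_by_crossover", "pfs_reported",
]
_OPTIONAL_COLUMNS = ["plateau_override_os", "plateau_override_pfs", "provenance"]

_BOOL_FLAGS = ["hematological", "primary_significant", "os_reported",
               "os_obscured_by_crossover", "pfs_reported"]


@dataclass
class TrialRecord:
    trial_id: str
    therapy_class: str
    therapy_subclass: str
    disease_site: str
    hematological: bool
    primary_endpoint: str
    primary_significant: bool
    os_reported: bool
    os_obscured_by_crossover: bool
    pfs_reported: bool
    curves: dict[tuple[str, str], StepCurve] = field(default_factory=dict)
    plateau_override: dict[str, bool] | None = None
    provenance: str | None = None

    def __post_init__(self) -> None:
        if self.therapy_class not in THERAPY_CLASSES:
            raise ValueError(
                f"trial {self.trial_id}: therapy_class must be one of "
                f"{THERAPY_CLASSES}, got {self.therapy_class!r}")
        if self.therapy_subclass not in THERAPY_SUBCLASSES:
            raise ValueError(
                f"trial {self.trial_id}: unknown therapy_subclass "
                f"{self.therapy_subclass!r}")
        if self.primary_endpoint not in PRIMARY_ENDPOINTS:
            raise ValueError(
                f"trial {self.trial_id}: primary_endpoint must be one of "
                f"{PRIMARY_ENDPOINTS}, got {self.primary_endpoint!r}")
        for endpoint, flag in (("OS", self.os_reported), ("PFS", self.pfs_reported)):
            if flag:
                for arm in ARMS:
                    if (endpoint, arm) not in self.curves:
                        raise ValueError(
                            f"trial {self.trial_id}: {endpoint.lower()}_reported "
                            f"but {endpoint}/{arm} curve is missing")

    def curve(self, endpoint: str, arm: str) -> StepCurve:
        return self.curves[(endpoint, arm)]


@dataclass
class Cohort:
    trials: list[TrialRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for trial in self.trials:
            if trial.trial_id in seen:
                raise ValueError(f"duplicate trial_id {trial.trial_id!r}")
            seen.add(trial.trial_id)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def get(self, trial_id: str) -> TrialRecord:
        for trial in self.trials:
            if trial.trial_id == trial_id:
                return trial
        raise KeyError(trial_id)


def esmo_eligible(trial: TrialRecord) -> bool:
    """Assessable for a long-term-plateau adjustment: statistically
    significant primary endpoint and not a hematological agent."""
    return trial.primary_significant and not trial.hematological


def _parse_bool(value, trial_id: str, column: str) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValueError(
        f"trial {trial_id}: cannot parse boolean field {column}={value!r}")


def curve_filename(trial_id: str, endpoint: str, arm: str) -> str:
    return f"{trial_id}__{endpoint}__{arm}.tsv"


def _rows_from_table(trial_table: Path) -> list[dict]:
    if trial_table.suffix.lower() == ".json":
        with open(trial_table) as handle:
            rows = json.load(handle)
        if not isinstance(rows, list):
            raise ValueError(f"{trial_table}: JSON trial table must be a list")
        return rows
    frame = pd.read_csv(trial_table, dtype=str)
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{trial_table}: missing columns {missing}")
    unknown = [c for c in frame.columns
               if c not in TRIAL_COLUMNS + _OPTIONAL_COLUMNS]
    if unknown:
        raise ValueError(f"{trial_table}: unknown columns {unknown}")
    return frame.to_dict(orient="records")


def read_cohort(trial_table, curve_dir) -> Cohort:
    """Load and fully validate a cohort from a trial table plus curve files.

    Every invariant is checked on load; errors name the offending trial and
    field.  Curves are only loaded for endpoints flagged as reported.
    """
    trial_table = Path(trial_table)
    curve_dir = Path(curve_dir)
    trials: list[TrialRecord] = []
    for row in _rows_from_table(trial_table):
        trial_id = str(row["trial_id"])
        flags = {col: _parse_bool(row[col], trial_id, col) for col in _BOOL_FLAGS}
        curves: dict[tuple[str, str], StepCurve] = {}
        for endpoint, reported in (("OS", flags["os_reported"]),
                                   ("PFS", flags["pfs_reported"])):
            if not reported:
                continue
            for arm in ARMS:
                path = curve_dir / curve_filename(trial_id, endpoint, arm)
                if not path.exists():
                    raise FileNotFoundError(
                        f"trial {trial_id}: curve file {path} not found")
                curves[(endpoint, arm)] = read_curve_tsv(path)
        override: dict[str, bool] | None = None
        for endpoint, column in (("OS", "plateau_override_os"),
                                 ("PFS", "plateau_override_pfs")):
            value = row.get(column)
            if value is not None and not pd.isna(value) and str(value) != "":
                override = override or {}
                override[endpoint] = _parse_bool(value, trial_id, column)
        provenance = row.get("provenance")
        if provenance is not None and pd.isna(provenance):
            provenance = None
        trials.append(TrialRecord(
            trial_id=trial_id,
            therapy_class=str(row["therapy_class"]),
            therapy_subclass=str(row["therapy_subclass"]),
            disease_site=str(row["disease_site"]),
            hematological=flags["hematological"],
            primary_endpoint=str(row["primary_endpoint"]),
            primary_significant=flags["primary_significant"],
            os_reported=flags["os_reported"],
            os_obscured_by_crossover=flags["os_obscured_by_crossover"],
            pfs_reported=flags["pfs_reported"],
            curves=curves,
            plateau_override=override,
            provenance=provenance,
        ))
    return Cohort(trials=trials)


def write_cohort(cohort: Cohort, trial_table, curve_dir) -> None:
    """Write the cohort table (CSV or JSON by suffix) and one TSV per curve."""
    trial_table = Path(trial_table)
    curve_dir = Path(curve_dir)
    curve_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in cohort:
        row = {
            "trial_id": trial.trial_id,
            "therapy_class": trial.therapy_class,
            "therapy_subclass": trial.therapy_subclass,
            "disease_site": trial.disease_site,
            "hematological": trial.hematological,
            "primary_endpoint": trial.primary_endpoint,
            "primary_significant": trial.primary_significant,
            "os_reported": trial.os_reported,
            "os_obscured_by_crossover": trial.os_obscured_by_crossover,
            "pfs_reported": trial.pfs_reported,
        }
        if trial.plateau_override:
            for endpoint, column in (("OS", "plateau_override_os"),
                                     ("PFS", "plateau_override_pfs")):
                if endpoint in trial.plateau_override:
                    row[column] = trial.plateau_override[endpoint]
        if trial.provenance is not None:
            row["provenance"] = trial.provenance
        rows.append(row)
        for (endpoint, arm), curve in trial.curves.items():
            write_curve_tsv(curve, curve_dir / curve_filename(
                trial.trial_id, endpoint, arm))
    if trial_table.suffix.lower() == ".json":
        with open(trial_table, "w") as handle:
            json.dump(rows, handle, indent=1, default=bool)
    else:
        pd.DataFrame(rows).to_csv(trial_table, index=False)
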