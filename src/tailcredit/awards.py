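"""Shared award-decision container for both framework rules."""

from __future__ import annotations

from dataclasses import dataclass, field

ASCO_TOC = "ASCO_TOC"
ESMO_LTP = "ESMO_LTP"

#: ESMO adjustment kinds (terminal: downstream grading is out of scope)
ADJUSTMENT_NONE = "none"
PFS_UPGRADE = "pfs_upgrade"
OS_CURATIVE_SCORING = "os_curative_scoring"


@dataclass
class AwardResult:
    """One framework's binary long-term-survival decision on one trial.

    ``points`` carries the 0/16/20 bonus on the ASCO path; ``adjustment``
    carries the kind of plateau adjustment on the ESMO path.  At most one
    award per trial per framework; ``criteria_detail`` keeps the full
    per-criterion breakdown for every endpoint that was actually evaluated.
    """

    framework: str
    trial_id: str
    awarded: bool
    endpoint_used: str  # "OS" | "PFS" | "none"
    points: int = 0
    adjustment: str = ADJUSTMENT_NONE
    ineligible_reason: str | None = None
    criteria_detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.framework not in (ASCO_TOC, ESMO_LTP):
            raise ValueError(f"unknown framework {self.framework!r}")
        if self.points not in (0, 16, 20):
            raise ValueError(f"points must be 0, 16 or 20, got {self.points}")
        if self.adjustment not in (ADJUSTMENT_NONE, PFS_UPGRADE, OS_CURATIVE_SCORING):
            raise ValueError(f"unknown adjustment kind {self.adjustment!r}")
        if self.awarded != (self.points > 0 or self.adjustment != ADJUSTMENT_NONE):
            raise ValueError("awarded flag inconsistent with points/adjustment")
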