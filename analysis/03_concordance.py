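"""Agreement between the two frameworks, on simulated and published counts.

Builds the dual-eligible 2x2 award table for the simulated cohort, computes
Cohen kappa, McNemar and percent agreement, and the ICI vs non-ICI risk
difference in award frequency; then recomputes the same statistics from the
published counts of the 100-trial FDA-approval cohort for comparison.
Writes results/concordance_summary.csv.
"""

from pathlib import Path

import pandas as pd

from tailcredit import (ConcordanceTable, TwoProportions, award_ltp, award_toc,
                        build_concordance, cohen_kappa, mcnemar,
                        percent_agreement, read_cohort, risk_difference)

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "results" / "cohort"

PUBLISHED_TABLE = ConcordanceTable(both=1, asco_only=37, esmo_only=1, neither=39)
PUBLISHED_TOC_RD = TwoProportions(8, 14, 37, 86)


def describe(label: str, table: ConcordanceTable) -> dict:
    kappa = cohen_kappa(table)
    mc = mcnemar(table)
    return {
        "source": label, "n": table.n, "both": table.both,
        "asco_only": table.asco_only, "esmo_only": table.esmo_only,
        "neither": table.neither,
        "percent_agreement": round(percent_agreement(table), 1),
        "kappa": None if kappa.kappa is None else round(kappa.kappa, 4),
        "mcnemar_chi2": None if mc.chi2 is None else round(mc.chi2, 2),
    }


def main() -> None:
    cohort = read_cohort(COHORT / "cohort.csv", COHORT / "curves")
    asco_results = [award_toc(t) for t in cohort]
    esmo_results = [award_ltp(t) for t in cohort]
    table, subgroups = build_concordance(cohort, asco_results, esmo_results)

    rows = [describe("simulated_cohort", table),
            describe("published_counts", PUBLISHED_TABLE)]
    for key, sub in sorted(subgroups.items()):
        if key.startswith("therapy_class="):
            rows.append(describe(f"simulated_{key}", sub))
    frame = pd.DataFrame(rows)
    out = ROOT / "results" / "concordance_summary.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out, index=False)
    print(frame.to_string(index=False))

    ici = [(r, t) for r, t in zip(asco_results, cohort)
           if t.therapy_class == "ICI"]
    non = [(r, t) for r, t in zip(asco_results, cohort)
           if t.therapy_class != "ICI"]
    rd = risk_difference(TwoProportions(
        sum(r.awarded for r, _ in ici), len(ici),
        sum(r.awarded for r, _ in non), len(non)))
    pub = risk_difference(PUBLISHED_TOC_RD)
    print(f"\nTOC award risk difference ICI vs non-ICI (simulated): "
          f"{rd.rd:+.2f} (95% CI {rd.ci_low:.2f} to {rd.ci_high:.2f})")
    print(f"TOC award risk difference ICI vs non-ICI (published): "
          f"{pub.rd:+.2f} (95% CI {pub.ci_low:.2f} to {pub.ci_high:.2f})")


if __name__ == "__main__":
    main()
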