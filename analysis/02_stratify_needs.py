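"""Stratify the synthetic cohort into general-demand vs high-need groups.

Applies the WHODAS 2.0 cutoffs (cognition > 77.5, mobility > 78.5,
self-care > 55, summary > 66.5, all required) and writes per-group counts
and score summaries under results/needs/.
"""

from pathlib import Path

import pandas as pd

from careaccess import data_io, needs

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = data_io.read_cases(ROOT / "synthetic" / "cases.csv")
    community, report = data_io.filter_community(table.records)
    groups, counts = needs.stratify_cohort(community)

    out = ROOT / "needs"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for group, members in groups.items():
        scores = pd.DataFrame([m.scores.as_tuple() for m in members],
                              columns=["d1", "d2", "d3", "d4", "d5", "d6", "summary"])
        row = {"group": group.value, "n": len(members)}
        row.update({f"mean_{c}": round(scores[c].mean(), 2) for c in scores})
        rows.append(row)
    summary = pd.DataFrame(rows)
    data_io.write_results(summary, out / "group_summary.csv")

    n = report.n_retained
    print(f"{n} community cases ({report.n_excluded} institutional excluded)")
    for _, r in summary.iterrows():
        print(
            f"  {r['group']}: n={r['n']} ({100 * r['n'] / n:.1f}%), "
            f"mean cognition {r['mean_d1']}, mean summary {r['mean_summary']}"
        )


if __name__ == "__main__":
    main()
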