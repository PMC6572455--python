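"""Re-analyse the bundled published area-level tables for Taiwan.

From the 22-area provider/case counts and reported PWD/TLD values, this
recomputes service densities, the four-way classification per needs
stratum, and the resource-allocation priority ranking.  Writes tables under
results/reference/.
"""

import json
from pathlib import Path

from careaccess import data_io, indicators, published
from careaccess.pipeline import area_results_from_table, results_frame

ROOT = Path(__file__).resolve().parents[1] / "results" / "reference"


def main() -> None:
    df = published.area_table()
    ROOT.mkdir(parents=True, exist_ok=True)

    df = df.assign(
        density_ratio=[
            indicators.service_density(int(c), int(p))
            for c, p in zip(df["n_cases"], df["n_providers"])
        ]
    )
    overall = indicators.service_density(int(df["n_cases"].sum()), int(df["n_providers"].sum()))
    data_io.write_results(df, ROOT / "area_densities.csv")

    summary = {}
    for group in ("all", "general_demand", "high_level_of_need"):
        results = area_results_from_table(published.area_table(), group)
        summary[group] = indicators.summarize(results)
    (ROOT / "category_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    ranking = indicators.rank_priorities(area_results_from_table(published.area_table(), "all"))
    data_io.write_results(results_frame(ranking), ROOT / "priority_ranking.csv")

    print(f"overall density {overall} cases/provider; "
          f"{int((df['density_ratio'] > overall).sum())} of {len(df)} areas above it")
    print("category summary:", json.dumps(summary["all"]))
    print("top-5 priority areas:")
    for r in ranking[:5]:
        print(f"  {r.priority_rank}. {r.area_code} ({r.category.value}, tld={r.tld})")


if __name__ == "__main__":
    main()
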