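"""Extract PWD/TLD, classify areas and rank them for allocation priority.

Reads the stored joinpoint fits, derives per-area indicators for each needs
stratum, and writes the area table, category summary and priority ranking
under results/indicators/.
"""

import json
from pathlib import Path

import pandas as pd

from careaccess import data_io, indicators
from careaccess.indicators import AreaResult
from careaccess.joinpoint import JoinpointFit
from careaccess.pipeline import results_frame

ROOT = Path(__file__).resolve().parents[1] / "results"
BIN_WIDTH = 50.0


def main() -> None:
    payload = json.loads((ROOT / "fits" / "fits.json").read_text())
    cases = data_io.read_cases(ROOT / "synthetic" / "cases.csv").records
    providers = data_io.read_providers(ROOT / "synthetic" / "providers.csv").records
    areas = sorted({c.area_code for c in cases} | {p.area_code for p in providers})
    prov_count = {a: sum(p.area_code == a for p in providers) for a in areas}
    case_count = {a: sum(c.area_code == a for c in cases) for a in areas}

    results: dict[str, list[AreaResult]] = {}
    for key, item in payload.items():
        area, _, group = key.partition("|")
        if "error" in item or item["k"] == 0:
            pwd = tld = None
        else:
            fit = JoinpointFit(
                k=item["k"],
                breakpoints=tuple(item["breakpoints"]),
                intercept=item["intercept"],
                slopes=tuple(item["slopes"]),
                rss=item["rss"],
                n_points=item["n_points"],
                selection=item["selection"],
                p_values=tuple(item["p_values"]),
            )
            pwd, tld = indicators.extract_pwd_tld(fit, bin_width=BIN_WIDTH)
        results.setdefault(group, []).append(
            AreaResult(
                area_code=area,
                group=group,
                pwd=pwd,
                tld=tld,
                category=indicators.classify_area(pwd, tld),
                n_cases=case_count.get(area, 0),
                n_providers=prov_count.get(area, 0),
                density_ratio=indicators.service_density(
                    case_count.get(area, 0), prov_count.get(area, 0)
                ),
            )
        )
    # areas absent from the fits (no curve at all) are "neither"
    for group in results:
        seen = {r.area_code for r in results[group]}
        for a in areas:
            if a not in seen:
                results[group].append(
                    AreaResult(
                        area_code=a, group=group, pwd=None, tld=None,
                        category=indicators.classify_area(None, None),
                        n_cases=case_count.get(a, 0), n_providers=prov_count.get(a, 0),
                        density_ratio=indicators.service_density(
                            case_count.get(a, 0), prov_count.get(a, 0)
                        ),
                    )
                )

    out = ROOT / "indicators"
    out.mkdir(parents=True, exist_ok=True)
    for group, res in results.items():
        data_io.write_results(results_frame(sorted(res, key=lambda r: r.area_code)),
                              out / f"areas_{group}.csv")
    summary = {g: indicators.summarize(res) for g, res in results.items()}
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    ranking = indicators.rank_priorities(results["all"])
    data_io.write_results(results_frame(ranking), out / "ranking.csv")

    print("category summary (all cases):", summary["all"])
    print("priority order:", " > ".join(r.area_code for r in ranking))
    for r in ranking:
        print(
            f"  {r.priority_rank}. {r.area_code}: {r.category.value}, "
            f"pwd={r.pwd}, tld={r.tld}, density={r.density_ratio}"
        )


if __name__ == "__main__":
    main()
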