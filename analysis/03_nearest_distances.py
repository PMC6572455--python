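"""Match cases to their nearest same-area provider and bin the distances.

Writes matches.csv (one row per served case) and curves.csv (50 m binned
frequency curves per area and needs stratum) under results/spatial/.
"""

from pathlib import Path

from careaccess import data_io, needs, spatial
from careaccess.needs import NeedsGroup

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cases = data_io.read_cases(ROOT / "synthetic" / "cases.csv").records
    providers = data_io.read_providers(ROOT / "synthetic" / "providers.csv").records
    community, _ = data_io.filter_community(cases)
    unique_providers, _ = data_io.dedupe_providers(providers)

    matches, unserved = spatial.nearest_distances_by_area(community, unique_providers)
    groups, _ = needs.stratify_cohort(community)
    membership = {
        "all": {c.case_id for c in community},
        "general_demand": {c.case_id for c in groups[NeedsGroup.GENERAL_DEMAND]},
        "high_level_of_need": {c.case_id for c in groups[NeedsGroup.HIGH_LEVEL_OF_NEED]},
    }

    out = ROOT / "spatial"
    out.mkdir(parents=True, exist_ok=True)
    data_io.write_results(spatial.matches_to_rows(matches), out / "matches.csv")

    curve_rows = []
    areas = sorted({m.area_code for m in matches})
    for area in areas:
        area_matches = [m for m in matches if m.area_code == area]
        for group, ids in membership.items():
            sub = [m for m in area_matches if m.case_id in ids]
            curve = spatial.build_distance_curve(sub, 50.0, area, group)
            curve_rows.extend(spatial.curve_to_rows(curve))
    data_io.write_results(curve_rows, out / "curves.csv")

    print(f"{len(matches)} cases matched in {len(areas)} served areas; {len(unserved)} unserved")
    for area in areas:
        ds = [m.distance for m in matches if m.area_code == area]
        print(f"  {area}: median nearest distance {sorted(ds)[len(ds) // 2]:.0f} m")


if __name__ == "__main__":
    main()
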