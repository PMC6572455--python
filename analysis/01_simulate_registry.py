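"""Build the synthetic study registry: four areas with known curve shapes.

Three served areas whose nearest-distance curves are rise-fall-rise with
known breakpoints (so the indicator stages can be checked against ground
truth) and one provider-less area, mirroring the situation of remote island
counties.  Writes cases.csv and providers.csv under results/synthetic/.
"""

import argparse
import dataclasses
from pathlib import Path

from careaccess import data_io
from careaccess.synthetic_data import AreaSpec, gen_registry

RESULTS = Path(__file__).resolve().parents[1] / "results" / "synthetic"

#: Ground truth per area: (pwd, tld) breakpoints baked into the curves.
AREA_SPECS = [
    AreaSpec("A01", n_providers=6, n_cases=2500, breakpoints=(300.0, 1500.0)),
    AreaSpec(
        "A02",
        n_providers=4,
        n_cases=1800,
        breakpoints=(400.0, 1800.0),
        slopes=(0.3, -0.1, 0.05),
        intercept=30.0,
        n_bins=48,
    ),
    AreaSpec(
        "A03",
        n_providers=5,
        n_cases=1500,
        provider_layout="clustered",
        breakpoints=(300.0, 1500.0),
        noise_sd=4.0,
    ),
    AreaSpec("A04", n_providers=0, n_cases=30),  # remote area without supply
]


def main(seed: int = 11) -> None:
    providers, cases = gen_registry(AREA_SPECS, seed=seed)
    RESULTS.mkdir(parents=True, exist_ok=True)
    data_io.write_results(
        [
            {
                "case_id": c.case_id,
                "area_code": c.area_code,
                "x": c.x,
                "y": c.y,
                "age": c.age,
                "sex": c.sex,
                "severity": c.severity,
                "residence": c.residence,
                **dict(zip(("d1", "d2", "d3", "d4", "d5", "d6", "summary"), c.scores.as_tuple())),
            }
            for c in cases
        ],
        RESULTS / "cases.csv",
    )
    data_io.write_results([dataclasses.asdict(p) for p in providers], RESULTS / "providers.csv")
    per_area = {s.area_code: sum(1 for c in cases if c.area_code == s.area_code) for s in AREA_SPECS}
    print(f"registry: {len(cases)} cases, {len(providers)} providers (seed {seed})")
    for spec in AREA_SPECS:
        truth = f"breakpoints {spec.breakpoints}" if spec.n_providers else "no providers"
        print(f"  {spec.area_code}: {per_area[spec.area_code]} cases, {spec.n_providers} providers, {truth}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    main(ap.parse_args().seed)
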