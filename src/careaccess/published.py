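"""Published area-level statistics bundled as an example dataset.

Provider and community-dementia-case counts, and the reported PWD/TLD
indicator values, for the 22 administrative areas of Taiwan (national
disability registry, July 2012 - October 2013; providers from the 2016
ministry roster).  The underlying case-level coordinates are not public, so
these area-level tables are the reference inputs for the reporting half of
the pipeline: service densities, four-way classification, category
summaries and priority ranking are all recomputable from them.

Missing indicator values (areas where no significant joinpoint of the
required sign was found) are NaN.

Provider-count note: the national roster deduplicates 2116 listed providers
to 1786 unique coordinate sites, while the area table below sums to 1782
(the published per-area tally).  Both figures are retained; density ratios
follow the area table.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["area_table", "SELECTION_FLOW"]

#: Published sample-selection flow counts for the case and provider rosters.
SELECTION_FLOW = {
    "registered_disability": 157_478,
    "dementia_cases": 11_967,
    "institutional_residents": 2_263,
    "community_cases": 9_704,
    "providers_listed": 2_116,
    "duplicate_coordinate_providers": 330,
    "providers_unique_coordinates": 1_786,
}

_AREA_CSV = """\
area,area_km2,n_providers,n_cases,n_general,n_high,pwd_all,tld_all,pwd_general,tld_general,pwd_high,tld_high
Taipei City,271.8,162,1564,996,568,650,1200,350,1300,,600
New Taipei City,2052.6,227,1554,1010,544,200,2200,200,1800,,950
Keelung City,132.8,38,105,81,24,300,1250,,,,550
Taoyuan City,1221.0,102,622,409,213,200,3250,250,1850,150,2250
Hsinchu County,1427.5,48,153,84,69,200,1500,300,1200,,
Hsinchu City,104.2,26,90,59,31,150,,,1200,,
Miaoli County,1820.3,41,194,122,72,150,2950,150,1000,,
Taichung City,2214.9,149,868,563,305,150,3000,150,3000,150,2150
Changhua County,1074.4,90,416,292,124,150,4750,,,,
Nantou County,4106.4,42,232,178,54,150,3650,,4050,,
Yunlin County,1290.8,72,388,251,137,,6250,,,,
Chiayi County,1903.6,54,358,261,97,300,1200,400,700,,
Chiayi City,60.0,40,152,103,49,250,,350,,350,
Tainan City,2191.7,169,965,719,246,350,1200,300,1450,450,4500
Kaohsiung City,2951.9,237,1005,737,268,350,1600,300,1700,300,1600
Pingtung County,2775.6,98,394,279,115,150,3600,150,2950,,
Yilan County,2143.6,72,263,197,66,150,1200,,1100,,
Hualien County,4628.6,40,181,126,55,600,1700,550,1650,,
Taitung County,3515.3,47,123,78,45,,1300,,,,900
Penghu County,126.9,13,32,20,12,,,,,,
Kinmen County,151.7,9,42,27,15,,,,,,
Lienchiang County,28.8,6,3,1,2,,,,,,
"""


def area_table() -> pd.DataFrame:
    """The 22-area reference table as a DataFrame (one row per area).

    Columns: provider/case counts per needs group and PWD/TLD in metres for
    the three analysis strata (all cases, general demand, high need).
    """
    return pd.read_csv(io.StringIO(_AREA_CSV))
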