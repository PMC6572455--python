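import numpy as np
import pytest

from careaccess.data_io import CaseRecord, DomainScores, ProviderRecord

GOOD_SCORES = DomainScores(80.0, 85.0, 60.0, 50.0, 70.0, 40.0, 70.0)
LOW_SCORES = DomainScores(10.0, 10.0, 10.0, 10.0, 10.0, 10.0, 10.0)


def make_case(
    case_id="c1",
    area="A",
    x=0.0,
    y=0.0,
    residence="community",
    scores=GOOD_SCORES,
    age=80.0,
    **kw,
):
    return CaseRecord(
        case_id=case_id,
        area_code=area,
        x=x,
        y=y,
        age=age,
        sex=kw.get("sex", "female"),
        severity=kw.get("severity", "moderate"),
        residence=residence,
        scores=scores,
        items=kw.get("items"),
    )


def make_provider(provider_id="p1", area="A", x=0.0, y=0.0):
    return ProviderRecord(provider_id=provider_id, area_code=area, x=x, y=y)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
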