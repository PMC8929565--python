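import numpy as np
import pytest

from rtebench import (
    CareType,
    ServiceRecord,
    default_knowledge_base,
    generate_services,
    quirc_domains_for,
)


def make_record(
    service_id="s1",
    care_type=CareType.SUPPORTED_HOUSING,
    places=20,
    staff_fte_per_user=0.5,
    annual_budget=500_000.0,
    length_of_stay=2.0,
    occupied_places=19,
    movers_2yr=4,
    quirc=None,
    **kw,
):
    if quirc is None:
        quirc = {d: 60.0 for d in quirc_domains_for(care_type)}
    return ServiceRecord(
        service_id=service_id,
        care_type=care_type,
        places=places,
        staff_fte_per_user=staff_fte_per_user,
        annual_budget=annual_budget,
        length_of_stay=length_of_stay,
        occupied_places=occupied_places,
        movers_2yr=movers_2yr,
        quirc=quirc,
        **kw,
    )


@pytest.fixture(scope="session")
def sh_cohort():
    """Small supported-housing cohort used across modules."""
    return generate_services(CareType.SUPPORTED_HOUSING, 12, seed=7)


@pytest.fixture(scope="session")
def sh_kb(sh_cohort):
    return default_knowledge_base(sh_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
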