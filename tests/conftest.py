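import datetime as dt

import pytest

from vaxtiming import ChildRecord, VaccinationEvent, Visit, default_epi_schedule

DOB = dt.date(2010, 1, 1)


def make_child(events=None, visits=None, dob=DOB, child_id="c1", sex="female", **covs):
    """Build a ChildRecord from {dose label: age in days} and [(age, card_seen)]."""
    events = events or {}
    visits = visits or [(400, True)]
    evs = sorted(
        (VaccinationEvent(lab, dob + dt.timedelta(days=age))
         for lab, age in events.items() if age is not None),
        key=lambda e: (e.date, e.antigen),
    )
    vis = [Visit(dob + dt.timedelta(days=a), seen) for a, seen in visits]
    return ChildRecord(child_id=child_id, dob=dob, sex=sex, covariates=covs,
                       visits=vis, events=evs)


ON_TIME = {
    "BCG": 0, "OPV0": 0,
    "OPV1": 42, "PENTA1": 42, "OPV2": 70, "PENTA2": 70,
    "OPV3": 98, "PENTA3": 98, "MV": 274,
}


@pytest.fixture(scope="session")
def schedule():
    return default_epi_schedule()


@pytest.fixture()
def on_time_child():
    return make_child(dict(ON_TIME))
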