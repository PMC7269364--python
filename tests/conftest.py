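import datetime

import pytest

from muacdose.anthropometry import synthetic_reference
from muacdose.qc import qc_cohort
from muacdose.synthetic import generate_cohort, preset_config
from muacdose.types import DischargeStatus, Facility, Oedema, PatientCard, Sex, VisitRecord


def make_card(
    card_id="C1",
    country="Kenya",
    facility=Facility.TFP,
    age_months=12,
    sex=Sex.FEMALE,
    visits=None,
    discharge_status=DischargeStatus.RECOVERED,
):
    """A hand-built card: visits as (day_offset, muac, weight[, height])."""
    base = datetime.date(2013, 1, 1)
    vs = []
    for v in visits or [(0, 100, 5.0), (7, 102, 5.2)]:
        day, muac, weight = v[:3]
        height = v[3] if len(v) > 3 else None
        vs.append(
            VisitRecord(
                visit_date=base + datetime.timedelta(days=day),
                muac=muac,
                weight=weight,
                height=height,
                oedema=Oedema.MISSING,
            )
        )
    return PatientCard(
        card_id=card_id,
        country=country,
        facility=facility,
        age_months=age_months,
        sex=sex,
        visits=tuple(vs),
        discharge_status=discharge_status,
    )


@pytest.fixture(scope="session")
def reference():
    return synthetic_reference()


@pytest.fixture(scope="session")
def anchor_cohort():
    """Moderate-noise cohort under the band-anchor preset (seed fixed)."""
    return generate_cohort(preset_config("band_anchor", n_per_country=300, seed=101))


@pytest.fixture(scope="session")
def anchor_observations(anchor_cohort):
    return qc_cohort(anchor_cohort).observations
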