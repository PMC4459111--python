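import datetime as dt

import pytest

from amiepisodes.claims_io import ClaimRecord


def make_claim(
    claim_id="C1",
    patient_id="P1",
    admission="2007-03-01",
    discharge="2007-03-10",
    *,
    provider_id="H001",
    sex="male",
    age_years=60,
    admission_route="emergency",
    dx_primary="I21.0",
    dx_secondary=(),
    proc_codes=(),
):
    """Shorthand claim factory for tests."""
    return ClaimRecord(
        claim_id=claim_id,
        patient_id=patient_id,
        provider_id=provider_id,
        sex=sex,
        age_years=age_years,
        admission_date=dt.date.fromisoformat(admission),
        discharge_date=dt.date.fromisoformat(discharge),
        admission_route=admission_route,
        dx_primary=dx_primary,
        dx_secondary=tuple(dx_secondary),
        proc_codes=tuple(proc_codes),
    )


@pytest.fixture
def claim_factory():
    return make_claim
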