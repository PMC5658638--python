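import datetime as dt

import pandas as pd
import pytest

from effortrisk.claims_io import ClaimRecord, ContactEvent, claims_to_frame, contacts_to_frame
from effortrisk.datasets import expert_panel_weights, published_factor_averages


@pytest.fixture(scope="session")
def panel_weights():
    """The six expert-elicited percentage weights (sum 100)."""
    return expert_panel_weights()


@pytest.fixture(scope="session")
def published_averages():
    """Per-diagnosis factor averages of the 25 published high-effort rows."""
    return published_factor_averages()


def make_claim(
    claim_id,
    household_id="H1",
    member_id=None,
    codes=("A",),
    out_of_network=False,
    denied=False,
    adjusted=False,
    date=dt.date(2014, 6, 1),
):
    return ClaimRecord(
        claim_id=claim_id,
        household_id=household_id,
        member_id=member_id or f"{household_id}-M1",
        service_date=date,
        diagnosis_codes=tuple(codes),
        out_of_network=out_of_network,
        denied=denied,
        adjusted=adjusted,
    )


def claims_frame(*records):
    return claims_to_frame(records)


def contacts_frame(*events):
    """Each event is a (household_id, channel) pair."""
    return contacts_to_frame(
        [ContactEvent(hh, ch, dt.date(2014, 7, 1)) for hh, ch in events]
    )


@pytest.fixture
def six_line_household():
    """One household: three claims {denied, clean, denied+adjusted} and
    contacts {phone, web, mobile} — the hand-countable aggregation fixture."""
    claims = claims_frame(
        make_claim("c1", "H1", denied=True),
        make_claim("c2", "H1"),
        make_claim("c3", "H1", denied=True, adjusted=True),
    )
    contacts = contacts_frame(("H1", "phone"), ("H1", "web"), ("H1", "mobile"))
    return claims, contacts
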