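import pytest
from hypothesis import settings

import nmbtender as nt

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def carotid():
    """The packaged carotid-stent tender (lot, offers); rates read as percent."""
    return nt.carotid_stent_fixture()


@pytest.fixture(scope="session")
def worked_example_lot():
    """A single-endpoint lot engineered to reproduce the published worked
    example's step trace exactly.

    The published example's per-endpoint fixed parameters are unavailable, so
    the printed intermediate totals (26.2625 disutility QALDs, 891.5365 euro
    total cost at a 530-euro price) are folded into one composite endpoint at
    rate 0.5: disutility = 26.2625 / (0.5 * 365) lasting the whole horizon,
    cost per event = (891.5365 - 530) / 0.5.
    """
    endpoint = nt.EndpointSpec(
        endpoint_id="composite",
        label="composite adverse outcome (synthetic calibration endpoint)",
        disutility=26.2625 / (0.5 * 365.0),
        duration_months=12.0,
        cost_per_event=(891.5365 - 530.0) / 0.5,
    )
    lot = nt.LotParameters(
        lot_id="worked-example",
        horizon_months=12.0,
        baseline_utility=0.93,
        wtp_per_qaly=60_000.0,
        starting_price=600.0,
        endpoints=(endpoint,),
    )
    offer = nt.DeviceOffer(
        device_id="winner", manufacturer="Winner", price=530.0,
        event_rates={"composite": 0.5})
    return lot, offer


def oracle_nmb(lot, offer, include_price=True):
    """Independent one-line expectation of the NMB, straight from the formula.

    Kept deliberately separate from the package's step-by-step pipeline so it
    can serve as a brute-force cross-check.
    """
    return (
        (lot.baseline_utility
         - sum(offer.event_rates[ep.endpoint_id] * ep.disutility
               * ep.duration_months / lot.horizon_months
               for ep in lot.endpoints))
        * lot.horizon_days / lot.days_per_year * lot.wtp_per_qaly
        - (sum(offer.event_rates[ep.endpoint_id] * ep.cost_per_event
               for ep in lot.endpoints)
           + (offer.price if include_price else 0.0))
    )
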