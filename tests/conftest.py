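import hypothesis
import pytest

import puffbox as pb

hypothesis.settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def nicotine():
    """The office-day constituent: 60 µg inhaled, 50 % retained → 30 µg out."""
    return pb.Constituent("nicotine", inhaled_mass_per_puff=60.0, retention_rate=50.0)


@pytest.fixture
def office_room():
    """15 m² × 2.5 m office, 37.5 m³, ACH 1.33, no recirculation."""
    return pb.Room(volume=37.5, ach=1.33, floor_area=15.0)


@pytest.fixture
def office_transport():
    return pb.TransportParams(front_speed=0.6, deposition_velocity=0.06)


@pytest.fixture
def office_puff(nicotine):
    return pb.Puff.from_constituent(0.0, nicotine)


@pytest.fixture
def bystander():
    return pb.Observer(distance=2.0, breathing_rate=8.0)
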