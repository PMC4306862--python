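"""Single-puff physics: emission, cuboid dilution, arrival and removal."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import puffbox as pb


class TestEmission:
    @pytest.mark.parametrize(
        "inhaled, retention, expected",
        [
            (60.0, 50.0, 30.0),   # office-day user: half of 60 µg re-exhaled
            (31.0, 0.0, 31.0),    # machine-generated aerosol: nothing retained
            (42.0, 100.0, 0.0),   # full retention releases nothing
        ],
    )
    def test_exhaled_mass(self, inhaled, retention, expected):
        assert pb.exhaled_mass(inhaled, retention) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "inhaled, retention", [(-1.0, 50.0), (10.0, -5.0), (10.0, 101.0)]
    )
    def test_exhaled_mass_domain_errors(self, inhaled, retention):
        with pytest.raises(ValueError):
            pb.exhaled_mass(inhaled, retention)

    def test_initial_concentration(self):
        assert pb.initial_concentration(30.0, 0.0005) == pytest.approx(60000.0)
        assert pb.initial_concentration(0.0, 0.01) == 0.0
        with pytest.raises(ValueError):
            pb.initial_concentration(30.0, 0.0)

    def test_constituent_links_inhaled_and_exhaled(self, nicotine):
        assert nicotine.exhaled_mass_per_puff == pytest.approx(30.0)


class TestAerosolVolume:
    def test_starts_at_exhaled_volume(self, office_puff, office_transport, office_room):
        assert pb.aerosol_volume(
            0.0, office_puff, office_transport, office_room
        ) == pytest.approx(office_puff.exhaled_volume)

    def test_office_puff_fills_room_within_three_minutes(
        self, office_puff, office_transport, office_room
    ):
        # at 0.6 m/min front speed a single puff fills the 37.5 m³ office in ~3 min
        assert pb.aerosol_volume(
            3.0, office_puff, office_transport, office_room
        ) == pytest.approx(37.5)
        assert pb.fill_time(office_puff, office_transport, office_room) < 3.0

    def test_chamber_puff_fills_room_within_one_minute(self, office_puff):
        room = pb.Room(volume=39.0, ach=12.6)
        transport = pb.TransportParams(front_speed=2.0)
        assert pb.aerosol_volume(1.0, office_puff, transport, room) == pytest.approx(39.0)

    def test_zero_speed_keeps_initial_volume(self, office_puff, office_room):
        transport = pb.TransportParams(front_speed=0.0)
        for t in (0.0, 5.0, 500.0):
            assert pb.aerosol_volume(
                t, office_puff, transport, office_room
            ) == pytest.approx(office_puff.exhaled_volume)

    @given(
        t1=st.floats(0.0, 100.0),
        t2=st.floats(0.0, 100.0),
        speed=st.floats(0.0, 5.0),
    )
    def test_nondecreasing_and_capped(self, t1, t2, speed):
        puff = pb.Puff(0.0, constituents=(("nicotine", 30.0),))
        room = pb.Room(volume=37.5, ach=1.33, floor_area=15.0)
        transport = pb.TransportParams(front_speed=speed)
        lo, hi = sorted((t1, t2))
        v_lo = pb.aerosol_volume(lo, puff, transport, room)
        v_hi = pb.aerosol_volume(hi, puff, transport, room)
        assert v_lo <= v_hi <= room.volume

    def test_anisotropic_growth(self, office_puff, office_room):
        transport = pb.TransportParams(front_speed=(0.6, 0.3, 0.0))
        L0 = office_puff.exhaled_volume ** (1 / 3)
        t = 1.0
        expected = (L0 + 1.2 * t) * (L0 + 0.6 * t) * L0
        assert pb.aerosol_volume(
            t, office_puff, transport, office_room
        ) == pytest.approx(expected)


class TestRemovalRates:
    def test_office_extraction_flow(self, office_room, office_transport):
        rates = pb.removal_rates(office_room, office_transport)
        assert rates.q_extract == pytest.approx(0.83125)
        assert rates.q_dep == pytest.approx(
            office_room.deposition_surface * 0.06
        )
        assert rates.a * office_room.volume == pytest.approx(
            rates.q_extract + rates.q_dep
        )

    def test_chamber_extraction_flow(self):
        room = pb.Room(volume=39.0, ach=12.6)
        rates = pb.removal_rates(room, pb.TransportParams(front_speed=2.0))
        assert rates.q_extract == pytest.approx(8.19)

    def test_full_recirculation_removes_nothing(self, office_transport):
        room = pb.Room(volume=37.5, ach=1.33, recycling_rate=100.0)
        assert pb.removal_rates(room, office_transport).q_extract == 0.0


class TestArrivalAndOnset:
    def test_bystander_reached_when_room_fills(
        self, office_puff, office_transport, office_room, bystander
    ):
        # front would need 3.27 min to travel 2 m, but the room fills at 2.72 min
        arrival = pb.arrival_time(office_puff, office_transport, office_room, bystander)
        assert arrival == pytest.approx(2.7232, rel=1e-3)

    def test_front_arrival_when_closer(self, office_puff, office_transport, office_room):
        observer = pb.Observer(distance=1.0)
        arrival = pb.arrival_time(office_puff, office_transport, office_room, observer)
        L0 = office_puff.exhaled_volume ** (1 / 3)
        assert arrival == pytest.approx((1.0 - L0 / 2) / 0.6)

    def test_observer_at_source(self, office_puff, office_transport, office_room):
        observer = pb.Observer(distance=0.0)
        assert pb.arrival_time(office_puff, office_transport, office_room, observer) == 0.0

    def test_never_reached_without_propagation(self, office_puff, office_room, bystander):
        transport = pb.TransportParams(front_speed=0.0)
        assert math.isinf(
            pb.arrival_time(office_puff, transport, office_room, bystander)
        )

    def test_extraction_starts_at_80_percent_fill(
        self, office_puff, office_transport, office_room
    ):
        t_init = pb.extraction_start_time(office_puff, office_transport, office_room)
        assert t_init == pytest.approx(2.5232, rel=1e-3)
        vol = pb.aerosol_volume(t_init, office_puff, office_transport, office_room)
        assert vol == pytest.approx(0.8 * 37.5)

    def test_fraction_one_means_full_fill(self, office_puff, office_room):
        transport = pb.TransportParams(front_speed=0.6, extraction_start_fraction=1.0)
        assert pb.extraction_start_time(
            office_puff, transport, office_room
        ) == pytest.approx(pb.fill_time(office_puff, transport, office_room))

    def test_already_filled_room_starts_immediately(self):
        puff = pb.Puff(0.0, exhaled_volume=1.0, constituents=(("x", 1.0),))
        room = pb.Room(volume=1.0, ach=1.0)
        transport = pb.TransportParams(front_speed=0.1)
        assert pb.extraction_start_time(puff, transport, room) == 0.0


class TestSinglePuffConcentration:
    def test_zero_before_arrival(
        self, office_puff, nicotine, office_room, office_transport, bystander
    ):
        assert (
            pb.single_puff_concentration(
                1.0, office_puff, nicotine, office_room, office_transport, bystander
            )
            == 0.0
        )

    def test_conservation_without_removal(self, office_puff, nicotine, bystander):
        # no ventilation, no deposition: the 30 µg stay airborne and end up
        # perfectly mixed at 30/37.5 = 0.8 µg/m³
        room = pb.Room(volume=37.5, ach=0.0, deposition_surface=0.0)
        transport = pb.TransportParams(front_speed=0.6, deposition_velocity=0.0)
        conc = pb.single_puff_concentration(
            60.0, office_puff, nicotine, room, transport, bystander
        )
        assert conc == pytest.approx(0.8)

    def test_half_life_after_mixing(
        self, office_puff, nicotine, office_room, office_transport, bystander
    ):
        a = pb.removal_rates(office_room, office_transport).a
        t_fill = pb.fill_time(office_puff, office_transport, office_room)
        t0 = t_fill + 1.0
        c0 = pb.single_puff_concentration(
            t0, office_puff, nicotine, office_room, office_transport, bystander
        )
        c_half = pb.single_puff_concentration(
            t0 + math.log(2) / a,
            office_puff, nicotine, office_room, office_transport, bystander,
        )
        assert c_half == pytest.approx(c0 / 2)

    @given(scale=st.floats(0.1, 10.0))
    def test_homogeneous_in_exhaled_mass(self, scale):
        room = pb.Room(volume=37.5, ach=1.33, floor_area=15.0)
        transport = pb.TransportParams(front_speed=0.6, deposition_velocity=0.06)
        observer = pb.Observer(distance=2.0)
        base = pb.Constituent("nicotine", 60.0, 50.0)
        scaled = pb.Constituent("nicotine", 60.0 * scale, 50.0)
        t = np.linspace(0.0, 30.0, 301)
        c1 = pb.single_puff_concentration(
            t, pb.Puff.from_constituent(0.0, base), base, room, transport, observer
        )
        c2 = pb.single_puff_concentration(
            t, pb.Puff.from_constituent(0.0, scaled), scaled, room, transport, observer
        )
        np.testing.assert_allclose(c2, scale * c1, rtol=1e-12)

    def test_profile_continuous_and_monotone_after_arrival(
        self, office_puff, nicotine, office_room, office_transport, bystander
    ):
        t = np.linspace(0.0, 60.0, 60001)
        c = pb.single_puff_concentration(
            t, office_puff, nicotine, office_room, office_transport, bystander
        )
        arrival = pb.arrival_time(office_puff, office_transport, office_room, bystander)
        after = c[t >= arrival + 1e-6]
        assert np.all(np.diff(after) <= 1e-12)
        # no jump larger than the grid-resolved slope anywhere after arrival
        assert np.max(np.abs(np.diff(after))) < 1e-2
        assert c.max() <= pb.initial_concentration(30.0, office_puff.exhaled_volume)

    def test_well_mixed_oracle(self, nicotine, bystander):
        # exhaling the whole room volume reduces the model to the classic
        # one-box solution C0 * exp(-a t), which is known in closed form
        room = pb.Room(volume=37.5, ach=1.33, floor_area=15.0)
        transport = pb.TransportParams(front_speed=0.6, deposition_velocity=0.06)
        puff = pb.Puff(
            0.0, exhaled_volume=37.5, constituents=(("nicotine", 30.0),)
        )
        a = pb.removal_rates(room, transport).a
        t = np.linspace(0.0, 120.0, 1201)
        model = pb.single_puff_concentration(
            t, puff, nicotine, room, transport, bystander
        )
        oracle = (30.0 / 37.5) * np.exp(-a * t)
        np.testing.assert_allclose(model, oracle, rtol=1e-12)

    def test_mass_balance_closes(
        self, office_puff, nicotine, office_room, office_transport
    ):
        # exhaled mass = airborne mass + cumulative removed mass; removal
        # acts with flux (Q_extract+Q_dep) * airborne/V_room once extraction
        # and deposition switch on at the 80 %-fill time
        observer = pb.Observer(distance=0.0)
        rates = pb.removal_rates(office_room, office_transport)
        flow = rates.q_extract + rates.q_dep
        t_init = pb.extraction_start_time(office_puff, office_transport, office_room)
        t = np.linspace(0.0, 120.0, 120001)
        conc = pb.single_puff_concentration(
            t, office_puff, nicotine, office_room, office_transport, observer
        )
        vol = pb.aerosol_volume(t, office_puff, office_transport, office_room)
        airborne = conc * vol
        removed_rate = np.where(t >= t_init, flow * airborne / office_room.volume, 0.0)
        removed = np.trapezoid(removed_rate, t)
        assert airborne[-1] + removed == pytest.approx(30.0, rel=5e-3)

    def test_time_before_emission_rejected(
        self, nicotine, office_room, office_transport, bystander
    ):
        puff = pb.Puff.from_constituent(10.0, nicotine)
        with pytest.raises(ValueError):
            pb.single_puff_concentration(
                5.0, puff, nicotine, office_room, office_transport, bystander
            )

    @pytest.mark.parametrize("parameter", ["deposition_velocity", "ach"])
    def test_pointwise_monotone_in_removal_parameters(
        self, parameter, office_puff, nicotine, bystander
    ):
        t = np.linspace(0.0, 60.0, 6001)
        profiles = []
        for value in (0.01, 0.06) if parameter == "deposition_velocity" else (1.0, 3.0):
            room = pb.Room(
                volume=37.5,
                ach=value if parameter == "ach" else 1.33,
                floor_area=15.0,
            )
            transport = pb.TransportParams(
                front_speed=0.6,
                deposition_velocity=value
                if parameter == "deposition_velocity"
                else 0.06,
            )
            profiles.append(
                pb.single_puff_concentration(
                    t, office_puff, nicotine, room, transport, bystander
                )
            )
        assert np.all(profiles[1] <= profiles[0] + 1e-15)
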