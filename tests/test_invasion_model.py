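"""Three-probability invasion model, provenance bookkeeping and aggregation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from invexpect.errors import ValidationError
from invexpect.invasion_model import (
    EARTH_RADIUS_KM,
    BallastParcel,
    ModelParams,
    PortCall,
    ShipSpec,
    ballast_provenance,
    complement_product,
    great_circle_distance,
    haversine_km,
    p_establish,
    p_intro,
    p_intro_values,
    p_nonindigenous,
    port_pair_invasion_probability,
    region_invasion_probability,
    route_invasion_probability,
    simulate_any_success_frequency,
)


def spherical_law_of_cosines(lon1, lat1, lon2, lat2):
    """Independent second-formula distance oracle."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dlam = math.radians(lon2 - lon1)
    return EARTH_RADIUS_KM * math.acos(
        min(1.0, math.sin(phi1) * math.sin(phi2) + math.cos(phi1) * math.cos(phi2) * math.cos(dlam))
    )


def any_success_enumeration(probs):
    """Exhaustive inclusion-exclusion over independent Bernoulli events."""
    total = 0.0
    for outcome in itertools.product([0, 1], repeat=len(probs)):
        if any(outcome):
            weight = 1.0
            for hit, p in zip(outcome, probs):
                weight *= p if hit else (1.0 - p)
            total += weight
    return total


params_strategy = st.builds(
    ModelParams,
    alpha=st.floats(1e-6, 1.0),
    beta=st.floats(0.1, 6.0),
    gamma=st.floats(1e-3, 1e12),
    lam=st.floats(1e-8, 1.0),
    mu=st.floats(0.0, 1.0),
    sigma_t=st.floats(0.1, 20.0),
    sigma_s=st.floats(0.1, 40.0),
)


class TestDistance:
    def test_identical_ports_distance_zero(self, port_factory):
        a = port_factory("a", lon=12.5, lat=-30.0)
        b = port_factory("b", lon=12.5, lat=-30.0)
        assert great_circle_distance(a, b) == 0.0

    def test_antipodal_on_equator(self):
        assert haversine_km(0.0, 0.0, 180.0, 0.0) == pytest.approx(
            math.pi * EARTH_RADIUS_KM, abs=1e-6
        )

    def test_matches_independent_spherical_law_of_cosines(self):
        got = haversine_km(4.0, 52.0, 28.0, 43.0)
        want = spherical_law_of_cosines(4.0, 52.0, 28.0, 43.0)
        assert got == pytest.approx(want, abs=0.1)

    def test_symmetry_and_coordinate_validation(self):
        assert haversine_km(4, 52, 28, 43) == haversine_km(28, 43, 4, 52)
        with pytest.raises(ValidationError):
            haversine_km(200.0, 0.0, 0.0, 0.0)


class TestNonindigenous:
    def test_symmetry_point_half(self, unit_params):
        assert p_nonindigenous(1.0, unit_params) == pytest.approx(0.5)

    def test_limit_to_one_at_large_distance(self, unit_params):
        assert p_nonindigenous(1e12, unit_params) > 1 - 1e-9

    def test_closed_form(self):
        params = ModelParams(
            alpha=1.0, beta=2.0, gamma=10.0, lam=1.0, mu=0.0, sigma_t=1.0, sigma_s=1.0
        )
        assert p_nonindigenous(5.0, params) == pytest.approx(1 / (1 + 10 / 25))

    def test_zero_distance_convention_and_negative_error(self, unit_params):
        assert p_nonindigenous(0.0, unit_params) == 0.0
        with pytest.raises(ValidationError):
            p_nonindigenous(-1.0, unit_params)

    @given(st.floats(1e-6, 1e9), st.floats(1.0, 1e6), params_strategy)
    def test_monotone_nondecreasing_in_distance(self, d, step, params):
        # non-strict: the sigmoid saturates to 1 within float precision
        assert p_nonindigenous(d + step, params) >= p_nonindigenous(d, params)


class TestIntro:
    def test_no_discharge_means_no_introduction(self, unit_params):
        assert p_intro_values(0.0, 5.0, unit_params) == 0.0

    def test_saturation_limit(self):
        params = ModelParams(
            alpha=1.0, beta=1.0, gamma=1.0, lam=1.0, mu=0.0, sigma_t=1.0, sigma_s=1.0
        )
        assert p_intro_values(50.0, 0.0, params) >= 1 - 1e-9

    def test_closed_form(self):
        params = ModelParams(
            alpha=1.0, beta=1.0, gamma=1.0, lam=0.001, mu=0.01, sigma_t=1.0, sigma_s=1.0
        )
        want = (1 - math.exp(-1.0)) * math.exp(-0.1)
        parcel = BallastParcel("i", "j", "r", volume=1000.0, travel_time=10.0)
        assert p_intro(parcel, params) == pytest.approx(want, rel=1e-12)

    def test_negative_inputs_rejected(self, unit_params):
        with pytest.raises(ValidationError):
            p_intro_values(-1.0, 0.0, unit_params)
        with pytest.raises(ValidationError):
            p_intro_values(1.0, -1.0, unit_params)

    @given(st.floats(0.0, 1e5), st.floats(0.1, 1e4), st.floats(0.0, 100.0), params_strategy)
    def test_monotone_in_volume_and_travel_time(self, volume, dv, dt, params):
        # non-strict at the float-saturated extremes of either exponential
        assert p_intro_values(volume + dv, dt, params) >= p_intro_values(volume, dt, params)
        if params.mu > 0:
            assert p_intro_values(volume + dv, dt + 1.0, params) <= p_intro_values(
                volume + dv, dt, params
            )


class TestEstablish:
    def test_perfect_match_attains_alpha(self, port_factory):
        params = ModelParams(
            alpha=0.37, beta=1.0, gamma=1.0, lam=1.0, mu=0.0, sigma_t=2.0, sigma_s=5.0
        )
        a = port_factory("a", temperature=10.0, salinity=30.0)
        b = port_factory("b", temperature=10.0, salinity=30.0)
        assert p_establish(a, b, params) == pytest.approx(0.37)

    def test_one_sigma_temperature_offset(self, port_factory, unit_params):
        a = port_factory("a", temperature=11.0, salinity=30.0)
        b = port_factory("b", temperature=10.0, salinity=30.0)
        assert p_establish(a, b, unit_params) == pytest.approx(math.exp(-0.5))

    def test_symmetric_in_port_swap(self, port_factory, unit_params):
        a = port_factory("a", temperature=14.0, salinity=8.0)
        b = port_factory("b", temperature=9.0, salinity=31.0)
        assert p_establish(a, b, unit_params) == p_establish(b, a, unit_params)

    def test_missing_environment_rejected(self, port_factory, unit_params):
        a = port_factory("a", salinity=float("nan"))
        b = port_factory("b")
        with pytest.raises(ValidationError, match="salinity"):
            p_establish(a, b, unit_params)

    @given(st.floats(0.0, 50.0), st.floats(0.0, 50.0), params_strategy)
    def test_decreasing_in_environmental_mismatch(self, dt, ds, params):
        def prob(dtemp, dsal):
            return params.alpha * math.exp(
                -0.5 * ((dtemp / params.sigma_t) ** 2 + (dsal / params.sigma_s) ** 2)
            )

        assert prob(dt + 1.0, ds) <= prob(dt, ds)


class TestRouteAndAggregation:
    def test_product_of_three_factors(self, port_factory, unit_params):
        ports = {
            "i": port_factory("i", lon=0.0, lat=0.0, temperature=10.0, salinity=20.0),
            "j": port_factory("j", lon=10.0, lat=0.0, temperature=12.0, salinity=25.0),
        }
        parcel = BallastParcel("i", "j", "r", volume=2.0, travel_time=3.0)
        d = great_circle_distance(ports["i"], ports["j"])
        want = (
            p_nonindigenous(d, unit_params)
            * p_intro(parcel, unit_params)
            * p_establish(ports["i"], ports["j"], unit_params)
        )
        assert route_invasion_probability(parcel, ports, unit_params) == pytest.approx(want)

    def test_any_zero_factor_annihilates(self, port_factory, unit_params):
        ports = {"i": port_factory("i"), "j": port_factory("j", lon=10.0)}
        parcel = BallastParcel("i", "j", "r", volume=0.0, travel_time=0.0)
        assert route_invasion_probability(parcel, ports, unit_params) == 0.0

    def test_unknown_port_rejected(self, port_factory, unit_params):
        parcel = BallastParcel("i", "ghost", "r", volume=1.0, travel_time=0.0)
        with pytest.raises(ValidationError, match="ghost"):
            route_invasion_probability(parcel, {"i": port_factory("i")}, unit_params)

    def test_custom_distance_hook_is_used(self, port_factory, unit_params):
        ports = {"i": port_factory("i"), "j": port_factory("j", lon=10.0)}
        parcel = BallastParcel("i", "j", "r", volume=50.0, travel_time=0.0)
        fixed = route_invasion_probability(
            parcel, ports, unit_params, distance_fn=lambda a, b: 1.0
        )
        assert fixed == pytest.approx(0.5 * p_intro(parcel, unit_params) * unit_params.alpha)

    def test_complement_product_examples(self):
        assert complement_product([0.3]) == pytest.approx(0.3)
        assert complement_product([0.5, 0.5]) == pytest.approx(0.75)
        assert complement_product([0.1, 0.2, 0.3]) == pytest.approx(0.496)
        assert complement_product([]) == 0.0

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_aggregation_matches_exhaustive_enumeration(self, probs):
        assert complement_product(probs) == pytest.approx(
            any_success_enumeration(probs), abs=1e-10
        )

    def test_port_pair_aggregation_matches_brute_force(self, port_factory, unit_params):
        rng = np.random.default_rng(5)
        ports = {
            "i": port_factory("i", lon=0.0, temperature=10.0, salinity=20.0),
            "j": port_factory("j", lon=40.0, temperature=13.0, salinity=22.0),
        }
        parcels = [
            BallastParcel("i", "j", f"r{k}", volume=float(rng.uniform(0, 5)), travel_time=float(rng.uniform(0, 20)))
            for k in range(10)
        ]
        pair = port_pair_invasion_probability(parcels, ports, unit_params)
        routes = [route_invasion_probability(p, ports, unit_params) for p in parcels]
        brute = 1.0
        for p in routes:
            brute *= 1.0 - p
        assert pair.p_invasion == pytest.approx(1.0 - brute, abs=1e-12)
        assert pair.p_invasion >= max(routes)
        assert pair.n_routes == 10

    def test_single_parcel_pair_equals_route_value(self, port_factory, unit_params):
        ports = {"i": port_factory("i"), "j": port_factory("j", lon=15.0)}
        parcel = BallastParcel("i", "j", "r", volume=1.0, travel_time=2.0)
        pair = port_pair_invasion_probability([parcel], ports, unit_params)
        assert pair.p_invasion == pytest.approx(
            route_invasion_probability(parcel, ports, unit_params)
        )

    def test_mixed_port_pairs_rejected(self, port_factory, unit_params):
        ports = {"i": port_factory("i"), "j": port_factory("j", lon=15.0)}
        parcels = [
            BallastParcel("i", "j", "r0", volume=1.0, travel_time=0.0),
            BallastParcel("j", "i", "r1", volume=1.0, travel_time=0.0),
        ]
        with pytest.raises(ValidationError, match="mix"):
            port_pair_invasion_probability(parcels, ports, unit_params)


class TestRegionAggregation:
    def _pair(self, p):
        from invexpect.invasion_model import PortPairProbability

        return PortPairProbability(
            i="a", j="b", distance_km=1.0, p_nonindigenous=1.0, p_establish=1.0,
            p_invasion=p, n_routes=1,
        )

    def test_single_pair_value_carried_through(self):
        pairs = [self._pair(0.04849)]
        got = region_invasion_probability(pairs, "north_baltic", "great_lakes_st_lawrence")
        assert got == pytest.approx(0.04849)

    def test_all_zero_pairs(self):
        pairs = [self._pair(0.0)] * 3
        assert region_invasion_probability(pairs, "eurasia", "north_baltic") == 0.0

    def test_complement_product_over_pairs(self):
        pairs = [self._pair(p) for p in (0.1, 0.2, 0.3)]
        got = region_invasion_probability(pairs, "eurasia", "north_baltic")
        assert got == pytest.approx(0.496)

    def test_monotone_as_pairs_added(self):
        values = [0.05, 0.1, 0.2, 0.4]
        last = 0.0
        for k in range(1, len(values) + 1):
            pairs = [self._pair(p) for p in values[:k]]
            current = region_invasion_probability(pairs, "eurasia", "north_baltic")
            assert current >= last
            last = current

    def test_empty_pair_list_warns_and_returns_zero(self, caplog):
        with caplog.at_level("WARNING"):
            got = region_invasion_probability([], "eurasia", "north_baltic")
        assert got == 0.0
        assert any("no shipping connection" in rec.message for rec in caplog.records)


class TestBallastProvenance:
    spec = ShipSpec("s1", "bulk_carrier", "medium", tank_volume=1000.0, mean_discharge_per_call=500.0)

    def _calls(self, ports_and_times):
        return [
            PortCall("s1", port, arrival, departure)
            for port, arrival, departure in ports_and_times
        ]

    def test_two_call_voyage_single_parcel(self):
        calls = self._calls([("i", 0.0, 1.0), ("j", 5.0, 6.0)])
        parcels = ballast_provenance(calls, self.spec, 0.25)
        assert len(parcels) == 1
        (parcel,) = parcels
        assert parcel.origin_port == "i" and parcel.discharge_port == "j"
        assert parcel.volume == pytest.approx(250.0)
        assert parcel.travel_time == pytest.approx(4.0)  # departure at i to arrival at j

    def test_three_call_well_mixed_bookkeeping(self):
        calls = self._calls([("i", 0.0, 1.0), ("j", 3.0, 4.0), ("k", 8.0, 9.0)])
        parcels = ballast_provenance(calls, self.spec, 0.5)
        at_k = {(p.origin_port, p.discharge_port): p.volume for p in parcels if p.discharge_port == "k"}
        assert at_k[("i", "k")] == pytest.approx(250.0)
        assert at_k[("j", "k")] == pytest.approx(250.0)

    def test_volume_conservation_at_every_call(self):
        rng = np.random.default_rng(11)
        t = 0.0
        triples = []
        for port in "abcdefab":
            arrival = t + float(rng.uniform(1, 5))
            departure = arrival + float(rng.uniform(0.2, 1.0))
            triples.append((port, arrival, departure))
            t = departure
        f = 0.37
        parcels = ballast_provenance(self._calls(triples), self.spec, f)
        per_call = {}
        for p in parcels:
            per_call.setdefault(p.route_id.split(":")[1], 0.0)
            per_call[p.route_id.split(":")[1]] += p.volume
        assert len(per_call) == len(triples) - 1
        for total in per_call.values():
            assert total == pytest.approx(f * self.spec.tank_volume, rel=1e-9)
        assert all(p.travel_time >= 0 for p in parcels)

    def test_invalid_discharge_fraction_and_short_voyage(self):
        calls = self._calls([("i", 0.0, 1.0), ("j", 2.0, 3.0)])
        with pytest.raises(ValidationError):
            ballast_provenance(calls, self.spec, 0.0)
        with pytest.raises(ValidationError):
            ballast_provenance(calls, self.spec, 1.5)
        assert ballast_provenance(calls[:1], self.spec, 0.5) == []


class TestMonteCarloConsistency:
    def test_simulated_any_success_matches_complement_product(self):
        rng = np.random.default_rng(21)
        probs = rng.uniform(0.0, 0.4, size=8)
        analytic = complement_product(probs)
        n = 20000
        freq = simulate_any_success_frequency(probs, n, np.random.default_rng(99))
        se = math.sqrt(analytic * (1 - analytic) / n)
        assert abs(freq - analytic) <= 3 * se


@given(
    st.floats(0.0, 1e9),
    st.floats(0.0, 1e5),
    st.floats(0.0, 1e3),
    st.floats(-40.0, 40.0),
    st.floats(-40.0, 40.0),
    st.floats(0.0, 45.0),
    st.floats(0.0, 45.0),
    params_strategy,
)
def test_all_probabilities_stay_in_unit_interval(d, vol, dt, t1, t2, s1, s2, params):
    """Bounds hold across random admissible parameters and inputs."""
    assert 0.0 <= p_nonindigenous(d, params) <= 1.0
    assert 0.0 <= p_intro_values(vol, dt, params) <= 1.0
    gauss = params.alpha * math.exp(
        -0.5 * (((t1 - t2) / params.sigma_t) ** 2 + ((s1 - s2) / params.sigma_s) ** 2)
    )
    assert 0.0 <= gauss <= params.alpha
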