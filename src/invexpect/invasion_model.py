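"""Ship-network ballast-water invasion probability model.

The probability that a species native at donor port *i* invades recipient
port *j* over a ship route *r* is the product of three independent factors:

* ``P_ij(Nonindigenous) = 1 / (1 + gamma * d_ij**(-beta))`` -- a sigmoid in
  the geographic distance ``d_ij`` between the ports: water carried over a
  short hop mostly contains species already native at the destination.
* ``P_r(Intro) = (1 - exp(-lambda * B_r)) * exp(-mu * dt_r)`` -- increasing
  in the discharged ballast volume ``B_r`` originating at *i* (propagule
  pressure) and decaying with en-route mortality ``mu`` over travel time
  ``dt_r``.
* ``P_ij(Estab) = alpha * exp(-0.5 * ((dT/sigma_T)**2 + (dS/sigma_S)**2))``
  -- a Gaussian environmental match in annual mean temperature and salinity
  differences between the ports, capped by the base rate ``alpha``.

Independent colonization chances aggregate by complement products: over the
routes of a port pair, ``P_ij = 1 - prod_r (1 - P_r(Inv))``, and over all
port pairs of a region pair, ``P_AB = 1 - prod_ab (1 - P_ab)``.

Ballast provenance follows a well-mixed tank: at every port of call a fixed
fraction of the tank is discharged (split across the origins currently in the
tank, proportional to their shares) and replaced by local water, yielding the
origin-tagged parcels ``(B_r, dt_r)`` that feed ``P_r(Intro)``.

The seven model constants are not fixed by this package; defaults returned by
:meth:`ModelParams.placeholder_defaults` are NON-CANONICAL placeholders for
demonstration and testing, and are flagged as such in logs.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .regions import validate_region

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class Port:
    """A shipping-network node with coordinates and annual-mean environment."""

    id: str
    name: str
    region: str
    lon: float
    lat: float
    temperature: float  # degC, annual mean
    salinity: float  # ppt, annual mean

    def __post_init__(self) -> None:
        validate_region(self.region, context=f"port {self.id}")
        _check_coords(self.lon, self.lat, context=f"port {self.id}")
        if self.salinity is not None and not math.isnan(self.salinity) and self.salinity < 0:
            raise ValidationError(f"port {self.id}: salinity must be >= 0")


@dataclass(frozen=True)
class ShipSpec:
    """Per-ship ballast capacity and mean per-call discharge."""

    ship_id: str
    ship_type: str
    size_class: str
    tank_volume: float  # m3
    mean_discharge_per_call: float  # m3

    def __post_init__(self) -> None:
        if not 0 < self.mean_discharge_per_call <= self.tank_volume:
            raise ValidationError(
                f"ship {self.ship_id}: discharge per call must be in (0, tank_volume]"
            )


@dataclass(frozen=True)
class PortCall:
    """One visit of a ship to a port; times in days."""

    ship_id: str
    port_id: str
    arrival: float
    departure: float

    def __post_init__(self) -> None:
        if self.departure < self.arrival:
            raise ValidationError(
                f"ship {self.ship_id} at {self.port_id}: departure before arrival"
            )


@dataclass(frozen=True)
class BallastParcel:
    """Origin-tagged discharged ballast volume with its in-tank travel time."""

    origin_port: str
    discharge_port: str
    route_id: str
    volume: float  # m3
    travel_time: float  # days

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValidationError(f"parcel {self.route_id}: volume must be >= 0")
        if self.travel_time < 0:
            raise ValidationError(f"parcel {self.route_id}: travel time must be >= 0")


@dataclass(frozen=True)
class ModelParams:
    """The seven model constants.

    alpha (dimensionless, in (0, 1]): establishment base rate;
    beta (dimensionless, > 0): distance-sigmoid steepness;
    gamma (km**beta, > 0): distance scale -- the sigmoid midpoint sits at
    d = gamma**(1/beta);
    lam (1/m3, > 0): per-volume inoculation rate;
    mu (1/day, >= 0): en-route mortality rate;
    sigma_t (degC, > 0) and sigma_s (ppt, > 0): environmental niche widths.
    """

    alpha: float
    beta: float
    gamma: float
    lam: float
    mu: float
    sigma_t: float
    sigma_s: float

    def __post_init__(self) -> None:
        checks = [
            (0 < self.alpha <= 1, "alpha must be in (0, 1]"),
            (self.beta > 0, "beta must be > 0"),
            (self.gamma > 0, "gamma must be > 0"),
            (self.lam > 0, "lambda must be > 0"),
            (self.mu >= 0, "mu must be >= 0"),
            (self.sigma_t > 0, "sigma_t must be > 0"),
            (self.sigma_s > 0, "sigma_s must be > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(f"ModelParams: {msg}")

    @classmethod
    def placeholder_defaults(cls) -> "ModelParams":
        """NON-CANONICAL placeholder constants for demos and tests.

        The published analyses this model family supports calibrate the
        constants against global traffic and invasion records; no such
        calibration is attempted here. The placeholder sigmoid midpoint is
        1000 km (gamma = 1000**beta).
        """
        logger.warning(
            "using NON-CANONICAL placeholder model parameters; "
            "supply calibrated constants for any real-data analysis"
        )
        beta = 4.0
        return cls(
            alpha=2e-4,
            beta=beta,
            gamma=1000.0**beta,
            lam=3e-5,
            mu=0.02,
            sigma_t=2.0,
            sigma_s=10.0,
        )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ModelParams":
        """Build from a config mapping with keys alpha, beta, gamma, lambda, mu, sigma_t, sigma_s."""
        data = dict(mapping)
        if "lambda" in data:
            data["lam"] = data.pop("lambda")
        try:
            return cls(**{k: float(v) for k, v in data.items()})
        except TypeError as exc:
            raise ValidationError(f"bad model parameter mapping: {exc}") from exc


@dataclass(frozen=True)
class PortPairProbability:
    """Aggregated invasion probability for one ordered port pair."""

    i: str
    j: str
    distance_km: float
    p_nonindigenous: float
    p_establish: float
    p_invasion: float
    n_routes: int


def _check_coords(lon: float, lat: float, *, context: str = "") -> None:
    if not (-180.0 <= lon <= 180.0) or not (-90.0 <= lat <= 90.0):
        where = f"{context}: " if context else ""
        raise ValidationError(f"{where}coordinates out of range (lon {lon}, lat {lat})")


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance on a sphere of radius 6371 km."""
    _check_coords(lon1, lat1)
    _check_coords(lon2, lat2)
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def great_circle_distance(a: Port, b: Port) -> float:
    """Haversine distance between two ports in km; zero iff same coordinates."""
    return haversine_km(a.lon, a.lat, b.lon, b.lat)


def p_nonindigenous(d: float, params: ModelParams) -> float:
    """Sigmoidal probability that donor-port water is nonindigenous at distance d.

    ``d = 0`` returns 0 by convention: same-port water is never nonindigenous
    (the raw sigmoid is undefined there for beta > 0).
    """
    if d < 0:
        raise ValidationError("distance must be >= 0")
    if d == 0:
        return 0.0
    try:
        term = params.gamma * d ** (-params.beta)
    except OverflowError:
        return 0.0  # d so small that d**(-beta) overflows: the limit is 0
    if math.isinf(term):
        return 0.0
    return 1.0 / (1.0 + term)


def p_intro_values(volume: float, travel_time: float, params: ModelParams) -> float:
    """Introduction probability for a discharged volume after a travel time."""
    if volume < 0:
        raise ValidationError("ballast volume must be >= 0")
    if travel_time < 0:
        raise ValidationError("travel time must be >= 0")
    return (1.0 - math.exp(-params.lam * volume)) * math.exp(-params.mu * travel_time)


def p_intro(parcel: BallastParcel, params: ModelParams) -> float:
    """Introduction probability of one ballast parcel."""
    return p_intro_values(parcel.volume, parcel.travel_time, params)


def p_establish(i: Port, j: Port, params: ModelParams) -> float:
    """Gaussian environmental-match establishment probability (symmetric in i, j)."""
    for port in (i, j):
        for attr in ("temperature", "salinity"):
            val = getattr(port, attr)
            if val is None or (isinstance(val, float) and math.isnan(val)):
                raise ValidationError(f"port {port.id}: missing {attr}")
    dt = (i.temperature - j.temperature) / params.sigma_t
    ds = (i.salinity - j.salinity) / params.sigma_s
    return params.alpha * math.exp(-0.5 * (dt * dt + ds * ds))


def route_invasion_probability(
    parcel: BallastParcel,
    ports: Mapping[str, Port],
    params: ModelParams,
    *,
    distance_fn: Callable[[Port, Port], float] | None = None,
) -> float:
    """Product of the three factors for one ballast parcel (route).

    ``distance_fn`` may supply an alternative port-to-port metric (e.g. a
    precomputed sea-route matrix lookup); the default is the haversine
    great-circle distance.
    """
    try:
        origin = ports[parcel.origin_port]
        dest = ports[parcel.discharge_port]
    except KeyError as exc:
        raise ValidationError(f"unknown port id {exc.args[0]!r}") from exc
    dist = (distance_fn or great_circle_distance)(origin, dest)
    return (
        p_nonindigenous(dist, params)
        * p_intro(parcel, params)
        * p_establish(origin, dest, params)
    )


def complement_product(probabilities: Iterable[float]) -> float:
    """``1 - prod(1 - p)`` over independent event probabilities."""
    out = 1.0
    for p in probabilities:
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"probability {p} outside [0, 1]")
        out *= 1.0 - p
    return 1.0 - out


def port_pair_invasion_probability(
    parcels: Sequence[BallastParcel],
    ports: Mapping[str, Port],
    params: ModelParams,
    *,
    distance_fn: Callable[[Port, Port], float] | None = None,
) -> PortPairProbability:
    """Aggregate all routes of one ordered port pair by the complement product."""
    if not parcels:
        raise ValidationError("port_pair_invasion_probability requires >= 1 parcel")
    pair = (parcels[0].origin_port, parcels[0].discharge_port)
    for parcel in parcels:
        if (parcel.origin_port, parcel.discharge_port) != pair:
            raise ValidationError("parcels mix different port pairs")
    origin, dest = ports[pair[0]], ports[pair[1]]
    dist = (distance_fn or great_circle_distance)(origin, dest)
    route_probs = [
        route_invasion_probability(p, ports, params, distance_fn=distance_fn)
        for p in parcels
    ]
    return PortPairProbability(
        i=pair[0],
        j=pair[1],
        distance_km=dist,
        p_nonindigenous=p_nonindigenous(dist, params),
        p_establish=p_establish(origin, dest, params),
        p_invasion=complement_product(route_probs),
        n_routes=len(parcels),
    )


def region_invasion_probability(
    pair_probs: Sequence[PortPairProbability],
    donor: str,
    recipient: str,
    *,
    ports: Mapping[str, Port] | None = None,
) -> float:
    """Region-level invasion probability ``1 - prod_ab (1 - P_ab)``.

    When ``ports`` is given the pair list is filtered to pairs whose origin is
    in ``donor`` and destination in ``recipient``; otherwise the caller must
    have restricted it already. An empty pair list means no shipping
    connection and yields probability 0 with a logged warning.
    """
    validate_region(donor, context="region_invasion_probability")
    validate_region(recipient, context="region_invasion_probability")
    pairs = list(pair_probs)
    if ports is not None:
        pairs = [
            p
            for p in pairs
            if ports[p.i].region == donor and ports[p.j].region == recipient
        ]
    if not pairs:
        logger.warning("no shipping connection %s -> %s; probability 0", donor, recipient)
        return 0.0
    return complement_product(p.p_invasion for p in pairs)


def ballast_provenance(
    calls: Sequence[PortCall],
    spec: ShipSpec,
    discharge_fraction: float,
) -> list[BallastParcel]:
    """Track well-mixed tank contents over a voyage; emit discharge parcels.

    The tank starts full of water from the first port of the observation
    window (earlier voyage history is censored; this truncation is logged at
    debug level). At each later call a fraction ``f`` of the tank volume is
    discharged -- one parcel per origin currently in the tank, in proportion
    to that origin's share, so the per-call discharged volume is exactly
    ``f * tank_volume`` -- and replaced by local water. A parcel's travel time
    runs from departure at its origin to arrival at the discharging port.
    """
    if not 0 < discharge_fraction <= 1:
        raise ValidationError("discharge_fraction must be in (0, 1]")
    if len(calls) < 2:
        return []
    for earlier, later in zip(calls, calls[1:]):
        if later.arrival < earlier.departure:
            raise ValidationError(f"ship {spec.ship_id}: port calls not time-ordered")
    logger.debug(
        "ship %s: tank assumed full of %s water at window start",
        spec.ship_id,
        calls[0].port_id,
    )
    volume = spec.tank_volume
    f = discharge_fraction
    # tank entries: (origin port, uptake time = departure at origin, volume share)
    tank: list[tuple[str, float, float]] = [(calls[0].port_id, calls[0].departure, volume)]
    parcels: list[BallastParcel] = []
    for k, call in enumerate(calls[1:], start=1):
        for e, (origin, uptake, share) in enumerate(tank):
            parcels.append(
                BallastParcel(
                    origin_port=origin,
                    discharge_port=call.port_id,
                    route_id=f"{spec.ship_id}:{k}:{e}",
                    volume=f * share,
                    travel_time=call.arrival - uptake,
                )
            )
        tank = [(origin, uptake, (1.0 - f) * share) for origin, uptake, share in tank]
        tank.append((call.port_id, call.departure, f * volume))
    return parcels


def pair_probabilities_from_traffic(
    ports: Mapping[str, Port],
    calls_by_ship: Mapping[str, Sequence[PortCall]],
    specs: Mapping[str, ShipSpec],
    params: ModelParams,
    *,
    discharge_fraction: float | None = None,
    distance_fn: Callable[[Port, Port], float] | None = None,
) -> list[PortPairProbability]:
    """Run provenance for every ship and aggregate routes per ordered port pair.

    ``discharge_fraction`` defaults per ship to
    ``mean_discharge_per_call / tank_volume`` from the ship spec.
    """
    by_pair: dict[tuple[str, str], list[BallastParcel]] = defaultdict(list)
    for ship_id, calls in calls_by_ship.items():
        try:
            spec = specs[ship_id]
        except KeyError:
            raise ValidationError(f"no ship spec for ship {ship_id!r}")
        f = discharge_fraction
        if f is None:
            f = spec.mean_discharge_per_call / spec.tank_volume
        for parcel in ballast_provenance(list(calls), spec, f):
            if parcel.origin_port != parcel.discharge_port:
                by_pair[(parcel.origin_port, parcel.discharge_port)].append(parcel)
    return [
        port_pair_invasion_probability(parcels, ports, params, distance_fn=distance_fn)
        for parcels in by_pair.values()
    ]


def region_probability_matrix(
    pair_probs: Sequence[PortPairProbability],
    ports: Mapping[str, Port],
) -> dict[tuple[str, str], float]:
    """All ordered region-pair probabilities present in the pair list."""
    grouped: dict[tuple[str, str], list[float]] = defaultdict(list)
    for p in pair_probs:
        key = (ports[p.i].region, ports[p.j].region)
        if key[0] != key[1]:
            grouped[key].append(p.p_invasion)
    return {key: complement_product(probs) for key, probs in sorted(grouped.items())}


def simulate_any_success_frequency(
    probabilities: Sequence[float],
    n_replicates: int,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo frequency of at least one success among independent Bernoulli events.

    Used to cross-check the complement-product aggregation: the frequency
    should approach ``complement_product(probabilities)``.
    """
    probs = np.asarray(probabilities, dtype=float)
    if probs.size == 0:
        return 0.0
    draws = rng.random((n_replicates, probs.size)) < probs
    return float(draws.any(axis=1).mean())
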