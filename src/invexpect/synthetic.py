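"""Seed-reproducible synthetic worlds for end-to-end pipeline testing.

A synthetic world emulates the statistical structure of the data sources the
invasion-probability pipeline consumes: geographically clustered ports with
regional temperature/salinity regimes (annual-mean fields), AIS-style ship
port-call logs produced by biased random walks over the port network,
ballast-capacity ship specs, equal-area richness grids with per-region cell
means, and a donor-region species pool sized by the realized per-cell average
richness. Observed checklists are then realized by independent Bernoulli
draws at the model's own region-pair invasion probabilities, so the
expected-versus-observed machinery can be validated on data whose generating
process is known exactly.

Randomness is organised as named substreams spawned in a documented, fixed
order from one :class:`numpy.random.SeedSequence` (ports, environment, ships,
voyages, grid, species, realization), so adding a generator never reshuffles
the draws of an existing one.

What these worlds do *not* emulate: coastline geometry (ports scatter around
regional centroids), seasonal traffic and environmental cycles, and the
heavy-tailed size distribution of real fleets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .checklist import Checklist, SpeciesRecord, load_checklist
from .errors import ValidationError
from .invasion_model import (
    ModelParams,
    Port,
    PortCall,
    PortPairProbability,
    ShipSpec,
    great_circle_distance,
    pair_probabilities_from_traffic,
    region_probability_matrix,
)
from .richness import RegionRichness, RichnessGrid, average_grid_richness, load_grid

#: default four-region world: two marine and two brackish systems
_DEFAULT_REGIONS = (
    ("northwest_atlantic", (-65.0, 42.0), 11.0, 32.0, 60.0),
    ("north_baltic", (8.0, 56.0), 9.0, 12.0, 45.0),
    ("northeast_pacific", (-130.0, 45.0), 12.0, 33.0, 75.0),
    ("ponto_caspian", (35.0, 44.0), 15.0, 11.0, 50.0),
    ("northwest_pacific", (140.0, 38.0), 14.0, 33.0, 80.0),
    ("mediterranean", (15.0, 38.0), 19.0, 38.0, 70.0),
    ("southwest_atlantic", (-50.0, -30.0), 18.0, 34.0, 65.0),
    ("indo_pacific", (100.0, 5.0), 27.0, 33.0, 90.0),
)

_TAXA = (
    ("Animalia", "Arthropoda", "Malacostraca"),
    ("Animalia", "Mollusca", "Bivalvia"),
    ("Animalia", "Chordata", "Actinopterygii"),
    ("Animalia", "Annelida", "Polychaeta"),
    ("Animalia", "Cnidaria", "Hydrozoa"),
    ("Plantae", "Tracheophyta", "Liliopsida"),
    ("Animalia", "Arthropoda", "Maxillopoda"),
    ("Animalia", "Mollusca", "Gastropoda"),
    ("Chromista", "Ochrophyta", "Phaeophyceae"),
    ("Animalia", "Bryozoa", "Gymnolaemata"),
)


def default_synthetic_params() -> ModelParams:
    """Well-conditioned model constants for synthetic worlds.

    Chosen so that a mid-size world yields region-pair invasion
    probabilities spread over roughly 0.05-0.6 and expected counts of a few
    to a few tens of species: sigmoid midpoint 1000 km (beta=2, gamma=1e6),
    inoculation saturating around 1500 m3 discharges (lambda=2e-3 per m3),
    mortality 0.05 per day, niche widths 4 degC and 8 ppt, base
    establishment rate 0.3. These govern the synthetic study conditions only.
    """
    return ModelParams(
        alpha=0.3, beta=2.0, gamma=1.0e6, lam=2.0e-3, mu=0.05, sigma_t=4.0, sigma_s=8.0
    )


@dataclass
class SyntheticWorldConfig:
    """Full parameterisation of a synthetic world.

    Per-region lists (codes, centers, temperature/salinity means, richness
    cell means) default to a built-in table of up to eight plausible regions;
    explicit lists must match ``n_regions``.
    """

    seed: int = 0
    n_regions: int = 4
    ports_per_region: int = 4
    n_ships: int = 30
    calls_per_ship: int = 10
    region_codes: Sequence[str] | None = None
    region_centers: Sequence[tuple[float, float]] | None = None
    region_temperature_mean: Sequence[float] | None = None
    temperature_sd: float = 1.5  # degC within-region spread
    region_salinity_mean: Sequence[float] | None = None
    salinity_sd: float = 2.0  # ppt within-region spread
    port_scatter_deg: float = 3.0
    richness_cell_mean: Sequence[float] | None = None
    richness_cv: float = 0.15
    cells_per_region: int = 6
    noncoastal_cells_per_region: int = 1
    tank_volume_mean: float = 5000.0  # m3
    tank_volume_sigma: float = 0.4  # sd of log tank volume
    discharge_fraction: float = 0.3
    ship_speed_km_per_day: float = 600.0
    port_stay_days: tuple[float, float] = (0.5, 2.0)
    intra_region_affinity: float = 0.6
    params: ModelParams = field(default_factory=default_synthetic_params)

    def __post_init__(self) -> None:
        counts = {
            "n_regions": self.n_regions,
            "ports_per_region": self.ports_per_region,
            "n_ships": self.n_ships,
            "calls_per_ship": self.calls_per_ship,
            "cells_per_region": self.cells_per_region,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValidationError(f"SyntheticWorldConfig.{name} must be >= 1")
        for name in ("temperature_sd", "salinity_sd", "richness_cv", "port_scatter_deg"):
            if getattr(self, name) < 0:
                raise ValidationError(f"SyntheticWorldConfig.{name} must be >= 0")
        if not 0 < self.discharge_fraction <= 1:
            raise ValidationError("SyntheticWorldConfig.discharge_fraction must be in (0, 1]")
        if not 0 <= self.intra_region_affinity <= 1:
            raise ValidationError(
                "SyntheticWorldConfig.intra_region_affinity must be in [0, 1]"
            )
        if self.region_codes is None and self.n_regions > len(_DEFAULT_REGIONS):
            raise ValidationError(
                f"SyntheticWorldConfig.n_regions > {len(_DEFAULT_REGIONS)} requires "
                "explicit region_codes"
            )
        for name in (
            "region_codes",
            "region_centers",
            "region_temperature_mean",
            "region_salinity_mean",
            "richness_cell_mean",
        ):
            value = getattr(self, name)
            if value is not None and len(value) != self.n_regions:
                raise ValidationError(
                    f"SyntheticWorldConfig.{name} must have length n_regions"
                )

    def resolved_regions(self) -> list[tuple[str, tuple[float, float], float, float, float]]:
        """(code, center, temperature mean, salinity mean, richness mean) per region."""
        defaults = _DEFAULT_REGIONS[: self.n_regions]
        codes = list(self.region_codes) if self.region_codes else [d[0] for d in defaults]
        centers = (
            list(self.region_centers) if self.region_centers else [d[1] for d in defaults]
        )
        temps = (
            list(self.region_temperature_mean)
            if self.region_temperature_mean
            else [d[2] for d in defaults]
        )
        sals = (
            list(self.region_salinity_mean)
            if self.region_salinity_mean
            else [d[3] for d in defaults]
        )
        rich = (
            list(self.richness_cell_mean)
            if self.richness_cell_mean
            else [d[4] for d in defaults]
        )
        return list(zip(codes, centers, temps, sals, rich))


@dataclass
class SyntheticWorld:
    """A generated world plus the model quantities derived from it."""

    config: SyntheticWorldConfig
    ports: dict[str, Port]
    specs: dict[str, ShipSpec]
    calls_by_ship: dict[str, list[PortCall]]
    grid: RichnessGrid
    region_richness: dict[str, RegionRichness]
    species_pool: pd.DataFrame  # columns: name, region, kingdom, phylum, class
    pair_probs: list[PortPairProbability]
    region_probs: dict[tuple[str, str], float]
    checklists: dict[str, Checklist]

    @property
    def region_codes(self) -> list[str]:
        return [entry[0] for entry in self.config.resolved_regions()]


def inflate_odds(p: float, factor: float) -> float:
    """Multiply the odds ``p / (1 - p)`` by ``factor`` and return the new probability."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError("probability outside [0, 1]")
    if factor < 0:
        raise ValidationError("odds factor must be >= 0")
    if p == 1.0:
        return 1.0
    return factor * p / (1.0 + (factor - 1.0) * p)


def _generate_ports(config: SyntheticWorldConfig, rng_port, rng_env) -> dict[str, Port]:
    ports: dict[str, Port] = {}
    for code, (lon0, lat0), t_mean, s_mean, _ in config.resolved_regions():
        for k in range(config.ports_per_region):
            lon = float(np.clip(lon0 + rng_port.normal(0.0, config.port_scatter_deg), -180, 180))
            lat = float(np.clip(lat0 + rng_port.normal(0.0, config.port_scatter_deg), -85, 85))
            pid = f"{code}_p{k}"
            ports[pid] = Port(
                id=pid,
                name=pid.replace("_", " "),
                region=code,
                lon=lon,
                lat=lat,
                temperature=float(t_mean + rng_env.normal(0.0, config.temperature_sd)),
                salinity=float(max(0.0, s_mean + rng_env.normal(0.0, config.salinity_sd))),
            )
    return ports


def _generate_specs(config: SyntheticWorldConfig, rng) -> dict[str, ShipSpec]:
    types = ("bulk_carrier", "container", "tanker", "general_cargo")
    specs: dict[str, ShipSpec] = {}
    for s in range(config.n_ships):
        tank = float(
            np.exp(rng.normal(math.log(config.tank_volume_mean), config.tank_volume_sigma))
        )
        size = "small" if tank < 3500 else ("medium" if tank < 7000 else "large")
        sid = f"ship{s:03d}"
        specs[sid] = ShipSpec(
            ship_id=sid,
            ship_type=types[s % len(types)],
            size_class=size,
            tank_volume=tank,
            mean_discharge_per_call=config.discharge_fraction * tank,
        )
    return specs


def _generate_voyages(
    config: SyntheticWorldConfig,
    ports: Mapping[str, Port],
    specs: Mapping[str, ShipSpec],
    rng,
) -> dict[str, list[PortCall]]:
    port_ids = list(ports)
    by_region: dict[str, list[str]] = {}
    for pid, port in ports.items():
        by_region.setdefault(port.region, []).append(pid)
    lo, hi = config.port_stay_days
    calls_by_ship: dict[str, list[PortCall]] = {}
    for sid in specs:
        current = port_ids[rng.integers(len(port_ids))]
        t = float(rng.uniform(0.0, 5.0))
        calls: list[PortCall] = []
        for _ in range(config.calls_per_ship):
            departure = t + float(rng.uniform(lo, hi))
            calls.append(PortCall(ship_id=sid, port_id=current, arrival=t, departure=departure))
            same = [p for p in by_region[ports[current].region] if p != current]
            other = [p for p in port_ids if ports[p].region != ports[current].region]
            if same and (not other or rng.random() < config.intra_region_affinity):
                nxt = same[rng.integers(len(same))]
            else:
                nxt = other[rng.integers(len(other))]
            travel = great_circle_distance(ports[current], ports[nxt]) / config.ship_speed_km_per_day
            t = departure + max(travel, 0.1)
            current = nxt
        calls_by_ship[sid] = calls
    return calls_by_ship


def _generate_grid(config: SyntheticWorldConfig, rng) -> RichnessGrid:
    rows = []
    for code, _, _, _, rich_mean in config.resolved_regions():
        for k in range(config.cells_per_region):
            value = max(1.0, float(rng.normal(rich_mean, config.richness_cv * rich_mean)))
            rows.append((f"{code}_c{k}", code, True, value))
        for k in range(config.noncoastal_cells_per_region):
            value = max(1.0, float(rng.normal(rich_mean, config.richness_cv * rich_mean)))
            rows.append((f"{code}_n{k}", code, False, value))
    frame = pd.DataFrame(rows, columns=["cell_id", "region", "coastal", "richness"])
    return RichnessGrid(cells=frame, resolution_note="synthetic equal-area grid")


def _generate_species_pool(
    region_richness: Mapping[str, RegionRichness], rng
) -> pd.DataFrame:
    rows = []
    for region, rich in region_richness.items():
        n = int(round(rich.average_richness))
        for k in range(n):
            kingdom, phylum, klass = _TAXA[int(rng.integers(len(_TAXA)))]
            rows.append((f"{region}_sp{k:04d}", region, kingdom, phylum, klass))
    return pd.DataFrame(rows, columns=["name", "region", "kingdom", "phylum", "class"])


def realize_invasions(
    world: SyntheticWorld,
    params: ModelParams | None = None,
    seed: int = 0,
    *,
    odds_inflation: Mapping[tuple[str, str], float] | None = None,
) -> dict[str, Checklist]:
    """Bernoulli-realize observed checklists from the region probabilities.

    Every species of donor A establishes in recipient B independently with
    probability ``P_AB``. ``params`` other than the world's own trigger a
    recomputation of the probabilities under those constants (an analysis /
    generation mismatch experiment). ``odds_inflation`` multiplies the
    establishment odds of specific (donor, recipient) pairs, emulating a
    donor whose species are intrinsically better colonizers than the
    shipping-and-environment null expects.
    """
    region_probs = world.region_probs
    if params is not None and params != world.config.params:
        pair_probs = pair_probabilities_from_traffic(
            world.ports,
            world.calls_by_ship,
            world.specs,
            params,
            discharge_fraction=world.config.discharge_fraction,
        )
        region_probs = region_probability_matrix(pair_probs, world.ports)
    rng = np.random.default_rng(seed)
    pool_by_region = {
        region: group["name"].tolist()
        for region, group in world.species_pool.groupby("region", sort=False)
    }
    taxa = {
        row["name"]: (row["kingdom"], row["phylum"], row["class"])
        for _, row in world.species_pool.iterrows()
    }
    checklists: dict[str, Checklist] = {}
    for recipient in world.region_codes:
        records: list[SpeciesRecord] = []
        for donor in world.region_codes:
            if donor == recipient:
                continue
            p = region_probs.get((donor, recipient), 0.0)
            if odds_inflation and (donor, recipient) in odds_inflation:
                p = inflate_odds(p, odds_inflation[(donor, recipient)])
            if p <= 0.0:
                continue
            names = pool_by_region.get(donor, [])
            hits = rng.random(len(names)) < p
            for name, hit in zip(names, hits):
                if hit:
                    kingdom, phylum, klass = taxa[name]
                    records.append(
                        SpeciesRecord(
                            name=name,
                            kingdom=kingdom,
                            phylum=phylum,
                            klass=klass,
                            native_regions=frozenset({donor}),
                            presence={recipient: True},
                        )
                    )
        checklists[recipient] = Checklist(
            recipient_region=recipient, subregion_ids=[recipient], records=records
        )
    return checklists


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate a complete world from one seed (identical seed, identical world)."""
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_port, rng_env, rng_ship, rng_voyage, rng_grid, rng_species, rng_realize = (
        np.random.default_rng(s) for s in streams
    )
    ports = _generate_ports(config, rng_port, rng_env)
    specs = _generate_specs(config, rng_ship)
    calls_by_ship = _generate_voyages(config, ports, specs, rng_voyage)
    grid = _generate_grid(config, rng_grid)
    region_richness = {
        code: average_grid_richness(grid, code)
        for code, *_ in config.resolved_regions()
    }
    species_pool = _generate_species_pool(region_richness, rng_species)
    pair_probs = pair_probabilities_from_traffic(
        ports, calls_by_ship, specs, config.params, discharge_fraction=config.discharge_fraction
    )
    region_probs = region_probability_matrix(pair_probs, ports)
    world = SyntheticWorld(
        config=config,
        ports=ports,
        specs=specs,
        calls_by_ship=calls_by_ship,
        grid=grid,
        region_richness=region_richness,
        species_pool=species_pool,
        pair_probs=pair_probs,
        region_probs=region_probs,
        checklists={},
    )
    world.checklists = realize_invasions(
        world, seed=int(rng_realize.integers(2**31 - 1))
    )
    return world


# --- serialisation ----------------------------------------------------------


def world_to_files(world: SyntheticWorld, directory: str | Path) -> dict[str, Path]:
    """Write the world in exactly the formats the pipeline stages consume."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    ports = pd.DataFrame(
        [
            (p.id, p.name, p.region, p.lon, p.lat, p.temperature, p.salinity)
            for p in world.ports.values()
        ],
        columns=["id", "name", "region", "lon", "lat", "temperature", "salinity"],
    )
    out["ports"] = directory / "ports.csv"
    ports.to_csv(out["ports"], index=False)

    ships = pd.DataFrame(
        [
            (s.ship_id, s.ship_type, s.size_class, s.tank_volume, s.mean_discharge_per_call)
            for s in world.specs.values()
        ],
        columns=["ship_id", "type", "size_class", "tank_volume", "mean_discharge"],
    )
    out["ships"] = directory / "ships.csv"
    ships.to_csv(out["ships"], index=False)

    calls = pd.DataFrame(
        [
            (c.ship_id, c.port_id, c.arrival, c.departure)
            for ship_calls in world.calls_by_ship.values()
            for c in ship_calls
        ],
        columns=["ship_id", "port_id", "arrival", "departure"],
    )
    out["calls"] = directory / "calls.csv"
    calls.to_csv(out["calls"], index=False)

    out["grid"] = directory / "grid.csv"
    grid = world.grid.cells.copy()
    grid["coastal"] = grid["coastal"].astype(int)
    grid.to_csv(out["grid"], index=False)

    out["species_pool"] = directory / "species_pool.csv"
    world.species_pool.to_csv(out["species_pool"], index=False)

    region_probs = pd.DataFrame(
        [(a, b, p) for (a, b), p in world.region_probs.items()],
        columns=["donor", "recipient", "p_invasion"],
    )
    out["region_probs"] = directory / "region_probabilities.csv"
    region_probs.to_csv(out["region_probs"], index=False)

    for recipient, cl in world.checklists.items():
        frame = pd.DataFrame(
            [
                (
                    r.name,
                    r.kingdom,
                    r.phylum,
                    r.klass,
                    ";".join(sorted(r.native_regions)),
                    *[int(r.presence.get(s, False)) for s in cl.subregion_ids],
                )
                for r in cl.records
            ],
            columns=["name", "kingdom", "phylum", "class", "native_regions"]
            + list(cl.subregion_ids),
        )
        path = directory / f"checklist_{recipient}.csv"
        frame.to_csv(path, index=False)
        out[f"checklist_{recipient}"] = path

    params = world.config.params
    meta = {
        "seed": world.config.seed,
        "model": {
            "alpha": params.alpha,
            "beta": params.beta,
            "gamma": params.gamma,
            "lambda": params.lam,
            "mu": params.mu,
            "sigma_t": params.sigma_t,
            "sigma_s": params.sigma_s,
        },
        "discharge_fraction": world.config.discharge_fraction,
        "regions": [code for code, *_ in world.config.resolved_regions()],
    }
    out["params"] = directory / "params.yaml"
    out["params"].write_text(yaml.safe_dump(meta, sort_keys=True))
    return out


def load_world_files(directory: str | Path) -> SyntheticWorld:
    """Reload a serialized world and rederive the model quantities.

    The derived layers (pair and region probabilities, average richness) are
    recomputed from the reloaded primitives, so a round trip checks the whole
    chain, not just the file I/O.
    """
    directory = Path(directory)
    meta = yaml.safe_load((directory / "params.yaml").read_text())
    params = ModelParams.from_mapping(meta["model"])
    ports_frame = pd.read_csv(directory / "ports.csv")
    ports = {
        row["id"]: Port(
            id=row["id"],
            name=row["name"],
            region=row["region"],
            lon=float(row["lon"]),
            lat=float(row["lat"]),
            temperature=float(row["temperature"]),
            salinity=float(row["salinity"]),
        )
        for _, row in ports_frame.iterrows()
    }
    ships_frame = pd.read_csv(directory / "ships.csv")
    specs = {
        row["ship_id"]: ShipSpec(
            ship_id=row["ship_id"],
            ship_type=row["type"],
            size_class=row["size_class"],
            tank_volume=float(row["tank_volume"]),
            mean_discharge_per_call=float(row["mean_discharge"]),
        )
        for _, row in ships_frame.iterrows()
    }
    calls_frame = pd.read_csv(directory / "calls.csv")
    calls_by_ship: dict[str, list[PortCall]] = {}
    for _, row in calls_frame.iterrows():
        calls_by_ship.setdefault(row["ship_id"], []).append(
            PortCall(
                ship_id=row["ship_id"],
                port_id=row["port_id"],
                arrival=float(row["arrival"]),
                departure=float(row["departure"]),
            )
        )
    grid = load_grid(directory / "grid.csv", resolution_note="synthetic equal-area grid")
    regions = list(meta["regions"])
    region_richness = {code: average_grid_richness(grid, code) for code in regions}
    species_pool = pd.read_csv(directory / "species_pool.csv")
    pair_probs = pair_probabilities_from_traffic(
        ports, calls_by_ship, specs, params, discharge_fraction=float(meta["discharge_fraction"])
    )
    region_probs = region_probability_matrix(pair_probs, ports)
    checklists = {}
    for code in regions:
        path = directory / f"checklist_{code}.csv"
        if path.exists():
            checklists[code] = load_checklist(path, recipient_region=code)
    config = SyntheticWorldConfig(
        seed=int(meta["seed"]),
        n_regions=len(regions),
        region_codes=regions,
        discharge_fraction=float(meta["discharge_fraction"]),
        params=params,
    )
    return SyntheticWorld(
        config=config,
        ports=ports,
        specs=specs,
        calls_by_ship=calls_by_ship,
        grid=grid,
        region_richness=region_richness,
        species_pool=species_pool,
        pair_probs=pair_probs,
        region_probs=region_probs,
        checklists=checklists,
    )


def worlds_equal(a: SyntheticWorld, b: SyntheticWorld, *, tol: float = 1e-9) -> bool:
    """Structural equality of the primitives and derived probabilities."""
    if set(a.ports) != set(b.ports) or set(a.specs) != set(b.specs):
        return False
    for pid in a.ports:
        pa, pb = a.ports[pid], b.ports[pid]
        if pa.region != pb.region:
            return False
        for attr in ("lon", "lat", "temperature", "salinity"):
            if abs(getattr(pa, attr) - getattr(pb, attr)) > tol:
                return False
    if set(a.region_probs) != set(b.region_probs):
        return False
    return all(
        abs(a.region_probs[key] - b.region_probs[key]) <= tol for key in a.region_probs
    )
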