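"""End-to-end orchestration behind a single configuration file.

A run is either *synthetic* (a ``synth:`` section describing a world to
generate) or *file-driven* (an ``inputs:`` section naming port, call, ship,
grid, checklist and/or comparison-fixture tables); exactly one of the two
data sources may be given. Stages execute in dependency order --
synth/load -> probabilities -> expected -> compare -> checklist summaries --
and every output file lands in the configured output directory together with
a machine-readable ``report.json`` (package version, parameters, per-stage
row counts, the comparison table, warnings, and a sha256 checksum per output
file). Re-running with the same config and seed reproduces identical
checksums.

Paths of the form ``builtin:<name>`` resolve to the packaged fixtures
(``builtin:table2``, ``builtin:table1``, ``builtin:demo_north_baltic``).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from . import datasets
from .checklist import (
    Checklist,
    load_checklist,
    origin_percentages,
    taxonomic_composition,
)
from .comparison import (
    overall_chi_square,
    results_frame,
    scatter_frame,
    table_from_fixture,
)
from .errors import SchemaError, StageError, ValidationError
from .experiments import world_comparison_rows
from .invasion_model import (
    ModelParams,
    Port,
    PortCall,
    ShipSpec,
    pair_probabilities_from_traffic,
    region_probability_matrix,
)
from .richness import (
    average_grid_richness,
    corrected_average_richness,
    correction_factor,
    load_grid,
)
from .synthetic import SyntheticWorldConfig, generate_world, world_to_files

logger = logging.getLogger(__name__)

_BUILTINS = {
    "table2": datasets.table2_path,
    "table1": datasets.table1_path,
    "demo_north_baltic": datasets.demo_checklist_path,
}


def resolve_path(value: str | Path) -> Path:
    value = str(value)
    if value.startswith("builtin:"):
        name = value.split(":", 1)[1]
        if name not in _BUILTINS:
            raise ValidationError(f"unknown builtin fixture {name!r}")
        return _BUILTINS[name]()
    return Path(value)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    outdir: Path = Path("invexpect_run")
    log_level: str = "INFO"
    exclude_phyla: list[str] = field(default_factory=list)
    model: ModelParams | None = None  # None -> NON-CANONICAL placeholders
    synth: SyntheticWorldConfig | None = None
    inputs: dict[str, Any] = field(default_factory=dict)
    richness_config: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        traffic_keys = {"ports", "calls", "ships"} & set(self.inputs)
        if self.synth is not None and traffic_keys:
            raise ValidationError(
                "config provides both a synth section and real traffic inputs; "
                "exactly one data source per role is allowed"
            )
        if traffic_keys and traffic_keys != {"ports", "calls", "ships"}:
            raise ValidationError(
                f"traffic inputs incomplete: need ports, calls and ships (got {sorted(traffic_keys)})"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        model = ModelParams.from_mapping(raw["model"]) if "model" in raw else None
        synth = None
        if "synth" in raw:
            synth_raw = dict(raw["synth"] or {})
            if "params" in synth_raw:
                synth_raw["params"] = ModelParams.from_mapping(synth_raw["params"])
            elif model is not None:
                synth_raw["params"] = model
            synth_raw.setdefault("seed", int(raw.get("seed", 0)))
            try:
                synth = SyntheticWorldConfig(**synth_raw)
            except TypeError as exc:
                raise ValidationError(f"bad synth config: {exc}") from exc
        return cls(
            seed=int(raw.get("seed", 0)),
            outdir=Path(raw.get("outdir", "invexpect_run")),
            log_level=str(raw.get("log_level", "INFO")),
            exclude_phyla=list(raw.get("exclude_phyla", [])),
            model=model,
            synth=synth,
            inputs=dict(raw.get("inputs", {})),
            richness_config=dict(raw.get("richness", {})),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_traffic(inputs: Mapping[str, Any]):
    ports_frame = pd.read_csv(resolve_path(inputs["ports"]))
    ports = {
        str(row["id"]): Port(
            id=str(row["id"]),
            name=str(row.get("name", row["id"])),
            region=str(row["region"]),
            lon=float(row["lon"]),
            lat=float(row["lat"]),
            temperature=float(row["temperature"]),
            salinity=float(row["salinity"]),
        )
        for _, row in ports_frame.iterrows()
    }
    ships_frame = pd.read_csv(resolve_path(inputs["ships"]))
    specs = {
        str(row["ship_id"]): ShipSpec(
            ship_id=str(row["ship_id"]),
            ship_type=str(row["type"]),
            size_class=str(row["size_class"]),
            tank_volume=float(row["tank_volume"]),
            mean_discharge_per_call=float(row["mean_discharge"]),
        )
        for _, row in ships_frame.iterrows()
    }
    calls_frame = pd.read_csv(resolve_path(inputs["calls"]))
    calls_by_ship: dict[str, list[PortCall]] = {}
    for _, row in calls_frame.iterrows():
        calls_by_ship.setdefault(str(row["ship_id"]), []).append(
            PortCall(
                ship_id=str(row["ship_id"]),
                port_id=str(row["port_id"]),
                arrival=float(row["arrival"]),
                departure=float(row["departure"]),
            )
        )
    return ports, specs, calls_by_ship


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all applicable stages; return (and write) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "invexpect_version": __version__,
        "seed": config.seed,
        "stages": {},
        "warnings": [],
        "files": {},
    }
    params = config.model
    if config.synth is not None:
        params = config.synth.params
    if params is None:
        params = ModelParams.placeholder_defaults()
        report["warnings"].append(
            "NON-CANONICAL placeholder model parameters in use; results are "
            "demonstrations, not reproductions of any published analysis"
        )
        report["non_canonical_params"] = True
    else:
        report["non_canonical_params"] = False
    report["parameters"] = {
        "alpha": params.alpha,
        "beta": params.beta,
        "gamma": params.gamma,
        "lambda": params.lam,
        "mu": params.mu,
        "sigma_t": params.sigma_t,
        "sigma_s": params.sigma_s,
    }

    def register(name: str, path: Path) -> None:
        report["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    world = None
    ports = specs = calls_by_ship = None
    stage = "setup"
    try:
        if config.synth is not None:
            stage = "synth"
            from dataclasses import replace

            world = generate_world(replace(config.synth, seed=config.seed))
            written = world_to_files(world, outdir / "world")
            for name, path in written.items():
                register(f"world/{name}", path)
            report["stages"]["synth"] = {
                "ports": len(world.ports),
                "port_calls": sum(len(c) for c in world.calls_by_ship.values()),
                "species": len(world.species_pool),
            }
            ports, specs, calls_by_ship = world.ports, world.specs, world.calls_by_ship
        elif {"ports", "calls", "ships"} <= set(config.inputs):
            stage = "load"
            ports, specs, calls_by_ship = _load_traffic(config.inputs)
            report["stages"]["load"] = {
                "ports": len(ports),
                "ships": len(specs),
                "port_calls": sum(len(c) for c in calls_by_ship.values()),
            }

        pair_probs = None
        region_probs = None
        if ports is not None:
            stage = "probabilities"
            pair_probs = pair_probabilities_from_traffic(
                ports, calls_by_ship, specs, params
            ) if world is None else world.pair_probs
            region_probs = (
                region_probability_matrix(pair_probs, ports)
                if world is None
                else world.region_probs
            )
            pairs_frame = pd.DataFrame(
                [
                    (p.i, p.j, p.distance_km, p.p_nonindigenous, p.p_establish, p.p_invasion, p.n_routes)
                    for p in pair_probs
                ],
                columns=["i", "j", "distance_km", "p_nonindigenous", "p_establish", "p_invasion", "n_routes"],
            )
            path = outdir / "pair_probabilities.csv"
            pairs_frame.to_csv(path, index=False)
            register("pair_probabilities", path)
            region_frame = pd.DataFrame(
                [(a, b, p) for (a, b), p in region_probs.items()],
                columns=["donor", "recipient", "p_invasion"],
            )
            path = outdir / "region_probabilities.csv"
            region_frame.to_csv(path, index=False)
            register("region_probabilities", path)
            report["stages"]["probabilities"] = {
                "port_pairs": len(pair_probs),
                "region_pairs": len(region_probs),
            }

        region_richness = {}
        if world is not None:
            region_richness = world.region_richness
        elif "grid" in config.inputs:
            stage = "expected"
            grid = load_grid(resolve_path(config.inputs["grid"]))
            for region in grid.cells["region"].unique():
                region_richness[str(region)] = average_grid_richness(grid, str(region))
        rc = config.richness_config
        if rc.get("reference_region") and rc.get("reference_total"):
            stage = "expected"
            ref = region_richness[rc["reference_region"]]
            factor = correction_factor(ref, float(rc["reference_total"]))
            report["stages"].setdefault("expected", {})["correction_factor"] = factor
            for region, total in dict(rc.get("totals", {})).items():
                region_richness[region] = corrected_average_richness(
                    float(total), factor, region
                )

        if region_probs is not None and region_richness:
            stage = "expected"
            rows = [
                (
                    a,
                    b,
                    region_richness[a].average_richness,
                    p,
                    region_richness[a].average_richness * p,
                )
                for (a, b), p in region_probs.items()
                if a in region_richness
            ]
            expected_frame = pd.DataFrame(
                rows, columns=["donor", "recipient", "richness", "p_inv", "expected"]
            )
            path = outdir / "expected.csv"
            expected_frame.to_csv(path, index=False)
            register("expected", path)
            report["stages"].setdefault("expected", {})["rows"] = len(expected_frame)

        results = None
        if "table2" in config.inputs:
            stage = "compare"
            results = table_from_fixture(resolve_path(config.inputs["table2"]))
        elif world is not None:
            stage = "compare"
            results = world_comparison_rows(world)
        if results is not None:
            frame = results_frame(results)
            path = outdir / "comparison.csv"
            frame.to_csv(path, index=False)
            register("comparison", path)
            path = outdir / "scatter.csv"
            scatter_frame(results).to_csv(path, index=False)
            register("scatter", path)
            overall = {}
            for recipient in sorted({r.recipient for r in results}):
                rows = [r for r in results if r.recipient == recipient]
                if len(rows) >= 2:
                    chi2, df, p = overall_chi_square(rows)
                    overall[recipient] = {"chi_square": chi2, "df": df, "p_value": p}
            if len(results) >= 2:
                chi2, df, p = overall_chi_square(results)
                overall["pooled"] = {"chi_square": chi2, "df": df, "p_value": p}
            report["stages"]["compare"] = {"rows": len(results), "overall": overall}
            report["comparison"] = frame.to_dict(orient="records")

        checklists: dict[str, Checklist] = {}
        if "checklists" in config.inputs:
            stage = "checklist"
            for recipient, path_value in dict(config.inputs["checklists"]).items():
                checklists[recipient] = load_checklist(
                    resolve_path(path_value), recipient_region=recipient
                )
        elif world is not None:
            checklists = world.checklists
        if checklists:
            stage = "checklist"
            summary_rows = []
            for recipient, cl in checklists.items():
                if not cl.records:
                    report["warnings"].append(f"checklist {recipient} is empty")
                    continue
                for region, pct in sorted(origin_percentages(cl, config.exclude_phyla).items()):
                    summary_rows.append((recipient, "origin", region, pct))
                for label, (count, pct) in taxonomic_composition(
                    cl, "phylum", config.exclude_phyla
                ).items():
                    summary_rows.append((recipient, "phylum", label, pct))
            summary = pd.DataFrame(
                summary_rows, columns=["recipient", "kind", "label", "percent"]
            )
            path = outdir / "checklist_summary.csv"
            summary.to_csv(path, index=False)
            register("checklist_summary", path)
            report["stages"]["checklist"] = {
                "checklists": len(checklists),
                "summary_rows": len(summary),
            }
    except (ValidationError, SchemaError) as exc:
        raise StageError(stage, str(exc)) from exc
    except OSError as exc:
        raise StageError(stage, f"I/O failure: {exc}") from exc

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("pipeline complete; report at %s", report_path)
    return report
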