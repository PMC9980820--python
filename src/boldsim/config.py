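"""YAML/JSON configuration loading and run manifests.

A config file is a flat mapping of :class:`~boldsim.engine.SimulationConfig`
fields (single run) or :class:`~boldsim.experiments.SweepDesign` fields
(sweep, recognised by the presence of ``swept_parameter``).  Missing fields
take the study baselines; unknown keys are rejected with their path.

Every CLI run writes a :class:`RunManifest` next to its outputs; the
manifest plus the package version reproduces every output byte.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import yaml

from . import __version__
from .engine import ConfigurationError, SimulationConfig
from .experiments import PUBLISHED_GRIDS, SweepDesign

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}
_SWEEP_FIELDS = {"swept_parameter", "grid", "replicates", "rules",
                 "master_seed", "baseline"}


def _load_mapping(path) -> dict:
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping at the top level")
    return data


def simulation_config_from_mapping(data: dict, context: str = "") -> SimulationConfig:
    unknown = set(data) - _SIM_FIELDS
    if unknown:
        raise ConfigurationError(
            f"{context}unknown keys {sorted(unknown)}; valid keys: "
            f"{sorted(_SIM_FIELDS)}")
    return SimulationConfig(**data)


def sweep_design_from_mapping(data: dict) -> SweepDesign:
    unknown = set(data) - _SWEEP_FIELDS
    if unknown:
        raise ConfigurationError(
            f"unknown keys {sorted(unknown)}; valid keys: {sorted(_SWEEP_FIELDS)}")
    baseline = simulation_config_from_mapping(
        data.get("baseline", {}), context="baseline: ")
    try:
        return SweepDesign(
            swept_parameter=data["swept_parameter"],
            grid=tuple(data.get("grid", PUBLISHED_GRIDS[data["swept_parameter"]])),
            baseline=baseline,
            replicates=int(data.get("replicates", 1)),
            rules=tuple(data.get("rules", ("central", "nearest_neighbour",
                                           "majority", "non_social"))),
            master_seed=int(data.get("master_seed", 0)),
        )
    except KeyError as exc:
        raise ConfigurationError(f"missing required key: {exc}") from exc
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from exc


def load_config(path) -> SimulationConfig | SweepDesign:
    """Parse a YAML/JSON file into a validated config or sweep design."""
    data = _load_mapping(path)
    if "swept_parameter" in data:
        return sweep_design_from_mapping(data)
    return simulation_config_from_mapping(data)


def dump_config(obj: SimulationConfig | SweepDesign) -> dict:
    """Serialise a config/design back to a plain mapping (round-trips)."""
    data = dataclasses.asdict(obj)
    if isinstance(obj, SweepDesign):
        data["grid"] = list(obj.grid)
        data["rules"] = list(obj.rules)
    return data


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce one CLI invocation byte-for-byte."""

    command: str
    configuration: dict
    version: str
    timestamp: str
    outputs: list[str]

    @classmethod
    def create(cls, command: str, obj, outputs: list[str]) -> "RunManifest":
        return cls(
            command=command,
            configuration=dump_config(obj),
            version=__version__,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
            outputs=[str(p) for p in outputs],
        )

    def write(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def read_manifest(path) -> RunManifest:
    data = yaml.safe_load(Path(path).read_text())
    return RunManifest(**data)
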