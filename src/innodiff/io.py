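"""Configuration files, run manifests and deterministic test fixtures.

Configs are flat YAML key/value files whose keys match the fields of
:class:`~innodiff.experiments.SimulationConfig`; unspecified fields take the
package defaults (n=100, l=2, p=0.3, t_total=100, reps=50) and unknown keys
are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from .cognition import CognitionVector
from .dynamics import PopulationState, Trajectory
from .experiments import SimulationConfig
from .network import ObservationNetwork

__all__ = [
    "ConfigError",
    "load_config",
    "save_config",
    "make_fixture",
    "RunManifest",
    "write_trajectory_json",
]

_CONFIG_FIELDS = {f.name: f.type for f in dataclasses.fields(SimulationConfig)}
_INT_FIELDS = {"n", "l", "t_total", "reps", "seed"}


class ConfigError(ValueError):
    """A configuration file failed to parse or validate."""


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML config; missing keys take the defaults."""
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping of key: value pairs")
    unknown = set(raw) - set(_CONFIG_FIELDS)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    coerced = {}
    for key, value in raw.items():
        try:
            coerced[key] = int(value) if key in _INT_FIELDS else float(value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"config key {key!r} has non-numeric value {value!r}") from exc
    config = SimulationConfig(**coerced)
    try:
        config.validate()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return config


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def make_fixture(
    kind: str, size: int
) -> tuple[ObservationNetwork, CognitionVector, PopulationState]:
    """Deterministic toy graph plus fixed cognition and seed patterns.

    Shapes: ``star`` (node 0 the hub), ``cycle``, ``complete`` and
    ``two-cliques`` (two cliques on the first and second halves of the
    nodes, joined by one bridge edge).  Cognition levels are the evenly
    spaced grid mu_i = (i + 1) / size, so node size-1 perceives the full
    value 1; node 0 starts as the only adopter.  Designed for exact,
    hand-checkable cascade tests.
    """
    if size < 2:
        raise ValueError(f"fixture size must be >= 2, got {size!r}")
    if kind == "star":
        graph = nx.star_graph(size - 1)
    elif kind == "cycle":
        graph = nx.cycle_graph(size)
    elif kind == "complete":
        graph = nx.complete_graph(size)
    elif kind == "two-cliques":
        half = size // 2
        graph = nx.complete_graph(half)
        graph.add_edges_from(
            (u, v) for u in range(half, size) for v in range(u + 1, size)
        )
        graph.add_nodes_from(range(size))
        graph.add_edge(0, half)  # bridge
    else:
        raise ValueError(
            f"unknown fixture kind {kind!r}; expected star, cycle, complete or two-cliques"
        )
    cognition = CognitionVector(np.arange(1, size + 1) / size)
    w = np.zeros(size, dtype=np.int8)
    w[0] = 1
    return ObservationNetwork(graph=graph), cognition, PopulationState(w=w, t=0)


@dataclass
class RunManifest:
    """Traceability record written next to every CLI result file."""

    command: str
    config: dict
    seed: int
    outputs: list[str]
    version: str
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")


def write_trajectory_json(
    traj: Trajectory, path: str | Path, seed: int, config: SimulationConfig
) -> None:
    """Serialize one run with the seed and config that produced it."""
    payload = traj.to_dict()
    payload["seed"] = int(seed)
    payload["config"] = dataclasses.asdict(config)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
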