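"""File formats: edge-list CSV / GraphML topologies, YAML configs, and
CSV exports of simulation outputs."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .dynamics import AttackSpec, ExternalDrive, PlasticityParams, SimConfig, SimResult
from .errors import ConfigurationError
from .topology import TopologyConfig, WeightedGraph

__all__ = [
    "write_edge_csv",
    "read_edge_csv",
    "write_graphml",
    "read_graphml",
    "load_config",
    "save_config",
    "write_raster_csv",
    "write_traces_csv",
    "write_msw_csv",
]


def write_edge_csv(graph: WeightedGraph, path: str | Path) -> None:
    """Write ``source,target,weight`` rows (0-based ids, source < target)."""
    edges = graph.edge_array()
    df = pd.DataFrame(
        {
            "source": edges[:, 0].astype(int),
            "target": edges[:, 1].astype(int),
            "weight": edges[:, 2],
        }
    )
    df.to_csv(path, index=False)


def read_edge_csv(path: str | Path, n_nodes: int | None = None) -> WeightedGraph:
    """Read an edge-list CSV written by :func:`write_edge_csv`."""
    df = pd.read_csv(path)
    required = {"source", "target", "weight"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"edge CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    if (df["weight"] <= 0).any():
        raise ConfigurationError("edge weights must be positive")
    g = nx.Graph()
    n = n_nodes if n_nodes is not None else int(df[["source", "target"]].max().max()) + 1
    g.add_nodes_from(range(n))
    g.add_weighted_edges_from(
        zip(df["source"].astype(int), df["target"].astype(int), df["weight"])
    )
    return WeightedGraph(n_nodes=n, graph=g)


def write_graphml(graph: WeightedGraph, path: str | Path) -> None:
    nx.write_graphml(graph.graph, path)


def read_graphml(path: str | Path) -> WeightedGraph:
    g = nx.read_graphml(path, node_type=int)
    g = nx.relabel_nodes(g, {n: int(n) for n in g.nodes})
    return WeightedGraph(n_nodes=g.number_of_nodes(), graph=g)


_CONFIG_TYPES = {
    "topology": TopologyConfig,
    "sim": SimConfig,
    "plasticity": PlasticityParams,
    "attack": AttackSpec,
    "drive": ExternalDrive,
}


def _from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(
            f"unknown keys for {cls.__name__}: {sorted(unknown)}"
        )
    if cls is SimConfig and "drive" in data and isinstance(data["drive"], dict):
        data = {**data, "drive": _from_dict(ExternalDrive, data["drive"])}
    return cls(**data)


def load_config(path: str | Path, kind: str):
    """Load a flat YAML mapping into one of the config dataclasses.

    ``kind`` is one of ``topology``, ``sim``, ``plasticity``, ``attack``,
    ``drive``.  Unknown keys are rejected.
    """
    if kind not in _CONFIG_TYPES:
        raise ConfigurationError(f"unknown config kind {kind!r}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must be a mapping")
    return _from_dict(_CONFIG_TYPES[kind], data)


def save_config(obj, path: str | Path) -> None:
    """Serialize a config dataclass to YAML."""
    data = dataclasses.asdict(obj)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_raster_csv(result: SimResult, path: str | Path) -> None:
    """Spike raster as ``neuron_id,spike_time_ms`` rows."""
    ids, times = [], []
    for i, s in enumerate(result.spike_times):
        ids.extend([i] * len(s))
        times.extend(np.asarray(s).tolist())
    pd.DataFrame({"neuron_id": ids, "spike_time_ms": times}).to_csv(path, index=False)


def write_traces_csv(
    result: SimResult, path: str | Path, neuron_ids=None
) -> None:
    """Membrane traces in wide format; first column ``time_ms``."""
    if result.v_traces is None:
        raise ConfigurationError("run was executed without record_v")
    if neuron_ids is None:
        neuron_ids = range(result.network.n)
    data = {"time_ms": result.times}
    for i in neuron_ids:
        data[f"v_{i}"] = result.v_traces[:, i]
    pd.DataFrame(data).to_csv(path, index=False)


def write_msw_csv(result: SimResult, path: str | Path) -> None:
    pd.DataFrame({"time_ms": result.msw_times, "msw": result.msw_values}).to_csv(
        path, index=False
    )
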