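"""Experiment orchestration: paired baseline/attacked sweeps across the
three topology classes and the stochastic-attack grid.

Every stochastic choice in a sweep derives deterministically from
``master_seed`` via :func:`derive_seed`, so re-running a manifest
reproduces each output exactly.  Each replicate draws its own topology
realization (the published ensemble values are treated as seed averages),
while the baseline and attacked runs of one replicate share the topology,
neuron assignment, synaptic delays and the drive seed — they differ only
in the attack.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .dynamics import (
    AttackSpec,
    PlasticityParams,
    SimConfig,
    apply_attack,
    build_network,
    simulate,
)
from .errors import ComsnnError, ConfigurationError
from .metrics import PairedRuns, pearson_with_ttest, time_resolved
from .topology import DEFAULT_M0, DEFAULT_ME, DEFAULT_PN, TopologyConfig, generate

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentManifest",
    "derive_seed",
    "default_topologies",
    "run_paired",
    "run_injury_sweep",
    "run_mechanism_analysis",
    "run_topology_progression",
    "make_fixtures",
    "ATTACK_GRID",
]

ATTACK_GRID = tuple(round(0.05 * k, 2) for k in range(1, 11))  # 5% .. 50%

# WS parameters calibrated so the 500-node small-world index matches the
# complex topology's (~1.96) at the same mean degree; see docs/methods.md.
DEFAULT_WS_K = 6
DEFAULT_WS_P_REWIRE = 0.74


def derive_seed(master_seed: int, *keys: int) -> int:
    """Deterministic sub-seed below 2**31 from a master seed and a key path."""
    ss = np.random.SeedSequence([int(master_seed), *[int(k) & 0x7FFFFFFF for k in keys]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def default_topologies(n_nodes: int) -> dict[str, TopologyConfig]:
    """The three study topologies at a given network size.

    ``com`` — weighted growth with reattachment (both scale-free and
    small-world); ``sf`` — Barabasi–Albert; ``sw`` — Watts–Strogatz, all
    matched in mean degree.
    """
    return {
        "com": TopologyConfig("bbv", n_nodes, pn=DEFAULT_PN, m0=DEFAULT_M0, me=DEFAULT_ME),
        "sf": TopologyConfig("ba", n_nodes, m0=DEFAULT_M0, me=DEFAULT_ME),
        "sw": TopologyConfig(
            "ws", n_nodes, K=DEFAULT_WS_K, p_rewire=DEFAULT_WS_P_REWIRE
        ),
    }


@dataclass
class ExperimentManifest:
    """Full description of one sweep."""

    topologies: dict[str, TopologyConfig]
    attack_grid: Sequence[float] = ATTACK_GRID
    n_replicates: int = 10
    sim_config: SimConfig = field(default_factory=SimConfig)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    master_seed: int = 0
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if not self.topologies:
            raise ConfigurationError("at least one topology is required")
        if self.output_dir is not None:
            self.output_dir = Path(self.output_dir)


# role codes for seed derivation
_ROLE_TOPO, _ROLE_NET, _ROLE_DRIVE, _ROLE_ATTACK = 0, 1, 2, 3


def run_paired(
    topo_cfg: TopologyConfig,
    proportion: float,
    sim_config: SimConfig,
    plasticity: PlasticityParams,
    master_seed: int,
    topo_index: int = 0,
    replicate: int = 0,
) -> PairedRuns:
    """One baseline/attacked pair for a single replicate.

    The attacked run reuses the baseline's network object and drive seed;
    only the removal differs.
    """
    t_seed = derive_seed(master_seed, topo_index, replicate, _ROLE_TOPO)
    n_seed = derive_seed(master_seed, topo_index, replicate, _ROLE_NET)
    d_seed = derive_seed(master_seed, topo_index, replicate, _ROLE_DRIVE)
    a_seed = derive_seed(master_seed, topo_index, replicate, _ROLE_ATTACK)

    graph = generate(replace(topo_cfg, seed=t_seed))
    cfg = replace(sim_config, seed=d_seed)
    network = build_network(graph, cfg, plasticity, seed=n_seed)
    baseline = simulate(network, cfg)
    attacked_net = apply_attack(network, AttackSpec(proportion, seed=a_seed))
    attacked = simulate(attacked_net, cfg)
    return PairedRuns(baseline=baseline, attacked=attacked)


def _aggregate(df: pd.DataFrame, value: str) -> pd.DataFrame:
    """Topology x P table of replicate means (shape of the published tables)."""
    return df.pivot_table(index="topology", columns="P", values=value, aggfunc="mean")


def run_injury_sweep(manifest: ExperimentManifest) -> dict[str, pd.DataFrame]:
    """Paired runs for every (topology, P, replicate) cell.

    Returns ``{"replicates": long-format frame, "delta": topology x P mean
    table, "rho": same for rho}`` and writes them as CSV when the
    manifest has an output directory.  Failed runs are recorded and
    skipped; the sweep aborts if more than 10% fail.
    """
    rows = []
    failures = 0
    total = 0
    for ti, (name, topo_cfg) in enumerate(manifest.topologies.items()):
        for p in manifest.attack_grid:
            for rep in range(manifest.n_replicates):
                total += 1
                try:
                    paired = run_paired(
                        topo_cfg, p, manifest.sim_config, manifest.plasticity,
                        manifest.master_seed, topo_index=ti, replicate=rep,
                    )
                    rows.append(
                        {
                            "topology": name,
                            "P": p,
                            "replicate": rep,
                            "delta_percent": _metrics.delta_metric(paired),
                            "rho": _metrics.rho_metric(paired),
                            "msw_final": float(paired.attacked.msw_values[-1]),
                        }
                    )
                except ComsnnError as exc:
                    failures += 1
                    logger.warning(
                        "run failed (topology=%s P=%s rep=%d): %s", name, p, rep, exc
                    )
    if total and failures > 0.1 * total:
        raise ComsnnError(f"{failures}/{total} runs failed; aborting sweep")
    df = pd.DataFrame(rows)
    out = {
        "replicates": df,
        "delta": _aggregate(df, "delta_percent"),
        "rho": _aggregate(df, "rho"),
    }
    if manifest.output_dir is not None:
        d = manifest.output_dir
        d.mkdir(parents=True, exist_ok=True)
        df.to_csv(d / "replicates.csv", index=False)
        out["delta"].to_csv(d / "table_delta.csv")
        out["rho"].to_csv(d / "table_rho.csv")
        _write_runlog(d, manifest, total, failures)
    return out


def run_mechanism_analysis(
    manifest: ExperimentManifest,
    proportions: Sequence[float] = (0.05, 0.25, 0.45),
    topology: str = "com",
    window_len: float = 50.0,
    stride: float = 10.0,
) -> dict[str, object]:
    """Time-resolved mean synaptic weight vs injury metrics.

    For each attack proportion, the sliding-window MSW, delta and rho
    series are computed per replicate and averaged; the centered Pearson
    correlation (with t-test) between the mean MSW series and each
    injury-metric series is tabulated.
    """
    topo_cfg = manifest.topologies[topology]
    ti = list(manifest.topologies).index(topology)
    sim_cfg = replace(manifest.sim_config, record_v=True)
    corr_rows = []
    series_out: dict[float, pd.DataFrame] = {}
    for p in proportions:
        series = []
        for rep in range(manifest.n_replicates):
            paired = run_paired(
                topo_cfg, p, sim_cfg, manifest.plasticity,
                manifest.master_seed, topo_index=ti, replicate=rep,
            )
            series.append(
                time_resolved(paired, window_len=window_len, stride=stride)
            )
        times = series[0].times
        msw = np.nanmean([s.msw for s in series], axis=0)
        delta = np.nanmean([s.delta for s in series], axis=0)
        rho = np.nanmean([s.rho for s in series], axis=0)
        series_out[p] = pd.DataFrame(
            {"time_ms": times, "msw": msw, "delta": delta, "rho": rho}
        )
        ok = np.isfinite(delta) & np.isfinite(rho) & np.isfinite(msw)
        r_d = pearson_with_ttest(msw[ok], delta[ok])
        r_r = pearson_with_ttest(msw[ok], rho[ok])
        corr_rows.append(
            {
                "P": p,
                "r_msw_delta": r_d.r, "p_msw_delta": r_d.p, "stars_delta": r_d.stars,
                "r_msw_rho": r_r.r, "p_msw_rho": r_r.p, "stars_rho": r_r.stars,
            }
        )
    corr = pd.DataFrame(corr_rows)
    if manifest.output_dir is not None:
        d = manifest.output_dir
        d.mkdir(parents=True, exist_ok=True)
        corr.to_csv(d / "table_msw_correlations.csv", index=False)
        for p, frame in series_out.items():
            frame.to_csv(d / f"series_P{int(round(100 * p))}.csv", index=False)
    return {"correlations": corr, "series": series_out}


def run_topology_progression(
    manifest: ExperimentManifest,
    proportion: float = 0.25,
    window_len: float = 50.0,
    stride: float = 10.0,
) -> dict[str, pd.DataFrame]:
    """Weighted clustering and path-length progression per topology.

    Runs each topology at one attack proportion with conductance
    snapshots enabled and returns the replicate-averaged time series of
    the Barrat clustering coefficient and the weighted shortest path
    length of the live network.
    """
    sim_cfg = replace(manifest.sim_config, record_v=True, record_g=True)
    out: dict[str, pd.DataFrame] = {}
    for ti, (name, topo_cfg) in enumerate(manifest.topologies.items()):
        series = []
        for rep in range(manifest.n_replicates):
            paired = run_paired(
                topo_cfg, proportion, sim_cfg, manifest.plasticity,
                manifest.master_seed, topo_index=ti, replicate=rep,
            )
            series.append(
                time_resolved(
                    paired, window_len=window_len, stride=stride, with_topology=True
                )
            )
        out[name] = pd.DataFrame(
            {
                "time_ms": series[0].times,
                "cw": np.nanmean([s.cw for s in series], axis=0),
                "lw": np.nanmean([s.lw for s in series], axis=0),
                "msw": np.nanmean([s.msw for s in series], axis=0),
            }
        )
        if manifest.output_dir is not None:
            d = manifest.output_dir
            d.mkdir(parents=True, exist_ok=True)
            out[name].to_csv(
                d / f"progression_{name}_P{int(round(100 * proportion))}.csv",
                index=False,
            )
    return out


def make_fixtures(scale: str = "tiny", seed: int = 0) -> dict[str, object]:
    """Deterministic small networks and a matching run config for tests.

    ``tiny`` is a 20-node bundle with a 100 ms config; ``small`` is a
    100-node bundle with a 500 ms config.
    """
    if scale == "tiny":
        n, duration = 20, 100.0
    elif scale == "small":
        n, duration = 100, 500.0
    else:
        raise ConfigurationError(f"unknown fixture scale {scale!r}")
    topos = {
        "com": TopologyConfig("bbv", n, pn=DEFAULT_PN, seed=derive_seed(seed, 0)),
        "sf": TopologyConfig("ba", n, seed=derive_seed(seed, 1)),
        "sw": TopologyConfig(
            "ws", n, K=DEFAULT_WS_K, p_rewire=DEFAULT_WS_P_REWIRE,
            seed=derive_seed(seed, 2),
        ),
    }
    graphs = {k: generate(cfg) for k, cfg in topos.items()}
    sim_cfg = SimConfig(duration=duration, seed=derive_seed(seed, 3))
    return {"configs": topos, "graphs": graphs, "sim_config": sim_cfg}


def _write_runlog(
    directory: Path, manifest: ExperimentManifest, total: int, failures: int
) -> None:
    entry = {
        "master_seed": manifest.master_seed,
        "n_replicates": manifest.n_replicates,
        "attack_grid": list(manifest.attack_grid),
        "topologies": {
            k: {"algorithm": c.algorithm, "n_nodes": c.n_nodes}
            for k, c in manifest.topologies.items()
        },
        "total_runs": total,
        "failed_runs": failures,
    }
    with open(directory / "runlog.jsonl", "a") as fh:
        fh.write(json.dumps(entry) + "\n")
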