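"""Injury-resistance and dynamic-topology metrics.

Two scalar metrics quantify how much a stochastic attack perturbs the
network relative to a paired, attack-free baseline run that shares every
seed:

* **delta** — mean over surviving neurons of the absolute relative change
  in firing rate, |f_b - f_a| / f_a, in percent.  Lower is more
  injury-resistant.
* **rho** — mean over surviving neurons of the *uncentered* correlation
  (cosine similarity) between the baseline and attacked membrane-potential
  traces.  Higher is more injury-resistant.  This is deliberately not the
  centered Pearson coefficient; the centered version is used only for the
  trajectory-correlation analysis (:func:`pearson_with_ttest`).

The live synaptic network additionally yields the mean synaptic weight,
the Barrat weighted clustering coefficient and the weighted shortest
path length (edge length 1/weight), all computable on snapshots over
time (:func:`time_resolved`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse import csgraph

from .dynamics import Network, SimResult
from .errors import MetricUndefinedError
from typing import NamedTuple

logger = logging.getLogger(__name__)

__all__ = [
    "PairedRuns",
    "MetricSeries",
    "firing_rate",
    "delta_metric",
    "rho_metric",
    "mean_synaptic_weight",
    "snapshot_weight_matrix",
    "weighted_clustering",
    "weighted_shortest_path",
    "pearson_with_ttest",
    "time_resolved",
]


@dataclass
class PairedRuns:
    """A baseline run and an attacked run of the same network.

    Both runs must share topology, neuron assignment, delays and the
    drive seed; they differ only in the applied attack.  ``alive_ids``
    are the neurons present in both (all ids minus the removed set).
    """

    baseline: SimResult
    attacked: SimResult

    def __post_init__(self) -> None:
        if self.baseline.config.seed != self.attacked.config.seed:
            raise MetricUndefinedError(
                "paired runs must share the drive seed; got "
                f"{self.baseline.config.seed} vs {self.attacked.config.seed}"
            )
        if self.baseline.network.n != self.attacked.network.n:
            raise MetricUndefinedError("paired runs must share the network size")

    @property
    def alive_ids(self) -> np.ndarray:
        mask = np.ones(self.baseline.network.n, dtype=bool)
        mask[list(self.attacked.removed)] = False
        mask[list(self.baseline.removed)] = False
        return np.flatnonzero(mask)

    @property
    def duration(self) -> float:
        return self.baseline.config.duration


def firing_rate(spike_times: np.ndarray, window: tuple[float, float]) -> float:
    """Spikes per second in the half-open window [t_start, t_end), times in ms."""
    t0, t1 = window
    if t1 <= t0:
        raise MetricUndefinedError(f"empty window ({t0}, {t1})")
    s = np.asarray(spike_times)
    count = np.count_nonzero((s >= t0) & (s < t1))
    return 1000.0 * count / (t1 - t0)


def delta_metric(
    paired: PairedRuns,
    window: tuple[float, float] | None = None,
    signed: bool = False,
) -> float:
    """Mean relative firing-rate change, in percent.

    By default the per-neuron deviation is taken in absolute value, which
    makes delta a monotone injury measure (zero iff the attacked rates
    equal the baseline rates).  ``signed=True`` averages the raw
    deviations instead, so systematic rate increases and decreases can
    cancel.  Computed over surviving neurons with a nonzero baseline rate
    in the window; silent-baseline neurons are excluded (their relative
    change is undefined) and their count logged.
    """
    if window is None:
        window = (0.0, paired.duration)
    ids = paired.alive_ids
    f_a = paired.baseline.spike_counts(*window)[ids].astype(float)
    f_b = paired.attacked.spike_counts(*window)[ids].astype(float)
    active = f_a > 0
    n_silent = int(np.count_nonzero(~active))
    if n_silent:
        logger.debug("delta_metric: excluding %d silent-baseline neurons", n_silent)
    if not np.any(active):
        raise MetricUndefinedError("all baseline rates are zero in the window")
    dev = (f_b[active] - f_a[active]) / f_a[active]
    if not signed:
        dev = np.abs(dev)
    return float(np.mean(dev) * 100.0)


def rho_metric(
    paired: PairedRuns, t1: float = 1.0, t2: float | None = None
) -> float:
    """Mean per-neuron uncentered correlation of membrane traces.

    For each surviving neuron, sum(x_a x_b) / sqrt(sum(x_a^2) sum(x_b^2))
    over samples in [t1, t2]; the mean over neurons is returned.
    Zero-energy traces are excluded (logged).
    """
    xa_full, xb_full = paired.baseline.v_traces, paired.attacked.v_traces
    if xa_full is None or xb_full is None:
        raise MetricUndefinedError("rho requires record_v=True in both runs")
    cfg = paired.baseline.config
    if t2 is None:
        t2 = cfg.duration
    times = paired.baseline.times
    sel = (times >= t1) & (times <= t2)
    if not np.any(sel):
        raise MetricUndefinedError(f"no samples in [{t1}, {t2}] ms")
    ids = paired.alive_ids
    xa = xa_full[np.ix_(sel, ids)].astype(np.float64)
    xb = xb_full[np.ix_(sel, ids)].astype(np.float64)
    num = np.einsum("ti,ti->i", xa, xb)
    ea = np.einsum("ti,ti->i", xa, xa)
    eb = np.einsum("ti,ti->i", xb, xb)
    ok = (ea > 0) & (eb > 0)
    if not np.any(ok):
        raise MetricUndefinedError("all traces have zero energy in the window")
    n_skip = int(np.count_nonzero(~ok))
    if n_skip:
        logger.debug("rho_metric: excluding %d zero-energy traces", n_skip)
    return float(np.mean(num[ok] / np.sqrt(ea[ok] * eb[ok])))


def mean_synaptic_weight(g: np.ndarray, alive_mask: np.ndarray | None = None) -> float:
    """Arithmetic mean conductance over synapses with both endpoints alive."""
    g = np.asarray(g, dtype=float)
    if alive_mask is not None:
        g = g[alive_mask]
    if g.size == 0:
        raise MetricUndefinedError("no alive synapses")
    return float(g.mean())


def snapshot_weight_matrix(
    network: Network, g: np.ndarray, restrict_alive: bool = True
) -> sparse.csr_matrix:
    """Undirected weighted snapshot of the live synaptic network.

    The weight between nodes i and j is the mean of the two directed
    conductances; pairs whose conductances are both zero carry no edge.
    Removed neurons are kept as isolated rows so indices stay aligned
    with neuron ids.
    """
    pre, post = network.pre, network.post
    g = np.asarray(g, dtype=float)
    if restrict_alive:
        live = network.synapse_alive_mask()
        pre, post, g = pre[live], post[live], g[live]
    n = network.n
    m = sparse.coo_matrix((g, (pre, post)), shape=(n, n)).tocsr()
    sym = (m + m.T) / 2.0
    sym.eliminate_zeros()
    return sym.tocsr()


def weighted_clustering(w: sparse.spmatrix | np.ndarray) -> float:
    """Barrat weighted clustering coefficient, averaged over all nodes.

    C_i = 1 / (s_i (k_i - 1)) * sum_{j,k} (w_ij + w_ik)/2 * a_ij a_jk a_ki,
    with node strength s_i and degree k_i; nodes of degree < 2 contribute
    zero.  The average runs over every (non-removed) node in the snapshot.
    """
    w = sparse.csr_matrix(w, dtype=float)
    n = w.shape[0]
    if n == 0 or w.nnz == 0:
        raise MetricUndefinedError("empty graph snapshot")
    a = (w > 0).astype(float)
    s = np.asarray(w.sum(axis=1)).ravel()
    k = np.asarray(a.sum(axis=1)).ravel()
    # sum_{j,k} ((w_ij + w_ik)/2) a_ij a_jk a_ki  ==  diag(W A A) by symmetry
    num = (w @ a @ a).diagonal()
    denom = s * (k - 1)
    c = np.zeros(n)
    ok = (k >= 2) & (denom > 0)
    c[ok] = num[ok] / denom[ok]
    return float(c.mean())


def weighted_shortest_path(w: sparse.spmatrix | np.ndarray) -> float:
    """Mean weighted shortest path length with edge length 1/weight.

    Averaged over ordered node pairs inside the largest connected
    component of the snapshot; pairs outside it (and isolated nodes) are
    excluded with a logged count.
    """
    w = sparse.csr_matrix(w, dtype=float)
    n = w.shape[0]
    if n == 0 or w.nnz == 0:
        raise MetricUndefinedError("all nodes isolated")
    lengths = w.copy()
    lengths.data = 1.0 / lengths.data
    n_comp, labels = csgraph.connected_components(w, directed=False)
    sizes = np.bincount(labels)
    # restrict to the largest component containing at least one edge
    keep = np.flatnonzero(labels == np.argmax(sizes))
    if keep.size < 2:
        raise MetricUndefinedError("largest component has fewer than 2 nodes")
    n_excluded = n * (n - 1) - keep.size * (keep.size - 1)
    if n_excluded:
        logger.debug(
            "weighted_shortest_path: %d ordered pairs outside the largest "
            "component excluded", n_excluded,
        )
    sub = lengths[np.ix_(keep, keep)]
    d = csgraph.shortest_path(sub, method="D", directed=False)
    iu = ~np.eye(keep.size, dtype=bool)
    return float(d[iu].mean())


class PearsonResult(NamedTuple):
    r: float
    t: float
    p: float
    stars: str


def pearson_with_ttest(x: np.ndarray, y: np.ndarray) -> PearsonResult:
    """Centered Pearson correlation with a two-sided t-test.

    t = r sqrt(n - 2) / sqrt(1 - r^2) with n - 2 degrees of freedom;
    ``stars`` is ``"**"`` when p < 0.01, else ``""``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise MetricUndefinedError("series must have equal length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise MetricUndefinedError("series contain non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise MetricUndefinedError("correlation undefined for zero-variance series")
    r, p = stats.pearsonr(x, y)
    n = x.size
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return PearsonResult(float(r), float(t), float(p), "**" if p < 0.01 else "")


@dataclass
class MetricSeries:
    """Time-resolved metrics on a sliding-window grid (window centers)."""

    times: np.ndarray
    delta: np.ndarray
    rho: np.ndarray
    msw: np.ndarray
    cw: np.ndarray | None = None
    lw: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ms": self.times, "delta": self.delta,
                "rho": self.rho, "msw": self.msw}
        if self.cw is not None:
            data["cw"] = self.cw
        if self.lw is not None:
            data["lw"] = self.lw
        return pd.DataFrame(data)


def time_resolved(
    paired: PairedRuns,
    window_len: float = 50.0,
    stride: float = 10.0,
    with_topology: bool = False,
) -> MetricSeries:
    """Sliding-window progression of delta, rho, MSW and (optionally) the
    weighted graph metrics.

    delta and rho are recomputed per window; MSW, the Barrat clustering
    and the weighted path length are evaluated on the attacked run's
    conductance snapshot nearest each window center (``record_g=True``
    required for the topology series).
    """
    duration = paired.duration
    if window_len > duration:
        raise MetricUndefinedError("window_len exceeds the run duration")
    starts = np.arange(0.0, duration - window_len + 1e-9, stride)
    centers = starts + window_len / 2.0

    att = paired.attacked
    deltas, rhos, msws = [], [], []
    cws: list[float] = []
    lws: list[float] = []
    if with_topology and att.g_snapshots is None:
        raise MetricUndefinedError(
            "topology series require record_g=True in the attacked run"
        )
    live_syn = att.network.synapse_alive_mask()
    for t0, tc in zip(starts, centers):
        t1 = t0 + window_len
        try:
            deltas.append(delta_metric(paired, window=(t0, t1)))
        except MetricUndefinedError:
            deltas.append(np.nan)
        try:
            rhos.append(rho_metric(paired, t1=max(t0, 1e-9), t2=t1))
        except MetricUndefinedError:
            rhos.append(np.nan)
        k = int(np.argmin(np.abs(att.msw_times - tc)))
        msws.append(att.msw_values[k])
        if with_topology:
            g_snap = att.g_snapshots[k].astype(float)
            wmat = snapshot_weight_matrix(att.network, g_snap)
            try:
                cws.append(weighted_clustering(wmat))
            except MetricUndefinedError:
                cws.append(np.nan)
            try:
                lws.append(weighted_shortest_path(wmat))
            except MetricUndefinedError:
                lws.append(np.nan)

    return MetricSeries(
        times=centers,
        delta=np.asarray(deltas),
        rho=np.asarray(rhos),
        msw=np.asarray(msws),
        cw=np.asarray(cws) if with_topology else None,
        lw=np.asarray(lws) if with_topology else None,
    )
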