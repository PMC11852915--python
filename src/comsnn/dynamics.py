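"""Spiking-network dynamics: Izhikevich neurons, delayed conductance
synapses with paired excitatory/inhibitory STDP, and stochastic attacks.

Model summary
-------------
Each node is a two-variable Izhikevich neuron,

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I_ext + I_g
    du/dt = a (b v - u),        with reset v <- c, u <- u + d at v >= 30 mV,

integrated by forward Euler.  Excitatory neurons use the regular-spiking
parameter set, inhibitory neurons the low-threshold-spiking set, mixed
4:1 by stratified assignment.

Every undirected topology edge becomes two directed synapses.  A synapse
carries a conductance weight ``g`` in [0, g_max], a gating variable
``r_g`` driven by the *delayed* presynaptic potential through a logistic
nonlinearity, a reversal potential (0 mV excitatory, -70 mV inhibitory)
and a transmission delay drawn uniformly from 0.1-40 ms:

    I_syn = g r_g (E_syn - V_post)
    dr_g/dt = alpha H (1 - r_g) - beta r_g,   H = 1 / (1 + exp(-V_pre(t - tau)))

Between spikes each conductance decays exponentially (time constant
``mu_ex`` or ``mu_in``); on each pre- or postsynaptic spike the weight is
incremented by ``g_max`` times an exponential spike-timing window whose
sign depends on the pre/post order and on the synapse class (excitatory
synapses strengthen on pre-before-post, inhibitory synapses on
post-before-pre), then clamped to [0, g_max].

A stochastic attack removes a uniformly random proportion of neurons:
removed neurons stop spiking and all their synapses carry no current.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError, SimulationError
from .topology import WeightedGraph

__all__ = [
    "NeuronParams",
    "NeuronState",
    "PlasticityParams",
    "ExternalDrive",
    "SimConfig",
    "AttackSpec",
    "Network",
    "SimResult",
    "step_neuron",
    "gating_drive",
    "step_gating",
    "synaptic_current",
    "stdp_window_ex",
    "stdp_window_in",
    "apply_weight_decay",
    "apply_spike_plasticity",
    "build_network",
    "apply_attack",
    "simulate",
    "V_PEAK",
]

V_PEAK = 30.0  # mV; spike cut-off of the Izhikevich model


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich (a, b, c, d) parameter set plus cell class."""

    a: float
    b: float
    c: float
    d: float
    cell_type: str = "excitatory"

    @classmethod
    def regular_spiking(cls) -> "NeuronParams":
        """Excitatory regular-spiking cell."""
        return cls(a=0.02, b=0.20, c=-65.0, d=8.0, cell_type="excitatory")

    @classmethod
    def low_threshold_spiking(cls) -> "NeuronParams":
        """Inhibitory low-threshold-spiking cell."""
        return cls(a=0.02, b=0.25, c=-65.0, d=2.0, cell_type="inhibitory")


@dataclass
class NeuronState:
    v: float
    u: float
    last_spike_time: float | None = None


@dataclass(frozen=True)
class PlasticityParams:
    """Synapse and plasticity constants.

    Most defaults follow the standard parameter set for this synapse
    model: weight ceiling ``g_max``, STDP window amplitudes
    ``a_plus``/``a_minus`` (excitatory) and ``b_plus``/``b_minus``
    (inhibitory), window time constants ``t_plus``/``t_minus`` (ms), and
    gating rate constants ``alpha``/``beta`` per class (1/ms).

    Two parameters are deliberately network-level calibrations rather
    than literature values (see the methods note for the analysis):

    * ``mu_ex``/``mu_in`` — weight-relaxation time constants.  The 3/5 ms
      constants quoted for this model describe the postsynaptic-current
      transient, which is already carried by the gating variable; applied
      to the plastic weight they collapse every conductance within tens
      of milliseconds and leave the network inert to attack.  The
      defaults keep the 3:5 excitatory:inhibitory ratio at a timescale
      (300/500 ms) that reproduces the reported mean-synaptic-weight
      progression (sharp early decrease, then stabilization).
    * ``syn_gain`` — dimensionless conversion between the conductance
      scale of ``g_max`` and the current units of the neuron model.
      With unit gain the summed synaptic current is ~10^-2, orders below
      the O(1-10) input scale the neuron model responds to, and no
      attack has any measurable effect; the default couples the network
      at ~10% of the external drive.
    """

    mu_ex: float = 300.0
    mu_in: float = 500.0
    g_max: float = 0.015
    syn_gain: float = 40.0
    a_plus: float = 0.1
    a_minus: float = 0.105
    b_plus: float = 0.02
    b_minus: float = 0.03
    t_plus: float = 20.0
    t_minus: float = 20.0
    alpha_ex: float = 2.0
    beta_ex: float = 1.0
    alpha_in: float = 0.9
    beta_in: float = 0.1
    e_syn_ex: float = 0.0
    e_syn_in: float = -70.0
    delay_min: float = 0.1
    delay_max: float = 40.0

    def __post_init__(self) -> None:
        for name in ("mu_ex", "mu_in", "g_max", "a_plus", "a_minus", "b_plus",
                     "b_minus", "t_plus", "t_minus", "alpha_ex", "beta_ex",
                     "alpha_in", "beta_in"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 < self.delay_min <= self.delay_max:
            raise ConfigurationError("delays must satisfy 0 < delay_min <= delay_max")


@dataclass(frozen=True)
class ExternalDrive:
    """External current specification.

    ``kind`` is one of:

    * ``"constant"`` (default) — constant current per cell class.  The
      default amplitude 5 drives regular-spiking cells at ~15-20 Hz; in
      this internally-driven regime the network's response to attack is
      shaped by its recurrent topology, which is the object of study.
    * ``"noise"`` — independent per-neuron Gaussian current, standard
      deviation ``amplitude_ex`` (excitatory) / ``amplitude_in``
      (inhibitory), redrawn every ``redraw_interval_ms`` (the classic
      noisy-thalamic-input convention for Izhikevich networks).  Paired
      runs share the noise via the simulation seed.
    * ``"none"`` — no external drive.
    """

    kind: str = "constant"
    amplitude_ex: float = 5.0
    amplitude_in: float = 5.0
    redraw_interval_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in {"noise", "constant", "none"}:
            raise ConfigurationError(f"unknown drive kind {self.kind!r}")
        if self.redraw_interval_ms <= 0:
            raise ConfigurationError("redraw_interval_ms must be positive")


@dataclass(frozen=True)
class SimConfig:
    """One simulation run: duration/step, drive, recording and seeding.

    ``seed`` controls every stochastic element of the run itself (the
    noise drive).  Paired baseline/attacked runs use the same ``seed`` so
    surviving neurons receive identical external input.
    """

    duration: float = 1000.0
    dt: float = 0.1
    drive: ExternalDrive = field(default_factory=ExternalDrive)
    ei_ratio: float = 0.2
    record_v: bool = True
    record_g: bool = False
    msw_sample_interval: float = 1.0
    v_init: float = -65.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ConfigurationError("duration and dt must be positive")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("duration must be an integer multiple of dt")
        m = self.msw_sample_interval / self.dt
        if abs(m - round(m)) > 1e-9 or round(m) < 1:
            raise ConfigurationError(
                "msw_sample_interval must be a positive integer multiple of dt"
            )
        if not 0.0 <= self.ei_ratio <= 1.0:
            raise ConfigurationError("ei_ratio must be in [0, 1]")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass(frozen=True)
class AttackSpec:
    """Stochastic removal of a proportion of neurons at ``removal_time``."""

    proportion: float
    seed: int = 0
    removal_time: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ConfigurationError(
                f"attack proportion must be in [0, 1], got {self.proportion}"
            )
        if self.removal_time < 0:
            raise ConfigurationError("removal_time must be non-negative")

    def n_removed(self, n_nodes: int) -> int:
        return int(round(self.proportion * n_nodes))


# ---------------------------------------------------------------------------
# elementary operations (scalar- and array-compatible)
# ---------------------------------------------------------------------------

def step_neuron(
    v: np.ndarray | float,
    u: np.ndarray | float,
    a: np.ndarray | float,
    b: np.ndarray | float,
    c: np.ndarray | float,
    d: np.ndarray | float,
    i_total: np.ndarray | float,
    dt: float,
):
    """One forward-Euler step of the Izhikevich model with hard reset.

    A state already at or above the 30 mV cut-off is taken as being in
    the reset branch: it is reset without integration.  Otherwise v and u
    are advanced one Euler step from the current state and the reset is
    applied if the updated v reaches the cut-off.  Returns
    ``(v', u', fired)``.
    """
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    in_reset = v >= V_PEAK
    dv = 0.04 * v * v + 5.0 * v + 140.0 - u + i_total
    du = a * (b * v - u)
    v_new = np.where(in_reset, v, v + dt * dv)
    u_new = np.where(in_reset, u, u + dt * du)
    fired = v_new >= V_PEAK
    v_out = np.where(fired, c, v_new)
    u_out = np.where(fired, u_new + d, u_new)
    if v_out.ndim == 0:
        return float(v_out), float(u_out), bool(fired)
    return v_out, u_out, fired


def gating_drive(v_pre_delayed):
    """Logistic gating drive H = 1 / (1 + exp(-V_pre(t - tau)))."""
    return expit(v_pre_delayed)


def step_gating(r_g, h, alpha, beta, dt: float):
    """Euler step of dr_g/dt = alpha H (1 - r_g) - beta r_g, clamped to [0, 1]."""
    return np.clip(r_g + dt * (alpha * h * (1.0 - r_g) - beta * r_g), 0.0, 1.0)


def synaptic_current(g, r_g, e_syn, v_post):
    """I_syn = g r_g (E_syn - V_post)."""
    return g * r_g * (e_syn - v_post)


def stdp_window_ex(delta_t, params: PlasticityParams = PlasticityParams()):
    """Excitatory STDP window w(dt), dt = t_pre_spike - t_post_spike.

    Pre-before-post (dt < 0) potentiates with amplitude ``a_plus``;
    post-before-pre (dt >= 0) depresses with amplitude ``a_minus``.
    """
    delta_t = np.asarray(delta_t, dtype=float)
    out = np.where(
        delta_t < 0,
        params.a_plus * np.exp(delta_t / params.t_plus),
        -params.a_minus * np.exp(-delta_t / params.t_minus),
    )
    return float(out) if out.ndim == 0 else out


def stdp_window_in(delta_t, params: PlasticityParams = PlasticityParams()):
    """Inhibitory STDP window m(dt): sign-mirrored relative to the
    excitatory window (pre-before-post weakens, post-before-pre
    strengthens the inhibitory conductance increment)."""
    delta_t = np.asarray(delta_t, dtype=float)
    out = np.where(
        delta_t < 0,
        -params.b_plus * np.exp(delta_t / params.t_plus),
        params.b_minus * np.exp(-delta_t / params.t_minus),
    )
    return float(out) if out.ndim == 0 else out


def apply_weight_decay(g, mu, dt: float):
    """Exact per-step solution of mu dg/dt = -g:  g <- g exp(-dt/mu)."""
    return g * np.exp(-dt / mu)


def apply_spike_plasticity(
    g,
    delta_t,
    is_es,
    params: PlasticityParams = PlasticityParams(),
):
    """Weight increment on a spike event, clamped to [0, g_max].

    ``delta_t`` is t_pre_spike - t_post_spike against the partner's most
    recent spike; callers must skip synapses whose partner never spiked.
    """
    w = np.where(
        is_es, stdp_window_ex(delta_t, params), stdp_window_in(delta_t, params)
    )
    return np.clip(g + w * params.g_max, 0.0, params.g_max)


# ---------------------------------------------------------------------------
# network assembly, attack, simulation
# ---------------------------------------------------------------------------

@dataclass
class Network:
    """Directed synaptic network ready for simulation.

    Neuron arrays have length ``n``; synapse arrays length ``n_synapses``
    (two directed synapses per undirected topology edge).  ``removed``
    holds ids silenced by an attack from ``removal_time`` onward.
    """

    n: int
    is_inhibitory: np.ndarray      # (n,) bool
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    pre: np.ndarray                # (S,) int
    post: np.ndarray               # (S,) int
    delay_ms: np.ndarray           # (S,) float
    is_es: np.ndarray              # (S,) bool; class of the presynaptic cell
    g_init: np.ndarray             # (S,) float
    plasticity: PlasticityParams
    graph: WeightedGraph | None = None
    removed: frozenset = frozenset()
    removal_time: float = 0.0
    attack: AttackSpec | None = None

    @property
    def n_synapses(self) -> int:
        return self.pre.size

    @property
    def alive_ids(self) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        mask[list(self.removed)] = False
        return np.flatnonzero(mask)

    def synapse_alive_mask(self) -> np.ndarray:
        dead = np.zeros(self.n, dtype=bool)
        dead[list(self.removed)] = True
        return ~(dead[self.pre] | dead[self.post])


def build_network(
    graph: WeightedGraph,
    sim_config: SimConfig,
    plasticity: PlasticityParams | None = None,
    seed: int = 0,
) -> Network:
    """Assemble the directed synaptic network from an undirected topology.

    A stratified random ``round(ei_ratio * n)`` of the nodes are made
    inhibitory (low-threshold spiking), the rest excitatory (regular
    spiking).  Each undirected edge yields two directed synapses with
    independent uniform delays; synapse class, reversal potential and
    gating rates follow the presynaptic cell.  All conductances start at
    ``g_max`` (saturated initialization).
    """
    if plasticity is None:
        plasticity = PlasticityParams()
    if not graph.is_connected():
        raise ConfigurationError(
            "build_network requires a connected topology; take the largest "
            "component or regenerate"
        )
    rng = np.random.default_rng(seed)
    n = graph.n_nodes
    n_inh = int(round(sim_config.ei_ratio * n))
    is_inh = np.zeros(n, dtype=bool)
    is_inh[rng.choice(n, size=n_inh, replace=False)] = True

    rs = NeuronParams.regular_spiking()
    lts = NeuronParams.low_threshold_spiking()
    a = np.where(is_inh, lts.a, rs.a)
    b = np.where(is_inh, lts.b, rs.b)
    c = np.where(is_inh, lts.c, rs.c)
    d = np.where(is_inh, lts.d, rs.d)

    edges = graph.edge_array()
    u = edges[:, 0].astype(int)
    v = edges[:, 1].astype(int)
    pre = np.concatenate([u, v])
    post = np.concatenate([v, u])
    n_syn = pre.size
    delay = rng.uniform(plasticity.delay_min, plasticity.delay_max, size=n_syn)
    is_es = ~is_inh[pre]
    g0 = np.full(n_syn, plasticity.g_max)

    return Network(
        n=n, is_inhibitory=is_inh, a=a, b=b, c=c, d=d,
        pre=pre, post=post, delay_ms=delay, is_es=is_es, g_init=g0,
        plasticity=plasticity, graph=graph,
    )


def apply_attack(
    network: Network, attack: AttackSpec, allow_extreme: bool = False
) -> Network:
    """Return a copy of the network with a random neuron subset removed.

    ``round(P n)`` ids are drawn uniformly without replacement from
    ``attack.seed``.  Proportions above 0.5 are outside the studied attack
    grid and require ``allow_extreme=True``.
    """
    if attack.proportion > 0.5 and not allow_extreme:
        raise ConfigurationError(
            "attack proportion > 0.5 is outside the studied range; "
            "pass allow_extreme=True to force it"
        )
    k = attack.n_removed(network.n)
    rng = np.random.default_rng(attack.seed)
    removed = frozenset(int(i) for i in rng.choice(network.n, size=k, replace=False))
    return replace(
        network, removed=removed, removal_time=attack.removal_time, attack=attack
    )


@dataclass
class SimResult:
    """Output of one simulation run."""

    spike_times: list            # per neuron, np.ndarray of ms
    v_traces: np.ndarray | None  # (n_steps, n) float32, None unless record_v
    msw_times: np.ndarray        # (n_samples,) ms
    msw_values: np.ndarray       # (n_samples,) mean live-synapse weight
    g_snapshots: np.ndarray | None  # (n_samples, S) float32, None unless record_g
    final_g: np.ndarray
    removed: frozenset
    config: SimConfig
    network: Network

    @property
    def times(self) -> np.ndarray:
        """Time grid of the membrane traces (ms)."""
        return (np.arange(self.config.n_steps) + 1) * self.config.dt

    def spike_counts(self, t_start: float, t_end: float) -> np.ndarray:
        """Per-neuron spike count in the half-open window [t_start, t_end)."""
        return np.array(
            [np.count_nonzero((s >= t_start) & (s < t_end)) for s in self.spike_times]
        )


def simulate(
    network: Network,
    sim_config: SimConfig,
    i_ext_override: np.ndarray | None = None,
) -> SimResult:
    """Run the fixed-step simulation loop.

    Per step: (1) read delayed presynaptic potentials from the membrane
    history; (2) update gating variables and synaptic currents; (3) Euler
    step of all alive neurons under external plus synaptic current;
    (4) on spikes, apply the STDP increments to all incident live
    synapses against the partner's most recent spike; (5) apply the
    exponential weight decay; (6) sample the mean synaptic weight on the
    configured grid.  Identical network, config and seeds reproduce the
    result bit for bit.

    ``i_ext_override`` (n_steps, n) replaces the configured drive with an
    arbitrary current matrix; intended for controlled experiments.
    """
    p = network.plasticity
    dt = sim_config.dt
    n_steps = sim_config.n_steps
    n = network.n
    n_syn = network.n_synapses

    if n_syn and dt > network.delay_ms.min() + 1e-12:
        raise ConfigurationError(
            f"dt={dt} exceeds the minimum synaptic delay "
            f"{network.delay_ms.min():.3g} ms"
        )

    pre, post = network.pre, network.post
    delay_steps = np.maximum(1, np.rint(network.delay_ms / dt).astype(np.int64))
    max_d = int(delay_steps.max()) if n_syn else 1

    # CSR-style incidence lists for spike-triggered plasticity
    order_e = np.argsort(pre, kind="stable")
    eff_idx = order_e
    eff_ptr = np.searchsorted(pre[order_e], np.arange(n + 1))
    order_a = np.argsort(post, kind="stable")
    aff_idx = order_a
    aff_ptr = np.searchsorted(post[order_a], np.arange(n + 1))

    alpha = np.where(network.is_es, p.alpha_ex, p.alpha_in)
    beta = np.where(network.is_es, p.beta_ex, p.beta_in)
    e_syn = np.where(network.is_es, p.e_syn_ex, p.e_syn_in)
    decay = np.exp(-dt / np.where(network.is_es, p.mu_ex, p.mu_in))
    is_es = network.is_es

    removal_step = int(round(network.removal_time / dt))
    dead_nodes = np.zeros(n, dtype=bool)
    if network.removed:
        dead_nodes[list(network.removed)] = True
    syn_dead = ~network.synapse_alive_mask()

    # state
    v = np.full(n, sim_config.v_init, dtype=float)
    u = network.b * v
    g = network.g_init.astype(float).copy()
    r_g = np.zeros(n_syn)
    last_spike = np.full(n, -np.inf)

    v_hist = np.full((max_d + n_steps, n), sim_config.v_init, dtype=float)
    record_v = sim_config.record_v
    traces = np.empty((n_steps, n), dtype=np.float32) if record_v else None

    drive = sim_config.drive
    rng = np.random.default_rng(sim_config.seed)
    amp = np.where(network.is_inhibitory, drive.amplitude_in, drive.amplitude_ex)
    redraw_steps = max(1, int(round(drive.redraw_interval_ms / dt)))
    i_ext = np.zeros(n)
    if drive.kind == "constant":
        i_ext = amp.astype(float).copy()

    msw_steps = int(round(sim_config.msw_sample_interval / dt))
    n_samples = n_steps // msw_steps
    msw_t = np.empty(n_samples)
    msw_v = np.empty(n_samples)
    g_snap = (
        np.empty((n_samples, n_syn), dtype=np.float32) if sim_config.record_g else None
    )
    sample_i = 0

    spike_steps: list[np.ndarray] = []
    spike_ids: list[np.ndarray] = []

    node_alive = ~dead_nodes if removal_step <= 0 else np.ones(n, dtype=bool)
    syn_live = ~syn_dead if removal_step <= 0 else np.ones(n_syn, dtype=bool)
    g_max = p.g_max

    for t in range(n_steps):
        if t == removal_step and removal_step > 0:
            node_alive = ~dead_nodes
            syn_live = ~syn_dead
        t_ms = (t + 1) * dt
        row = max_d + t

        # (1)-(2) delayed gating drive, gating update, synaptic currents
        if n_syn:
            v_del = v_hist[row - delay_steps, pre]
            h = gating_drive(v_del)
            r_g = step_gating(r_g, h, alpha, beta, dt)
            i_per = synaptic_current(g, r_g, e_syn, v[post])
            i_per[~syn_live] = 0.0
            i_g = p.syn_gain * np.bincount(post, weights=i_per, minlength=n)
        else:
            i_g = np.zeros(n)

        # (3) external drive + neuron update
        if i_ext_override is not None:
            i_ext = i_ext_override[t]
        elif drive.kind == "noise":
            if t % redraw_steps == 0:
                i_ext = amp * rng.standard_normal(n)
        v_new, u_new, fired = step_neuron(
            v, u, network.a, network.b, network.c, network.d, i_ext + i_g, dt
        )
        fired &= node_alive
        # frozen (removed) neurons hold their pre-removal state; the reset
        # for fired neurons is applied inside step_neuron, the trace keeps
        # the 30 mV spike peak
        v_trace = np.where(fired, V_PEAK, np.where(node_alive, v_new, v))
        v = np.where(node_alive, v_new, v)
        u = np.where(node_alive, u_new, u)
        v_hist[row] = v_trace
        if record_v:
            traces[t] = v_trace

        # (4) spike bookkeeping + STDP
        idx = np.flatnonzero(fired)
        if idx.size:
            spike_steps.append(np.full(idx.size, t_ms))
            spike_ids.append(idx.copy())
            sids_e = (
                np.concatenate([eff_idx[eff_ptr[i]:eff_ptr[i + 1]] for i in idx])
                if idx.size
                else np.empty(0, dtype=int)
            )
            if sids_e.size:
                partner = last_spike[post[sids_e]]
                ok = np.isfinite(partner) & syn_live[sids_e]
                s = sids_e[ok]
                if s.size:
                    g[s] = apply_spike_plasticity(
                        g[s], t_ms - partner[ok], is_es[s], p
                    )
            sids_a = np.concatenate([aff_idx[aff_ptr[i]:aff_ptr[i + 1]] for i in idx])
            if sids_a.size:
                partner = last_spike[pre[sids_a]]
                ok = np.isfinite(partner) & syn_live[sids_a]
                s = sids_a[ok]
                if s.size:
                    g[s] = apply_spike_plasticity(
                        g[s], partner[ok] - t_ms, is_es[s], p
                    )
            last_spike[idx] = t_ms

        # (5) weight decay
        g *= decay

        # (6) mean-synaptic-weight sampling
        if (t + 1) % msw_steps == 0:
            msw_t[sample_i] = t_ms
            live = g[syn_live]
            msw_v[sample_i] = live.mean() if live.size else np.nan
            if g_snap is not None:
                g_snap[sample_i] = g
            sample_i += 1

        if t % 200 == 0 and (not np.all(np.isfinite(v)) or np.abs(v).max() > 1e3):
            bad = int(np.argmax(~np.isfinite(v) | (np.abs(v) > 1e3)))
            raise SimulationError(
                f"membrane potential diverged at t={t_ms:.1f} ms (neuron {bad})"
            )

    if spike_ids:
        all_t = np.concatenate(spike_steps)
        all_i = np.concatenate(spike_ids)
        order = np.lexsort((all_t, all_i))
        all_t, all_i = all_t[order], all_i[order]
        bounds = np.searchsorted(all_i, np.arange(n + 1))
        spike_times = [all_t[bounds[i]:bounds[i + 1]] for i in range(n)]
    else:
        spike_times = [np.empty(0) for _ in range(n)]

    return SimResult(
        spike_times=spike_times,
        v_traces=traces,
        msw_times=msw_t,
        msw_values=msw_v,
        g_snapshots=g_snap,
        final_g=g,
        removed=network.removed,
        config=sim_config,
        network=network,
    )
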