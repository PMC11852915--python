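# comsnn

Spiking neural networks on complex topologies, and how much damage they
absorb. `comsnn` builds networks whose wiring combines scale-free and
small-world structure (the regime reported for functional brain
networks), runs them as Izhikevich spiking networks with plastic,
delayed conductance synapses, removes random subsets of neurons to
emulate stochastic attacks, and measures how far the surviving dynamics
drift from an unharmed twin run. It is written for computational
neuroscientists and complex-networks researchers studying the injury
resistance of brain-inspired models.

## The model

**Topology.** A weighted growth process in the
Barrat–Barthelemy–Vespignani family: new nodes attach by
strength-preferential selection, each new edge reinforces the target's
existing weights (increment δ), and a *reattachment factor* p_n
re-assigns each extra edge to a uniformly random node, otherwise it
closes a weighted triad around the anchor. Sweeping p_n trades the
degree-distribution exponent γ against the small-world index
σ = (C/C_rand)/(L/L_rand); at p_n = 0.3 the 500-node ensemble sits at
γ ≈ 2.3, σ ≈ 1.9 — both scale-free and small-world. Barabási–Albert and
Watts–Strogatz generators provide matched comparison topologies.

**Dynamics.** Each node is an Izhikevich neuron,

    dv/dt = 0.04 v² + 5v + 140 − u + I_ext + I_g
    du/dt = a (b v − u),    with reset v ← c, u ← u + d at v ≥ 30 mV,

80% regular-spiking (excitatory), 20% low-threshold-spiking
(inhibitory). Every undirected edge becomes two directed synapses with
independent transmission delays τ ~ U(0.1, 40) ms, conductance current
I_syn = g·r_g·(E_syn − V_post), logistic gating r_g driven by the
delayed presynaptic potential, and paired spike-timing-dependent
plasticity: exponential windows w(Δt), m(Δt) increment the weight on
every pre- and postsynaptic spike (excitatory synapses strengthen on
pre-before-post, inhibitory on the reverse), weights decay between
spikes and are clamped to [0, g_max].

**Injury resistance.** A stochastic attack removes a proportion P of
neurons at t = 0. Against a baseline run sharing every seed, two metrics
are computed over survivors: δ, the mean relative firing-rate change
|f_b − f_a|/f_a (percent; lower = more resistant), and ρ, the mean
uncentered correlation of membrane-potential traces (higher = more
resistant). Mechanism analyses track the mean synaptic weight and the
Barrat weighted clustering coefficient / weighted shortest path length
of the live network over time.

## Worked example

```python
from comsnn.topology import TopologyConfig, generate, estimate_gamma, estimate_sigma
from comsnn.dynamics import SimConfig, AttackSpec, build_network, apply_attack, simulate
from comsnn.metrics import PairedRuns, delta_metric, rho_metric

graph = generate(TopologyConfig("bbv", n_nodes=500, pn=0.3, seed=1))
print(f"edges={graph.n_edges}  gamma={estimate_gamma(graph):.2f}  "
      f"sigma={estimate_sigma(graph, n_reference=10, seed=2):.2f}")

cfg = SimConfig(duration=1000.0, seed=7)          # 1 s at dt = 0.1 ms
net = build_network(graph, cfg, seed=3)
baseline = simulate(net, cfg)
attacked = simulate(apply_attack(net, AttackSpec(proportion=0.25, seed=11)), cfg)

pair = PairedRuns(baseline, attacked)
print(f"delta={delta_metric(pair):.2f}%  rho={rho_metric(pair):.4f}")
```

prints

```
edges=1494  gamma=2.27  sigma=1.85
delta=6.05%  rho=0.9817
```

The 500-node graph lands near the calibration point (γ ≈ 2.3,
σ ≈ 1.9). Removing 25% of the neurons changes the surviving neurons'
firing rates by ≈6% on average, while their membrane traces stay highly
correlated with the unharmed twin (ρ ≈ 0.98) — the network absorbs the
attack rather than reorganizing wholesale.

The same study runs from a shell:

```
comsnn generate --algorithm bbv --n 500 --seed 42 --out topo.csv
comsnn simulate --topology topo.csv --attack-p 0.25 --out rundir/
comsnn sweep --n 200 --replicates 10 --out sweep/     # 3 topologies x P grid
```

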