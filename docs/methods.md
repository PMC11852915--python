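# Methods

`comsnn` simulates spiking neural networks whose wiring is drawn from
three complex-network families, subjects them to stochastic node-removal
attacks, and quantifies injury resistance. This note records the models,
the parameters that matter, the choices made where the underlying study
design was open, and what the package's synthetic experiments do and do
not demonstrate.

## Topology generation

Three undirected substrates, matched in mean degree (~6 at the default
`me=3` / `K=6`):

* **Complex topology** (`bbv`): a weighted growth model in the
  Barrat–Barthelemy–Vespignani family. Each new node adds `me` edges.
  The first edge (the *anchor*) attaches with probability proportional
  to node strength. Each further edge is, with the reattachment factor
  `pn`, re-assigned to a uniformly random node; otherwise it closes a
  weighted triad around the anchor with probability `p_triad` (choosing
  an anchor neighbor proportionally to the connecting edge weight), else
  attaches strength-preferentially. Every new edge triggers the BBV
  local rearrangement: an extra `delta_bbv` of weight is distributed
  over the target's existing edges in proportion to their current
  weights. Raising `pn` lightens the degree tail monotonically; the
  triad component gives real clustering, so the small-world index passes
  through an interior maximum — the combination that motivates the
  intermediate default `pn=0.3`.
* **Scale-free comparison** (`ba`): Barabási–Albert growth from a
  complete `m0`-clique, unit weights.
* **Small-world comparison** (`ws`): Watts–Strogatz ring rewiring, unit
  weights; disconnected draws are retried with a derived seed.

**Degree-distribution exponent γ.** The default estimator is the
least-squares slope of the log-log complementary cumulative degree
distribution above `k_min = me`; this is the regression-style fit whose
values the applied complex-networks literature reports for graphs of
this kind. The discrete maximum-likelihood (Hill) estimator is available
as `method="mle"` and is the statistically efficient choice on genuine
power-law samples, but on growth-model degree sequences it is bounded
below by `1 + 1/ln(k̄/k_min)` (Jensen's inequality applied to the
likelihood), ≈2.6 at mean degree 6 — it cannot produce exponents near 2
for these graphs regardless of their tail, which is why it is not the
default.

**Small-world index σ** = (C/C_rand)/(L/L_rand), with mean local
clustering C and characteristic path length L, normalized by means over
degree-preserving double-edge-swap references (20 by default).
Swap-saturated graphs (e.g. complete graphs) are their own
randomization. σ is only defined on connected graphs; fragmented inputs
must be reduced to their largest component explicitly by the caller.

**Calibration.** With `m0=4, me=3, delta_bbv=4, p_triad=0.7` at
`n=500`, the ensemble means at `pn=0.3` are γ ≈ 2.28 and σ ≈ 1.90, γ is
rank-monotone in `pn` across 0.1–0.9 (Spearman 1.0), and σ peaks at an
interior `pn`. The WS comparison reaches σ ≈ 2.0 at `K=6,
p_rewire=0.74`. The BA comparison cannot be tuned to γ ≈ 2.12 (its
exponent is pinned near 3; the CCDF fit reads ≈2.8 at n=500);
`calibrate_to_target` reports such misses as `CalibrationError` with the
best grid point found.

## Network dynamics

Nodes are Izhikevich neurons integrated by forward Euler at `dt=0.1` ms:
regular-spiking excitatory cells and low-threshold-spiking inhibitory
cells, assigned 4:1 by stratified sampling (the inhibitory count is
exact, not binomial). Initial state v = −65 mV, u = b·v. A membrane
trace records the 30 mV spike peak at threshold crossings; the reset is
applied within the same step, so v ≤ 30 after every completed step.

Each undirected edge becomes two directed synapses with independent
delays uniform on 0.1–40 ms (quantized to the step grid, minimum one
step). A synapse carries a conductance weight g ∈ [0, g_max], a gating
variable r_g driven by the logistic of the *delayed* presynaptic
potential (rate constants α, β per class), a reversal potential (0 mV
excitatory, −70 mV inhibitory), and the paired STDP rule: on each pre-
or postsynaptic spike the weight is incremented by g_max times the
exponential window of Δt = t_pre − t_post against the partner's most
recent spike (no update if the partner never spiked; simultaneous
spikes use the Δt ≥ 0 branch), then clamped to [0, g_max]. Between
spikes the weight relaxes exponentially. Weights start saturated at
g_max, consistent with the sharply decreasing early mean-synaptic-weight
trajectory this initialization produces.

### Deliberate departures from the literature constants

Two parameters could not be used as quoted because they leave the
network with no functional coupling at all; both were re-derived once
from the network's operating requirements and then frozen (see the
parameter table in `PlasticityParams`):

* **Weight-relaxation constants** `mu_ex`/`mu_in` = 300/500 ms rather
  than 3/5 ms. The 3/5 ms values describe the postsynaptic-current
  transient, which in this model is already carried by the gating
  variable (ES gating decays in ~1 ms, IS in ~10 ms); applied to the
  plastic weight they drive every conductance to ~10⁻⁵·g_max within
  50 ms, after which removing even half the network changes nothing
  measurable (δ ≡ 0). The defaults preserve the 3:5 class ratio at a
  timescale that still produces the characteristic mean-weight
  trajectory: a sharp decrease over the first ~100 ms followed by
  stabilization near 0.1–0.2 g_max.
* **Synaptic gain** `syn_gain=40`: a dimensionless conversion between
  the conductance scale (g_max = 0.015) and the current units of the
  Izhikevich model. Without it the summed synaptic current is bounded by
  ~0.04 while the neuron responds to O(1–10) currents; the default
  couples the network at roughly 10% of the external drive. The gain
  multiplies the summed current at network level; the single-synapse
  current expression g·r_g·(E_syn − V_post) is unchanged.

### External drive

The drive is the model's main free parameter. The default is a constant
current of amplitude 5 to both classes, which puts regular-spiking cells
at ~15–20 Hz and makes the network *internally driven*: its response to
an attack is shaped by the recurrent topology rather than pinned to a
shared noise signal. This choice matters: under the noisy-thalamic-input
convention (per-neuron Gaussian drive), paired runs are so strongly
pinned to the shared noise that topology has no measurable effect on
either injury metric, and only in the internally-driven regime does the
robustness ordering between the three topologies emerge. Gaussian noise
(`kind="noise"`, redrawn each 1 ms, seed-reproducible) and zero drive
remain configuration options, and arbitrary per-step current matrices
can be injected for controlled experiments.

## Attacks and injury metrics

An attack removes `round(P·N)` uniformly random neurons at t=0 (the
removal time is configurable): they emit no spikes and their synapses
carry no current. The paired baseline shares the topology, the E/I
assignment, the delays and the drive seed, and differs only in the
removal, so paired differences isolate the injury.

* **δ** (percent): mean over surviving neurons of |f_b − f_a| / f_a,
  with firing rates counted in a half-open window. Silent-baseline
  neurons are excluded (logged). A signed variant (no absolute value) is
  available; it lets systematic rate increases and decreases cancel and
  is not the default because only the absolute form is a monotone
  injury measure.
* **ρ**: mean over surviving neurons of the *uncentered* correlation
  (cosine similarity) of the paired membrane traces over [t1, t2]
  (defaults 1–1000 ms). Because traces sit near −65 mV, ρ has a high
  floor (~0.9 even for fully decorrelated fluctuations); it is sensitive
  mainly to spike-timing misalignment.
* **Mean synaptic weight (MSW)**: mean conductance over synapses with
  both endpoints alive, sampled on a configurable grid.
* **Weighted clustering C̃w** (Barrat) and **weighted shortest path
  L̃w** (edge length 1/weight) of the live-network snapshot: the
  undirected snapshot weight between two alive nodes is the mean of the
  two directed conductances; L̃w averages ordered pairs within the
  largest connected component (excluded pairs are logged). Both agree
  with brute-force oracles (ordered-pair triangle enumeration;
  Floyd–Warshall) to 1e−12 on small graphs.

Time-resolved versions use sliding windows (default 50 ms windows,
10 ms stride, chosen to resolve the sub-200 ms post-attack transient);
graph metrics are evaluated on the conductance snapshot nearest each
window center (requires `record_g=True`). The trajectory-correlation
analysis uses the centered Pearson coefficient with a two-sided t-test
(t = r·√(n−2)/√(1−r²)), distinct from the uncentered ρ.

## Experiment layer and reproducibility

`ExperimentManifest` drives paired sweeps over topology × attack
proportion × replicate. Every seed derives deterministically from
`master_seed` via `SeedSequence([master, topology_index, replicate,
role])`, so re-running a manifest reproduces every output byte for byte.
Each replicate draws a fresh topology (published ensemble values are
treated as seed averages); ten replicates per cell is the default.
Failed runs are logged and skipped; a sweep aborts if more than 10%
fail.

## Problem sizes

Full-scale experiments use N=500 networks simulated for 1000 ms; the
ordering and mechanism analyses also run at the desk scale N=200 with
5–10 replicates, and the unit-test fixtures use 20–100 nodes. These
sizes keep a complete paired sweep in minutes on one core while leaving
the ensemble means stable to within the tolerances quoted above.

## What the model reproduces, and what it does not

Reproduced under the default study conditions:

* topology calibration (γ ≈ 2.28, σ ≈ 1.90 at `pn=0.3`; monotone γ;
  interior σ peak);
* the robustness ordering at N=500 — δ(complex) < δ(scale-free) <
  δ(small-world) and ρ(complex) highest — and δ/ρ magnitudes at heavy
  attack (δ ≈ 5% and ρ ≈ 0.98 at P=50%);
* monotone growth of δ and decay of ρ with attack proportion;
* the mean-weight trajectory shape (sharp decrease, then
  stabilization), and the live-network graph-metric ordering under
  attack (highest C̃w, lowest L̃w for the complex topology).

Not reproduced, with the diagnosis:

* **δ at small P.** Published values imply a ~20:1 ratio between P=50%
  and P=5%; this model's chaotic decorrelation floor keeps δ(5%) near
  2–3% whenever δ(50%) is in range. No scanned combination of drive
  kind/amplitude, gain and relaxation time produced both ends at once:
  regimes quiet enough for δ(5%) < 0.4% are noise-pinned and lose the
  topology ordering entirely.
* **Recovery signatures.** The published positive correlation between
  the MSW trajectory and the δ series (and negative with ρ) describes
  *post-attack recovery*: windowed injury shrinking as the weights
  relax. Here the attacked and baseline trajectories diverge and stay
  diverged — windowed δ rises and saturates — so these correlations come
  out near zero or with the opposite sign. Re-convergence of paired
  traces would require either strong shared noise (which erases the
  topology ordering) or late re-strengthening of the coupling (which
  contradicts the decaying mean weight); within this model family the
  two published findings pull in opposite directions.
* At the reduced scale N=200 the topology separation shrinks to the
  replicate noise level, so the strict δ/ρ ordering chains can fail
  there even though they hold at N=500.

The synthetic experiments show the behavior of *this* model under
*these* conditions; they do not establish how a biological network, or a
network with a measured connectome and physiological drive, would
respond to lesioning.
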