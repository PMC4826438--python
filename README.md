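# antimemory

A spiking recurrent-network simulator for studying how associative
memories can be stored in **balanced excitatory–inhibitory ensembles**,
silenced by inhibitory synaptic plasticity, and selectively re-exposed by
a global reduction of inhibitory efficacy (the network-level analogue of a
tDCS-induced drop in cortical GABA).

It is written for computational neuroscientists who want a small, fully
deterministic, testable model of the *antimemory* idea: when learning
strengthens excitatory connections between cell assemblies, inhibitory
spike-timing plasticity builds a matching inhibitory replica that cancels
the new excitation. The memory persists in the weights but its expression
is suppressed — until inhibition is turned down.

## Model

Conductance-based leaky integrate-and-fire neurons (2000 excitatory + 500
inhibitory by default, Erdős–Rényi connectivity at p = 0.02):

    τ_m dV/dt = (V_rest − V) + g_e (E_e − V) + g_i (E_i − V),
    τ_e dg_e/dt = −g_e,   τ_i dg_i/dt = −g_i,

with V_rest = −60 mV, V_thresh = −50 mV, refractory 5 ms, E_e = 0 mV,
E_i = −80 mV, and an independent Poisson background drive per neuron.
A spike at a synapse with weight w increments the target conductance by
w (inhibitory synapses by `w × global_inhibition_scale`).

I→E synapses obey the set-point-seeking inhibitory plasticity rule: every
neuron keeps a low-pass spike trace x (τ_STDP = 20 ms) and

    presynaptic spike:   w ← w + η (x_post − α),    α = 2 ρ₀ τ_STDP
    postsynaptic spike:  w ← w + η x_pre,

whose expected drift η r_pre (2 r_post τ_STDP − α) vanishes exactly at the
target rate ρ₀ = 5 Hz. Inhibition therefore grows wherever excitation is
in surplus — including onto assemblies that just learned an association —
and the network re-balances at 5 Hz with the memory rendered dormant.

The staged protocol mirrors the reference timeline (80 min compressed
10× with η raised accordingly): embed four 100-neuron assemblies
(t = 7 min), strengthen "associative" E→E connections between the
red–green and blue–yellow pairs (t = 23.5 min), rebalance, then reduce
the efficacy of *all* inhibitory synapses by 15 % (t = 74 min).
Assemblies are probed by transiently disinhibiting their members and
asking whether the associated partner's rate exceeds background by three
standard deviations (the coactivation index).

## Worked example

`python examples/02_staged_protocol.py` balances the default network and
runs the full staged timeline (about 90 s of wall time). It prints:

```
snapshot probes (stimulating red, 5 trials each):
tag  stim(Hz)  associate(Hz)  background(Hz)  index  coactivated
  A      59.4           5.14            8.09   -5.9  False
  B      79.9          22.31            9.95   24.7  True
  C      29.8           7.75            6.29    2.9  False
  D      48.6          12.41            6.20   12.4  True

verdict sequence (A, B, C, D): (False, True, False, True)
```

Reading the rows: at **A** the balanced assemblies are independent —
driving red to ~60 Hz leaves green at background. Right after the
association is imposed (**B**) the same stimulus coactivates green at
22 Hz. After inhibitory plasticity builds the replica (**C**) the
association is dormant (index 2.9, below the threshold of 3). After the
global 15 % reduction of inhibitory efficacy and re-stabilization (**D**)
the same probe again coactivates green (12.4 Hz, index 12.4) while the
unstimulated background changes only moderately (6.3 → 6.2 Hz here).

Other examples: `01_balanced_network.py` (set-point convergence),
`03_reduction_scan.py` (verdicts across 0–40 % reductions),
`04_latching_control.py` (homeostatic-scaling control producing
spontaneous serial assembly activation), `05_oracle_checks.py`
(closed-form and reference-integrator checks).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds the scaled default network from scratch, converges the
inhibitory plasticity rule, and reports the mean excitatory-population
firing rate of the naive network (`t1`) and of the network after the four
assemblies are embedded and rebalanced (`t2`), each over a 10 s window
(runtime ≈ 30 s). See `docs/methods.md` for the model's assumptions,
parameter provenance, numerical choices, and known desk-scale limitations.
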