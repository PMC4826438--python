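"""The homeostatic-scaling control: latching instead of stable dormancy.

Stabilizes a recurrence-dominated variant of the network with
multiplicative scaling of excitatory synapses (no inhibitory plasticity),
embeds the four assemblies, and records a stimulus-free epoch. Without
inhibitory replicas, assemblies ignite spontaneously and serially — the
latching failure mode. Runtime: ~40 s.
"""

import antimemory as am

cfg = am.load_config(overrides=am.latching_control_overrides())
state, assemblies, assoc, _, _, scaling = am.setup_from_config(cfg, seed=1)

print("stabilizing with homeostatic scaling (no inhibitory plasticity) ...")
am.integrate_interval(state, 120_000.0, scaling=scaling)
am.embed_assemblies(state, assemblies)
am.strengthen_associations(state, assoc, assemblies)
am.integrate_interval(state, 120_000.0, scaling=scaling)

print("recording a 150 s stimulus-free epoch ...")
_, rec = am.integrate_interval(state, 150_000.0, scaling=scaling)
groups = dict(assemblies.assemblies)
groups["background"] = assemblies.background_ids(state.n_excitatory)
timeline = am.estimate_rates(rec, 2000.0, groups)
report = am.detect_latching(timeline)

print(f"\nlatching detected: {report.latching}")
print(f"activation threshold: {report.threshold_hz:.1f} Hz")
print("spontaneous activation sequence (time s, assembly):")
for t, lab in report.activations[:10]:
    print(f"  {t:7.1f}  {lab}")
print("\nAssemblies ignite serially with no stimulus: scaling keeps mean")
print("rates in check but cannot build the assembly-specific inhibitory")
print("replicas that keep memories dormant.")
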