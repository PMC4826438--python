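"""Set-point convergence of the naive network.

Builds the default 2000E+500I sparse network and lets the inhibitory
spike-timing rule rebalance it. The printed trajectory shows the mean
excitatory rate approaching the 5 Hz set-point as the I->E weights grow
to cancel surplus excitation. Runtime: ~20 s.
"""

import antimemory as am

cfg = am.load_config()
state, _, _, sched, plast, _ = am.setup_from_config(cfg, seed=1)
boosted = am.InhibPlasticityParams(eta=sched.base_eta, target_rate_hz=5.0)

print("t (s)   mean E rate (Hz)   mean I->E weight")
for block in range(6):
    _, rec = am.integrate_interval(state, 40_000.0, plasticity=boosted)
    rate = rec.counts(state.n_total)[:state.n_excitatory].mean() / 40.0
    w = state.synapses["ie"].weights.mean()
    print(f"{(block + 1) * 40:5d}   {rate:16.2f}   {w:16.3f}")

print("\nThe rate settles near the 5 Hz set-point: the inhibitory rule's")
print("depression bias makes weight drift vanish exactly at that rate.")
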