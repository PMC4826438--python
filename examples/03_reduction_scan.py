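"""Scan of the global inhibition-reduction fraction.

Loads the rebalanced (dormant) snapshot written by 02_staged_protocol.py
(or recomputes it) and, for each reduction fraction, applies the global
downscale, lets the network re-stabilize, and probes both associated
pairs. The printed verdicts show which reductions re-expose the dormant
association and that the unstimulated background changes only moderately.
Runtime: ~2 min (plus the protocol if the snapshot is missing).
"""

from pathlib import Path

import antimemory as am

SNAP = Path("example_output/snapshot_C.h5")

cfg = am.load_config()
state, assemblies, assoc, sched, plast, _ = am.setup_from_config(cfg, seed=1)
if SNAP.exists():
    cstate = am.load_state(SNAP)
    print(f"loaded rebalanced snapshot from {SNAP}")
else:
    print("snapshot not found; running the protocol first ...")
    am.balance_network(state, plast, 240_000.0, eta=sched.base_eta)
    result = am.run_protocol(state, assemblies, assoc, sched, plast,
                             master_seed=1)
    cstate = result.snapshots["C"]

fast = am.InhibPlasticityParams(eta=sched.stages[-1].eta, target_rate_hz=5.0)
tbl = am.scan_inhibition_reduction(
    cstate, assemblies, assoc, [0.0, 0.08, 0.15, 0.25, 0.40], sched,
    plasticity=fast, rebalance_ms=cfg["schedule"]["scan_rebalance_ms"],
    master_seed=1)

print("\nfraction  pair        associate(Hz)  background(Hz)  index  verdict")
for r in tbl.itertuples():
    print(f"  {r.fraction:5.2f}   {r.stimulated}->{r.associate:7s} "
          f"{r.assoc_rate:10.2f}  {r.unstimulated_background_rate:14.2f}  "
          f"{r.coactivation_index:5.1f}  {r.verdict}")
print("\nThe 0% control stays dormant. At this desk scale the inhibitory")
print("population's rate response compensates much of the cut, so only")
print("part of the scanned range clears the coactivation threshold (see")
print("docs/methods.md for the scale analysis).")
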