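"""Naive dense-matrix reference integrator (cross-check oracle).

A deliberately simple, slow re-implementation of the same membrane,
synapse, drive and plasticity equations as the compiled kernel, written
against dense weight matrices with explicit per-step NumPy operations. It
exists purely as an independent oracle for small fixtures: the production
kernel must agree with it (total spike count within 1% on the 20-neuron
fixture; typically bit-identical). It shares only the drive-event stream
(`rng.DriveStream`) so that both integrators see the same noise
realization and the comparison isolates the integration arithmetic.
"""

from __future__ import annotations

import numpy as np

from .params import InhibPlasticityParams
from .rng import DriveStream
from .state import NetworkState, SpikeRecord


def reference_integrate(state: NetworkState, duration_ms: float,
                        step_ms: float = 0.1,
                        plasticity: InhibPlasticityParams | None = None,
                        ) -> tuple[NetworkState, SpikeRecord]:
    """Advance ``state`` by ``duration_ms`` with the naive integrator.

    Mutates ``state`` in place (including the drive RNG counter) and
    returns the emitted spikes, exactly like `network.integrate_interval`.
    Intended for networks of tens of neurons; cost grows as n^2 per step.
    """
    p, s = state.params, state.spec
    n_e, n_i = s.n_excitatory, s.n_inhibitory
    n = n_e + n_i
    plast_on = plasticity is not None and plasticity.enabled and plasticity.eta > 0

    # dense (n, n) weight matrix in global indexing, split by sign
    w_exc = np.zeros((n, n))
    w_inh = np.zeros((n, n))
    w_exc[:n_e, :n_e] = state.synapses["ee"].dense()
    w_exc[:n_e, n_e:] = state.synapses["ei"].dense()
    w_ie = state.synapses["ie"].dense()          # (n_i, n_e), plastic
    w_inh[n_e:, n_e:] = state.synapses["ii"].dense()

    ie_mask = w_ie > 0  # structural synapses (baseline weights are > 0)

    stream = DriveStream(state.drive_rng_state)
    lam = n * p.drive_rate_hz * step_ms * 1e-3

    decay_e = 1.0 - step_ms / p.tau_exc
    decay_i = 1.0 - step_ms / p.tau_inh
    n_steps = int(round(duration_ms / step_ms))
    times, ids = [], []
    t0 = state.t_ms

    for step in range(n_steps):
        t_now = t0 + step * step_ms
        t_spike = t_now + step_ms

        state.g_exc *= decay_e
        state.g_inh *= decay_i
        if plast_on:
            decay_tr = 1.0 - step_ms / plasticity.tau_stdp
            state.trace_e *= decay_tr
            state.trace_i *= decay_tr

        for tgt in stream.event_targets(lam, n):
            state.g_exc[tgt] += p.drive_weight

        refractory = t_now < state.refractory_until
        dv = ((p.v_rest - state.v)
              + state.g_exc * (p.e_exc - state.v)
              + state.g_inh * (p.e_inh - state.v)
              + p.drive_current_mv) * (step_ms / p.tau_m)
        v_new = state.v + dv
        v_new[refractory] = p.v_reset
        spiking = (~refractory) & (v_new >= p.v_thresh)
        v_new[spiking] = p.v_reset
        state.v = v_new
        state.refractory_until[spiking] = t_spike + p.tau_ref
        spikers = np.nonzero(spiking)[0]

        for i in spikers:
            times.append(t_spike)
            ids.append(i)
            if i < n_e:
                state.g_exc += w_exc[i]
                if plast_on:
                    w_ie[:, i] = np.where(
                        ie_mask[:, i],
                        np.clip(w_ie[:, i] + plasticity.eta * state.trace_i,
                                0.0, plasticity.weight_max),
                        w_ie[:, i])
            else:
                j = i - n_e
                if plast_on:
                    w_ie[j] = np.where(
                        ie_mask[j],
                        np.clip(w_ie[j] + plasticity.eta
                                * (state.trace_e - plasticity.alpha),
                                0.0, plasticity.weight_max),
                        w_ie[j])
                state.g_inh[:n_e] += (w_ie[j] * state.global_inhibition_scale
                                      * state.stimulus_scale)
                state.g_inh += w_inh[i] * state.global_inhibition_scale

        if plast_on:
            for i in spikers:
                if i < n_e:
                    state.trace_e[i] += 1.0
                else:
                    state.trace_i[i - n_e] += 1.0

    state.t_ms = t0 + n_steps * step_ms
    # write plastic weights back into the sparse store
    ie = state.synapses["ie"]
    for j in range(n_i):
        sl = slice(ie.indptr[j], ie.indptr[j + 1])
        ie.weights[sl] = w_ie[j, ie.targets[sl]]
    state.drive_rng_state = stream.state
    rec = SpikeRecord(np.asarray(times, dtype=float),
                      np.asarray(ids, dtype=np.int32), t0, state.t_ms)
    return state, rec
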