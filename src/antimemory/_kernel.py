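"""Compiled fixed-step integration kernel (forward Euler, single-threaded).

One step, in order: (1) decay conductances and plasticity traces; (2) draw
pooled background-drive events from the splitmix64 counter stream and add
them to excitatory conductances; (3) update membrane potentials of
non-refractory neurons and detect threshold crossings; (4) propagate this
step's spikes to postsynaptic conductances — effective inhibitory weight is
the stored weight times the global inhibition scale (times the per-target
stimulus scale for I→E) — applying the inhibitory plasticity rule at I→E
synapses when enabled; (5) increment the traces of the neurons that spiked.
Spike-driven conductance changes are seen from the next step on (no axonal
delay beyond the step itself). The update order is mirrored exactly by the
pure-Python reference integrator used as a cross-check oracle.

Status codes returned: 0 = completed, 1 = spike buffer full (caller resumes
with a fresh buffer), 2 = non-finite membrane potential.
"""

import math

import numpy as np
from numba import njit

_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_KNUTH_MAX = 30.0

STATUS_OK = 0
STATUS_BUFFER_FULL = 1
STATUS_NONFINITE = 2


@njit(cache=True, inline="always")
def _sm_next(state):
    state = state + _GAMMA
    z = state
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    return state, z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _sm_uniform(state):
    state, z = _sm_next(state)
    return state, (z >> np.uint64(11)) * 2.0 ** -53


@njit(cache=True)
def _poisson(state, lam):
    if lam <= 0.0:
        return state, 0
    if lam < _KNUTH_MAX:
        limit = math.exp(-lam)
        k = 0
        p = 1.0
        while True:
            state, u = _sm_uniform(state)
            p *= u
            if p <= limit:
                return state, k
            k += 1
    else:
        state, u1 = _sm_uniform(state)
        state, u2 = _sm_uniform(state)
        if u1 <= 0.0:
            u1 = 2.0 ** -53
        z = math.sqrt(-2.0 * math.log(u1)) * math.cos(2.0 * math.pi * u2)
        k = int(round(lam + math.sqrt(lam) * z))
        if k < 0:
            k = 0
        return state, k


@njit(cache=True)
def integrate_kernel(
        n_e, n_i, dt, n_steps, t0,
        v, g_exc, g_inh, ref_until,
        ee_indptr, ee_targets, ee_w,
        ei_indptr, ei_targets, ei_w,
        ie_indptr, ie_targets, ie_w,
        ii_indptr, ii_targets, ii_w,
        ie_csc_indptr, ie_csc_flat, ie_csc_pre,
        tau_m, v_rest, v_thresh, v_reset, tau_ref,
        e_exc, e_inh, tau_exc, tau_inh,
        drive_rate_hz, drive_weight, drive_current, rng_state_arr,
        inh_scale, stim_scale,
        plast_on, eta, alpha, tau_stdp, w_max,
        trace_e, trace_i,
        spike_times, spike_ids, neuron_counts):
    n = n_e + n_i
    decay_e = 1.0 - dt / tau_exc
    decay_i = 1.0 - dt / tau_inh
    decay_tr = 1.0 - dt / tau_stdp
    lam = n * drive_rate_hz * dt * 1e-3
    dt_over_tau = dt / tau_m
    cap = spike_times.shape[0]
    n_spikes = 0
    rng_state = rng_state_arr[0]
    spikers = np.empty(n, dtype=np.int64)

    for step in range(n_steps):
        t_now = t0 + step * dt
        t_spike = t_now + dt

        for i in range(n):
            g_exc[i] *= decay_e
            g_inh[i] *= decay_i
        if plast_on:
            for i in range(n_e):
                trace_e[i] *= decay_tr
            for i in range(n_i):
                trace_i[i] *= decay_tr

        if lam > 0.0:
            rng_state, k = _poisson(rng_state, lam)
            for _ in range(k):
                rng_state, z = _sm_next(rng_state)
                g_exc[int(z % np.uint64(n))] += drive_weight

        n_spk = 0
        for i in range(n):
            if t_now < ref_until[i]:
                v[i] = v_reset
                continue
            vi = v[i]
            dv = ((v_rest - vi) + g_exc[i] * (e_exc - vi)
                  + g_inh[i] * (e_inh - vi) + drive_current)
            vi += dv * dt_over_tau
            if not (vi > -1e6 and vi < 1e6):
                rng_state_arr[0] = rng_state
                return step, STATUS_NONFINITE, n_spikes
            if vi >= v_thresh:
                v[i] = v_reset
                ref_until[i] = t_spike + tau_ref
                spikers[n_spk] = i
                n_spk += 1
            else:
                v[i] = vi

        if n_spikes + n_spk > cap:
            rng_state_arr[0] = rng_state
            return step, STATUS_BUFFER_FULL, n_spikes

        for s in range(n_spk):
            i = spikers[s]
            spike_times[n_spikes] = t_spike
            spike_ids[n_spikes] = i
            n_spikes += 1
            neuron_counts[i] += 1

            if i < n_e:
                # excitatory spike: E->E and E->I propagation
                for p in range(ee_indptr[i], ee_indptr[i + 1]):
                    g_exc[ee_targets[p]] += ee_w[p]
                for p in range(ei_indptr[i], ei_indptr[i + 1]):
                    g_exc[n_e + ei_targets[p]] += ei_w[p]
                if plast_on:
                    # postsynaptic spike: potentiate all I->E synapses onto i
                    for p in range(ie_csc_indptr[i], ie_csc_indptr[i + 1]):
                        f = ie_csc_flat[p]
                        w = ie_w[f] + eta * trace_i[ie_csc_pre[p]]
                        if w < 0.0:
                            w = 0.0
                        elif w > w_max:
                            w = w_max
                        ie_w[f] = w
            else:
                j = i - n_e
                # inhibitory spike: plasticity first, then propagate the
                # updated weight (scaled by inhibition scale and stimulus)
                for p in range(ie_indptr[j], ie_indptr[j + 1]):
                    tgt = ie_targets[p]
                    w = ie_w[p]
                    if plast_on:
                        w += eta * (trace_e[tgt] - alpha)
                        if w < 0.0:
                            w = 0.0
                        elif w > w_max:
                            w = w_max
                        ie_w[p] = w
                    g_inh[tgt] += w * inh_scale * stim_scale[tgt]
                for p in range(ii_indptr[j], ii_indptr[j + 1]):
                    g_inh[n_e + ii_targets[p]] += ii_w[p] * inh_scale

        if plast_on:
            for s in range(n_spk):
                i = spikers[s]
                if i < n_e:
                    trace_e[i] += 1.0
                else:
                    trace_i[i - n_e] += 1.0

    rng_state_arr[0] = rng_state
    return n_steps, STATUS_OK, n_spikes
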