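"""Time integration of the recurrent network.

`integrate_interval` advances a `NetworkState` in place with the compiled
fixed-step kernel and returns the spikes emitted. Inhibitory spike-timing
plasticity runs inside the kernel when enabled; homeostatic scaling (the
control stabilization rule) is applied between kernel chunks at its
configured interval.
"""

from __future__ import annotations

import math

import numpy as np

from ._kernel import (STATUS_BUFFER_FULL, STATUS_NONFINITE, STATUS_OK,
                      integrate_kernel)
from .params import InhibPlasticityParams, ScalingParams
from .plasticity import homeostatic_scaling_update
from .state import NetworkState, SpikeRecord

DEFAULT_STEP_MS = 0.1

_FROZEN = InhibPlasticityParams(eta=0.0, enabled=False)


class NumericError(RuntimeError):
    """Integration produced a non-finite state variable."""

    def __init__(self, t_ms: float):
        super().__init__(
            f"non-finite membrane potential at simulated time {t_ms:.3f} ms")
        self.t_ms = t_ms


def _run_kernel(state: NetworkState, n_steps: int, step: float,
                plast: InhibPlasticityParams) -> SpikeRecord:
    p, s = state.params, state.spec
    syn = state.synapses
    ee, ei, ie, ii = syn["ee"], syn["ei"], syn["ie"], syn["ii"]
    n = s.n_total
    t0 = state.t_ms
    plast_on = bool(plast.enabled and plast.eta > 0.0)

    times_out, ids_out = [], []
    neuron_counts = np.zeros(n, dtype=np.int64)
    rng_arr = np.array([state.drive_rng_state], dtype=np.uint64)

    # expected-rate sized buffer; the kernel reports overflow and we resume
    exp_spikes = int(n * (n_steps * step / 1000.0) * 50.0) + 10_000
    steps_left = n_steps
    while steps_left > 0:
        cap = min(exp_spikes, 20_000_000)
        spike_times = np.empty(cap, dtype=np.float64)
        spike_ids = np.empty(cap, dtype=np.int32)
        done, status, n_spk = integrate_kernel(
            s.n_excitatory, s.n_inhibitory, step, steps_left, state.t_ms,
            state.v, state.g_exc, state.g_inh, state.refractory_until,
            ee.indptr, ee.targets, ee.weights,
            ei.indptr, ei.targets, ei.weights,
            ie.indptr, ie.targets, ie.weights,
            ii.indptr, ii.targets, ii.weights,
            ie.csc_indptr, ie.csc_flat, ie.csc_pre,
            p.tau_m, p.v_rest, p.v_thresh, p.v_reset, p.tau_ref,
            p.e_exc, p.e_inh, p.tau_exc, p.tau_inh,
            p.drive_rate_hz, p.drive_weight, p.drive_current_mv, rng_arr,
            state.global_inhibition_scale, state.stimulus_scale,
            plast_on, plast.eta, plast.alpha, plast.tau_stdp, plast.weight_max,
            state.trace_e, state.trace_i,
            spike_times, spike_ids, neuron_counts)
        times_out.append(spike_times[:n_spk].copy())
        ids_out.append(spike_ids[:n_spk].copy())
        state.t_ms += done * step
        steps_left -= done
        state.drive_rng_state = int(rng_arr[0])
        if status == STATUS_NONFINITE:
            raise NumericError(state.t_ms)
        if status == STATUS_OK:
            break
        # STATUS_BUFFER_FULL: grow and continue
        exp_spikes *= 4

    rec = SpikeRecord(
        np.concatenate(times_out) if times_out else np.empty(0),
        np.concatenate(ids_out) if ids_out else np.empty(0, np.int32),
        t0, t0 + n_steps * step)
    rec._neuron_counts = neuron_counts  # cached for rate estimation
    return rec


def integrate_interval(state: NetworkState, duration_ms: float,
                       step_ms: float = DEFAULT_STEP_MS,
                       plasticity: InhibPlasticityParams | None = None,
                       scaling: ScalingParams | None = None,
                       ) -> tuple[NetworkState, SpikeRecord]:
    """Advance the network by ``duration_ms`` and record spikes.

    ``plasticity=None`` freezes all weights; otherwise the inhibitory
    spike-timing rule runs at every step. ``scaling`` activates the
    homeostatic excitatory-scaling control rule, applied every
    ``scaling.interval_ms`` using the rates of the elapsed interval.
    The state is modified in place and also returned.
    """
    if step_ms <= 0:
        raise ValueError("step_ms must be > 0")
    if duration_ms < step_ms:
        raise ValueError("duration_ms must be at least one step")
    plast = plasticity if plasticity is not None else _FROZEN

    if scaling is None or not scaling.enabled:
        n_steps = int(round(duration_ms / step_ms))
        return state, _run_kernel(state, n_steps, step_ms, plast)

    scaling.validate()
    records = []
    remaining = duration_ms
    while remaining > step_ms * 0.5:
        chunk = min(scaling.interval_ms, remaining)
        n_steps = int(round(chunk / step_ms))
        rec = _run_kernel(state, n_steps, step_ms, plast)
        records.append(rec)
        counts_e = rec._neuron_counts[:state.n_excitatory]
        rates = counts_e / (n_steps * step_ms * 1e-3)
        homeostatic_scaling_update(state, rates, scaling)
        remaining -= chunk
    return state, SpikeRecord.concatenate(records)


def lif_rate_constant_current(params, current_mv: float) -> float:
    """Closed-form firing rate (Hz) of an isolated LIF neuron under constant
    current drive ``current_mv`` (expressed as R·I in mV), zero otherwise."""
    drive = current_mv + params.v_rest
    if drive <= params.v_thresh:
        return 0.0
    t_isi = params.tau_ref + params.tau_m * math.log(
        (drive - params.v_reset) / (drive - params.v_thresh))
    return 1000.0 / t_isi
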