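"""Plasticity rules: inhibitory spike-timing plasticity, homeostatic scaling,
and the global inhibitory-efficacy scale.

The inhibitory rule is the set-point-seeking trace rule: every neuron keeps
a low-pass spike trace x with time constant tau_stdp; at each I→E synapse a
presynaptic spike changes the weight by eta*(x_post - alpha) and a
postsynaptic spike by eta*x_pre, with alpha = 2*rho0*tau_stdp. The expected
drift at presynaptic rate r_pre and postsynaptic rate r_post is

    eta * r_pre * (2 * r_post * tau_stdp - alpha)   per second,

which vanishes exactly at r_post = rho0: inhibition grows onto neurons
firing above the set-point and weakens below it, stabilizing the
excitatory population at rho0 and building inhibitory replicas of any
surplus excitation ("antimemories").

During long integrations the same rule runs inside the compiled kernel;
`inhibitory_stdp_update` is the single-step form used by the reference
integrator and by tests that drive it with clamped spike trains.
"""

from __future__ import annotations

import numpy as np

from .params import ConfigurationError, InhibPlasticityParams, ScalingParams
from .state import NetworkState


def inhibitory_stdp_update(state: NetworkState, spikes_this_step,
                           params: InhibPlasticityParams) -> NetworkState:
    """Apply one step of the inhibitory rule given this step's spikes.

    ``spikes_this_step`` holds global neuron ids. Traces are read as they
    stand (already decayed for this step); trace increments for the spiking
    neurons are applied afterwards by the caller. Weights are clipped to
    [0, weight_max]. Only I→E synapses are plastic.
    """
    if not params.enabled or params.eta == 0.0:
        return state
    ie = state.synapses["ie"]
    n_e = state.n_excitatory
    eta, alpha, wmax = params.eta, params.alpha, params.weight_max
    for i in spikes_this_step:
        if i < n_e:
            # postsynaptic (excitatory) spike: w += eta * pre_trace
            sl = slice(ie.csc_indptr[i], ie.csc_indptr[i + 1])
            flat = ie.csc_flat[sl]
            ie.weights[flat] = np.clip(
                ie.weights[flat] + eta * state.trace_i[ie.csc_pre[sl]],
                0.0, wmax)
        else:
            # presynaptic (inhibitory) spike: w += eta * (post_trace - alpha)
            j = i - n_e
            sl = slice(ie.indptr[j], ie.indptr[j + 1])
            ie.weights[sl] = np.clip(
                ie.weights[sl] + eta * (state.trace_e[ie.targets[sl]] - alpha),
                0.0, wmax)
    return state


def expected_stdp_drift(params: InhibPlasticityParams,
                        r_pre_hz: float, r_post_hz: float) -> float:
    """Closed-form expected weight drift per second for independent Poisson
    pre/post trains (zero at ``r_post == target_rate``)."""
    tau_s = params.tau_stdp * 1e-3
    return params.eta * r_pre_hz * (2.0 * r_post_hz * tau_s - params.alpha)


def homeostatic_scaling_update(state: NetworkState, recent_rates_hz,
                               params: ScalingParams) -> NetworkState:
    """Multiplicatively scale E→E weights onto each excitatory neuron toward
    the target rate (the scaling-only control stabilization).

    The factor for a neuron with recent rate r is
    ``(target / max(r, rate_floor)) ** gain`` capped to
    ``[factor_min, factor_max]``; silent neurons therefore scale up by at
    most ``factor_max`` per update. Inhibitory weights are untouched and the
    relative proportions among a neuron's excitatory inputs are preserved.
    """
    if not params.enabled:
        return state
    rates = np.asarray(recent_rates_hz, dtype=float)
    if rates.shape != (state.n_excitatory,):
        raise ConfigurationError(
            "recent_rates_hz must have one entry per excitatory neuron")
    r = np.maximum(rates, params.rate_floor_hz)
    factors = np.clip((params.target_rate_hz / r) ** params.gain,
                      params.factor_min, params.factor_max)
    ee = state.synapses["ee"]
    # CSC order groups flat indices by postsynaptic neuron
    per_syn = np.repeat(factors, np.diff(ee.csc_indptr))
    ee.weights[ee.csc_flat] *= per_syn
    return state


def set_global_inhibition_scale(state: NetworkState,
                                reduction_fraction: float) -> NetworkState:
    """Reduce the efficacy of every inhibitory synapse by ``reduction_fraction``.

    Sets ``global_inhibition_scale = 1 - reduction_fraction``; subsequent
    dynamics use stored weight × scale for every I→E and I→I conductance.
    Stored weights are untouched, so the manipulation is exactly reversible
    (the simulator's abstraction of a tDCS-induced GABA reduction).
    """
    if not 0.0 <= reduction_fraction < 1.0:
        raise ConfigurationError(
            f"reduction_fraction must lie in [0, 1); got {reduction_fraction}")
    state.global_inhibition_scale = 1.0 - reduction_fraction
    return state
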