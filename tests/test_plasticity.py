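"""Plasticity rules: closed-form drift of the inhibitory rule under clamped
spike trains, the homeostatic scaling factor, and the global inhibition
scale's exact multiplicativity and reversibility."""

import numpy as np
import pytest

import antimemory as am


# ---------------------------------------------------------------------------
# inhibitory rule on the clamped pair

def _clamped_drift(r_pre_hz, r_post_hz, params, duration_s, rng,
                   regular_post=False):
    """Drive the single pair-clamp synapse with a Poisson presynaptic train
    and a Poisson (or perfectly regular) postsynaptic train, applying the
    rule step by step exactly as the kernel does; returns the weight change
    per second."""
    state, _ = am.make_fixture("pair-clamp")
    ie = state.synapses["ie"]
    w0 = float(ie.weights[0])
    dt = 1.0  # ms
    decay = 1.0 - dt / params.tau_stdp
    n_steps = int(duration_s * 1000 / dt)
    p_pre = r_pre_hz * dt * 1e-3
    post_period = int(round(1000.0 / r_post_hz / dt))
    p_post = r_post_hz * dt * 1e-3
    for step in range(n_steps):
        state.trace_e *= decay
        state.trace_i *= decay
        spikes = []
        if rng.random() < p_pre:
            spikes.append(1)            # global id of the inhibitory neuron
        if regular_post:
            if step % post_period == 0:
                spikes.append(0)
        elif rng.random() < p_post:
            spikes.append(0)
        am.inhibitory_stdp_update(state, spikes, params)
        for i in spikes:
            if i == 0:
                state.trace_e[0] += 1.0
            else:
                state.trace_i[0] += 1.0
    return (float(ie.weights[0]) - w0) / duration_s


@pytest.mark.parametrize("r_post_factor, sign", [
    (1.0, 0),      # at the set-point: no drift
    (2.0, +1),     # above: inhibition potentiates
    (0.5, -1),     # below: inhibition depresses
])
def test_clamped_pair_drift_matches_closed_form(r_post_factor, sign):
    params = am.InhibPlasticityParams(eta=0.01, target_rate_hz=5.0,
                                      tau_stdp=20.0, weight_max=100.0)
    r_pre, r_post = 10.0, 5.0 * r_post_factor
    rng = np.random.default_rng(123)
    reps = [_clamped_drift(r_pre, r_post, params, 5.0, rng,
                           regular_post=(r_post_factor == 1.0))
            for _ in range(20)]
    mean = np.mean(reps)
    se = np.std(reps, ddof=1) / np.sqrt(len(reps))
    expected = am.expected_stdp_drift(params, r_pre, r_post)
    if sign == 0:
        assert expected == 0.0
        assert abs(mean) < 3 * se
    else:
        assert np.sign(expected) == sign
        assert np.sign(mean) == sign
        assert abs(mean - expected) < 4 * se


def test_zero_learning_rate_freezes_weights(small_state):
    frozen = {c: s.weights.copy() for c, s in small_state.synapses.items()}
    am.integrate_interval(small_state, 2000.0,
                          plasticity=am.InhibPlasticityParams(eta=0.0))
    for c, w in frozen.items():
        assert np.array_equal(small_state.synapses[c].weights, w)


def test_weights_stay_clipped(small_state):
    params = am.InhibPlasticityParams(eta=5.0, weight_max=0.7)
    am.integrate_interval(small_state, 2000.0, plasticity=params)
    w = small_state.synapses["ie"].weights
    assert np.all(w >= 0.0) and np.all(w <= params.weight_max)


# ---------------------------------------------------------------------------
# homeostatic scaling

def test_scaling_fixed_point(small_state):
    params = am.ScalingParams()
    before = small_state.synapses["ee"].weights.copy()
    rates = np.full(small_state.n_excitatory, params.target_rate_hz)
    am.homeostatic_scaling_update(small_state, rates, params)
    assert np.array_equal(small_state.synapses["ee"].weights, before)


def test_scaling_factor_and_proportions(small_state):
    params = am.ScalingParams(gain=0.5)
    ee = small_state.synapses["ee"]
    # perturb weights so proportions are nontrivial
    rng = np.random.default_rng(0)
    ee.weights[:] = rng.uniform(0.01, 0.1, ee.nnz)
    before = ee.weights.copy()
    inh_before = small_state.synapses["ie"].weights.copy()
    rates = np.full(small_state.n_excitatory, params.target_rate_hz)
    rates[3] = 2.0 * params.target_rate_hz
    am.homeostatic_scaling_update(small_state, rates, params)
    factor = params.factor(rates[3])
    assert factor == pytest.approx(0.5 ** 0.5)
    sl = slice(ee.csc_indptr[3], ee.csc_indptr[3 + 1])
    flat = ee.csc_flat[sl]
    assert np.allclose(ee.weights[flat], before[flat] * factor)
    # all other weights untouched; inhibitory untouched
    others = np.setdiff1d(np.arange(ee.nnz), flat)
    assert np.array_equal(ee.weights[others], before[others])
    assert np.array_equal(small_state.synapses["ie"].weights, inh_before)


def test_scaling_silent_neuron_capped(small_state):
    params = am.ScalingParams(gain=1.0, factor_max=2.0)
    assert params.factor(0.0) == 2.0  # capped despite huge target/rate ratio


def test_scaling_rejects_wrong_rate_shape(small_state):
    with pytest.raises(am.ConfigurationError):
        am.homeostatic_scaling_update(small_state, np.ones(3),
                                      am.ScalingParams())


# ---------------------------------------------------------------------------
# global inhibition scale

def _spikes(state, dur=1500.0):
    _, rec = am.integrate_interval(state, dur)
    return rec


def test_scale_fraction_zero_is_identity(small_state):
    a = small_state.copy()
    b = small_state.copy()
    am.set_global_inhibition_scale(b, 0.0)
    ra, rb = _spikes(a), _spikes(b)
    assert np.array_equal(ra.times, rb.times)
    assert np.array_equal(ra.ids, rb.ids)


def test_scale_equals_prescaled_stored_weights(small_state):
    # effective conductance = stored weight x scale, for every I synapse:
    # scaling by 0.85 must reproduce a network whose stored inhibitory
    # weights are 0.85x, spike for spike
    a = small_state.copy()
    am.set_global_inhibition_scale(a, 0.15)
    b = small_state.copy()
    b.synapses["ie"].weights *= 0.85
    b.synapses["ii"].weights *= 0.85
    ra, rb = _spikes(a), _spikes(b)
    assert np.array_equal(ra.times, rb.times)
    assert np.array_equal(ra.ids, rb.ids)


def test_scale_is_reversible_and_nondestructive(small_state):
    stored = small_state.synapses["ie"].weights.copy()
    baseline = _spikes(small_state.copy())
    s = small_state.copy()
    am.set_global_inhibition_scale(s, 0.15)
    am.set_global_inhibition_scale(s, 0.0)
    assert np.array_equal(s.synapses["ie"].weights, stored)
    after = _spikes(s)
    assert np.array_equal(baseline.times, after.times)


@pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
def test_scale_rejects_out_of_range_fraction(small_state, bad):
    with pytest.raises(am.ConfigurationError):
        am.set_global_inhibition_scale(small_state, bad)
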