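"""Integration kernel: analytic single-neuron limits, the refractory bound,
drive monotonicity, determinism, and numeric-failure reporting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import antimemory as am


def _single_neuron(drive_current=0.0, v0=None):
    spec = am.NetworkSpec(n_excitatory=1, n_inhibitory=1,
                          connection_probability=0.0, seed=0)
    params = am.NeuronParams(drive_rate_hz=0.0, drive_current_mv=drive_current)
    state = am.build_network(spec, params)
    if v0 is not None:
        state.v[:] = v0
    return state, params


def test_subthreshold_relaxation_to_rest():
    state, params = _single_neuron(v0=-52.0)
    state, rec = am.integrate_interval(state, 1000.0)
    assert rec.n_events == 0
    assert state.v[0] == pytest.approx(params.v_rest, abs=1e-6)


@pytest.mark.parametrize("current_mv", [12.0, 20.0, 40.0])
def test_constant_current_rate_matches_closed_form(current_mv):
    # analytic LIF frequency-current curve, 2% tolerance at dt = 0.01 ms
    state, params = _single_neuron(drive_current=current_mv)
    state, rec = am.integrate_interval(state, 10_000.0, step_ms=0.01)
    measured = rec.counts(1)[0] / 10.0
    expected = am.lif_rate_constant_current(params, current_mv)
    assert measured == pytest.approx(expected, rel=0.02)


def test_subthreshold_current_never_spikes():
    state, params = _single_neuron(drive_current=9.0)  # 9 mV < 10 mV gap
    state, rec = am.integrate_interval(state, 2000.0)
    assert rec.n_events == 0
    assert am.lif_rate_constant_current(params, 9.0) == 0.0


def test_rate_bounded_by_refractory_period():
    state, params = _single_neuron(drive_current=2000.0)
    state, rec = am.integrate_interval(state, 5000.0)
    assert rec.counts(1)[0] / 5.0 <= 1000.0 / params.tau_ref + 1


@settings(max_examples=8, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_interspike_intervals_respect_refractory_period(seed):
    spec = am.NetworkSpec(n_excitatory=25, n_inhibitory=6,
                          connection_probability=0.1, seed=seed)
    params = am.NeuronParams(drive_rate_hz=800.0)
    state = am.build_network(spec, params)
    _, rec = am.integrate_interval(state, 3000.0)
    for i in np.unique(rec.ids):
        t = rec.times[rec.ids == i]
        if len(t) > 1:
            assert np.all(np.diff(t) >= params.tau_ref - 1e-9)
    # times nondecreasing, ids in range
    assert np.all(np.diff(rec.times) >= 0)
    assert rec.ids.min() >= 0 and rec.ids.max() < spec.n_total


def test_mean_rate_monotone_in_background_drive():
    # inhibition disabled via zero I->E / I->I weights
    rates = []
    for drive in (200.0, 400.0, 800.0):
        spec = am.NetworkSpec(
            n_excitatory=50, n_inhibitory=10, connection_probability=0.1,
            baseline_weights={"ee": 0.05, "ei": 0.05, "ie": 0.0, "ii": 0.0},
            seed=11)
        params = am.NeuronParams(drive_rate_hz=drive)
        state = am.build_network(spec, params)
        _, rec = am.integrate_interval(state, 20_000.0)
        rates.append(rec.counts(state.n_total)[:50].mean() / 20.0)
    assert rates[0] <= rates[1] <= rates[2]


def test_bit_reproducible_given_seed():
    def run():
        spec = am.NetworkSpec(n_excitatory=40, n_inhibitory=10,
                              connection_probability=0.1, seed=5)
        state = am.build_network(spec, am.NeuronParams())
        _, rec = am.integrate_interval(
            state, 2000.0, plasticity=am.InhibPlasticityParams(eta=0.05))
        return state, rec

    s1, r1 = run()
    s2, r2 = run()
    assert np.array_equal(r1.times, r2.times)
    assert np.array_equal(r1.ids, r2.ids)
    assert s1.allclose(s2)


def test_numeric_failure_reports_simulated_time():
    state, _ = _single_neuron(drive_current=1e12)
    with pytest.raises(am.NumericError) as err:
        am.integrate_interval(state, 100.0)
    assert err.value.t_ms <= 100.0


def test_invalid_step_rejected():
    state, _ = _single_neuron()
    with pytest.raises(ValueError):
        am.integrate_interval(state, 100.0, step_ms=0.0)
    with pytest.raises(ValueError):
        am.integrate_interval(state, 0.05, step_ms=0.1)
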