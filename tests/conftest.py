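"""Shared fixtures.

The full staged protocol at the default desk scale takes about a minute, so
it runs once per session (`default_run`) and the acceptance tests assert on
different aspects of the same run — mirroring how the stages of the
protocol build on each other scientifically.
"""

import numpy as np
import pytest

import antimemory as am

ACCEPTANCE_SEED = 1


@pytest.fixture(scope="session")
def default_config():
    return am.load_config()


@pytest.fixture(scope="session")
def default_run(default_config):
    """Balance the naive default network, measure its set-point rate, then
    execute the full staged protocol. Returns everything downstream tests
    need: rates, snapshots, the probe report and the verdicts."""
    state, assemblies, assoc, sched, plast, _ = am.setup_from_config(
        default_config, seed=ACCEPTANCE_SEED)
    am.balance_network(state, plast, 240_000.0, eta=sched.base_eta)
    run_plast = am.InhibPlasticityParams(
        eta=sched.base_eta, target_rate_hz=plast.target_rate_hz,
        tau_stdp=plast.tau_stdp, weight_max=plast.weight_max)
    _, rec = am.integrate_interval(state, 10_000.0, plasticity=run_plast)
    naive_rate = rec.counts(state.n_total)[:state.n_excitatory].mean() / 10.0
    naive_record = rec
    result = am.run_protocol(state, assemblies, assoc, sched, plast,
                             master_seed=ACCEPTANCE_SEED)
    return {
        "config": default_config,
        "assemblies": assemblies,
        "associations": assoc,
        "schedule": sched,
        "plasticity": plast,
        "naive_rate_hz": naive_rate,
        "naive_record": naive_record,
        "result": result,
    }


@pytest.fixture(scope="session")
def toy():
    state, expected = am.make_fixture("two-assembly-toy", seed=1)
    return state, expected


@pytest.fixture()
def small_state():
    """Fresh 50E+12I network with default constants (cheap per-test)."""
    spec = am.NetworkSpec(n_excitatory=50, n_inhibitory=12,
                          connection_probability=0.1, seed=7)
    return am.build_network(spec, am.NeuronParams())
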