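"""Protocol interventions: embedding and association masks, stimulus
reversibility, schedule validation, and the zero-stage run."""

import numpy as np
import pytest

import antimemory as am


def _assembly_pair(n_e=16):
    return am.AssemblySpec({"red": np.arange(0, 4), "green": np.arange(4, 8)},
                           within_assembly_gain=2.0)


def test_embed_identity_gain_leaves_weights(toy):
    state, expected = toy
    st = state.copy()
    spec = am.AssemblySpec(dict(expected["assemblies"].assemblies),
                           within_assembly_gain=1.0)
    before = st.synapses["ee"].weights.copy()
    am.embed_assemblies(st, spec)
    assert np.array_equal(st.synapses["ee"].weights, before)


def test_embed_scales_exactly_the_within_assembly_entries(toy):
    state, expected = toy
    st = state.copy()
    spec = expected["assemblies"]
    gain = spec.within_assembly_gain
    dense_before = st.synapses["ee"].dense()
    am.embed_assemblies(st, spec)
    dense_after = st.synapses["ee"].dense()
    for j in range(16):
        for k in range(16):
            factor = gain if (j, k) in expected["within_pairs"] else 1.0
            assert dense_after[j, k] == pytest.approx(
                dense_before[j, k] * factor)


def test_membership_matches_enumeration(toy):
    _, expected = toy
    memb = expected["assemblies"].membership(16)
    assert np.array_equal(memb, expected["membership"][:16])


def test_overlapping_assemblies_rejected(toy):
    state, _ = toy
    spec = am.AssemblySpec({"a": np.arange(0, 4), "b": np.arange(3, 7)})
    with pytest.raises(am.SpecificationError, match="overlap"):
        am.embed_assemblies(state.copy(), spec)


def test_association_scales_cross_pair_entries_both_directions(toy):
    state, expected = toy
    st = state.copy()
    aspec = expected["assemblies"]
    assoc = am.AssociationSpec(pairs=[("red", "green")],
                               between_assembly_gain=3.0)
    dense_before = st.synapses["ee"].dense()
    am.strengthen_associations(st, assoc, aspec)
    dense_after = st.synapses["ee"].dense()
    memb = aspec.membership(16)
    for j in range(16):
        for k in range(16):
            cross = (memb[j] >= 0 and memb[k] >= 0 and memb[j] != memb[k])
            factor = 3.0 if cross else 1.0
            assert dense_after[j, k] == pytest.approx(
                dense_before[j, k] * factor)


def test_association_unknown_label_rejected(toy):
    state, expected = toy
    assoc = am.AssociationSpec(pairs=[("red", "purple")])
    with pytest.raises(am.SpecificationError, match="purple"):
        am.strengthen_associations(state.copy(), assoc,
                                   expected["assemblies"])


def test_stimulus_factor_one_rejected():
    with pytest.raises(am.SpecificationError):
        am.StimulusSpec("red", disinhibition_factor=1.0).validate()


def test_stimulus_restores_scale_bit_exactly(small_state):
    spec = am.AssemblySpec({"red": np.arange(0, 10),
                            "green": np.arange(10, 20)})
    st = small_state.copy()
    before = st.stimulus_scale.copy()
    stim = am.StimulusSpec("red", 0.2, 500.0)
    am.apply_stimulus(st, stim, spec)
    assert np.array_equal(st.stimulus_scale, before)
    # stored inhibitory weights never touched by stimulation
    assert np.array_equal(st.synapses["ie"].weights,
                          small_state.synapses["ie"].weights)


def test_overlapping_concurrent_stimuli_rejected(small_state):
    spec = am.AssemblySpec({"red": np.arange(0, 10),
                            "green": np.arange(10, 20)})
    st = small_state.copy()
    st.stimulus_scale[np.arange(0, 10)] = 0.5   # ongoing stimulus
    with pytest.raises(am.ProtocolError):
        am.apply_stimulus(st, am.StimulusSpec("red", 0.2, 100.0), spec)


def test_schedule_onsets_must_increase():
    stages = [am.Stage(5.0, "embed"), am.Stage(2.0, "associate")]
    with pytest.raises(am.SpecificationError):
        am.ProtocolSchedule(stages=stages, total_duration_min=8.0).validate()


def test_default_schedule_compresses_reference_onsets():
    sched = am.default_schedule(compression=10.0, base_eta=0.01)
    onsets = [s.onset_min for s in sched.stages]
    assert onsets == pytest.approx([0.7, 2.35, 7.4])
    assert sched.total_duration_min == pytest.approx(8.0)
    assert sched.base_eta == pytest.approx(0.1)
    kinds = [s.kind for s in sched.stages]
    assert kinds == ["embed", "associate", "downscale"]


def test_zero_stage_schedule_runs_background_only(small_state):
    spec = am.AssemblySpec({"red": np.arange(0, 10),
                            "green": np.arange(10, 20)})
    assoc = am.AssociationSpec(pairs=[("red", "green")])
    sched = am.ProtocolSchedule(stages=[], total_duration_min=0.05,
                                probe_interval_s=0.0, trials_per_probe=1)
    res = am.run_protocol(small_state.copy(), spec, assoc, sched,
                          am.InhibPlasticityParams(eta=0.0),
                          probe_throughout=False)
    assert res.report.empty
    assert res.snapshots == {}
    assert not res.timeline.rates.empty


def test_protocol_report_deterministic_under_seed(small_state):
    spec = am.AssemblySpec({"red": np.arange(0, 10),
                            "green": np.arange(10, 20)},
                           within_assembly_gain=2.0)
    assoc = am.AssociationSpec(pairs=[("red", "green")],
                               between_assembly_gain=2.0)
    sched = am.ProtocolSchedule(
        stages=[am.Stage(0.01, "embed"), am.Stage(0.02, "associate"),
                am.Stage(0.04, "downscale")],
        total_duration_min=0.05, base_eta=0.05, probe_interval_s=0.0,
        trials_per_probe=2, probe_duration_ms=200.0,
        probe_assemblies=("red",), train_stimulation=False)
    runs = []
    for _ in range(2):
        res = am.run_protocol(small_state.copy(), spec, assoc, sched,
                              am.InhibPlasticityParams(eta=0.05),
                              master_seed=3, probe_throughout=False)
        runs.append(res)
    a, b = runs
    assert a.verdicts == b.verdicts
    num = a.report.select_dtypes(float)
    assert np.allclose(num.to_numpy(dtype=float),
                       b.report[num.columns].to_numpy(dtype=float),
                       equal_nan=True)


def test_scan_rejects_empty_fraction_list(small_state):
    spec = am.AssemblySpec({"red": np.arange(0, 10),
                            "green": np.arange(10, 20)})
    assoc = am.AssociationSpec(pairs=[("red", "green")])
    sched = am.ProtocolSchedule(stages=[], total_duration_min=1.0,
                                probe_assemblies=("red",))
    with pytest.raises(am.SpecificationError):
        am.scan_inhibition_reduction(small_state, spec, assoc, [], sched)
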