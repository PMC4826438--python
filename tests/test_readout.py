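"""Rate estimation, coactivation index, latching detection, grid maps.

Rate estimators are exact counting arithmetic, so they are cross-checked
against a naive per-event loop on randomly generated records.
"""

import numpy as np
import pandas as pd
import pytest

import antimemory as am
from antimemory.readout import ReadoutSpecificationError


def _record(times, ids, t0, t1):
    return am.SpikeRecord(np.asarray(times, dtype=float),
                          np.asarray(ids, dtype=np.int32), t0, t1)


# ---------------------------------------------------------------------------
# windowed rates

def test_hand_counted_rate():
    # 3 neurons, 6 spikes in one 1 s window -> 6 / (3 x 1 s) = 2 Hz
    rec = _record([100, 200, 300, 400, 500, 600], [0, 1, 2, 0, 1, 2],
                  0.0, 1000.0)
    tl = am.estimate_rates(rec, 1000.0, {"grp": [0, 1, 2]})
    assert tl.rates["grp"].tolist() == [2.0]


def test_empty_record_gives_zero_rates():
    rec = _record([], [], 0.0, 3000.0)
    tl = am.estimate_rates(rec, 1000.0, {"grp": [0, 1]})
    assert np.all(tl.rates["grp"] == 0.0)
    assert len(tl.rates) == 3


def test_split_windows_average_to_full_window():
    rng = np.random.default_rng(5)
    times = np.sort(rng.uniform(0, 2000.0, 200))
    ids = rng.integers(0, 4, 200).astype(np.int32)
    rec = _record(times, ids, 0.0, 2000.0)
    full = am.estimate_rates(rec, 2000.0, {"g": [0, 1, 2, 3]})
    halves = am.estimate_rates(rec, 1000.0, {"g": [0, 1, 2, 3]})
    assert halves.rates["g"].mean() == pytest.approx(
        full.rates["g"].iloc[0])


def test_rates_match_naive_per_event_loop():
    rng = np.random.default_rng(17)
    n, t_stop = 10, 5000.0
    times = np.sort(rng.uniform(0, t_stop, 400))
    ids = rng.integers(0, n, 400).astype(np.int32)
    rec = _record(times, ids, 0.0, t_stop)
    groups = {"a": [0, 1, 2], "b": [3, 4, 5, 6]}
    window = 1000.0
    tl = am.estimate_rates(rec, window, groups)
    for lab, members in groups.items():
        for w in range(5):
            count = sum(1 for t, i in zip(times, ids)
                        if w * window <= t < (w + 1) * window
                        and i in members)
            assert tl.rates[lab].iloc[w] == pytest.approx(
                count / (len(members) * 1.0))


def test_empty_group_rejected():
    rec = _record([10.0], [0], 0.0, 1000.0)
    with pytest.raises(ReadoutSpecificationError):
        am.estimate_rates(rec, 1000.0, {"grp": []})


# ---------------------------------------------------------------------------
# coactivation index

@pytest.mark.parametrize("assoc, bg, sd, expected", [
    (9.0, 5.0, 1.0, 4.0),
    (5.0, 5.0, 1.0, 0.0),
    (7.0, 5.0, 0.0, 4.0),    # zero sd handled by the 0.5 Hz floor
])
def test_coactivation_index(assoc, bg, sd, expected):
    assert am.coactivation_index(assoc, bg, sd) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# latching

def _timeline(rates_by_label, window_s=2.0, sizes=None):
    n = len(next(iter(rates_by_label.values())))
    df = pd.DataFrame({"time_s": np.arange(n) * window_s} | rates_by_label)
    sizes = sizes or {lab: 100 for lab in rates_by_label}
    return am.RateTimeline(window_s, df, sizes)


def test_forced_rotation_flags_latching_with_sequence():
    n = 30
    base = np.full(n, 2.0)
    labels = ["red", "green", "yellow", "blue"]
    rates = {lab: base.copy() for lab in labels}
    rates["background"] = base.copy()
    # serial activations: red at window 2, green at 4, yellow at 6 ...
    order = ["red", "green", "yellow", "blue", "red", "green"]
    for k, lab in enumerate(order):
        rates[lab][2 + 2 * k] = 40.0
    tl = _timeline(rates)
    rep = am.detect_latching(tl)
    assert rep.latching
    assert rep.sequence()[:6] == order


def test_all_zero_timeline_no_latching():
    zero = {lab: np.zeros(20) for lab in
            ["red", "green", "yellow", "blue", "background"]}
    rep = am.detect_latching(_timeline(zero))
    assert not rep.latching
    assert rep.activations == []


def test_single_assembly_activation_is_not_latching():
    labels = ["red", "green", "yellow", "blue", "background"]
    rates = {lab: np.full(20, 2.0) for lab in labels}
    rates["red"][5:8] = 50.0   # one assembly only
    rep = am.detect_latching(_timeline(rates))
    assert not rep.latching


# ---------------------------------------------------------------------------
# grid maps

def test_grid_map_silenced_quadrant_is_zero_block():
    spec = am.NetworkSpec(n_excitatory=100, n_inhibitory=10)  # 10x10 grid
    rng = np.random.default_rng(2)
    active = [i for i in range(100)
              if not (spec.grid_position(i)[0] < 5
                      and spec.grid_position(i)[1] < 5)]
    times = np.sort(rng.uniform(0, 1000.0, 500))
    ids = rng.choice(active, 500).astype(np.int32)
    field = am.grid_rate_map(_record(times, ids, 0.0, 1000.0), 1000.0, spec)
    assert field.shape == (10, 10)
    assert np.all(field[:5, :5] == 0.0)
    assert field[5:, :].sum() > 0


def test_grid_map_pads_unused_cells_with_nan():
    spec = am.NetworkSpec(n_excitatory=90, n_inhibitory=10)  # 10x10, 10 unused
    field = am.grid_rate_map(_record([], [], 0.0, 1000.0), 1000.0, spec)
    assert np.isnan(field.ravel()[90:]).all()
    assert np.nansum(field) == 0.0


def test_grid_map_window_outside_record_rejected():
    spec = am.NetworkSpec(n_excitatory=16, n_inhibitory=4)
    with pytest.raises(ReadoutSpecificationError):
        am.grid_rate_map(_record([], [], 0.0, 500.0), 1000.0, spec)
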