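"""Summary quantities from spike records: windowed rates, assembly
timelines, grid-rate maps, the coactivation index, and the latching
detector.

Rates are exact counting arithmetic throughout: spikes in window divided
by (group size × window length). The coactivation index standardizes the
associate assembly's probe rate against the background population
(``(associate − background) / background sd``, with a configurable sd
floor against degenerate trial spreads); an index above 3 counts as
coactivation. Latching — spontaneous serial activation of assemblies in
the absence of any stimulus — is flagged when at least ``min_distinct``
different assemblies exceed an activation threshold within any sliding
span of a stimulus-free epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .state import SpikeRecord


class ReadoutSpecificationError(ValueError):
    """A readout request is inconsistent with the record or layout."""


DEFAULT_SD_FLOOR_HZ = 0.5
DEFAULT_COACTIVATION_THRESHOLD = 3.0


# ---------------------------------------------------------------------------
# rate timelines

@dataclass
class RateTimeline:
    """Per-group mean rates (Hz) on a regular grid of windows.

    ``rates`` has one row per window (column ``time_s`` = window start) and
    one column per group label; ``group_sizes`` maps labels to neuron
    counts so population means can be reconstructed exactly.
    """

    window_s: float
    rates: pd.DataFrame
    group_sizes: dict = field(default_factory=dict)

    @property
    def labels(self) -> list:
        return [c for c in self.rates.columns if c != "time_s"]

    def population_mean(self, labels=None) -> pd.Series:
        """Size-weighted mean rate over the given groups, per window."""
        labels = labels or self.labels
        sizes = np.array([self.group_sizes[lab] for lab in labels], float)
        vals = self.rates[list(labels)].to_numpy()
        return pd.Series(vals @ sizes / sizes.sum(),
                         index=self.rates.index, name="population_mean")

    def to_csv(self, path) -> None:
        long = self.rates.melt(id_vars="time_s", var_name="assembly_label",
                               value_name="mean_rate_hz")
        long.to_csv(path, index=False)


def estimate_rates(spikes: SpikeRecord, window_ms: float,
                   groups: dict) -> RateTimeline:
    """Windowed mean rates per group; ``groups`` maps label -> neuron ids.

    Windows tile ``[t_start, t_stop)``; a trailing remainder shorter than
    one window is dropped. Rate = spike count in window / (group size ×
    window length).
    """
    if window_ms <= 0:
        raise ReadoutSpecificationError("window_ms must be > 0")
    for lab, ids in groups.items():
        if len(np.asarray(ids)) == 0:
            raise ReadoutSpecificationError(f"group {lab!r} is empty")
    duration = spikes.t_stop - spikes.t_start
    n_win = int(duration / window_ms + 1e-9)
    if n_win == 0:
        raise ReadoutSpecificationError("record shorter than one window")
    t_edges = spikes.t_start + window_ms * np.arange(n_win + 1)
    out = {"time_s": (t_edges[:-1] - t_edges[0]) / 1000.0 + spikes.t_start / 1000.0}
    sizes = {}
    for lab, ids in groups.items():
        ids = np.asarray(ids)
        sizes[lab] = len(ids)
        mask = np.isin(spikes.ids, ids)
        counts, _ = np.histogram(spikes.times[mask], bins=t_edges)
        out[lab] = counts / (len(ids) * window_ms * 1e-3)
    return RateTimeline(window_ms * 1e-3, pd.DataFrame(out), sizes)


class TimelineAccumulator:
    """Streaming window-count accumulator for long protocol runs.

    Aggregates chunked spike records into per-assembly and background
    windowed rates without retaining the spikes, so an 80-minute run needs
    only O(windows) memory.
    """

    def __init__(self, assemblies, n_excitatory: int, window_ms: float,
                 t0_ms: float = 0.0):
        self.window_ms = float(window_ms)
        self.t0_ms = float(t0_ms)
        self.labels = list(assemblies.labels) + ["background"]
        memb = assemblies.membership(n_excitatory)
        # group index per excitatory neuron; background = last group
        self.group_of = np.where(memb >= 0, memb, len(self.labels) - 1)
        self.n_excitatory = n_excitatory
        self.sizes = {lab: int(np.sum(self.group_of == k))
                      for k, lab in enumerate(self.labels)}
        self.counts: dict[int, np.ndarray] = {}

    def add(self, rec: SpikeRecord) -> None:
        exc = rec.ids < self.n_excitatory
        t, i = rec.times[exc], rec.ids[exc]
        win = ((t - self.t0_ms) / self.window_ms - 1e-12).astype(np.int64)
        grp = self.group_of[i]
        for w in np.unique(win):
            row = self.counts.setdefault(
                int(w), np.zeros(len(self.labels), dtype=np.int64))
            sel = win == w
            np.add.at(row, grp[sel], 1)

    def finalize(self) -> RateTimeline:
        if not self.counts:
            empty = pd.DataFrame({"time_s": []} | {l: [] for l in self.labels})
            return RateTimeline(self.window_ms * 1e-3, empty, self.sizes)
        w_max = max(self.counts)
        data = np.zeros((w_max + 1, len(self.labels)))
        for w, row in self.counts.items():
            data[w] = row
        df = pd.DataFrame(data, columns=self.labels)
        for k, lab in enumerate(self.labels):
            df[lab] = df[lab] / (max(self.sizes[lab], 1)
                                 * self.window_ms * 1e-3)
        df.insert(0, "time_s",
                  (self.t0_ms + self.window_ms * np.arange(w_max + 1)) / 1e3)
        return RateTimeline(self.window_ms * 1e-3, df, self.sizes)


def probe_rates(rec: SpikeRecord, assemblies, n_excitatory: int) -> dict:
    """Mean rate (Hz) of each assembly and of the background population
    over one probe record."""
    counts = rec.counts(n_excitatory + 1)[:n_excitatory]
    dur_s = (rec.t_stop - rec.t_start) * 1e-3
    out = {}
    for lab, ids in assemblies.assemblies.items():
        ids = np.asarray(ids)
        out[lab] = counts[ids].sum() / (len(ids) * dur_s)
    bg = assemblies.background_ids(n_excitatory)
    out["background"] = counts[bg].sum() / (len(bg) * dur_s)
    return out


# ---------------------------------------------------------------------------
# coactivation

def coactivation_index(associate_rate_hz: float, background_rate_hz: float,
                       background_sd_hz: float,
                       sd_floor_hz: float = DEFAULT_SD_FLOOR_HZ) -> float:
    """Standardized elevation of the associate assembly above background."""
    sd = max(background_sd_hz, sd_floor_hz)
    if not np.isfinite(sd) or sd <= 0:
        sd = sd_floor_hz
    return (associate_rate_hz - background_rate_hz) / sd


# ---------------------------------------------------------------------------
# latching

@dataclass
class LatchingReport:
    latching: bool
    activations: list          # (time_s, label) activation onsets, in order
    threshold_hz: float

    def sequence(self) -> list:
        return [lab for _, lab in self.activations]


def detect_latching(timeline: RateTimeline, assembly_labels=None,
                    threshold_factor: float = 3.0,
                    min_distinct: int = 3,
                    span_s: float = 10.0) -> LatchingReport:
    """Flag spontaneous serial assembly activation in a stimulus-free epoch.

    Activation: an assembly's windowed rate exceeds ``threshold_factor``
    times the epoch's global mean excitatory rate. Latching: at least
    ``min_distinct`` distinct assemblies have an activation onset within
    some sliding span of ``span_s`` seconds.
    """
    labels = list(assembly_labels) if assembly_labels is not None else [
        lab for lab in timeline.labels if lab != "background"]
    if timeline.rates.empty:
        return LatchingReport(False, [], 0.0)
    global_mean = float(timeline.population_mean().mean())
    thresh = threshold_factor * global_mean
    onsets = []
    times = timeline.rates["time_s"].to_numpy()
    for lab in labels:
        active = timeline.rates[lab].to_numpy() > thresh
        rising = active & ~np.concatenate(([False], active[:-1]))
        onsets.extend((float(times[i]), lab) for i in np.nonzero(rising)[0])
    onsets.sort()
    latch = False
    for k in range(len(onsets)):
        t0 = onsets[k][0]
        distinct = {lab for t, lab in onsets if t0 <= t <= t0 + span_s}
        if len(distinct) >= min_distinct:
            latch = True
            break
    return LatchingReport(latch, onsets, thresh)


# ---------------------------------------------------------------------------
# grid maps

def grid_rate_map(spikes: SpikeRecord, window_ms: float, spec,
                  t_start: float | None = None) -> np.ndarray:
    """Per-neuron rates over one window arranged on the excitatory grid.

    Returns a (grid_width, grid_width) array in Hz; cells beyond the last
    excitatory neuron are NaN. ``t_start`` defaults to the record start.
    """
    if window_ms <= 0:
        raise ReadoutSpecificationError("window_ms must be > 0")
    t0 = spikes.t_start if t_start is None else float(t_start)
    t1 = t0 + window_ms
    if t0 < spikes.t_start - 1e-9 or t1 > spikes.t_stop + 1e-9:
        raise ReadoutSpecificationError("window outside the record")
    w = spec.grid_width
    n_e = spec.n_excitatory
    in_win = (spikes.times >= t0) & (spikes.times < t1) & (spikes.ids < n_e)
    counts = np.bincount(spikes.ids[in_win], minlength=n_e)[:n_e]
    field_ = np.full(w * w, np.nan)
    field_[:n_e] = counts / (window_ms * 1e-3)
    return field_.reshape(w, w)
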