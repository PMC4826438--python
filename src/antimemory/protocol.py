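"""Experimental protocol: assembly embedding, association, rebalancing,
global inhibitory downscaling, and disinhibition probes.

The staged timeline mirrors the modelling protocol: a naive balanced
network receives four nonoverlapping cell assemblies (strengthened E→E
connections within each group); inhibitory plasticity re-stabilizes the
network at its set-point, building an inhibitory replica of each assembly;
"associative" E→E connections are then strengthened between paired
assemblies and again rebalanced into dormancy; finally the efficacy of all
inhibitory synapses is reduced globally (the tDCS analogue), which unmasks
the dormant associations. Assemblies are probed by transiently reducing
the efficacy of the inhibitory synapses onto their members (functional
disinhibition) and measuring coactivation of the associated partner.

Probe trials run on copies of the network with frozen plasticity and
independent drive-noise substreams, so probing never perturbs the main
timeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .params import ConfigurationError, InhibPlasticityParams, ScalingParams
from .network import integrate_interval
from .plasticity import set_global_inhibition_scale
from .readout import (RateTimeline, TimelineAccumulator, coactivation_index,
                      probe_rates)
from .rng import substream_seed
from .state import NetworkState, SpikeRecord

DEFAULT_LABELS = ("red", "green", "yellow", "blue")


class SpecificationError(ValueError):
    """An assembly/association/stimulus specification is inconsistent."""


class ProtocolError(RuntimeError):
    """Protocol-level misuse (e.g. overlapping concurrent stimuli)."""


# ---------------------------------------------------------------------------
# specifications

@dataclass
class AssemblySpec:
    """Labeled, disjoint sets of excitatory neurons plus the within-assembly
    E→E gain applied when the assemblies are embedded."""

    assemblies: dict                      # label -> int array of E ids
    within_assembly_gain: float = 10.0

    def validate(self, n_excitatory: int) -> "AssemblySpec":
        seen = np.zeros(n_excitatory, dtype=bool)
        for label, ids in self.assemblies.items():
            ids = np.asarray(ids)
            if len(ids) == 0:
                raise SpecificationError(f"assembly {label!r} is empty")
            if ids.min() < 0 or ids.max() >= n_excitatory:
                raise SpecificationError(
                    f"assembly {label!r} has out-of-range neuron ids")
            if seen[ids].any():
                raise SpecificationError(
                    f"assembly {label!r} overlaps another assembly")
            seen[ids] = True
        if self.within_assembly_gain < 1.0:
            raise SpecificationError("within_assembly_gain must be >= 1")
        return self

    def membership(self, n_excitatory: int) -> np.ndarray:
        """Per-excitatory-neuron assembly index (-1 = background)."""
        memb = np.full(n_excitatory, -1, dtype=np.int64)
        for k, ids in enumerate(self.assemblies.values()):
            memb[np.asarray(ids)] = k
        return memb

    @property
    def labels(self) -> list:
        return list(self.assemblies.keys())

    def background_ids(self, n_excitatory: int) -> np.ndarray:
        return np.nonzero(self.membership(n_excitatory) < 0)[0]


@dataclass
class AssociationSpec:
    """Unordered assembly pairs whose mutual E→E connections are
    strengthened to encode associations."""

    pairs: list = field(default_factory=lambda: [
        ("red", "green"), ("blue", "yellow")])
    between_assembly_gain: float = 5.0

    def validate(self, assembly_spec: AssemblySpec) -> "AssociationSpec":
        used = set()
        for a, b in self.pairs:
            for lab in (a, b):
                if lab not in assembly_spec.assemblies:
                    raise SpecificationError(f"unknown assembly label {lab!r}")
                if lab in used:
                    raise SpecificationError(
                        f"assembly {lab!r} appears in more than one pair")
                used.add(lab)
        if self.between_assembly_gain < 1.0:
            raise SpecificationError("between_assembly_gain must be >= 1")
        return self

    def partner(self, label: str):
        for a, b in self.pairs:
            if label == a:
                return b
            if label == b:
                return a
        return None


@dataclass
class StimulusSpec:
    """Activate one assembly by scaling down the I→E synapses onto its
    members (reduced efficacy of the local interneurons) for a fixed window."""

    target_assembly: str
    disinhibition_factor: float = 0.1
    duration_ms: float = 1000.0

    def validate(self) -> "StimulusSpec":
        if not 0.0 <= self.disinhibition_factor < 1.0:
            raise SpecificationError(
                "disinhibition_factor must lie in [0, 1): stimulation is "
                "disinhibition, factor 1 would be a no-op")
        if self.duration_ms <= 0:
            raise SpecificationError("duration_ms must be > 0")
        return self


def default_assemblies(spec, n_per_assembly: int = 100,
                       labels=DEFAULT_LABELS,
                       within_assembly_gain: float = 10.0) -> AssemblySpec:
    """Four square assemblies, one centered in each quadrant of the grid."""
    w = spec.grid_width
    half = w // 2
    side = math.ceil(math.sqrt(n_per_assembly))
    if side > half:
        raise SpecificationError("assembly does not fit in a grid quadrant")
    quads = [(0, 0), (0, 1), (1, 0), (1, 1)]
    assemblies = {}
    for label, (qr, qc) in zip(labels, quads):
        r0 = qr * half + (half - side) // 2
        c0 = qc * half + (half - side) // 2
        ids = [r * w + c
               for r in range(r0, r0 + side)
               for c in range(c0, c0 + side)]
        ids = [i for i in ids if i < spec.n_excitatory][:n_per_assembly]
        if len(ids) < n_per_assembly:
            raise SpecificationError(
                "grid too small for the requested assembly size")
        assemblies[label] = np.asarray(ids, dtype=np.int64)
    return AssemblySpec(assemblies, within_assembly_gain)


# ---------------------------------------------------------------------------
# interventions

def _ee_presyn_index(syn) -> np.ndarray:
    return np.repeat(np.arange(syn.n_pre), np.diff(syn.indptr))


def embed_assemblies(state: NetworkState,
                     spec: AssemblySpec) -> NetworkState:
    """Multiply E→E weights with both endpoints inside the same assembly by
    the within-assembly gain; every other weight is untouched."""
    spec.validate(state.n_excitatory)
    memb = spec.membership(state.n_excitatory)
    ee = state.synapses["ee"]
    pre = _ee_presyn_index(ee)
    same = (memb[pre] >= 0) & (memb[pre] == memb[ee.targets])
    ee.weights[same] *= spec.within_assembly_gain
    return state


def strengthen_associations(state: NetworkState, assoc: AssociationSpec,
                            assemblies: AssemblySpec) -> NetworkState:
    """Multiply E→E weights running between paired assemblies (both
    directions) by the between-assembly gain."""
    assoc.validate(assemblies)
    memb = assemblies.membership(state.n_excitatory)
    labels = assemblies.labels
    ee = state.synapses["ee"]
    pre = _ee_presyn_index(ee)
    for a, b in assoc.pairs:
        ia, ib = labels.index(a), labels.index(b)
        cross = (((memb[pre] == ia) & (memb[ee.targets] == ib))
                 | ((memb[pre] == ib) & (memb[ee.targets] == ia)))
        ee.weights[cross] *= assoc.between_assembly_gain
    return state


def apply_stimulus(state: NetworkState, stim: StimulusSpec,
                   assemblies: AssemblySpec,
                   step_ms: float = 0.1,
                   plasticity: InhibPlasticityParams | None = None,
                   ) -> tuple[NetworkState, SpikeRecord]:
    """Disinhibit the target assembly for the stimulus window and record
    spikes; the stimulus scale is restored bit-exactly afterwards."""
    stim.validate()
    if stim.target_assembly not in assemblies.assemblies:
        raise SpecificationError(
            f"unknown assembly label {stim.target_assembly!r}")
    ids = np.asarray(assemblies.assemblies[stim.target_assembly])
    if np.any(state.stimulus_scale[ids] != 1.0):
        raise ProtocolError("overlapping concurrent stimuli on "
                            f"{stim.target_assembly!r}")
    state.stimulus_scale[ids] = stim.disinhibition_factor
    try:
        state, rec = integrate_interval(state, stim.duration_ms,
                                        step_ms=step_ms,
                                        plasticity=plasticity)
    finally:
        state.stimulus_scale[ids] = 1.0
    return state, rec


# ---------------------------------------------------------------------------
# schedule

@dataclass
class Stage:
    onset_min: float
    kind: str                      # embed | associate | downscale | plain_run
    eta: float | None = None       # stage learning rate (None = schedule base)
    fraction: float = 0.15         # downscale reduction fraction
    snapshot: str | None = None    # label snapshots taken at this boundary

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ProtocolSchedule:
    """Ordered stage onsets and probing policy for one full run.

    The reference timeline runs 80 biological minutes with stage onsets at
    7 (embed), 23.5 (associate) and 74 min (downscale). `default_schedule`
    compresses it by an integer factor with the learning rate raised by the
    same factor, the caption's own device for fitting slow rebalancing into
    a short run.
    """

    stages: list
    total_duration_min: float = 80.0
    base_eta: float = 1e-3
    probe_interval_s: float = 40.0
    trials_per_probe: int = 5
    probe_duration_ms: float = 1000.0
    probe_assemblies: tuple = ("red", "blue")
    disinhibition_factor: float = 0.1
    train_stimulation: bool = True  # in-run stimulations at probe points
    train_duration_ms: float = 1000.0
    timeline_window_ms: float = 2000.0
    step_ms: float = 0.1

    def validate(self) -> "ProtocolSchedule":
        onsets = [st.onset_min for st in self.stages]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise SpecificationError("stage onsets must be strictly increasing")
        if onsets and onsets[-1] >= self.total_duration_min:
            raise SpecificationError("stage onsets must precede total duration")
        if self.trials_per_probe < 1:
            raise SpecificationError("trials_per_probe must be >= 1")
        return self


def default_schedule(compression: float = 10.0, base_eta: float = 0.01,
                     fraction: float = 0.15,
                     post_downscale_eta_factor: float = 3.0,
                     **overrides) -> ProtocolSchedule:
    """The 80-minute staged protocol compressed by ``compression`` with the
    learning rate scaled up accordingly.

    The post-downscale stage runs at ``post_downscale_eta_factor`` times
    the compressed learning rate so that background activity re-stabilizes
    within the short epoch between the global downscale and the end of the
    run — the re-stabilization whose additive weight updates under-cancel
    the inhibitory replicas and thereby re-expose the associations.
    """
    c = float(compression)
    stages = [
        Stage(onset_min=7.0 / c, kind="embed", snapshot="A"),
        Stage(onset_min=23.5 / c, kind="associate", snapshot="B"),
        Stage(onset_min=74.0 / c, kind="downscale", fraction=fraction,
              eta=base_eta * c * post_downscale_eta_factor, snapshot="D"),
    ]
    sched = ProtocolSchedule(stages=stages, total_duration_min=80.0 / c,
                             base_eta=base_eta * c, **overrides)
    return sched.validate()


def setup_from_config(cfg: dict, seed: int | None = None):
    """Instantiate the full protocol bundle from a configuration mapping.

    Returns ``(state, assemblies, associations, schedule, plasticity,
    scaling)`` ready for `balance_network` / `run_protocol`. ``seed``
    overrides ``cfg["seed"]`` for the network build and all substreams.
    """
    from .build import build_network
    from .config import objects_from_config

    if seed is not None:
        cfg = {**cfg, "seed": int(seed)}
    spec, params, plast, scaling = objects_from_config(cfg)
    spec.seed = cfg["seed"]
    state = build_network(spec, params)
    a_cfg = cfg["assemblies"]
    assemblies = default_assemblies(
        spec, a_cfg["n_per_assembly"], labels=tuple(a_cfg["labels"]),
        within_assembly_gain=a_cfg["within_assembly_gain"])
    assoc = AssociationSpec(
        pairs=[tuple(p) for p in cfg["associations"]["pairs"]],
        between_assembly_gain=cfg["associations"]["between_assembly_gain"])
    s_cfg = cfg["schedule"]
    schedule = default_schedule(
        compression=s_cfg["compression"], base_eta=s_cfg["base_eta"],
        fraction=s_cfg["downscale_fraction"],
        probe_interval_s=s_cfg["probe_interval_s"],
        trials_per_probe=s_cfg["trials_per_probe"],
        probe_duration_ms=s_cfg["probe_duration_ms"],
        disinhibition_factor=cfg["stimulus"]["disinhibition_factor"],
        train_stimulation=s_cfg["train_stimulation"],
        train_duration_ms=s_cfg["train_duration_ms"],
        timeline_window_ms=s_cfg["timeline_window_ms"],
        step_ms=s_cfg["step_ms"])
    return state, assemblies, assoc, schedule, plast, scaling


def balance_network(state: NetworkState, plasticity: InhibPlasticityParams,
                    duration_ms: float = 240_000.0, eta: float | None = None,
                    step_ms: float = 0.1) -> NetworkState:
    """Run the naive network with the inhibitory rule until its excitatory
    population settles at the set-point (the pre-protocol balancing epoch).
    ``eta`` defaults to the rule's own learning rate."""
    plast = InhibPlasticityParams(
        eta=(eta if eta is not None else plasticity.eta),
        target_rate_hz=plasticity.target_rate_hz,
        tau_stdp=plasticity.tau_stdp,
        weight_max=plasticity.weight_max, enabled=True)
    integrate_interval(state, duration_ms, step_ms=step_ms, plasticity=plast)
    return state


# ---------------------------------------------------------------------------
# probing

def probe_assembly(state: NetworkState, assemblies: AssemblySpec,
                   assoc: AssociationSpec, target: str,
                   schedule: ProtocolSchedule, master_seed: int,
                   probe_tag: str) -> dict:
    """Stimulate ``target`` for `trials_per_probe` independent trials on
    copies of the network (frozen plasticity, fresh drive noise per trial)
    and summarize stimulated / associate / non-associate / background rates.
    """
    n_e = state.n_excitatory
    partner = assoc.partner(target)
    stim = StimulusSpec(target, schedule.disinhibition_factor,
                        schedule.probe_duration_ms)
    per_trial = []
    for k in range(schedule.trials_per_probe):
        trial = state.copy()
        trial.drive_rng_state = substream_seed(
            master_seed, f"probe-{probe_tag}-{target}-trial-{k}")
        _, rec = apply_stimulus(trial, stim, assemblies,
                                step_ms=schedule.step_ms, plasticity=None)
        per_trial.append(probe_rates(rec, assemblies, n_e))
    df = pd.DataFrame(per_trial)
    row = {"stimulated": target, "associate": partner}
    nonassoc = [lab for lab in assemblies.labels
                if lab not in (target, partner)]
    row["stim_rate"] = df[target].mean()
    row["stim_sd"] = df[target].std(ddof=1)
    row["assoc_rate"] = df[partner].mean() if partner else np.nan
    row["assoc_sd"] = df[partner].std(ddof=1) if partner else np.nan
    row["background_rate"] = df["background"].mean()
    row["background_sd"] = df["background"].std(ddof=1)
    for lab in nonassoc:
        row[f"rate_{lab}"] = df[lab].mean()
        row[f"sd_{lab}"] = df[lab].std(ddof=1)
    row["n_trials"] = schedule.trials_per_probe
    if partner:
        idx = coactivation_index(row["assoc_rate"], row["background_rate"],
                                 row["background_sd"])
        row["coactivation_index"] = idx
        row["coactivated"] = bool(idx > 3.0)
    return row


# ---------------------------------------------------------------------------
# the full run

@dataclass
class ProtocolResult:
    timeline: RateTimeline
    report: pd.DataFrame              # one row per probe per stimulated assembly
    snapshots: dict                   # label -> NetworkState copy
    verdicts: dict                    # snapshot label -> coactivated? (red probe)

    def verdict_sequence(self, order="ABCD") -> tuple:
        return tuple(bool(self.verdicts[k]) for k in order if k in self.verdicts)


def run_protocol(state: NetworkState, assemblies: AssemblySpec,
                 associations: AssociationSpec, schedule: ProtocolSchedule,
                 plasticity: InhibPlasticityParams,
                 scaling: ScalingParams | None = None,
                 master_seed: int = 0,
                 probe_throughout: bool = True,
                 ) -> ProtocolResult:
    """Execute the staged protocol on ``state`` (modified in place).

    ``plasticity`` is the inhibitory rule active throughout the run
    (per-stage ``eta`` overrides apply); passing ``scaling`` replaces it
    with the homeostatic-scaling control. At every probe point the tracked
    assemblies are probed on frozen copies for the report, and — when
    ``schedule.train_stimulation`` — each assembly is then stimulated once
    in-run with plasticity active, as in the reference timeline where the
    40 s-interval stimulations are part of the plastic run. This in-run
    stimulation is what lets the inhibitory replica learn to cancel the
    probe-evoked coactivation (snapshot C); because the rule's updates are
    additive, the post-downscale rebalancing epoch restores background
    balance but under-compensates the large replica weights, which is what
    re-exposes the association (snapshot D).

    Snapshots: "A" just before association, "B" just after, "C" just
    before the global downscale, "D" at the end of the post-downscale
    rebalancing epoch.
    """
    schedule.validate()
    assemblies.validate(state.n_excitatory)
    associations.validate(assemblies)
    acc = TimelineAccumulator(assemblies, state.n_excitatory,
                              schedule.timeline_window_ms, t0_ms=state.t_ms)
    snapshots: dict[str, NetworkState] = {}
    verdicts: dict[str, bool] = {}
    rows = []
    t_origin = state.t_ms

    def stage_plast(eta):
        if scaling is not None:
            return None
        return InhibPlasticityParams(
            eta=(eta if eta is not None else schedule.base_eta),
            target_rate_hz=plasticity.target_rate_hz,
            tau_stdp=plasticity.tau_stdp,
            weight_max=plasticity.weight_max, enabled=plasticity.enabled)

    def run_probe(tag):
        for target in schedule.probe_assemblies:
            row = probe_assembly(state, assemblies, associations, target,
                                 schedule, master_seed, tag)
            row["time_s"] = (state.t_ms - t_origin) / 1000.0
            row["tag"] = tag
            rows.append(row)
        return rows[-len(schedule.probe_assemblies)]

    def train_stimulations(plast):
        if not schedule.train_stimulation:
            return
        for label in assemblies.labels:
            stim = StimulusSpec(label, schedule.disinhibition_factor,
                                schedule.train_duration_ms)
            _, rec = apply_stimulus(state, stim, assemblies,
                                    step_ms=schedule.step_ms,
                                    plasticity=plast)
            acc.add(rec)

    def snapshot_and_probe(label):
        snapshots[label] = state.copy()
        first = run_probe(label)
        verdicts[label] = bool(first.get("coactivated", False))

    # timeline events: probes and stage boundaries, in order
    total_ms = schedule.total_duration_min * 60e3
    probe_times = []
    if probe_throughout and schedule.probe_interval_s > 0:
        step = schedule.probe_interval_s * 1e3
        probe_times = list(np.arange(step, total_ms, step))
    events = sorted(
        [(st.onset_min * 60e3, "stage", st) for st in schedule.stages]
        + [(t, "probe", None) for t in probe_times]
        + [(total_ms, "end", None)])

    current_eta = schedule.base_eta
    cursor = 0.0
    probe_counter = 0
    downscaled = False
    for t_event, kind, stage in events:
        if t_event > cursor:
            _, rec = integrate_interval(
                state, t_event - cursor, step_ms=schedule.step_ms,
                plasticity=stage_plast(current_eta), scaling=scaling)
            acc.add(rec)
            cursor = t_event
        if kind == "probe":
            probe_counter += 1
            run_probe(f"p{probe_counter}")
            train_stimulations(stage_plast(current_eta))
        elif kind == "stage":
            if stage.kind == "embed":
                embed_assemblies(state, assemblies)
            elif stage.kind == "associate":
                snapshot_and_probe("A")   # balanced pre-association state
                strengthen_associations(state, associations, assemblies)
                snapshot_and_probe("B")   # fresh association, not yet rebalanced
            elif stage.kind == "downscale":
                snapshot_and_probe("C")   # rebalanced, association dormant
                set_global_inhibition_scale(state, stage.fraction)
                downscaled = True
            elif stage.kind == "plain_run":
                pass
            else:
                raise SpecificationError(f"unknown stage kind {stage.kind!r}")
            if stage.eta is not None:
                current_eta = stage.eta
        elif kind == "end" and downscaled:
            snapshot_and_probe("D")   # post-downscale rebalanced: unmasked

    report = pd.DataFrame(rows)
    return ProtocolResult(acc.finalize(), report, snapshots, verdicts)


# ---------------------------------------------------------------------------
# reduction-range scan

def scan_inhibition_reduction(state: NetworkState, assemblies: AssemblySpec,
                              associations: AssociationSpec,
                              fractions, schedule: ProtocolSchedule,
                              plasticity: InhibPlasticityParams | None = None,
                              rebalance_ms: float = 60_000.0,
                              master_seed: int = 0) -> pd.DataFrame:
    """Verdict table over global inhibition-reduction fractions.

    For each fraction, a copy of the (rebalanced, association-embedded)
    state is globally disinhibited and then — mirroring the post-downscale
    epoch of the staged protocol — integrated for ``rebalance_ms`` with the
    inhibitory rule active, so that background activity re-stabilizes while
    the additively updated replica weights stay short of full cancellation.
    Both associated pairs are then probed and the unstimulated background
    rate measured; the input state is never modified. Verdict per pair:
    "unmasked" if the associate coactivates, else "dormant".
    """
    fractions = list(fractions)
    if not fractions:
        raise SpecificationError("empty fraction list")
    rows = []
    for frac in fractions:
        probe_state = state.copy()
        set_global_inhibition_scale(probe_state, frac)
        probe_state.drive_rng_state = substream_seed(
            master_seed, f"scan-rebalance-{frac}")
        # rebalancing epoch mirrors the main run: plain integration broken
        # by the periodic in-run stimulations that maintain the replicas
        remaining = rebalance_ms
        block = schedule.probe_interval_s * 1e3
        train_ms = (len(assemblies.labels) * schedule.train_duration_ms
                    if schedule.train_stimulation else 0.0)
        while remaining > 0:
            chunk = min(max(block - train_ms, schedule.step_ms), remaining)
            integrate_interval(probe_state, chunk,
                               step_ms=schedule.step_ms,
                               plasticity=plasticity)
            remaining -= chunk
            if schedule.train_stimulation and remaining > 0:
                for label in assemblies.labels:
                    stim = StimulusSpec(label, schedule.disinhibition_factor,
                                        schedule.train_duration_ms)
                    apply_stimulus(probe_state, stim, assemblies,
                                   step_ms=schedule.step_ms,
                                   plasticity=plasticity)
                    remaining -= schedule.train_duration_ms
                    if remaining <= 0:
                        break
        # unstimulated background rate at this reduction
        bg_state = probe_state.copy()
        bg_state.drive_rng_state = substream_seed(
            master_seed, f"scan-bg-{frac}")
        _, rec = integrate_interval(bg_state, 2000.0,
                                    step_ms=schedule.step_ms)
        bg = probe_rates(rec, assemblies, state.n_excitatory)
        for target in schedule.probe_assemblies:
            row = probe_assembly(probe_state, assemblies, associations,
                                 target, schedule, master_seed,
                                 f"scan-{frac}")
            row["fraction"] = frac
            row["unstimulated_background_rate"] = bg["background"]
            row["verdict"] = ("unmasked" if row.get("coactivated", False)
                              else "dormant")
            rows.append(row)
    return pd.DataFrame(rows)
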