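"""Parameter containers for neurons, the network graph, and plasticity rules.

Units follow the conventions of conductance-based leaky integrate-and-fire
modelling: time in ms, voltage in mV, synaptic conductance dimensionless in
units of the leak conductance, rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

SYNAPSE_CLASSES = ("ee", "ei", "ie", "ii")


class ConfigurationError(ValueError):
    """A parameter value violates its documented constraint."""


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ConfigurationError(message)


@dataclass
class NeuronParams:
    """Constants of the conductance-based leaky integrate-and-fire neuron.

    The membrane relaxes toward ``v_rest`` with time constant ``tau_m`` and
    is driven by exponentially decaying excitatory and inhibitory
    conductances (reversal potentials ``e_exc``/``e_inh``). ``drive_rate_hz``
    is the per-neuron rate of the independent Poisson background drive, each
    event adding ``drive_weight`` to the excitatory conductance;
    ``drive_current_mv`` is an optional constant current expressed as the
    steady-state depolarization it would produce (R·I, in mV).
    """

    tau_m: float = 20.0            # ms
    v_rest: float = -60.0          # mV
    v_thresh: float = -50.0        # mV
    v_reset: float = -60.0         # mV
    tau_ref: float = 5.0           # ms
    e_exc: float = 0.0             # mV
    e_inh: float = -80.0           # mV
    tau_exc: float = 5.0           # ms
    tau_inh: float = 10.0          # ms
    drive_rate_hz: float = 310.0   # Hz per neuron
    drive_weight: float = 0.08     # leak-conductance units per event
    drive_current_mv: float = 0.0  # mV (R·I)

    def validate(self) -> "NeuronParams":
        _require(self.v_thresh > self.v_rest,
                 "v_thresh must exceed v_rest")
        _require(self.v_reset <= self.v_rest,
                 "v_reset must not exceed v_rest")
        for name in ("tau_m", "tau_exc", "tau_inh"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(self.tau_ref >= 0, "tau_ref must be >= 0")
        _require(self.drive_rate_hz >= 0, "drive_rate_hz must be >= 0")
        _require(self.drive_weight >= 0, "drive_weight must be >= 0")
        return self

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class NetworkSpec:
    """Size, sparse-connectivity and baseline-weight specification.

    Connectivity is Erdős–Rényi per ordered pair, independently for each of
    the four synapse classes (E→E, E→I, I→E, I→I), with no self-connections
    and at most one synapse per ordered pair. Excitatory neurons are laid
    out row-major on a near-square grid for the rate-map views.
    """

    n_excitatory: int = 2000
    n_inhibitory: int = 500
    connection_probability: float = 0.02
    baseline_weights: dict = field(default_factory=lambda: {
        "ee": 0.08, "ei": 0.08, "ie": 0.6, "ii": 0.6})
    seed: int = 0

    def validate(self) -> "NetworkSpec":
        _require(self.n_excitatory > 0, "n_excitatory must be > 0")
        _require(self.n_inhibitory > 0, "n_inhibitory must be > 0")
        _require(0.0 <= self.connection_probability <= 1.0,
                 "connection_probability must lie in [0, 1]")
        missing = [c for c in SYNAPSE_CLASSES if c not in self.baseline_weights]
        _require(not missing, f"baseline_weights missing classes: {missing}")
        for cls in SYNAPSE_CLASSES:
            _require(self.baseline_weights[cls] >= 0,
                     f"baseline_weights[{cls!r}] must be >= 0")
        return self

    @property
    def n_total(self) -> int:
        return self.n_excitatory + self.n_inhibitory

    @property
    def grid_width(self) -> int:
        import math
        return math.ceil(math.sqrt(self.n_excitatory))

    def grid_position(self, neuron_id: int) -> tuple[int, int]:
        """(row, col) of an excitatory neuron on the square grid."""
        w = self.grid_width
        return neuron_id // w, neuron_id % w

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class InhibPlasticityParams:
    """Inhibitory spike-timing plasticity driving postsynaptic rates to a set-point.

    Symmetric pre/post trace rule on I→E synapses: each spike increments a
    low-pass trace (time constant ``tau_stdp``); a presynaptic (inhibitory)
    spike changes the weight by ``eta * (post_trace - alpha)`` and a
    postsynaptic (excitatory) spike by ``eta * pre_trace``. The depression
    bias ``alpha = 2 * target_rate * tau_stdp`` makes the expected drift
    vanish exactly when the postsynaptic neuron fires at ``target_rate``.
    Weights are clipped to ``[0, weight_max]``.
    """

    eta: float = 1e-3
    target_rate_hz: float = 5.0
    tau_stdp: float = 20.0   # ms
    weight_max: float = 50.0
    enabled: bool = True

    @property
    def alpha(self) -> float:
        # 2 * rho0 * tau, with tau in seconds so the product is dimensionless
        return 2.0 * self.target_rate_hz * (self.tau_stdp * 1e-3)

    def validate(self) -> "InhibPlasticityParams":
        _require(self.eta >= 0, "eta must be >= 0")
        _require(self.target_rate_hz > 0, "target_rate_hz must be > 0")
        _require(self.tau_stdp > 0, "tau_stdp must be > 0")
        _require(self.weight_max > 0, "weight_max must be > 0")
        return self

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScalingParams:
    """Homeostatic multiplicative scaling of excitatory synapses (control rule).

    Every ``interval_ms`` of simulated time, the E→E weights onto each
    excitatory neuron are multiplied by
    ``(target_rate / max(recent_rate, rate_floor)) ** gain``, capped to
    ``[factor_min, factor_max]`` per update. Inhibitory weights are never
    touched; relative proportions among a neuron's inputs are preserved.
    """

    interval_ms: float = 1000.0
    target_rate_hz: float = 5.0
    gain: float = 0.02
    rate_floor_hz: float = 0.1
    factor_min: float = 0.5
    factor_max: float = 2.0
    enabled: bool = True

    def validate(self) -> "ScalingParams":
        _require(self.interval_ms > 0, "interval_ms must be > 0")
        _require(self.gain > 0, "gain must be > 0")
        _require(self.target_rate_hz > 0, "target_rate_hz must be > 0")
        _require(0 < self.factor_min <= 1.0 <= self.factor_max,
                 "factor bounds must bracket 1")
        return self

    def factor(self, recent_rate_hz: float) -> float:
        """Closed-form scaling factor for one neuron's recent rate."""
        r = max(recent_rate_hz, self.rate_floor_hz)
        f = (self.target_rate_hz / r) ** self.gain
        return min(max(f, self.factor_min), self.factor_max)

    def as_dict(self) -> dict:
        return asdict(self)
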