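"""Layered feedforward spiking networks with synchronisation pulses.

Each non-input layer receives the previous layer's spike times concatenated
with its own *pulses*: auxiliary inputs with a learnable spike time shared by
all neurons of the layer (each neuron keeps its own weight onto each pulse).
Pulses act as a temporal bias that keeps neurons spiking, and at long target
latencies they learn to trigger the output at the required time.

Weights are initialised with a mean-shifted Glorot scheme:
``w ~ Normal(multiplier * sigma, sigma)`` with
``sigma = sqrt(2 / (fan_in + fan_out))``, where fan_in counts pulses, and
pulse connections may use a different multiplier than regular connections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spike_core import NO_SPIKE, LayerSolution, ModelParams, simulate_layer

__all__ = [
    "LayerParams",
    "NetworkSpec",
    "ForwardTrace",
    "init_pulses",
    "init_weights",
    "forward_pass",
    "param_count",
    "save_network",
    "load_network",
]


@dataclass
class LayerParams:
    """Learnable parameters of one non-input layer.

    ``weights`` has shape ``(n_inputs + n_pulses, n_outputs)``; the last
    ``n_pulses`` rows are the pulse connections.  ``pulse_times`` holds the
    layer's shared learnable pulse spike times (non-negative).
    """

    weights: np.ndarray
    pulse_times: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be a 2-d matrix")
        if np.any(self.pulse_times < 0):
            raise ValueError("pulse times must be non-negative")

    @property
    def n_pulses(self) -> int:
        return self.pulse_times.size

    @property
    def n_inputs(self) -> int:
        return self.weights.shape[0] - self.n_pulses

    @property
    def n_outputs(self) -> int:
        return self.weights.shape[1]

    def copy(self) -> "LayerParams":
        return LayerParams(self.weights.copy(), self.pulse_times.copy())


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description: layer sizes, pulses per layer, neuron params.

    ``layer_sizes`` lists (input, hidden..., output) sizes.  ``n_pulses`` is
    either one integer applied to every non-input layer or a sequence with one
    entry per non-input layer.  The usual autoencoder shape has the last size
    equal to the first with a smaller bottleneck in between, but any depth
    with at least two layers is accepted.
    """

    layer_sizes: tuple
    n_pulses: tuple
    params: ModelParams

    def __init__(self, layer_sizes, n_pulses, params: ModelParams):
        sizes = tuple(int(s) for s in layer_sizes)
        if len(sizes) < 2:
            raise ValueError("a network needs at least input and output layers")
        if any(s <= 0 for s in sizes):
            raise ValueError("layer sizes must be positive")
        if np.isscalar(n_pulses):
            pulses = (int(n_pulses),) * (len(sizes) - 1)
        else:
            pulses = tuple(int(p) for p in n_pulses)
        if len(pulses) != len(sizes) - 1:
            raise ValueError("need one pulse count per non-input layer")
        if any(p < 0 for p in pulses):
            raise ValueError("pulse counts must be non-negative")
        object.__setattr__(self, "layer_sizes", sizes)
        object.__setattr__(self, "n_pulses", pulses)
        object.__setattr__(self, "params", params)

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes)


@dataclass
class ForwardTrace:
    """Everything the forward pass saw, kept for exact backpropagation.

    ``layer_inputs[k]`` are the concatenated input spike times (previous layer
    outputs ++ pulses) fed to non-input layer ``k``; ``solutions[k]`` the
    per-neuron spike solutions; ``outputs[k]`` is an alias of
    ``solutions[k].times``.
    """

    layer_inputs: list
    solutions: list

    @property
    def outputs(self) -> list:
        return [s.times for s in self.solutions]

    @property
    def output_times(self) -> np.ndarray:
        return self.solutions[-1].times


def init_pulses(n_pulses: int, interval=(0.0, 1.0)) -> np.ndarray:
    """Pulse times evenly spread over ``interval``.

    Endpoints are included for ``n_pulses >= 2``; a single pulse sits at the
    midpoint; zero pulses give an empty array.
    """
    if n_pulses < 0:
        raise ValueError("n_pulses must be non-negative")
    lo, hi = float(interval[0]), float(interval[1])
    if n_pulses == 0:
        return np.empty(0)
    if n_pulses == 1:
        return np.array([(lo + hi) / 2.0])
    return np.linspace(lo, hi, n_pulses)


def init_weights(
    spec: NetworkSpec,
    nonpulse_multiplier: float = 0.0,
    pulse_multiplier: float = 0.0,
    seed: int = 0,
    pulse_interval=(0.0, 1.0),
) -> list:
    """Mean-shifted Glorot initialisation of every layer.

    Each weight is drawn ``Normal(multiplier * sigma, sigma)`` with
    ``sigma = sqrt(2 / (fan_in + fan_out))``; fan_in includes the pulse
    connections.  Regular and pulse connections use their own multiplier.
    Pulse times are evenly spaced over ``pulse_interval``.  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(seed)
    layers = []
    for k in range(1, spec.n_layers):
        n_in = spec.layer_sizes[k - 1]
        n_out = spec.layer_sizes[k]
        p = spec.n_pulses[k - 1]
        sigma = np.sqrt(2.0 / (n_in + p + n_out))
        w = rng.normal(nonpulse_multiplier * sigma, sigma, size=(n_in + p, n_out))
        if p:
            w[n_in:] = rng.normal(pulse_multiplier * sigma, sigma, size=(p, n_out))
        layers.append(LayerParams(w, init_pulses(p, pulse_interval)))
    return layers


def forward_pass(spec: NetworkSpec, layers: list, input_times) -> ForwardTrace:
    """Propagate one example through the network, layer by layer.

    Each neuron's spike is the event-based solution over the previous layer's
    outputs concatenated with this layer's pulses; ``NO_SPIKE`` outputs simply
    never appear as events downstream.
    """
    x = np.asarray(input_times, dtype=float)
    if x.shape != (spec.layer_sizes[0],):
        raise ValueError(
            f"input has shape {x.shape}, expected ({spec.layer_sizes[0]},)"
        )
    if len(layers) != spec.n_layers - 1:
        raise ValueError("wrong number of layers for this spec")
    layer_inputs = []
    solutions = []
    for k, lp in enumerate(layers):
        if lp.n_inputs != x.size or lp.n_outputs != spec.layer_sizes[k + 1]:
            raise ValueError(f"layer {k} weight shape inconsistent with spec")
        full_in = np.concatenate([x, lp.pulse_times])
        sol = simulate_layer(full_in, lp.weights, spec.params)
        layer_inputs.append(full_in)
        solutions.append(sol)
        x = sol.times
    return ForwardTrace(layer_inputs=layer_inputs, solutions=solutions)


def param_count(spec: NetworkSpec) -> int:
    """Number of learnable scalars: all weights plus the pulse times.

    For the three-layer shape (i, h, o) with p pulses per layer this is
    ``(i+p)h + (h+p)o + 2p``.
    """
    total = 0
    for k in range(1, spec.n_layers):
        p = spec.n_pulses[k - 1]
        total += (spec.layer_sizes[k - 1] + p) * spec.layer_sizes[k] + p
    return total


def _spec_to_dict(spec: NetworkSpec) -> dict:
    return {
        "layer_sizes": list(spec.layer_sizes),
        "n_pulses": list(spec.n_pulses),
        "tau": spec.params.tau,
        "theta": spec.params.theta,
    }


def _spec_from_dict(d: dict) -> NetworkSpec:
    return NetworkSpec(d["layer_sizes"], d["n_pulses"], ModelParams(d["tau"], d["theta"]))


def save_network(path, spec: NetworkSpec, layers: list, config: dict | None = None) -> None:
    """Serialise spec, parameters and (optionally) the training config as JSON.

    Floats are written with full repr precision, so a load is bit-exact.
    """
    payload = {
        "format": "spikeae-network",
        "version": 1,
        "spec": _spec_to_dict(spec),
        "layers": [
            {"weights": lp.weights.tolist(), "pulse_times": lp.pulse_times.tolist()}
            for lp in layers
        ],
        "config": config,
    }
    Path(path).write_text(json.dumps(payload))


def load_network(path):
    """Inverse of :func:`save_network`; returns ``(spec, layers, config)``."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "spikeae-network":
        raise ValueError(f"{path} is not a spikeae network file")
    spec = _spec_from_dict(payload["spec"])
    layers = []
    for k, d in enumerate(payload["layers"]):
        w = np.asarray(d["weights"], dtype=float)
        if w.size == 0:
            w = w.reshape(spec.layer_sizes[k] + spec.n_pulses[k], spec.layer_sizes[k + 1])
        layers.append(LayerParams(w, np.asarray(d["pulse_times"], dtype=float)))
    return spec, layers, payload.get("config")
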