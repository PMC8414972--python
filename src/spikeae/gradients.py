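"""Exact spike-time derivatives and chain-rule backpropagation.

Because the closed-form spike time is differentiable in the input spike times
and weights, gradients through the network are exact, not surrogate.  With
``A``, ``B`` the causal sums and ``W`` the cached principal-branch Lambert
value at the solution, a spiking neuron's partials are

    dt_out/dt_i = w_i e^{tau t_i} (tau (t_i - B/A) + W + 1) / (A (1 + W))
    dt_out/dw_i =     e^{tau t_i} (t_i - B/A + W / tau)     / (A (1 + W))

for every *causal* input (t_i < t_out); non-causal inputs receive exactly
zero.  Both partials blow up as the membrane potential becomes tangent to the
threshold (W -> -1), so each partial is clamped to ``[-clip, +clip]`` at
evaluation time.  Neurons that never spike receive a constant negative
incoming-weight gradient (the no-spike penalty) that pushes their weights up
until they fire again.

The partials are evaluated in the solution's shifted time frame (times
relative to ``t_ref``); both expressions are invariant under that shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spike_core import CausalSums, ModelParams, SpikeSolution
from .network import ForwardTrace

__all__ = [
    "GradientBundle",
    "d_spike_d_input",
    "d_spike_d_weight",
    "backprop",
]

# |1 + W| below this is treated as threshold tangency: the partial is
# replaced by its sign at the clip bound.
_TANGENCY_EPS = 1e-6


@dataclass
class GradientBundle:
    """Per-layer gradient accumulators mirroring ``LayerParams`` shapes."""

    d_weights: list
    d_pulse_times: list

    def scaled(self, factor: float) -> "GradientBundle":
        return GradientBundle(
            [g * factor for g in self.d_weights],
            [g * factor for g in self.d_pulse_times],
        )

    def add_(self, other: "GradientBundle") -> None:
        for a, b in zip(self.d_weights, other.d_weights):
            a += b
        for a, b in zip(self.d_pulse_times, other.d_pulse_times):
            a += b


def _shifted(solution: SpikeSolution, input_time: float):
    s = input_time - solution.t_ref
    a, b = solution.sums.a, solution.sums.b
    w_l = solution.lambert_w
    return s, a, b, w_l


def d_spike_d_input(
    solution: SpikeSolution,
    input_time: float,
    input_weight: float,
    sums: CausalSums | None = None,
    params: ModelParams | None = None,
) -> float:
    """Exact derivative of the output spike time w.r.t. one causal input time.

    The input must belong to the causal set (``input_time < solution.time``);
    callers are responsible for masking non-causal inputs to zero.
    """
    if not input_time < solution.time:
        raise ValueError("derivative requested for a non-causal input")
    s, a, b, w_l = _shifted(solution, input_time)
    if sums is not None:
        a, b = sums.a, sums.b
        s = input_time  # caller-supplied sums are in the caller's frame
    tau = params.tau if params is not None else None
    if tau is None:
        raise ValueError("params (for tau) are required")
    num = input_weight * np.exp(tau * s) * (tau * (s - b / a) + w_l + 1.0)
    den = a * (1.0 + w_l)
    return float(num / den)


def d_spike_d_weight(
    solution: SpikeSolution,
    input_time: float,
    sums: CausalSums | None = None,
    params: ModelParams | None = None,
) -> float:
    """Exact derivative of the output spike time w.r.t. one causal weight."""
    if not input_time < solution.time:
        raise ValueError("derivative requested for a non-causal input")
    s, a, b, w_l = _shifted(solution, input_time)
    if sums is not None:
        a, b = sums.a, sums.b
        s = input_time
    if params is None:
        raise ValueError("params (for tau) are required")
    tau = params.tau
    num = np.exp(tau * s) * (s - b / a + w_l / tau)
    den = a * (1.0 + w_l)
    return float(num / den)


def _layer_partials(sol, in_times, weights, tau, clip):
    """Clipped partial matrices (m_full, n) for one layer.

    Returns ``(pt, pw, causal)`` where ``pt[i, j] = dt_j/dt_i`` and
    ``pw[i, j] = dt_j/dw_ij``, zero outside the causal mask, each partial
    clamped to ``[-clip, +clip]`` (tangency replaced by the signed bound).
    """
    spiked = sol.spiked
    t_out = sol.times
    causal = (
        np.isfinite(in_times)[:, None]
        & (in_times[:, None] < t_out[None, :])
        & spiked[None, :]
    )
    s = np.where(causal, in_times[:, None] - np.where(spiked, sol.t_ref, 0.0)[None, :], 0.0)
    a = np.where(spiked, sol.a, 1.0)[None, :]
    ratio = np.where(spiked, sol.b / np.where(spiked, sol.a, 1.0), 0.0)[None, :]
    w_l = np.where(spiked, sol.lambert_w, 0.0)[None, :]
    e = np.where(causal, np.exp(tau * s), 0.0)
    num_t = weights * e * (tau * (s - ratio) + w_l + 1.0)
    num_w = e * (s - ratio + w_l / tau)
    one_plus = 1.0 + w_l
    tangent = np.abs(one_plus) < _TANGENCY_EPS
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        den = a * one_plus
        pt = num_t / den
        pw = num_w / den
    # at tangency (W -> -1, A > 0) the partial diverges with the sign of its
    # numerator; emit the signed clip bound instead
    pt = np.where(tangent | ~np.isfinite(pt), np.sign(num_t) * clip, pt)
    pw = np.where(tangent | ~np.isfinite(pw), np.sign(num_w) * clip, pw)
    pt = np.clip(pt, -clip, clip)
    pw = np.clip(pw, -clip, clip)
    pt = np.where(causal, pt, 0.0)
    pw = np.where(causal, pw, 0.0)
    return pt, pw, causal


def backprop(trace: ForwardTrace, layers, target, config, params: ModelParams):
    """Loss and exact gradients for one example.

    Parameters
    ----------
    trace : ForwardTrace
        Produced by :func:`spikeae.network.forward_pass` on these ``layers``.
    layers : list of LayerParams
    target : array
        Clean encoded target spike times; ``NO_SPIKE`` targets (white pixels,
        no information) are excluded from the loss.
    config : TrainConfig-like
        Uses ``latency``, ``clip_derivative``, ``penalty_no_spike`` and
        ``surrogate``.
    params : ModelParams
        The network's shared decay rate and threshold.

    Returns
    -------
    (loss, GradientBundle)
        ``loss`` is the latency-targeted squared error
        ``sum_i (t_out_i - target_i - l)^2`` over informative pixels, with
        non-spiking outputs evaluated at the surrogate time.  Gradients flow
        only through causal connections; every spike-time partial is clamped to
        ``[-clip, +clip]`` before use; non-spiking neurons (hidden or output)
        receive ``-penalty_no_spike`` on each incoming weight whose input
        spiked.
    """
    target = np.asarray(target, dtype=float)
    out_sol = trace.solutions[-1]
    if target.shape != out_sol.times.shape:
        raise ValueError("target length does not match the output layer")
    latency = config.latency
    clip = config.clip_derivative
    penalty = config.penalty_no_spike
    surrogate = config.surrogate

    informative = np.isfinite(target)
    out_spiked = out_sol.spiked
    t_eff = np.where(out_spiked, out_sol.times, surrogate)
    resid = np.where(informative, t_eff - target - latency, 0.0)
    loss = float(np.sum(resid**2))
    # adjoint dL/dt_out; only spiking outputs have a differentiable spike time
    adjoint = np.where(informative & out_spiked, 2.0 * resid, 0.0)

    d_weights = []
    d_pulses = []
    for k in range(len(layers) - 1, -1, -1):
        lp = layers[k]
        sol = trace.solutions[k]
        in_times = trace.layer_inputs[k]
        pt, pw, _ = _layer_partials(sol, in_times, lp.weights, params.tau, clip)
        d_w = pw * adjoint[None, :]
        if penalty:
            silent = ~sol.spiked
            if np.any(silent):
                rows = np.isfinite(in_times)
                d_w[np.ix_(rows, silent)] += -penalty
        upstream = pt @ adjoint
        m = lp.n_inputs
        d_weights.append(d_w)
        d_pulses.append(upstream[m:].copy())
        adjoint = upstream[:m]
    d_weights.reverse()
    d_pulses.reverse()
    return loss, GradientBundle(d_weights, d_pulses)
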