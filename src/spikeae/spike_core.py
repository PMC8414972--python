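"""Alpha-synapse spiking neuron with a closed-form spike time.

A presynaptic spike at time ``t_i`` with synaptic weight ``w_i`` contributes
an alpha-shaped kernel ``w_i * (t - t_i) * exp(-tau * (t - t_i))`` to the
membrane potential of a downstream neuron.  The neuron emits a single spike
the first time its potential reaches the threshold ``theta``.  Writing
``A = sum_i w_i exp(tau t_i)`` and ``B = sum_i w_i exp(tau t_i) t_i`` over the
causal input set, the threshold-crossing time has the closed form

    t_out = B/A - (1/tau) * W0(-(tau*theta/A) * exp(tau*B/A))

on the principal branch ``W0`` of the Lambert W function (the earliest of the
two crossings).  Simulation is event-based: inputs are processed in
chronological order and a predicted crossing is only accepted if no later
input arrives before it.

All spike-time vectors use ``NO_SPIKE`` (= +inf) for neurons that never fire;
it compares later than every finite time, which the event logic relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import lambertw

__all__ = [
    "NO_SPIKE",
    "ModelParams",
    "CausalSums",
    "SpikeSolution",
    "LayerSolution",
    "is_spike",
    "membrane_potential",
    "spike_time_closed_form",
    "simulate_layer",
    "simulate_neuron",
]

#: Sentinel spike time for a neuron that never fires.  +inf sorts after every
#: finite time, so "no spike" is simply "later than everything".
NO_SPIKE: float = math.inf

# Arguments of W0 this far below -1/e are treated as tangent (clamped).
_LAMBERT_SLACK = 1e-12
_MIN_LAMBERT_ARG = -1.0 / math.e


@dataclass(frozen=True)
class ModelParams:
    """Global neuron constants shared by every neuron in a network.

    Parameters
    ----------
    tau : float
        Decay rate of the alpha kernel (1/time).  Must be positive.
    theta : float
        Firing threshold of the membrane potential.  Must be positive.
    """

    tau: float
    theta: float

    def __post_init__(self) -> None:
        if not (self.tau > 0 and math.isfinite(self.tau)):
            raise ValueError(f"tau must be a positive finite real, got {self.tau}")
        if not (self.theta > 0 and math.isfinite(self.theta)):
            raise ValueError(f"theta must be a positive finite real, got {self.theta}")


@dataclass(frozen=True)
class CausalSums:
    """Weighted exponential sums over a candidate causal input set.

    ``a = sum_i w_i exp(tau t_i)`` and ``b = sum_i w_i exp(tau t_i) t_i``.
    Times may be expressed in any common frame; the closed-form spike time is
    equivariant under time translation of that frame.
    """

    a: float
    b: float


@dataclass(frozen=True)
class SpikeSolution:
    """A resolved spike of one neuron.

    Attributes
    ----------
    time : float
        The spike time (absolute frame).
    causal_set : numpy.ndarray
        Indices (into the caller's input order) of inputs with ``t_i < time``.
        ``None`` when the solution was computed from bare sums and no input
        list exists.
    lambert_w : float
        Value of ``W0`` at the solution; cached because the exact spike-time
        derivatives reuse it.
    sums : CausalSums
        The sums the solution was computed from, expressed in a frame shifted
        by ``-t_ref`` (numerical guard against ``exp(tau t)`` overflow).
    t_ref : float
        The frame shift: absolute time = shifted time + ``t_ref``.
    """

    time: float
    causal_set: np.ndarray | None
    lambert_w: float
    sums: CausalSums
    t_ref: float = 0.0


@dataclass
class LayerSolution:
    """Vectorised spike solutions for all neurons of one layer.

    Arrays are aligned per-neuron; entries of non-spiking neurons hold
    ``NO_SPIKE`` / NaN.  ``a``, ``b`` are causal sums in a per-neuron frame
    shifted by ``t_ref`` (see :class:`SpikeSolution`).
    """

    times: np.ndarray
    a: np.ndarray
    b: np.ndarray
    lambert_w: np.ndarray
    t_ref: np.ndarray

    @property
    def spiked(self) -> np.ndarray:
        return np.isfinite(self.times)


def is_spike(times: np.ndarray | float) -> np.ndarray | bool:
    """True where a spike-time entry is an actual spike (finite)."""
    return np.isfinite(times)


def _as_times(values) -> np.ndarray:
    t = np.asarray(values, dtype=float)
    finite = np.isfinite(t)
    if np.any(t[finite] < 0):
        raise ValueError("spike times must be non-negative")
    if np.any(np.isnan(t)):
        raise ValueError("spike times must be real or NO_SPIKE (inf)")
    return t


def membrane_potential(t, inputs, weights, params: ModelParams):
    """Membrane potential at time(s) ``t`` before any spike is emitted.

    Inputs with ``t_i <= t`` contribute ``w_i (t - t_i) exp(tau (t_i - t))``;
    later inputs and ``NO_SPIKE`` entries contribute nothing.  ``t`` may be a
    scalar or an array.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("evaluation time must be finite")
    times = _as_times(inputs)
    w = np.asarray(weights, dtype=float)
    if times.shape != w.shape:
        raise ValueError("inputs and weights must have matching shapes")
    if times.size == 0:
        return np.zeros(t.shape)[()] if t.shape else 0.0
    dt = t[..., None] - times  # (..., n)
    active = (dt >= 0) & np.isfinite(times)
    kern = np.where(active, w * dt * np.exp(-params.tau * np.where(active, dt, 0.0)), 0.0)
    out = kern.sum(axis=-1)
    return out[()] if out.shape == () else out


def _solve_shifted(a, b, tau: float, theta: float):
    """Vectorised closed-form crossing for shifted sums ``a``, ``b``.

    Returns ``(t_rel, w)`` arrays where ``t_rel`` is the crossing time in the
    shifted frame (NaN when the threshold is unreachable: ``a <= 0``, Lambert
    argument below the principal-branch domain, or overflow).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t_rel = np.full(a.shape, np.nan)
    w_out = np.full(a.shape, np.nan)
    pos = a > 0
    if not np.any(pos):
        return t_rel, w_out
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        ratio = np.where(pos, b / np.where(pos, a, 1.0), 0.0)
        arg = -(tau * theta) / np.where(pos, a, 1.0) * np.exp(tau * ratio)
    arg = np.where(pos, arg, np.nan)
    # tangency clamp: arguments within numerical slack below -1/e
    near = arg < _MIN_LAMBERT_ARG
    clampable = near & (arg >= _MIN_LAMBERT_ARG - _LAMBERT_SLACK)
    arg = np.where(clampable, _MIN_LAMBERT_ARG, arg)
    ok = pos & np.isfinite(arg) & (arg >= _MIN_LAMBERT_ARG)
    if np.any(ok):
        w_val = np.real(lambertw(np.where(ok, arg, 0.0), 0))
        # scipy yields NaN at the representable float nearest -1/e: tangency
        tangent = ok & ~np.isfinite(w_val) & (arg <= _MIN_LAMBERT_ARG + _LAMBERT_SLACK)
        w_val = np.where(tangent, -1.0, w_val)
        ok &= np.isfinite(w_val)
        t_rel = np.where(ok, ratio - w_val / tau, np.nan)
        w_out = np.where(ok, w_val, np.nan)
    return t_rel, w_out


def spike_time_closed_form(sums: CausalSums, params: ModelParams) -> SpikeSolution | None:
    """Earliest threshold crossing for a fixed causal set, or ``None``.

    Applies the Lambert-W closed form on the principal branch.  Returns
    ``None`` when there is no real crossing: non-positive ``A`` (the potential
    is non-increasing wherever positive, so no new upward crossing exists) or
    a Lambert argument below ``-1/e`` (threshold never reached).
    """
    t_rel, w = _solve_shifted(np.array([sums.a]), np.array([sums.b]), params.tau, params.theta)
    if not np.isfinite(t_rel[0]):
        return None
    return SpikeSolution(
        time=float(t_rel[0]),
        causal_set=None,
        lambert_w=float(w[0]),
        sums=sums,
        t_ref=0.0,
    )


def simulate_layer(input_times, weight_matrix, params: ModelParams) -> LayerSolution:
    """Event-based simulation of a whole layer sharing one input spike train.

    Parameters
    ----------
    input_times : array of shape (m,)
        Input spike times (``NO_SPIKE`` entries are ignored).  Need not be
        sorted; simultaneous spikes are processed together.
    weight_matrix : array of shape (m, n)
        Column ``j`` holds neuron ``j``'s weights onto the shared inputs.
    params : ModelParams

    Returns
    -------
    LayerSolution
        Per-neuron spike times (``NO_SPIKE`` where the threshold is never
        reached) plus the causal sums and Lambert values needed for exact
        gradients.

    Notes
    -----
    After each batch of simultaneous inputs at time ``t_k`` the closed form is
    solved for every not-yet-spiked neuron; a candidate is accepted iff
    ``t_k <= t_cand <= t_next`` (next input time, +inf if none), ties at
    ``t_next`` accepted.  Sums are maintained in a frame shifted to the latest
    processed input so ``exp(tau t)`` cannot overflow at large latencies.
    """
    times = _as_times(input_times)
    w = np.asarray(weight_matrix, dtype=float)
    if w.ndim != 2 or w.shape[0] != times.size:
        raise ValueError(
            f"weight matrix shape {w.shape} does not match {times.size} inputs"
        )
    n = w.shape[1]
    tau, theta = params.tau, params.theta

    out = LayerSolution(
        times=np.full(n, NO_SPIKE),
        a=np.full(n, np.nan),
        b=np.full(n, np.nan),
        lambert_w=np.full(n, np.nan),
        t_ref=np.full(n, np.nan),
    )
    finite = np.isfinite(times)
    if not np.any(finite) or n == 0:
        return out

    events = np.unique(times[finite])  # ascending, batches simultaneous spikes
    a = np.zeros(n)
    b = np.zeros(n)
    active = np.ones(n, dtype=bool)
    t_ref = events[0]
    for k, t_k in enumerate(events):
        delta = t_k - t_ref
        if delta > 0:
            decay = math.exp(-tau * delta)
            b = (b - delta * a) * decay
            a = a * decay
            t_ref = t_k
        batch = finite & (times == t_k)
        a = a + w[batch].sum(axis=0)
        # new inputs sit at shifted time 0, so they add nothing to b
        t_next = events[k + 1] if k + 1 < len(events) else NO_SPIKE
        t_rel, w_val = _solve_shifted(a, b, tau, theta)
        cand = active & np.isfinite(t_rel)
        if np.any(cand):
            t_abs = t_ref + np.clip(t_rel, 0.0, None)
            # accept: crossing happens before (or exactly at) the next input
            accept = cand & (t_rel >= -1e-12) & (t_abs <= t_next)
            if np.any(accept):
                out.times[accept] = t_abs[accept]
                out.a[accept] = a[accept]
                out.b[accept] = b[accept]
                out.lambert_w[accept] = w_val[accept]
                out.t_ref[accept] = t_ref
                active &= ~accept
                if not np.any(active):
                    break
    return out


def simulate_neuron(inputs, weights, params: ModelParams) -> SpikeSolution | None:
    """Event-based simulation of a single neuron.

    Returns the neuron's :class:`SpikeSolution` (spike time, causal set, cached
    Lambert value and causal sums) or ``None`` when the threshold is never
    reached.  Inputs may be unsorted; ``NO_SPIKE`` entries are ignored; each
    neuron spikes at most once.
    """
    times = _as_times(inputs)
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.shape != times.shape:
        raise ValueError("inputs and weights must be 1-d with matching lengths")
    sol = simulate_layer(times, w[:, None], params)
    if not np.isfinite(sol.times[0]):
        return None
    t_out = float(sol.times[0])
    causal = np.flatnonzero(np.isfinite(times) & (times < t_out))
    return SpikeSolution(
        time=t_out,
        causal_set=causal,
        lambert_w=float(sol.lambert_w[0]),
        sums=CausalSums(a=float(sol.a[0]), b=float(sol.b[0])),
        t_ref=float(sol.t_ref[0]),
    )
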