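"""Diagnostics of trained spiking autoencoders.

Summaries that expose how a trained network works: reconstruction error at
the target latency, spike-time distributions per layer (with pulse times),
weight statistics split by regular vs pulse connections — the split that
reveals the inhibition/excitation division of labour — and export of the
hidden-layer spike times as embeddings for downstream analyses (t-SNE, SVM
classification) run with off-the-shelf tooling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spike_core import NO_SPIKE, simulate_layer
from .network import NetworkSpec, forward_pass
from .training import TrainConfig, latency_loss

__all__ = [
    "reconstruction_error",
    "spike_distribution",
    "weight_distribution",
    "embed",
    "interpolate_embeddings",
    "EMBED_NO_SPIKE_SENTINEL",
]

#: Value standing in for NO_SPIKE in exported embedding matrices (all real
#: spike times are non-negative, so -1 is unambiguous).
EMBED_NO_SPIKE_SENTINEL = -1.0


def reconstruction_error(spec: NetworkSpec, layers, dataset, config: TrainConfig) -> float:
    """Mean latency loss per informative pixel over a dataset.

    ``dataset`` is a sequence of (noisy input, clean target) spike-vector
    pairs; the error is the squared latency residual summed per example and
    normalised by the number of informative (spiking-target) pixels.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset is empty")
    total = 0.0
    pixels = 0
    for noisy, clean in dataset:
        trace = forward_pass(spec, layers, noisy)
        total += latency_loss(clean, trace.output_times, config.latency, config.surrogate)
        pixels += int(np.sum(np.isfinite(np.asarray(clean, dtype=float))))
    if pixels == 0:
        raise ValueError("dataset has no informative pixels")
    return total / pixels


def spike_distribution(spec: NetworkSpec, layers, inputs, bins=20, time_range=None):
    """Binned spike-time counts per non-input layer, plus current pulse times.

    Returns ``(histograms, pulses)``: a DataFrame with columns (layer, bin_left,
    bin_right, count) and a DataFrame with columns (layer, pulse_index, time).
    Only emitted spikes are counted; a layer that never spikes contributes an
    all-zero histogram.
    """
    per_layer = [[] for _ in range(spec.n_layers - 1)]
    for x in inputs:
        trace = forward_pass(spec, layers, x)
        for k, t in enumerate(trace.outputs):
            per_layer[k].extend(t[np.isfinite(t)].tolist())
    if time_range is None:
        allspikes = [t for lst in per_layer for t in lst]
        hi = max(allspikes) if allspikes else 1.0
        time_range = (0.0, max(hi, 1.0))
    rows = []
    for k, lst in enumerate(per_layer):
        counts, edges = np.histogram(np.asarray(lst), bins=bins, range=time_range)
        for c, lo, hi in zip(counts, edges[:-1], edges[1:]):
            rows.append({"layer": k + 1, "bin_left": lo, "bin_right": hi, "count": int(c)})
    hist = pd.DataFrame(rows)
    pulse_rows = [
        {"layer": k + 1, "pulse_index": j, "time": float(t)}
        for k, lp in enumerate(layers)
        for j, t in enumerate(lp.pulse_times)
    ]
    pulses = pd.DataFrame(pulse_rows, columns=["layer", "pulse_index", "time"])
    return hist, pulses


def weight_distribution(layers) -> pd.DataFrame:
    """Mean and quantiles of weights per layer, split regular vs pulse.

    The regular/pulse split is the diagnostic of interest: at long target
    latencies trained networks drive regular connections inhibitory on
    average while pulse connections stay strongly excitatory.
    """
    rows = []
    quantiles = (0.1, 0.25, 0.5, 0.75, 0.9)
    for k, lp in enumerate(layers):
        groups = {"regular": lp.weights[: lp.n_inputs]}
        if lp.n_pulses:
            groups["pulse"] = lp.weights[lp.n_inputs :]
        for name, w in groups.items():
            flat = w.ravel()
            row = {
                "layer": k + 1,
                "connection": name,
                "n": flat.size,
                "mean": float(flat.mean()),
            }
            for q in quantiles:
                row[f"q{int(q * 100)}"] = float(np.quantile(flat, q))
            rows.append(row)
    return pd.DataFrame(rows)


def embed(spec: NetworkSpec, layers, inputs, hidden_layer: int = 1) -> np.ndarray:
    """Hidden-layer spike times, one row per example.

    ``NO_SPIKE`` entries are kept as +inf in the returned matrix; use
    :func:`embedding_frame` for CSV export with the documented sentinel.
    """
    rows = [forward_pass(spec, layers, x).outputs[hidden_layer - 1] for x in inputs]
    return np.stack(rows)


def embedding_frame(embeddings: np.ndarray) -> pd.DataFrame:
    """Embeddings as a DataFrame, NO_SPIKE replaced by the sentinel value."""
    emb = np.where(np.isfinite(embeddings), embeddings, EMBED_NO_SPIKE_SENTINEL)
    cols = [f"hidden_{j}" for j in range(emb.shape[1])]
    df = pd.DataFrame(emb, columns=cols)
    df.attrs["no_spike_sentinel"] = EMBED_NO_SPIKE_SENTINEL
    return df


def interpolate_embeddings(spec: NetworkSpec, layers, emb_a, emb_b, alpha: float):
    """Decode a convex combination of two embeddings through the decoder.

    Hidden spike times are mixed linearly; if either embedding lacks a spike
    for a neuron, the mixture lacks it too.  Returns the output-layer spike
    times of the mixed embedding.
    """
    a = np.asarray(emb_a, dtype=float)
    b = np.asarray(emb_b, dtype=float)
    both = np.isfinite(a) & np.isfinite(b)
    mixed = np.where(both, (1.0 - alpha) * a + alpha * b, NO_SPIKE)
    decoder = layers[-1]
    full_in = np.concatenate([mixed, decoder.pulse_times])
    sol = simulate_layer(full_in, decoder.weights, spec.params)
    return sol.times
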