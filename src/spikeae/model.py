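"""High-level Model/Results interface for spiking autoencoders.

:class:`SpikingAutoencoder` is constructed from image data plus the
architecture and training options; :meth:`SpikingAutoencoder.fit` runs
event-based training and returns a :class:`SpikingAutoencoderResults`
carrying the trained parameters, the loss history, diagnostics and a
``summary()`` table.  Reconstruction, embedding export and the spike/weight
distribution summaries hang off the results object.

Example
-------
>>> from spikeae import SpikingAutoencoder
>>> from spikeae.synthetic_data import FixtureSpec
>>> model = SpikingAutoencoder.from_fixture(FixtureSpec(size=8, n_images=64),
...                                         hidden_size=4, latency=1.0, noise=0.2)
>>> results = model.fit(seed=0)
>>> print(results.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spike_core import ModelParams
from .network import (
    NetworkSpec,
    forward_pass,
    load_network,
    param_count,
    save_network,
)
from .training import (
    TrainConfig,
    default_model_params,
    train,
)
from .encoding import decode_spikes, encode_image, make_denoising_dataset
from . import analysis, idx, synthetic_data

__all__ = ["SpikingAutoencoder", "SpikingAutoencoderResults"]


class SpikingAutoencoder:
    """A three-layer (or deeper) spiking autoencoder bound to a dataset.

    Parameters
    ----------
    images : array-like, shape (n, rows, cols)
        Pixel values in [0, 1]; informative pixels carry large values
        (MNIST convention) and are encoded to early spike times after
        brightness inversion.
    hidden_size : int or sequence of int
        Bottleneck size(s); a single int gives the classic in-h-in shape.
    latency : float
        Target latency l: each informative pixel's output neuron is trained
        to spike at its input time + l.
    noise : float
        Noise factor eta of the clipped-Gaussian input corruption; targets
        stay clean (denoising setup).
    config : TrainConfig, optional
        Full training options; overrides ``latency`` if both given.
    params : ModelParams, optional
        Neuron constants; defaults to the published operating point for the
        chosen latency regime.
    n_pulses : int, optional
        Synchronisation pulses per non-input layer (default from the
        hyperparameter preset).
    """

    def __init__(
        self,
        images,
        hidden_size=4,
        latency: float = 1.0,
        noise: float = 0.0,
        config: TrainConfig | None = None,
        params: ModelParams | None = None,
        n_pulses: int | None = None,
        invert: bool = True,
        noise_seed: int = 1,
        labels=None,
    ):
        self.images = np.asarray(images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n, rows, cols) stack")
        self.labels = None if labels is None else np.asarray(labels)
        long_latency = latency > 4
        if config is None:
            config = (
                TrainConfig.long_latency(latency=latency)
                if long_latency
                else TrainConfig(latency=latency)
            )
        self.config = config
        self.params = params if params is not None else default_model_params(long_latency)
        if n_pulses is None:
            n_pulses = 8 if long_latency else 10
        self.invert = invert
        self.noise = float(noise)
        self.noise_seed = noise_seed
        n_pix = self.images.shape[1] * self.images.shape[2]
        hidden = [hidden_size] if np.isscalar(hidden_size) else list(hidden_size)
        self.spec = NetworkSpec([n_pix, *hidden, n_pix], n_pulses, self.params)
        self.dataset = make_denoising_dataset(
            self.images, eta=self.noise, seed=noise_seed, invert=invert
        )

    @classmethod
    def from_idx(cls, images_path, labels_path=None, limit=None, **kwargs):
        """Build from MNIST/FMNIST-style IDX files."""
        images = idx.read_idx_images(images_path)
        labels = idx.read_idx_labels(labels_path) if labels_path else None
        if limit is not None:
            images = images[:limit]
            labels = None if labels is None else labels[:limit]
        return cls(images, labels=labels, **kwargs)

    @classmethod
    def from_fixture(cls, fixture_spec=None, **kwargs):
        """Build from the deterministic synthetic fixture generator."""
        if fixture_spec is None:
            fixture_spec = synthetic_data.FixtureSpec()
        images, labels = synthetic_data.generate(fixture_spec)
        return cls(images, labels=labels, **kwargs)

    def fit(self, epochs: int | None = None, seed: int | None = None, callback=None):
        """Train with mini-batch Adam; returns a results object."""
        cfg = self.config
        overrides = {}
        if epochs is not None:
            overrides["epochs"] = epochs
        if seed is not None:
            overrides["seed"] = seed
        if overrides:
            from dataclasses import replace

            cfg = replace(cfg, **overrides)
        result = train(self.spec, self.dataset, cfg, callback=callback)
        return SpikingAutoencoderResults(self, result.layers, result.history, cfg)


class SpikingAutoencoderResults:
    """Trained spiking autoencoder: parameters, history and diagnostics."""

    def __init__(self, model: SpikingAutoencoder, layers, history, config: TrainConfig):
        self.model = model
        self.layers = layers
        self.history = list(history)
        self.config = config

    # -- core quantities ---------------------------------------------------

    @property
    def spec(self) -> NetworkSpec:
        return self.model.spec

    @property
    def n_params(self) -> int:
        return param_count(self.spec)

    @property
    def loss_history(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": np.arange(1, len(self.history) + 1), "mean_train_loss": self.history}
        )

    def reconstruction_error(self, dataset=None) -> float:
        """Mean squared latency residual per informative pixel."""
        ds = dataset if dataset is not None else self.model.dataset
        return analysis.reconstruction_error(self.spec, self.layers, ds, self.config)

    def _encode_inputs(self, images=None):
        if images is None:
            return [noisy for noisy, _ in self.model.dataset]
        return [encode_image(im, invert=self.model.invert) for im in np.asarray(images, dtype=float)]

    def reconstruct(self, images=None):
        """Decode the network's outputs back to images."""
        shape = self.model.images.shape[1:]
        out = []
        for x in self._encode_inputs(images):
            trace = forward_pass(self.spec, self.layers, x)
            out.append(
                decode_spikes(trace.output_times, self.config.latency, shape, invert=self.model.invert)
            )
        return out

    def embed(self, images=None) -> np.ndarray:
        """Hidden-layer spike times, one row per example (+inf = no spike)."""
        return analysis.embed(self.spec, self.layers, self._encode_inputs(images))

    def embedding_frame(self, images=None) -> pd.DataFrame:
        return analysis.embedding_frame(self.embed(images))

    def spike_distribution(self, images=None, bins=20):
        return analysis.spike_distribution(
            self.spec, self.layers, self._encode_inputs(images), bins=bins
        )

    def weight_distribution(self) -> pd.DataFrame:
        return analysis.weight_distribution(self.layers)

    def interpolate(self, index_a: int, index_b: int, alpha: float):
        """Decode a convex mix of two examples' embeddings through the decoder."""
        emb = self.embed()
        times = analysis.interpolate_embeddings(
            self.spec, self.layers, emb[index_a], emb[index_b], alpha
        )
        shape = self.model.images.shape[1:]
        return decode_spikes(times, self.config.latency, shape, invert=self.model.invert)

    # -- persistence and reporting ----------------------------------------

    def save(self, path) -> None:
        from dataclasses import asdict

        save_network(path, self.spec, self.layers, config=asdict(self.config))

    @classmethod
    def load(cls, path, model: SpikingAutoencoder | None = None):
        spec, layers, cfg_dict = load_network(path)
        config = TrainConfig(**cfg_dict) if cfg_dict else TrainConfig()
        if model is None:
            results = cls.__new__(cls)
            results.model = None
            results.layers = layers
            results.history = []
            results.config = config
            results._spec = spec
            return results
        return cls(model, layers, [], config)

    def summary(self) -> str:
        """Human-readable training report."""
        spec = self.spec
        wd = self.weight_distribution()
        lines = [
            "Spiking Autoencoder Results",
            "=" * 60,
            f"Architecture        {'-'.join(str(s) for s in spec.layer_sizes)}"
            f"  (+{spec.n_pulses[0]} pulses/layer)",
            f"Learnable params    {self.n_params}",
            f"tau={spec.params.tau:.4f}  theta={spec.params.theta:.4f}  "
            f"latency l={self.config.latency:g}",
            f"Noise factor eta    {self.model.noise:g}" if self.model else "",
            f"Epochs              {len(self.history)}",
        ]
        if self.history:
            lines += [
                f"Train loss          first={self.history[0]:.4f}  "
                f"final={self.history[-1]:.4f}",
                f"Error per pixel     {self.reconstruction_error():.4f}",
            ]
        lines.append("-" * 60)
        lines.append(f"{'layer':>6} {'connection':>11} {'mean':>9} {'q10':>9} {'q50':>9} {'q90':>9}")
        for _, r in wd.iterrows():
            lines.append(
                f"{int(r['layer']):>6} {r['connection']:>11} {r['mean']:>9.4f} "
                f"{r['q10']:>9.4f} {r['q50']:>9.4f} {r['q90']:>9.4f}"
            )
        for k, lp in enumerate(self.layers):
            if lp.n_pulses:
                pt = np.array2string(lp.pulse_times, precision=2, separator=", ")
                lines.append(f"layer {k + 1} pulse times: {pt}")
        return "\n".join(line for line in lines if line != "")

    # -- plotting ----------------------------------------------------------

    def plot_loss(self, ax=None):
        """Loss-history curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.loss_history["epoch"], self.loss_history["mean_train_loss"])
        ax.set_xlabel("epoch")
        ax.set_ylabel("mean train loss")
        ax.set_yscale("log")
        return ax

    def plot_reconstructions(self, indices=(0, 1, 2), axes=None):
        """Original vs reconstructed images side by side (requires matplotlib)."""
        import matplotlib.pyplot as plt

        recon = self.reconstruct()
        if axes is None:
            _, axes = plt.subplots(2, len(indices), figsize=(2 * len(indices), 4))
        for col, i in enumerate(indices):
            axes[0][col].imshow(self.model.images[i], cmap="gray_r", vmin=0, vmax=1)
            axes[1][col].imshow(recon[i].pixels, cmap="gray_r", vmin=0, vmax=1)
            for row in (0, 1):
                axes[row][col].set_xticks([])
                axes[row][col].set_yticks([])
        axes[0][0].set_ylabel("input")
        axes[1][0].set_ylabel("reconstruction")
        return axes
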