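"""Analog pixel <-> spike-time conversion and the clipped-Gaussian noise model.

Temporal coding places salient information early: a pixel's spike time is
proportional to its (inverted) brightness.  For MNIST-style images, where
informative pixels carry large values, brightness is inverted so that the
encoded value ``v' = 1 - v`` is the spike time; pixels whose encoded value is
exactly 1 (background) carry no information and emit no spike.

Noise (for denoising experiments) acts in encoded space:

    t_i <- max(0, min(t_i + eta * r, 1)),   r ~ Normal(r_mean, 1)

with ``r_mean = 1`` under inverted-brightness encoding, so the noise pushes
values toward the uninformative end; values clamped at 1 map back to the
no-spike state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spike_core import NO_SPIKE

__all__ = [
    "ImageGrid",
    "NoiseConfig",
    "encode_image",
    "decode_spikes",
    "add_noise",
    "encode_dataset",
    "make_denoising_dataset",
]


@dataclass
class ImageGrid:
    """A single-channel image with values in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-d grid")
        if np.any(~np.isfinite(self.pixels)) or np.any(
            (self.pixels < 0) | (self.pixels > 1)
        ):
            raise ValueError("pixel values must lie in [0, 1]")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class NoiseConfig:
    """Clipped-Gaussian pixel noise: ``eta`` scales a unit-sd normal ``r``.

    ``r_mean`` is 1 for inverted-brightness encoding (noise drifts toward the
    uninformative end) and 0 otherwise.
    """

    eta: float
    r_mean: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be non-negative")


def _grid_values(image) -> np.ndarray:
    if isinstance(image, ImageGrid):
        return image.pixels
    arr = np.asarray(image, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("pixel values must lie in [0, 1]")
    return arr


def encode_image(image, invert: bool = True) -> np.ndarray:
    """Encode pixels as spike times in [0, 1]; flat output, row-major.

    With ``invert`` the encoded value is ``1 - v``; either way, the spike
    time equals the encoded value and encoded values of exactly 1 become
    ``NO_SPIKE`` (no information).
    """
    v = _grid_values(image).ravel()
    enc = 1.0 - v if invert else v.copy()
    enc[enc >= 1.0] = NO_SPIKE
    return enc


def decode_spikes(output_times, latency: float, shape, invert: bool = True) -> ImageGrid:
    """Invert the target map ``t~ = t + l`` back to an image.

    Encoded value = ``clamp(t~ - l, 0, 1)``; ``NO_SPIKE`` decodes to 1 (no
    information); with ``invert`` the display brightness is re-inverted.
    """
    t = np.asarray(output_times, dtype=float)
    enc = np.where(np.isfinite(t), np.clip(t - latency, 0.0, 1.0), 1.0)
    if invert:
        enc = 1.0 - enc
    return ImageGrid(enc.reshape(shape))


def add_noise(encoded, config: NoiseConfig, rng=None) -> np.ndarray:
    """Apply clipped-Gaussian noise in encoded (spike-time) space.

    ``NO_SPIKE`` entries are represented as value 1 before noising; results
    equal to 1 map back to ``NO_SPIKE``.  With ``eta = 0`` the input is
    returned unchanged (no-spike states round-trip).
    """
    t = np.asarray(encoded, dtype=float)
    if config.eta == 0:
        return t.copy()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    v = np.where(np.isfinite(t), t, 1.0)
    r = rng.normal(config.r_mean, 1.0, size=v.shape)
    noisy = np.clip(v + config.eta * r, 0.0, 1.0)
    noisy[noisy >= 1.0] = NO_SPIKE
    return noisy


def encode_dataset(images, invert: bool = True) -> np.ndarray:
    """Encode a stack of images into a (n_images, n_pixels) spike-time array."""
    return np.stack([encode_image(im, invert=invert) for im in images])


def make_denoising_dataset(images, eta: float, seed: int = 0, invert: bool = True):
    """(noisy input, clean target) spike-vector pairs for denoising training.

    Noise is drawn once per image with a single seeded generator; the clean
    encoding is both the loss target and the reference for evaluation.
    """
    rng = np.random.default_rng(seed)
    cfg = NoiseConfig(eta=eta, r_mean=1.0 if invert else 0.0, seed=seed)
    pairs = []
    for im in images:
        clean = encode_image(im, invert=invert)
        pairs.append((add_noise(clean, cfg, rng=rng), clean))
    return pairs
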