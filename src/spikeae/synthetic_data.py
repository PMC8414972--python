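"""Deterministic MNIST-like fixture images for end-to-end testing.

Real neuromorphic-encoded digit sets are large downloads; every pipeline
stage here is exercised instead on small generated images that copy the
statistics that matter for temporal coding: a background of empty pixels
(value 0, which encodes to the no-spike state under brightness inversion)
and a centred, class-specific stroke pattern of bright pixels covering
roughly 19% of the grid — the informative-pixel fraction of MNIST digits
(about 150 of 784 pixels).  Shapes are simple templates (bar, cross, ring,
two diagonals) jittered by one pixel, with graded stroke brightness.

Fixture sets can be written in the same IDX dialect the encoding module
reads, so synthetic and real data share one loading path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import idx

__all__ = ["FixtureSpec", "template_mask", "generate", "write_fixture_idx"]

_N_TEMPLATES = 5


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a generated fixture set."""

    size: int = 8
    n_images: int = 64
    salient_fraction: float = 0.19
    n_classes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size <= 0 or self.n_images <= 0:
            raise ValueError("size and n_images must be positive")
        if not (0 < self.salient_fraction <= 1):
            raise ValueError("salient_fraction must lie in (0, 1]")
        if self.salient_fraction * self.size**2 < 1:
            raise ValueError("salient_fraction too small for this image size")
        if not (1 <= self.n_classes <= _N_TEMPLATES):
            raise ValueError(f"n_classes must be in [1, {_N_TEMPLATES}]")


def template_mask(class_id: int, size: int, salient_fraction: float = 0.19) -> np.ndarray:
    """Boolean stroke mask of one class template, centred, unjittered."""
    target = salient_fraction * size**2
    c = size // 2
    length = max(2, round(0.75 * size))
    lo = max(0, c - length // 2)
    hi = min(size, lo + length)
    mask = np.zeros((size, size), dtype=bool)
    if class_id == 0:  # vertical bar
        width = max(1, round(target / (hi - lo)))
        mask[lo:hi, c - width // 2 : c - width // 2 + width] = True
    elif class_id == 1:  # cross
        width = max(1, round(target / (2 * (hi - lo) - 1)))
        w0 = c - width // 2
        mask[lo:hi, w0 : w0 + width] = True
        mask[w0 : w0 + width, lo:hi] = True
    elif class_id == 2:  # square ring
        th = max(1, size // 8)
        side = int(np.clip(round((target + 4 * th**2) / (4 * th)), 2 * th + 1, size))
        s0 = c - side // 2
        s1 = s0 + side
        mask[s0:s1, s0:s1] = True
        mask[s0 + th : s1 - th, s0 + th : s1 - th] = False
    elif class_id == 3:  # main diagonal stroke
        width = max(1, round(target / (hi - lo)))
        for k in range(width):
            idx_ = np.arange(lo, hi)
            cols = np.clip(idx_ + k - width // 2, 0, size - 1)
            mask[idx_, cols] = True
    elif class_id == 4:  # horizontal bar
        width = max(1, round(target / (hi - lo)))
        mask[c - width // 2 : c - width // 2 + width, lo:hi] = True
    else:
        raise ValueError(f"unknown template class {class_id}")
    return mask


def generate(spec: FixtureSpec):
    """Generate ``(images, labels)``: a (n, size, size) float stack in [0, 1].

    Labels cycle through the classes for balance; each image jitters its
    class template by +/-1 pixel and grades the stroke brightness uniformly
    in [0.3, 1].  Byte-for-byte deterministic for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    images = np.zeros((spec.n_images, spec.size, spec.size))
    labels = np.arange(spec.n_images) % spec.n_classes
    for i, lab in enumerate(labels):
        mask = template_mask(int(lab), spec.size, spec.salient_fraction)
        dy, dx = rng.integers(-1, 2, size=2)
        mask = np.roll(np.roll(mask, dy, axis=0), dx, axis=1)
        vals = rng.uniform(0.3, 1.0, size=int(mask.sum()))
        images[i][mask] = vals
    return images, labels


def write_fixture_idx(images_path, labels_path, spec: FixtureSpec):
    """Generate a fixture set and write it as IDX image/label files."""
    images, labels = generate(spec)
    idx.write_idx_images(images_path, images)
    idx.write_idx_labels(labels_path, labels)
    return images, labels
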