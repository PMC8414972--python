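"""Reader/writer for the IDX container used by MNIST and FMNIST.

Layout: big-endian uint32 magic (0x00000803 for uint8 image tensors,
0x00000801 for uint8 label vectors), one big-endian uint32 per dimension,
then the raw unsigned bytes.  Image bytes are scaled to [0, 1] by /255 on
read.  Synthetic fixture sets are written in the same dialect so real and
generated data share one loading path.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["read_idx_images", "read_idx_labels", "write_idx_images", "write_idx_labels"]

_MAGIC_IMAGES = 0x00000803
_MAGIC_LABELS = 0x00000801


def read_idx_images(path) -> np.ndarray:
    """Load an IDX image tensor as floats in [0, 1], shape (n, rows, cols)."""
    raw = Path(path).read_bytes()
    magic, n, rows, cols = struct.unpack(">IIII", raw[:16])
    if magic != _MAGIC_IMAGES:
        raise ValueError(f"{path}: bad magic {magic:#010x} for an IDX image file")
    data = np.frombuffer(raw, dtype=np.uint8, offset=16)
    if data.size != n * rows * cols:
        raise ValueError(f"{path}: truncated IDX payload")
    return data.reshape(n, rows, cols).astype(float) / 255.0


def read_idx_labels(path) -> np.ndarray:
    """Load an IDX label vector as integers."""
    raw = Path(path).read_bytes()
    magic, n = struct.unpack(">II", raw[:8])
    if magic != _MAGIC_LABELS:
        raise ValueError(f"{path}: bad magic {magic:#010x} for an IDX label file")
    data = np.frombuffer(raw, dtype=np.uint8, offset=8)
    if data.size != n:
        raise ValueError(f"{path}: truncated IDX payload")
    return data.astype(int)


def write_idx_images(path, images) -> None:
    """Write a stack of [0, 1] images as an IDX uint8 tensor."""
    arr = np.asarray(images, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected (n, rows, cols) image stack")
    data = np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(struct.pack(">IIII", _MAGIC_IMAGES, *data.shape))
        fh.write(data.tobytes())


def write_idx_labels(path, labels) -> None:
    """Write integer labels (0..255) as an IDX uint8 vector."""
    lab = np.asarray(labels)
    data = lab.astype(np.uint8)
    if np.any(lab < 0) or np.any(lab > 255):
        raise ValueError("labels must fit in a byte")
    with open(path, "wb") as fh:
        fh.write(struct.pack(">II", _MAGIC_LABELS, data.size))
        fh.write(data.tobytes())
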