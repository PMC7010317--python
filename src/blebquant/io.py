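"""TIFF reading/writing for channel stacks and label maps."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

__all__ = ["write_channel_stack", "read_channel_stack", "write_labels", "read_labels"]

#: fixed multi-page channel order for scene TIFFs
CHANNEL_ORDER = ("cytoplasm", "nuclei", "adhesion")


def write_channel_stack(path, channels: dict) -> None:
    """Write the three channels as one 16-bit multi-page TIFF."""
    pages = [
        np.clip(np.asarray(channels[name]), 0, 65535).astype(np.uint16)
        for name in CHANNEL_ORDER
    ]
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")


def read_channel_stack(path) -> dict:
    """Read a multi-page scene TIFF back into named float64 channels."""
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != len(CHANNEL_ORDER):
        raise ValueError(
            f"{path}: expected a {len(CHANNEL_ORDER)}-page TIFF, got shape {stack.shape}"
        )
    return {name: stack[i].astype(np.float64) for i, name in enumerate(CHANNEL_ORDER)}


def write_labels(path, labels: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(labels).astype(np.int32))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int64)
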