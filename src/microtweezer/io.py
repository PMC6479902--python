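"""Frame I/O: multi-page TIFF stacks and globbed image sequences."""

from __future__ import annotations

import glob
import os
from typing import List

import numpy as np

from .tracking import to_grayscale

__all__ = ["read_frames"]


def read_frames(source: str) -> List[np.ndarray]:
    """Read a frame sequence as a list of single-channel float arrays.

    ``source`` is either a multi-page TIFF path or a glob pattern
    matching numbered PNG/TIFF files; globbed files are ordered
    lexicographically.  RGB input is reduced to grayscale with fixed
    luminance weights.
    """
    if any(ch in source for ch in "*?["):
        paths = sorted(glob.glob(source))
        if not paths:
            raise FileNotFoundError(f"no frames match {source!r}")
        import imageio.v3 as iio

        return [to_grayscale(iio.imread(p)) for p in paths]
    if not os.path.exists(source):
        raise FileNotFoundError(source)
    if source.lower().endswith((".tif", ".tiff")):
        import tifffile

        stack = tifffile.imread(source)
        if stack.ndim == 2:
            return [to_grayscale(stack)]
        return [to_grayscale(frame) for frame in stack]
    import imageio.v3 as iio

    return [to_grayscale(iio.imread(source))]
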