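"""Tile tracking through a stepped compression sequence.

The matcher is the plain normalized dot product (cosine similarity): a
tile chosen in the first frame is flattened, L2-normalised, and swept as
an integer-offset template over a scan window in the next frame; the
placement maximising the dot product with the (equally normalised)
candidate is the new tile position.  The matched region then becomes the
template for the following frame (template update), so the tracker
follows slowly evolving appearance at the cost of possible drift.

Matching is integer-pixel only.  Positions are the tile's *top-left*
corner in 0-based (row, col) coordinates.  Scores lie in [0, 1] for
non-negative intensities.  A zero-mean (NCC-style) variant is available
behind ``zero_mean=True`` but the default reproduces the plain cosine
similarity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "TileRef",
    "Track",
    "MatchResult",
    "DegenerateTileError",
    "ScanWindowError",
    "normalize_tile",
    "match_tile",
    "track_sequence",
    "displacement_series",
    "derive_mechanics",
    "estimate_angle",
]

LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)  # fixed RGB -> grayscale reduction


class DegenerateTileError(ValueError):
    """Tile has zero norm (all-zero intensities): cannot be normalised."""


class ScanWindowError(ValueError):
    """Scan window (after clipping to the frame) admits no tile placement."""


@dataclass(frozen=True)
class TileRef:
    """A tile anchored at ``top_left`` (row, col) with shape ``size`` (h, w)."""

    top_left: Tuple[int, int]
    size: Tuple[int, int] = (50, 50)

    def validate(self, frame_shape: Tuple[int, int]) -> None:
        r, c = self.top_left
        h, w = self.size
        if r < 0 or c < 0 or r + h > frame_shape[0] or c + w > frame_shape[1]:
            raise ValueError(f"tile {self} not fully inside frame of shape {frame_shape}")


@dataclass
class Track:
    """Per-step positions of one tracked tile through a frame sequence."""

    positions: np.ndarray  # (n, 2) int, tile top-left (row, col)
    scores: np.ndarray  # (n,) best dot product per step
    flags: np.ndarray  # (n,) bool, True where the match is low-confidence
    tile_size: Tuple[int, int] = (50, 50)
    scan_size: Tuple[int, int] = (100, 100)
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MatchResult:
    position: Tuple[int, int]
    score: float
    degenerate: bool = False


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Reduce an (H, W[, 3]) frame to single-channel float64."""
    arr = np.asarray(frame)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.asarray(LUMA_WEIGHTS)
    elif arr.ndim != 2:
        raise ValueError(f"expected 2-D or RGB frame, got shape {arr.shape}")
    return np.ascontiguousarray(arr, dtype=np.float64)


def normalize_tile(tile: np.ndarray) -> np.ndarray:
    """Flatten a tile and divide by its Euclidean norm (unit L2 vector)."""
    vec = np.asarray(tile, dtype=np.float64).ravel()
    norm = np.linalg.norm(vec)
    if norm == 0.0:
        raise DegenerateTileError("all-zero tile cannot be normalised")
    return vec / norm


def _window_sq_norms(region: np.ndarray, tile_size: Tuple[int, int]) -> np.ndarray:
    # sum of squares over every tile placement, via a padded integral image
    h, w = tile_size
    sq = np.cumsum(np.cumsum(region.astype(np.float64) ** 2, axis=0), axis=1)
    sq = np.pad(sq, ((1, 0), (1, 0)))
    return sq[h:, w:] - sq[:-h, w:] - sq[h:, :-w] + sq[:-h, :-w]


def match_tile(
    template: np.ndarray,
    tile_size: Tuple[int, int],
    frame: np.ndarray,
    scan_window: Tuple[int, int, int, int],
    zero_mean: bool = False,
) -> MatchResult:
    """Exhaustive integer search for the best-matching tile placement.

    Parameters
    ----------
    template
        Unit-normalised flattened tile vector (``normalize_tile`` output).
    tile_size
        (h, w) of the tile the template was cut from.
    scan_window
        (top, left, height, width) search region; clipped to the frame.

    Returns the top-left position of the argmax of the normalized dot
    product, ties broken by first occurrence in row-major order.  If every
    candidate is degenerate (zero norm) the window's first placement is
    returned with score 0 and ``degenerate=True``.
    """
    frame = to_grayscale(frame)
    h, w = tile_size
    top, left, H, W = scan_window
    # clip to frame bounds
    top0, left0 = max(top, 0), max(left, 0)
    bot, right = min(top + H, frame.shape[0]), min(left + W, frame.shape[1])
    if bot - top0 < h or right - left0 < w:
        raise ScanWindowError(
            f"scan window {scan_window} clipped to frame {frame.shape} cannot hold a {tile_size} tile"
        )
    region = frame[top0:bot, left0:right]
    tvec = np.asarray(template, dtype=np.float64).ravel()
    if zero_mean:
        tvec = tvec - tvec.mean()
        tnorm = np.linalg.norm(tvec)
        if tnorm == 0.0:
            raise DegenerateTileError("zero-mean template is constant")
        tvec = tvec / tnorm

    windows = sliding_window_view(region, (h, w))
    dots = np.tensordot(windows, tvec.reshape(h, w), axes=2)
    if zero_mean:
        ones = np.ones((h, w)) / (h * w)
        means = np.tensordot(windows, ones, axes=2)
        # template is zero-mean, so subtracting candidate means changes norms only
        sq = _window_sq_norms(region, tile_size)
        var = sq - (h * w) * means**2
        norms = np.sqrt(np.maximum(var, 0.0))
    else:
        norms = np.sqrt(np.maximum(_window_sq_norms(region, tile_size), 0.0))

    valid = norms > 0.0
    if not valid.any():
        return MatchResult((top0, left0), 0.0, degenerate=True)
    scores = np.where(valid, dots / np.where(valid, norms, 1.0), -np.inf)
    flat = int(np.argmax(scores))  # first maximum in row-major order
    r, c = np.unravel_index(flat, scores.shape)
    score = float(min(max(scores[r, c], -1.0), 1.0))
    return MatchResult((top0 + int(r), left0 + int(c)), score)


def _centered_window(
    prev: Tuple[int, int], tile_size: Tuple[int, int], scan_size: Tuple[int, int]
) -> Tuple[int, int, int, int]:
    h, w = tile_size
    H, W = scan_size
    top = prev[0] + h // 2 - H // 2
    left = prev[1] + w // 2 - W // 2
    return top, left, H, W


def track_sequence(
    frames: Sequence[np.ndarray],
    init: TileRef,
    scan_size: Tuple[int, int] = (100, 100),
    zero_mean: bool = False,
    min_score: float = 0.5,
    update: str = "every_step",
    refresh_score: float = 0.85,
) -> Track:
    """Track one tile through a frame sequence.

    The scan window of each step is centred on the previous best position
    and clipped at the frame border.  If the tracked tile reaches the
    border (no full placement possible, or the match sits on the frame
    edge), the track is truncated with a warning and the partial track
    returned.  Matches scoring below ``min_score`` are flagged.

    ``update`` selects the template policy:

    ``"every_step"``
        Re-cut the template from the matched area of each new frame (the
        classic stepwise procedure).  Follows appearance change, but on
        steady sub-pixel motion each step contributes its own rounding
        error and the track ratchets: cumulative drift grows like
        N * |round(v) - v| for per-step motion v.
    ``"adaptive"``
        Keep the current template while it still matches well and re-cut
        it only when the best score falls below ``refresh_score``.  On
        slowly evolving scenes this anchors the match to one reference
        and keeps the cumulative error at the matcher's ~1 px floor,
        while still refreshing when the appearance genuinely changes.
    ``"never"``
        Always match the step-0 template (pure anchor tracking).
    """
    if update not in ("every_step", "adaptive", "never"):
        raise ValueError(f"unknown template update mode {update!r}")
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    frame0 = to_grayscale(frames[0])
    init.validate(frame0.shape)
    h, w = init.size
    template = normalize_tile(
        frame0[init.top_left[0] : init.top_left[0] + h, init.top_left[1] : init.top_left[1] + w]
    )
    positions = [init.top_left]
    scores = [1.0]
    flags = [False]
    truncated = False
    for frame in frames[1:]:
        frame = to_grayscale(frame)
        window = _centered_window(positions[-1], init.size, scan_size)
        try:
            result = match_tile(template, init.size, frame, window, zero_mean=zero_mean)
        except ScanWindowError:
            warnings.warn("tracked tile reached the frame border; track truncated", stacklevel=2)
            truncated = True
            break
        r, c = result.position
        on_border = r in (0, frame.shape[0] - h) or c in (0, frame.shape[1] - w)
        positions.append(result.position)
        scores.append(result.score)
        flags.append(result.degenerate or result.score < min_score)
        if on_border:
            warnings.warn("tracked tile reached the frame border; track truncated", stacklevel=2)
            truncated = True
            break
        if update == "every_step" or (update == "adaptive" and result.score < refresh_score):
            tile = frame[r : r + h, c : c + w]
            if tile.any():
                template = normalize_tile(tile)
    return Track(
        positions=np.asarray(positions, dtype=int),
        scores=np.asarray(scores, dtype=float),
        flags=np.asarray(flags, dtype=bool),
        tile_size=init.size,
        scan_size=scan_size,
        truncated=truncated,
    )


def displacement_series(track: Track, scale_mm_per_px: float) -> np.ndarray:
    """Per-step displacement relative to step 0, in mm.

    Returns an (n, 3) array of columns (dx, dy, magnitude), where dx is
    the column motion and dy the row motion times ``scale_mm_per_px``.
    """
    if scale_mm_per_px <= 0:
        raise ValueError("scale must be > 0")
    rel = (track.positions - track.positions[0]).astype(float) * scale_mm_per_px
    dy, dx = rel[:, 0], rel[:, 1]
    return np.column_stack([dx, dy, np.hypot(dx, dy)])


def derive_mechanics(
    tip_fixed: Track,
    contact_left: Track,
    contact_right: Track,
    scale_mm_per_px: float,
    theta,
):
    """Convert tracked pixel motions to per-step deflection records.

    The compression axis is the unit vector from the left to the right
    initial contact positions.  ``dc1`` is the magnitude of the fixed-arm
    tip motion projected on that axis (the fixed arm's base is
    stationary, so tip motion equals bending; only the axial component
    does work against the sample).  ``Ds`` is the decrease of the
    along-axis contact separation since step 0, clamped at zero.
    ``theta`` may be a scalar or a per-step sequence.
    """
    from .mechanics import DeflectionRecord

    n = len(tip_fixed)
    if len(contact_left) != n or len(contact_right) != n:
        raise ValueError("all tracks must have the same length")
    theta_arr = np.broadcast_to(np.asarray(theta, dtype=float), (n,))
    # (row, col) -> (x, y) = (col, row)
    tip = tip_fixed.positions[:, ::-1].astype(float)
    left = contact_left.positions[:, ::-1].astype(float)
    right = contact_right.positions[:, ::-1].astype(float)
    axis = right[0] - left[0]
    sep0 = np.linalg.norm(axis)
    if sep0 == 0:
        raise ValueError("initial contact separation must be > 0")
    axis = axis / sep0
    dc1 = np.abs((tip - tip[0]) @ axis) * scale_mm_per_px
    sep = (right - left) @ axis
    Ds = np.maximum((sep[0] - sep) * scale_mm_per_px, 0.0)
    return [
        DeflectionRecord(step=i, dc1_mm=float(dc1[i]), Ds_mm=float(Ds[i]), theta1=float(theta_arr[i]))
        for i in range(n)
    ]


def estimate_angle(
    track_a: Track, track_b: Track, axis_xy: Tuple[float, float] = (1.0, 0.0)
) -> np.ndarray:
    """Per-step angle between the segment a->b and the compression-axis normal.

    Two tiles tracked on the same cantilever define its orientation; the
    returned angle is 0 when the cantilever is perpendicular to the
    compression axis and grows with tilt, in [0, pi/2).
    """
    if len(track_a) != len(track_b):
        raise ValueError("tracks must have the same length")
    a = track_a.positions[:, ::-1].astype(float)
    b = track_b.positions[:, ::-1].astype(float)
    seg = b - a
    lengths = np.linalg.norm(seg, axis=1)
    if np.any(lengths == 0):
        raise ValueError("coincident tracked points: cantilever direction undefined")
    ax = np.asarray(axis_xy, dtype=float)
    ax = ax / np.linalg.norm(ax)
    normal = np.array([-ax[1], ax[0]])
    cosang = np.abs(seg @ normal) / lengths
    return np.arccos(np.clip(cosang, 0.0, 1.0))
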