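"""Shared fixtures: small synthetic scenes and translating test sequences."""

from __future__ import annotations

import numpy as np
import pytest

from microtweezer.synthetic import SceneParams


@pytest.fixture
def small_scene_params():
    """Factory for a compact scene that renders quickly in unit tests."""

    def make(seed: int = 7, **overrides) -> SceneParams:
        defaults = dict(
            seed=seed,
            steps=12,
            closure_per_step_mm=0.004,
            frame_shape=(400, 500),
            embryo_width_mm=0.4,
            embryo_height_mm=0.3,
            noise_sigma=0.0,
        )
        defaults.update(overrides)
        return SceneParams(**defaults)

    return make


def make_translating_sequence(
    n_steps: int,
    shift_per_step=(0, 2),
    shape=(160, 260),
    noise_sigma: float = 0.0,
    seed: int = 0,
):
    """Frames of a rough random texture rigidly rolled by an integer shift.

    Returns (frames, true_positions) where true_positions is the per-step
    (row, col) of a tile that starts at (40, 40).
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.1, 1.0, shape)
    frames = []
    positions = []
    for i in range(n_steps):
        dr, dc = shift_per_step[0] * i, shift_per_step[1] * i
        frame = np.roll(np.roll(base, dr, axis=0), dc, axis=1)
        if noise_sigma > 0:
            frame = np.clip(frame + rng.normal(0, noise_sigma, shape), 0, None)
        frames.append(frame)
        positions.append((40 + dr, 40 + dc))
    return frames, np.asarray(positions)


def brute_force_match(template, tile_size, frame, scan_window):
    """Independent double-loop reference for the tile matcher."""
    h, w = tile_size
    top, left, H, W = scan_window
    top0, left0 = max(top, 0), max(left, 0)
    bot = min(top + H, frame.shape[0])
    right = min(left + W, frame.shape[1])
    best_score, best_pos = -np.inf, None
    tvec = np.asarray(template, dtype=float).ravel()
    for r in range(top0, bot - h + 1):
        for c in range(left0, right - w + 1):
            cand = np.asarray(frame[r : r + h, c : c + w], dtype=float).ravel()
            norm = np.linalg.norm(cand)
            if norm == 0:
                continue
            score = float(tvec @ cand) / norm
            if score > best_score:
                best_score, best_pos = score, (r, c)
    return best_pos, best_score
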