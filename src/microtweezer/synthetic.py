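"""Ground-truthed synthetic compression experiments.

A stepped compression of an elastic specimen between two cantilevers is
solved analytically as four Hookean springs in series: fixed-arm
cantilever (kc1), two equal sample half-springs (ks each), moving-arm
cantilever (kc2).  For cumulative actuator closure Delta the common force
and the element compressions are

    F   = Delta / (cos(theta1)/kc1 + cos(theta2)/kc2 + 2/ks)
    dc_i = F * cos(theta_i) / kc_i,   ds_i = F / ks,   Ds = 2 F / ks

so that Delta = dc1 + dc2 + Ds holds exactly at every step.  In the
canonical scene theta = 0 and dc_i = F / kc_i.

Each solved step is rendered as a microscope-like frame: dark background,
two bright beams whose tips sit at the ground-truth contact positions, a
two-lobe elliptical "embryo" whose width shrinks by Ds, a high-contrast
speckle texture rigidly attached to every tracked landmark (so 50x50
tiles are non-degenerate), a saturated tip blob marking each contact, and
additive Gaussian noise.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["SceneParams", "CompressionScene", "solve_compression", "render_frame",
           "simulate_scene", "make_experiment"]

LANDMARKS = ("fixed_tip", "contact_left", "contact_right", "angle_a", "angle_b")


@dataclass(frozen=True)
class SceneParams:
    """Study conditions of one synthetic compression experiment.

    Defaults reproduce the experimental regime the package targets: two
    calibrated 1.48e-2 N/m cantilevers, a specimen spring in the measured
    embryo range, 30 actuation steps of 0.01 mm, a 5x objective on a
    964x1288 CCD (0.002 mm/px), and 2%-of-range sensor noise.
    """

    seed: int  # mandatory for reproducibility
    kc1: float = 1.48e-2  # N/m
    kc2: float = 1.48e-2  # N/m
    ks: float = 5.9e-3  # N/m, per-side sample spring
    steps: int = 30
    closure_per_step_mm: float = 0.01
    scale_mm_per_px: float = 0.002
    frame_shape: Tuple[int, int] = (964, 1288)
    theta1: float = 0.0
    theta2: float = 0.0
    profile: str = "linear"  # or "saturating" (piezo-like)
    embryo_width_mm: float = 0.7
    embryo_height_mm: float = 0.6
    texture_amplitude: float = 0.35
    noise_sigma: float = 0.02  # fraction of full dynamic range

    def __post_init__(self) -> None:
        if min(self.kc1, self.kc2, self.ks) <= 0:
            raise ValueError("spring constants must be > 0")
        if self.steps < 2:
            raise ValueError("need >= 2 steps")
        if self.scale_mm_per_px <= 0:
            raise ValueError("scale must be > 0")
        if self.profile not in ("linear", "saturating"):
            raise ValueError(f"unknown closure profile {self.profile!r}")


@dataclass
class CompressionScene:
    """A fully solved and rendered synthetic experiment."""

    params: SceneParams
    truth: pd.DataFrame  # step, delta_mm, force_N, dc1_mm, dc2_mm, ds1_mm, ds2_mm, Ds_mm
    landmarks: Dict[str, np.ndarray]  # name -> (steps, 2) float (row, col) px
    frames: np.ndarray  # (steps, H, W) uint8
    initial_tiles: Dict[str, Tuple[int, int]]  # tile top-left for 50x50 tiles


def _closure_profile(params: SceneParams) -> np.ndarray:
    i = np.arange(params.steps, dtype=float)
    total = params.closure_per_step_mm * (params.steps - 1)
    if params.profile == "linear":
        return params.closure_per_step_mm * i
    x = i / (params.steps - 1)
    return total * (1.0 - np.exp(-3.0 * x)) / (1.0 - math.exp(-3.0))


def solve_compression(params: SceneParams) -> pd.DataFrame:
    """Exact per-step series-spring ground truth for the scene."""
    delta = _closure_profile(params)  # mm
    c1 = math.cos(params.theta1) / params.kc1
    c2 = math.cos(params.theta2) / params.kc2
    compliance = c1 + c2 + 2.0 / params.ks
    force = delta * 1e-3 / compliance  # N (delta mm -> m)
    dc1 = force * c1 * 1e3  # mm
    dc2 = force * c2 * 1e3
    ds = force / params.ks * 1e3
    return pd.DataFrame(
        {
            "step": np.arange(params.steps),
            "delta_mm": delta,
            "force_N": force,
            "dc1_mm": dc1,
            "dc2_mm": dc2,
            "ds1_mm": ds,
            "ds2_mm": ds,
            "Ds_mm": 2.0 * ds,
        }
    )


def _landmark_positions(params: SceneParams, truth: pd.DataFrame) -> Dict[str, np.ndarray]:
    """Ground-truth (row, col) pixel path of every tracked landmark.

    The fixed arm is on the left: its tip recoils by dc1 along the axis.
    The moving arm advances by (Delta - dc2).  Angle landmarks sit on the
    fixed beam's centreline, offset by its tilt.
    """
    H, W = params.frame_shape
    y0, cx = H / 2.0, W / 2.0
    half_w = params.embryo_width_mm / params.scale_mm_per_px / 2.0
    xL0, xR0 = cx - half_w, cx + half_w
    scale = params.scale_mm_per_px
    xL = xL0 - truth["dc1_mm"].to_numpy() / scale
    xR = xR0 - (truth["delta_mm"].to_numpy() - truth["dc2_mm"].to_numpy()) / scale
    t1 = math.tan(params.theta1)
    n = params.steps
    const = lambda v: np.full(n, float(v))
    marks = {
        "fixed_tip": np.column_stack([const(y0 - 60), xL + t1 * 60]),
        "contact_left": np.column_stack([const(y0), xL]),
        "contact_right": np.column_stack([const(y0), xR]),
        "angle_a": np.column_stack([const(y0 - 160), xL + t1 * 160]),
        "angle_b": np.column_stack([const(y0 - 40), xL + t1 * 40]),
    }
    for name, pos in marks.items():
        if (pos[:, 0] < 0).any() or (pos[:, 0] >= H).any() or (pos[:, 1] < 0).any() or (
            pos[:, 1] >= W
        ).any():
            raise ValueError(f"landmark {name!r} leaves the frame; shrink the closure or scene")
    return marks


def _texture_params(seed: int, index: int, n_components: int = 40):
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 10_000 + index])
    amp = rng.uniform(0.5, 1.0, n_components)
    amp /= np.sqrt(np.sum(amp**2) / 2.0)  # roughly unit-RMS texture
    freq = rng.uniform(0.03, 0.35, (n_components, 2)) * rng.choice([-1, 1], (n_components, 2))
    phase = rng.uniform(0, 2 * math.pi, n_components)
    return amp, freq, phase


def _texture_value(xx: np.ndarray, yy: np.ndarray, tex) -> np.ndarray:
    amp, freq, phase = tex
    out = np.zeros_like(xx, dtype=float)
    for a, (fx, fy), ph in zip(amp, freq, phase):
        out += a * np.sin(2 * math.pi * (fx * xx + fy * yy) + ph)
    return out


def render_frame(
    params: SceneParams,
    truth: pd.DataFrame,
    landmarks: Dict[str, np.ndarray],
    textures,
    step: int,
) -> np.ndarray:
    """Render one step of the scene as a uint8 frame (deterministic)."""
    H, W = params.frame_shape
    y0 = H / 2.0
    scale = params.scale_mm_per_px
    img = np.full((H, W), 0.08, dtype=np.float64)
    yy, xx = np.mgrid[0:H, 0:W].astype(float)

    xL = landmarks["contact_left"][step, 1]
    xR = landmarks["contact_right"][step, 1]
    t1, t2 = math.tan(params.theta1), math.tan(params.theta2)

    # beams: left from the top down to its tip at y0, right from y0 down
    left_beam = (yy <= y0) & (np.abs(xx - (xL + t1 * (y0 - yy))) <= 4.0)
    right_beam = (yy >= y0) & (np.abs(xx - (xR - t2 * (yy - y0))) <= 4.0)
    img[left_beam | right_beam] = 0.70

    # embryo: ellipse squeezed to the current contact separation, plus yolk lobe
    cx_e = (xL + xR) / 2.0
    semi_x = max((xR - xL) / 2.0, 1.0)
    semi_y = params.embryo_height_mm / scale / 2.0
    body = ((xx - cx_e) / semi_x) ** 2 + ((yy - y0) / semi_y) ** 2 <= 1.0
    img[body] = 0.40
    yolk_r = 0.6 * min(semi_x, semi_y)
    yolk = (xx - cx_e + 0.2 * semi_x) ** 2 + (yy - y0) ** 2 <= yolk_r**2
    img[yolk] = 0.55

    # speckle texture rigidly attached to each landmark (continuous shift)
    pad = 45
    for i, name in enumerate(LANDMARKS):
        r0, c0 = landmarks[name][0]
        r, c = landmarks[name][step]
        uy, ux = r - r0, c - c0
        ri, ci = int(round(r)), int(round(c))
        rlo, rhi = max(ri - pad, 0), min(ri + pad + 1, H)
        clo, chi = max(ci - pad, 0), min(ci + pad + 1, W)
        if rlo >= rhi or clo >= chi:
            continue
        py, px = np.mgrid[rlo:rhi, clo:chi].astype(float)
        window = np.exp(-(((px - c) ** 2 + (py - r) ** 2) / (2 * 22.0**2)))
        tex = _texture_value(px - ux, py - uy, textures[i])
        img[rlo:rhi, clo:chi] += params.texture_amplitude * window * tex

    # cap the textured image, then stamp saturated tip blobs so the
    # brightest pixel of each beam end marks the ground-truth contact
    np.clip(img, 0.0, 0.92, out=img)
    for name in ("contact_left", "contact_right"):
        r, c = landmarks[name][step]
        ri, ci = int(round(r)), int(round(c))
        rlo, rhi = max(ri - 6, 0), min(ri + 7, H)
        clo, chi = max(ci - 6, 0), min(ci + 7, W)
        py, px = np.mgrid[rlo:rhi, clo:chi].astype(float)
        # amplitude saturates only pixels within ~0.7 px of the true tip,
        # so the brightest rendered pixel marks the ground-truth contact
        blob = 1.12 * np.exp(-(((px - c) ** 2 + (py - r) ** 2) / (2 * 1.5**2)))
        img[rlo:rhi, clo:chi] = np.maximum(img[rlo:rhi, clo:chi], blob)

    if params.noise_sigma > 0:
        rng = np.random.default_rng([params.seed & 0x7FFFFFFF, step])
        img = img + rng.normal(0.0, params.noise_sigma, img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    return np.round(img * 255.0).astype(np.uint8)


def simulate_scene(params: SceneParams) -> CompressionScene:
    """Solve the mechanics and render every frame of the scene."""
    truth = solve_compression(params)
    landmarks = _landmark_positions(params, truth)
    textures = [_texture_params(params.seed, i) for i in range(len(LANDMARKS))]
    frames = np.stack(
        [render_frame(params, truth, landmarks, textures, s) for s in range(params.steps)]
    )
    tiles = {
        name: (int(round(pos[0, 0])) - 25, int(round(pos[0, 1])) - 25)
        for name, pos in landmarks.items()
    }
    return CompressionScene(params, truth, landmarks, frames, tiles)


def make_experiment(params: SceneParams, outdir: Optional[str] = None) -> CompressionScene:
    """Simulate a scene and optionally write frames + ground truth to disk.

    Writes ``frames.tif`` (multi-page TIFF), ``ground_truth.csv`` (per-step
    mechanics and landmark pixel positions) and ``params.yaml``; two runs
    with the same seed produce identical files.
    """
    scene = simulate_scene(params)
    if outdir is not None:
        import tifffile
        import yaml

        os.makedirs(outdir, exist_ok=True)
        tifffile.imwrite(os.path.join(outdir, "frames.tif"), scene.frames)
        gt = scene.truth.copy()
        for name, pos in scene.landmarks.items():
            gt[f"{name}_row_px"] = pos[:, 0]
            gt[f"{name}_col_px"] = pos[:, 1]
        gt.to_csv(os.path.join(outdir, "ground_truth.csv"), index=False)
        cfg = asdict(scene.params)
        cfg["frame_shape"] = list(cfg["frame_shape"])
        cfg["initial_tiles"] = {k: list(v) for k, v in scene.initial_tiles.items()}
        with open(os.path.join(outdir, "params.yaml"), "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
    return scene
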