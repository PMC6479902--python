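"""Inverse estimation of compartment Young's moduli from measured strains.

The specimen is reduced to two elastic compartments (body and yolk)
loaded in parallel between the tweezer tips.  The surrogate forward
model assumes a uniform contact pressure: the applied force partitions
over the compartments in proportion to their contact areas, so each
compartment sees the same stress sigma = F / (A_body + A_yolk) and
responds with its own linear strain

    strain_i = sigma / E_i .

This closure keeps every physical property expected of the compression
(equal moduli and geometry give equal strains; a rigid compartment's
strain vanishes; strain falls monotonically with its own modulus) while
making the two-strain, two-modulus inverse problem well posed.  It is a
deliberately simple stand-in for a full finite-element forward model;
the optimizer below is written against the generic interface
``parameters -> strains`` so a higher-fidelity model can be plugged in
without touching it.

The inverse fit is coordinate-wise hill climbing in log-modulus space:
try +/- one step on each parameter, accept the best improving move,
shrink all steps when nothing improves, stop when the steps fall below
tolerance.  Deterministic, derivative-free, and fully trace-logged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

MM = 1e-3

__all__ = [
    "TwoCompartmentModel",
    "HillClimbConfig",
    "HillClimbResult",
    "ModulusEstimate",
    "forward_strains",
    "hill_climb",
    "estimate_moduli",
]


@dataclass(frozen=True)
class TwoCompartmentModel:
    """Geometry and moduli of the body/yolk surrogate (lengths in mm).

    ``*_contact_height_mm`` are the vertical extents of the cantilever
    contact patches on each compartment; ``depth_mm`` is the effective
    out-of-plane load-bearing depth shared by both.  ``*_length_mm`` are
    the compartment extents along the compression axis, used only to
    convert strains back to absolute displacements.
    """

    E_body: float  # Pa
    E_yolk: float  # Pa
    body_contact_height_mm: float = 0.2
    yolk_contact_height_mm: float = 0.35
    depth_mm: float = 0.5
    body_length_mm: float = 0.9
    yolk_length_mm: float = 0.6

    def __post_init__(self) -> None:
        vals = (
            self.E_body,
            self.E_yolk,
            self.body_contact_height_mm,
            self.yolk_contact_height_mm,
            self.depth_mm,
            self.body_length_mm,
            self.yolk_length_mm,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all moduli and dimensions must be > 0")

    @property
    def contact_areas_m2(self) -> Tuple[float, float]:
        return (
            self.body_contact_height_mm * MM * self.depth_mm * MM,
            self.yolk_contact_height_mm * MM * self.depth_mm * MM,
        )


def forward_strains(model: TwoCompartmentModel, force_n: float) -> Tuple[float, float]:
    """Predicted (body, yolk) compressive strains under a tip force, uniform pressure."""
    if force_n <= 0:
        raise ValueError("force must be > 0")
    a_body, a_yolk = model.contact_areas_m2
    sigma = force_n / (a_body + a_yolk)
    return sigma / model.E_body, sigma / model.E_yolk


@dataclass(frozen=True)
class HillClimbConfig:
    initial: Tuple[float, ...]
    steps: Tuple[float, ...]
    shrink: float = 0.5
    max_iter: int = 10_000
    tolerance: float = 1e-8  # stop when every step is below this
    bounds: Optional[Tuple[Tuple[float, float], ...]] = None

    def __post_init__(self) -> None:
        if len(self.initial) != len(self.steps):
            raise ValueError("initial point and steps must have equal length")
        if any(s <= 0 for s in self.steps):
            raise ValueError("step sizes must be > 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if not (0 < self.shrink < 1):
            raise ValueError("shrink factor must be in (0, 1)")


@dataclass
class HillClimbResult:
    x: np.ndarray
    fun: float
    n_iter: int
    n_eval: int
    n_accepted: int
    converged: bool
    trace: List[Tuple[np.ndarray, float]] = field(default_factory=list)


def hill_climb(objective: Callable[[np.ndarray], float], config: HillClimbConfig) -> HillClimbResult:
    """Deterministic coordinate-wise hill climbing (descent on ``objective``).

    Each iteration evaluates +/- the current step along every coordinate
    (clipped to bounds) and accepts the single best improving move; when
    no move improves, all steps shrink by ``config.shrink``.  The trace of
    accepted states is non-increasing by construction.
    """
    x = np.asarray(config.initial, dtype=float).copy()
    steps = np.asarray(config.steps, dtype=float).copy()
    bounds = config.bounds
    f = float(objective(x))
    if not math.isfinite(f):
        raise ValueError("objective is not finite at the initial point")
    trace = [(x.copy(), f)]
    n_eval, n_accepted, it = 1, 0, 0
    converged = False
    while it < config.max_iter:
        it += 1
        best_f, best_x = f, None
        for j in range(x.size):
            for sign in (+1.0, -1.0):
                cand = x.copy()
                cand[j] += sign * steps[j]
                if bounds is not None:
                    lo, hi = bounds[j]
                    cand[j] = min(max(cand[j], lo), hi)
                fc = float(objective(cand))
                n_eval += 1
                if math.isfinite(fc) and fc < best_f:
                    best_f, best_x = fc, cand
        if best_x is None:
            steps *= config.shrink
            if np.all(steps < config.tolerance):
                converged = True
                break
        else:
            x, f = best_x, best_f
            n_accepted += 1
            trace.append((x.copy(), f))
    return HillClimbResult(x, f, it, n_eval, n_accepted, converged, trace)


@dataclass
class ModulusEstimate:
    E_body: float
    E_yolk: float
    fitted_strains: Tuple[float, float]
    residual: float
    result: HillClimbResult


def estimate_moduli(
    measured_strains: Tuple[float, float],
    force_n: float,
    geometry: Optional[TwoCompartmentModel] = None,
    config: Optional[HillClimbConfig] = None,
) -> ModulusEstimate:
    """Fit (E_body, E_yolk) to measured (body, yolk) strains at a known force.

    Minimises the summed squared relative strain mismatch by hill
    climbing in log10-modulus space (positivity and scale balance come
    for free since moduli span decades).  Strains must be physical,
    i.e. in the open interval (0, 1).
    """
    s_body, s_yolk = measured_strains
    if not (0 < s_body < 1 and 0 < s_yolk < 1):
        raise ValueError("measured strains must lie strictly between 0 and 1")
    if force_n <= 0:
        raise ValueError("force must be > 0")
    geom = geometry if geometry is not None else TwoCompartmentModel(E_body=100.0, E_yolk=100.0)

    def objective(z: np.ndarray) -> float:
        model = replace(geom, E_body=10.0 ** z[0], E_yolk=10.0 ** z[1])
        p_body, p_yolk = forward_strains(model, force_n)
        return ((p_body - s_body) / s_body) ** 2 + ((p_yolk - s_yolk) / s_yolk) ** 2

    if config is None:
        config = HillClimbConfig(
            initial=(2.0, 2.0),  # 100 Pa starting point
            steps=(0.5, 0.5),  # half a decade
            shrink=0.5,
            max_iter=5_000,
            tolerance=1e-7,
            bounds=((-3.0, 12.0), (-3.0, 12.0)),
        )
    res = hill_climb(objective, config)
    e_body, e_yolk = 10.0 ** res.x[0], 10.0 ** res.x[1]
    fitted = forward_strains(replace(geom, E_body=e_body, E_yolk=e_yolk), force_n)
    return ModulusEstimate(e_body, e_yolk, fitted, res.fun, res)
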