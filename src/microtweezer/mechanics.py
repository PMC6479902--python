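"""Beam mechanics for cantilever-based force sensing.

A pair of compliant rectangular cantilevers squeezes a specimen; the
specimen is modelled quasi-statically as two equal Hookean springs of
constant ``ks`` in series (one per contact side).  Force balance at the
fixed-arm tip reads ``F * cos(theta1) = kc1 * dc1`` where ``dc1`` is the
tip deflection and ``theta1`` the angle between the cantilever and the
sample tangent.  With the total indentation ``Ds = ds1 + ds2`` the sample
spring constant follows as

    ks = 2 * kc1 * dc1 / (Ds * cos(theta1)).

Unit convention
---------------
All public functions accept lengths in **millimetres** (the natural unit
at the microscope) and convert once to SI internally; forces are newtons,
spring constants N/m, moduli Pa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

MM = 1e-3  # millimetres -> metres

__all__ = [
    "CantileverGeometry",
    "CantileverSpec",
    "DeflectionRecord",
    "StiffnessResult",
    "LinearFit",
    "InvalidGeometryError",
    "DegenerateContactError",
    "spring_constant",
    "youngs_modulus",
    "force_from_deflection",
    "sample_stiffness",
    "strain",
    "polyline_length",
    "linear_fit",
]


class InvalidGeometryError(ValueError):
    """A cantilever dimension or spring constant is non-positive."""


class DegenerateContactError(ValueError):
    """Contact angle at or beyond 90 degrees: no axial force transmission."""


@dataclass(frozen=True)
class CantileverGeometry:
    """Rectangular-section cantilever dimensions, in mm.

    ``length`` is the free beam length L, ``width`` W and ``thickness`` T
    the cross-section.  Euler-Bernoulli beam theory (second moment
    I = W*T^3/12, tip load) degrades for stubby beams, so L/T < 5 raises
    a warning rather than an error.
    """

    length: float
    width: float
    thickness: float

    def __post_init__(self) -> None:
        for name in ("length", "width", "thickness"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.length / self.thickness < 5:
            warnings.warn(
                f"L/T = {self.length / self.thickness:.2f} < 5: slender-beam "
                "theory is a poor approximation for this geometry",
                stacklevel=2,
            )


@dataclass(frozen=True)
class CantileverSpec:
    """A calibrated cantilever: geometry plus spring constant.

    ``youngs_modulus_pa`` is optional; when both it and the geometry are
    present the pair must be consistent with the rectangular-beam formula
    k = E*W*T^3/(4*L^3) within ``rtol`` (defaults allow for the printed
    rounding of calibration constants).
    """

    spring_constant: float  # N/m
    geometry: Optional[CantileverGeometry] = None
    youngs_modulus_pa: Optional[float] = None
    rtol: float = 0.01

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise InvalidGeometryError("spring constant must be > 0")
        if self.geometry is not None and self.youngs_modulus_pa is not None:
            k_pred = spring_constant(self.geometry, self.youngs_modulus_pa)
            if not math.isclose(k_pred, self.spring_constant, rel_tol=self.rtol):
                raise InvalidGeometryError(
                    f"spring constant {self.spring_constant:g} N/m inconsistent with "
                    f"E={self.youngs_modulus_pa:g} Pa and geometry (predicts {k_pred:g} N/m)"
                )

    @classmethod
    def from_modulus(cls, geometry: CantileverGeometry, youngs_modulus_pa: float) -> "CantileverSpec":
        return cls(
            spring_constant=spring_constant(geometry, youngs_modulus_pa),
            geometry=geometry,
            youngs_modulus_pa=youngs_modulus_pa,
        )


@dataclass(frozen=True)
class DeflectionRecord:
    """Per-step mechanical state of one compression step (lengths in mm).

    ``dc1``/``theta1`` belong to the fixed arm (always measured);
    ``dc2``/``theta2`` to the moving arm (optional, enables a two-sided
    consistency check).  ``Ds`` is the total sample indentation ds1+ds2.
    """

    step: int
    dc1_mm: float
    Ds_mm: float
    theta1: float = 0.0
    dc2_mm: Optional[float] = None
    theta2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dc1_mm < 0:
            raise ValueError("dc1 must be >= 0")
        if self.Ds_mm < 0:
            raise ValueError("Ds must be >= 0")
        for th in (self.theta1, self.theta2):
            if th is not None and not (0 <= th < math.pi / 2):
                raise DegenerateContactError(f"theta = {th!r} outside [0, pi/2)")


@dataclass(frozen=True)
class StiffnessResult:
    """Sample stiffness at one step: force (N), ks (N/m), quality flag."""

    step: int
    force_n: float
    ks: float
    usable: bool = True
    flag: str = ""
    side_discrepancy: Optional[float] = None  # |ks1-ks2|/ks1 when both arms given


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    through_origin: bool
    n: int = 0
    residual_ss: float = float("nan")


def spring_constant(geom: CantileverGeometry, youngs_modulus_pa: float) -> float:
    """Tip spring constant of a rectangular cantilever, N/m.

    k = E * W * T^3 / (4 * L^3), from k = 3 E I / L^3 with I = W T^3 / 12.
    """
    if youngs_modulus_pa < 0:
        raise InvalidGeometryError("Young's modulus must be >= 0")
    L, W, T = geom.length * MM, geom.width * MM, geom.thickness * MM
    return youngs_modulus_pa * W * T**3 / (4.0 * L**3)


def youngs_modulus(geom: CantileverGeometry, k: float) -> float:
    """Invert the rectangular-beam formula: E = 4 k L^3 / (W T^3), Pa."""
    if k <= 0:
        raise InvalidGeometryError("spring constant must be > 0")
    L, W, T = geom.length * MM, geom.width * MM, geom.thickness * MM
    return 4.0 * k * L**3 / (W * T**3)


def force_from_deflection(spec: CantileverSpec, dc_mm: float, theta: float = 0.0) -> float:
    """Contact force from tip deflection: F = k * dc / cos(theta), N."""
    if dc_mm < 0:
        raise ValueError("deflection must be >= 0")
    if not (0 <= theta < math.pi / 2):
        raise DegenerateContactError(f"theta = {theta!r} outside [0, pi/2)")
    return spec.spring_constant * dc_mm * MM / math.cos(theta)


def sample_stiffness(
    record: DeflectionRecord,
    spec1: CantileverSpec,
    spec2: Optional[CantileverSpec] = None,
    ds_floor_mm: float = 0.0,
) -> StiffnessResult:
    """Sample spring constant at one step: ks = 2 kc1 dc1 / (Ds cos theta1).

    Steps with ``Ds`` at zero or below ``ds_floor_mm`` (e.g. one
    pixel-equivalent) are returned flagged rather than raising, so a
    series survives pre-contact or degenerate steps.  When the moving
    arm's deflection and angle are supplied together with ``spec2``, the
    relative discrepancy between the two single-arm estimates is reported
    as a quality metric.
    """
    F = force_from_deflection(spec1, record.dc1_mm, record.theta1)
    if record.Ds_mm <= max(ds_floor_mm, 0.0):
        return StiffnessResult(
            step=record.step,
            force_n=F,
            ks=float("nan"),
            usable=False,
            flag="indentation-below-floor" if record.Ds_mm > 0 else "zero-indentation",
        )
    ks1 = 2.0 * F / (record.Ds_mm * MM)
    discrepancy = None
    if spec2 is not None and record.dc2_mm is not None:
        theta2 = record.theta2 if record.theta2 is not None else 0.0
        F2 = force_from_deflection(spec2, record.dc2_mm, theta2)
        ks2 = 2.0 * F2 / (record.Ds_mm * MM)
        discrepancy = abs(ks1 - ks2) / ks1 if ks1 > 0 else float("inf")
    return StiffnessResult(
        step=record.step, force_n=F, ks=ks1, usable=True, side_discrepancy=discrepancy
    )


def strain(length_now_mm: float, length_ref_mm: float) -> float:
    """Engineering strain, compression positive.

    strain = (L_ref - L_now) / L_ref; negative values indicate extension.
    """
    if length_ref_mm <= 0:
        raise ValueError("reference length must be > 0")
    return (length_ref_mm - length_now_mm) / length_ref_mm


def polyline_length(points: Sequence[Sequence[float]]) -> float:
    """Total Euclidean length of an ordered 2-D polyline (same unit in/out)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need an (n>=2, 2) array of points")
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def linear_fit(x: Sequence[float], y: Sequence[float], through_origin: bool = False) -> LinearFit:
    """Ordinary least squares line fit.

    With an intercept, ``r_squared`` is the usual centred coefficient of
    determination.  The through-origin variant minimises sum (y - a*x)^2
    and reports the uncentred R^2 = 1 - SS_res / sum(y^2), the standard
    convention for no-intercept regression.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if through_origin:
        if x.size < 1:
            raise ValueError("need >= 1 point for a through-origin fit")
        sxx = float(np.dot(x, x))
        if sxx == 0.0:
            raise ValueError("singular fit: all x are zero")
        slope = float(np.dot(x, y)) / sxx
        resid = y - slope * x
        ss_res = float(np.dot(resid, resid))
        ss_tot = float(np.dot(y, y))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return LinearFit(slope, 0.0, r2, True, n=x.size, residual_ss=ss_res)
    if x.size < 2:
        raise ValueError("need >= 2 points for a fit with intercept")
    if np.ptp(x) == 0.0:
        raise ValueError("singular fit: all x equal")
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - (slope * x + intercept)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LinearFit(float(slope), float(intercept), r2, False, n=x.size, residual_ss=ss_res)
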