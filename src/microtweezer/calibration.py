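"""Two-stage cantilever calibration.

Stage 1 calibrates a stiff reference cantilever against a load cell:
paired (deflection, force) steps are fit through the origin, F = kref*d.
Stage 2 transfers that stiffness tip-to-tip to a soft test cantilever:
both beams share the contact force, so kref*delta_ref = kc*delta_c and
kc = kref * (delta_ref / delta_c) at every step.  The returned kc is the
through-origin regression of kref*delta_ref on delta_c, which equals the
ratio form exactly on noise-free data and is robust to small-deflection
steps otherwise; per-step ratios are reported for dispersion diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .mechanics import CantileverSpec, LinearFit, linear_fit, youngs_modulus

MM = 1e-3

__all__ = [
    "ReferenceFit",
    "TransferResult",
    "BatchSummary",
    "fit_reference_stiffness",
    "transfer_stiffness",
    "summarize_batch",
]


@dataclass(frozen=True)
class ReferenceFit:
    """Load-cell calibration result: spring constant in N/m plus fit quality."""

    kref: float
    r_squared: float
    n: int
    fit: LinearFit


@dataclass(frozen=True)
class TransferResult:
    """Tip-to-tip transfer result: kc in N/m, per-step ratio estimates, excluded steps."""

    kc: float
    per_step_kc: np.ndarray
    r_squared: float
    n_used: int
    n_excluded: int


@dataclass(frozen=True)
class BatchSummary:
    """Mean/SD of measured dimensions, spring constants and moduli over a batch."""

    n: int
    mean_length_mm: float
    mean_width_mm: float
    mean_thickness_mm: float
    sd_length_mm: float
    sd_width_mm: float
    sd_thickness_mm: float
    mean_k: float
    sd_k: float
    mean_modulus_pa: float
    sd_modulus_pa: float


def fit_reference_stiffness(
    deflections_mm: Sequence[float], forces_n: Sequence[float]
) -> ReferenceFit:
    """Through-origin fit of load-cell force against reference deflection.

    Returns kref in N/m (input deflections are mm, forces N).
    """
    d = np.asarray(deflections_mm, dtype=float)
    f = np.asarray(forces_n, dtype=float)
    if d.size < 2:
        raise ValueError("need >= 2 paired calibration points")
    fit = linear_fit(d * MM, f, through_origin=True)
    return ReferenceFit(kref=fit.slope, r_squared=fit.r_squared, n=d.size, fit=fit)


def transfer_stiffness(
    kref: float, delta_ref_mm: Sequence[float], delta_c_mm: Sequence[float]
) -> TransferResult:
    """Transfer reference stiffness to the test cantilever: kc = kref * dref/dc.

    Steps with zero test-cantilever deflection are excluded with a warning
    (the ratio is undefined there); if all steps are excluded an error is
    raised.  Units cancel in the ratio, so kc carries kref's unit (N/m).
    """
    dref = np.asarray(delta_ref_mm, dtype=float)
    dc = np.asarray(delta_c_mm, dtype=float)
    if dref.shape != dc.shape:
        raise ValueError("delta_ref and delta_c must have equal length")
    keep = dc > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} step(s) with delta_c = 0", stacklevel=2)
    if not keep.any():
        raise ValueError("all steps have delta_c = 0; cannot transfer stiffness")
    dref, dc = dref[keep], dc[keep]
    fit = linear_fit(dc, kref * dref, through_origin=True)
    return TransferResult(
        kc=fit.slope,
        per_step_kc=kref * dref / dc,
        r_squared=fit.r_squared,
        n_used=int(keep.sum()),
        n_excluded=n_excluded,
    )


def summarize_batch(specs: Sequence[CantileverSpec]) -> BatchSummary:
    """Mean and sample SD (ddof=1) of batch dimensions, k, and per-beam modulus.

    The Young's modulus is computed per cantilever from its own measured
    dimensions and spring constant before averaging; every spec must
    therefore carry a geometry.
    """
    if len(specs) < 2:
        raise ValueError("need >= 2 cantilevers for a batch summary")
    if any(s.geometry is None for s in specs):
        raise ValueError("every spec needs measured dimensions")
    L = np.array([s.geometry.length for s in specs])
    W = np.array([s.geometry.width for s in specs])
    T = np.array([s.geometry.thickness for s in specs])
    k = np.array([s.spring_constant for s in specs])
    E = np.array([youngs_modulus(s.geometry, s.spring_constant) for s in specs])
    sd = lambda a: float(np.std(a, ddof=1))
    return BatchSummary(
        n=len(specs),
        mean_length_mm=float(L.mean()),
        mean_width_mm=float(W.mean()),
        mean_thickness_mm=float(T.mean()),
        sd_length_mm=sd(L),
        sd_width_mm=sd(W),
        sd_thickness_mm=sd(T),
        mean_k=float(k.mean()),
        sd_k=sd(k),
        mean_modulus_pa=float(E.mean()),
        sd_modulus_pa=sd(E),
    )
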