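"""Parametric static plan-dose surrogate.

The clinical reference for this pipeline is a two-arc VMAT lung-SBRT
plan (60 Gy in 5 fractions prescribed to the ITV) computed by a
commercial treatment planning system.  That optimizer and its
collapsed-cone dose calculation are far outside desk scale, so this
module replaces the plan dose with an analytic field that reproduces
the plan's defining *properties* on the phantom grid:

* the minimum ITV dose equals the prescription,
* the prescription sits at a chosen isodose level (70/80/90%) of the
  maximum dose, which is reached a few mm inside the ITV surface,
* outside the ITV the dose falls off with a finite Gaussian penumbra.

In terms of the signed Euclidean distance s to the ITV surface
(negative inside, boundary voxels at s = 0):

    dose(s <= 0) = D_max * (L + (1 - L) * min(1, -s / core_depth))
    dose(s > 0)  = Rx * exp(-s^2 / (2 * sigma_pen^2))

with D_max = Rx / L for prescription Rx and isodose level L.  All
downstream numbers therefore reproduce the qualitative structure of a
TPS-computed plan, not its printed dosimetric values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import SI_RANGE_MM, PhantomGrid, VolumeMask, build_itv

__all__ = ["PlanSpec", "DoseField", "plan_dose", "robust_plan_dose", "save_dose_nifti"]


@dataclass(frozen=True)
class PlanSpec:
    """Prescription and shape parameters of the dose surrogate.

    ``core_depth_mm`` is the depth inside the ITV at which the dose
    plateaus at its maximum; ``penumbra_sigma_mm`` the Gaussian
    fall-off scale outside (the 80%-to-20% penumbra width is ~1.67
    sigma).  Defaults are generic lung-SBRT values.
    """

    prescription_gy: float = 60.0
    n_fractions: int = 5
    isodose_level: float = 0.80
    core_depth_mm: float = 5.0
    penumbra_sigma_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription_gy must be > 0")
        if not 0 < self.isodose_level < 1:
            raise ValueError("isodose_level must lie in (0, 1)")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.core_depth_mm <= 0:
            raise ValueError("core_depth_mm must be > 0")
        if self.penumbra_sigma_mm <= 0:
            raise ValueError("penumbra_sigma_mm must be > 0")

    @property
    def max_dose_gy(self) -> float:
        return self.prescription_gy / self.isodose_level

    @property
    def dose_per_fraction_gy(self) -> float:
        return self.prescription_gy / self.n_fractions


@dataclass(frozen=True)
class DoseField:
    """A static 3-D dose (Gy) on the phantom grid, tied to its plan
    spec and the ITV it was shaped around."""

    dose_gy: np.ndarray
    grid: PhantomGrid
    spec: PlanSpec
    itv: VolumeMask

    def __post_init__(self) -> None:
        if self.dose_gy.shape != self.grid.shape:
            raise ValueError("dose array shape must match the grid")


def signed_surface_distance_mm(mask: VolumeMask) -> np.ndarray:
    """Signed distance to the mask surface, negative inside.

    Discretization convention: mask voxels adjacent to the outside are
    *on* the surface (s = 0); outside voxels start at s = +1 voxel.
    """
    m = mask.mask
    voxel = mask.grid.voxel_mm
    inside = (ndimage.distance_transform_edt(m, sampling=voxel) - voxel)
    outside = ndimage.distance_transform_edt(~m, sampling=voxel)
    return np.where(m, -inside, outside)


def plan_dose(itv: VolumeMask, spec: PlanSpec) -> DoseField:
    """Build the analytic plan-dose surrogate around an ITV.

    By construction the ITV surface receives exactly the prescription,
    the interior ramps linearly over ``core_depth_mm`` to
    ``prescription / isodose_level``, and the exterior falls off as a
    Gaussian of scale ``penumbra_sigma_mm``.
    """
    s = signed_surface_distance_mm(itv)
    level = spec.isodose_level
    d_max = spec.max_dose_gy
    inside = d_max * (level + (1 - level) * np.minimum(1.0, -s / spec.core_depth_mm))
    outside = spec.prescription_gy * np.exp(-(s**2) / (2 * spec.penumbra_sigma_mm**2))
    dose = np.where(itv.mask, inside, outside)
    return DoseField(dose, itv.grid, spec, itv)


def robust_plan_dose(
    traditional_positions_mm,
    pdf_interval_mm: tuple[int, int],
    diameter_cm: float,
    grid: PhantomGrid,
    spec: PlanSpec,
) -> tuple[DoseField, list[int]]:
    """Dose surrogate of the pdf-extended robust plan.

    The traditional phase positions are augmented with every integer
    mm of the position-probability coverage interval, the ITV rebuilt
    over the extended set, and the same dose model applied.  Returns
    the dose field together with the extended position set.
    """
    lo, hi = (int(pdf_interval_mm[0]), int(pdf_interval_mm[1]))
    if lo > hi:
        raise ValueError("pdf interval must satisfy lo <= hi")
    clamp_lo, clamp_hi = SI_RANGE_MM
    if lo < clamp_lo or hi > clamp_hi:
        warnings.warn(
            f"coverage interval ({lo}, {hi}) mm exceeds the phantom range "
            f"[{clamp_lo}, {clamp_hi}] mm; clamping",
            stacklevel=2,
        )
        lo, hi = max(lo, clamp_lo), min(hi, clamp_hi)
    extended = sorted({int(p) for p in traditional_positions_mm} | set(range(lo, hi + 1)))
    itv = build_itv(grid, diameter_cm, extended)
    field = plan_dose(itv, spec)
    return field, extended


def save_dose_nifti(field: DoseField, path) -> None:
    """Export a dose field as a NIfTI volume (requires nibabel)."""
    import nibabel as nib

    affine = np.diag([field.grid.voxel_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(field.dose_gy.astype(np.float32), affine), str(path))
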