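"""Digital lung-tumor phantom.

A voxelized geometric phantom: a spherical gross target volume (GTV)
of diameter 2, 3 or 4 cm on an isotropic 1-mm grid, displaced along
the superior--inferior (SI) axis at integer-mm offsets in [-15, 15].
The phase-sorted sample bank holds one entry per (diameter, SI offset)
— 3 x 31 = 93 samples — each tagged with the breathing phase its
offset maps to.  The internal target volume (ITV) is the union of the
GTV masks over a set of phase positions.

The clinical CT background (lung parenchyma, diaphragm) is not
reproduced: the downstream dose surrogate is purely geometric, so
tissue heterogeneity plays no role here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhantomGrid",
    "TargetGeometry",
    "VolumeMask",
    "SampleImage",
    "make_gtv_mask",
    "map_si_to_phase",
    "build_itv",
    "build_sample_bank",
    "save_mask_nifti",
]

SI_RANGE_MM = (-15, 15)


@dataclass(frozen=True)
class PhantomGrid:
    """Isotropic voxel grid; the reference sphere center sits at the
    mm-coordinate origin, in the middle of the grid."""

    shape: tuple[int, int, int] = (120, 120, 120)
    voxel_mm: float = 1.0
    si_axis: int = 2

    def __post_init__(self) -> None:
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be > 0")
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError("shape must be three positive integers")
        if self.si_axis not in (0, 1, 2):
            raise ValueError("si_axis must be 0, 1 or 2")
        si_extent = self.shape[self.si_axis] * self.voxel_mm
        if si_extent < 70:
            raise ValueError(
                "SI extent must be >= 70 mm (largest sphere plus +/-15 mm travel), "
                f"got {si_extent:g} mm"
            )

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis, centered on 0."""
        n = self.shape[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.voxel_mm


@dataclass(frozen=True)
class TargetGeometry:
    """A spherical GTV at an integer SI offset from the reference."""

    diameter_cm: float
    si_offset_mm: int = 0

    def __post_init__(self) -> None:
        if self.diameter_cm <= 0:
            raise ValueError("diameter_cm must be > 0")
        if int(self.si_offset_mm) != self.si_offset_mm:
            raise ValueError("si_offset_mm must be an integer millimetre")
        lo, hi = SI_RANGE_MM
        if not lo <= self.si_offset_mm <= hi:
            raise ValueError(f"si_offset_mm must lie in [{lo}, {hi}]")

    @property
    def radius_mm(self) -> float:
        return self.diameter_cm * 10.0 / 2.0


@dataclass(frozen=True)
class VolumeMask:
    """A boolean field on the phantom grid with a role tag."""

    mask: np.ndarray
    grid: PhantomGrid
    role: str = "GTV"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.shape != self.grid.shape:
            raise ValueError("mask shape must match the grid")
        if not m.any():
            raise ValueError("mask is empty")

    @property
    def volume_mm3(self) -> float:
        return float(self.mask.sum()) * self.grid.voxel_mm**3


def make_gtv_mask(grid: PhantomGrid, geom: TargetGeometry) -> VolumeMask:
    """Voxelize the sphere: a voxel belongs to the GTV iff its center
    lies within the sphere radius of the (SI-shifted) sphere center."""
    coords = [grid.axis_coords_mm(a) for a in range(3)]
    center = [0.0, 0.0, 0.0]
    center[grid.si_axis] = float(geom.si_offset_mm)
    lo = center[grid.si_axis] - geom.radius_mm
    hi = center[grid.si_axis] + geom.radius_mm
    si = coords[grid.si_axis]
    half = grid.voxel_mm / 2.0
    if lo < si[0] - half or hi > si[-1] + half:
        raise ValueError(
            f"sphere (diameter {geom.diameter_cm} cm at SI {geom.si_offset_mm:+d} mm) "
            "exceeds the grid SI extent"
        )
    x, y, z = np.meshgrid(*coords, indexing="ij", sparse=True)
    r2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return VolumeMask(r2 <= geom.radius_mm**2, grid, role="GTV")


def map_si_to_phase(i: int) -> int:
    """Breathing phase assigned to a sphere at SI position ``i`` mm.

    P = floor((i + 15) / 3) for i = -15..14, and P = 9 for i = 15, so
    the ten phases tile the 31 integer positions in bins of three
    (phase 9 additionally absorbing i = 15).
    """
    if int(i) != i:
        raise ValueError("SI position must be an integer millimetre")
    lo, hi = SI_RANGE_MM
    if not lo <= i <= hi:
        raise ValueError(f"SI position must lie in [{lo}, {hi}], got {i}")
    if i == hi:
        return 9
    return int((int(i) + 15) // 3)


def build_itv(
    grid: PhantomGrid, diameter_cm: float, positions_mm
) -> VolumeMask:
    """ITV = union of the phase GTV masks over the given SI positions."""
    positions = sorted({int(p) for p in np.asarray(list(positions_mm)).ravel()})
    if not positions:
        raise ValueError("positions_mm must be a nonempty set of integer mm")
    union = np.zeros(grid.shape, dtype=bool)
    for p in positions:
        union |= make_gtv_mask(grid, TargetGeometry(diameter_cm, p)).mask
    return VolumeMask(union, grid, role="ITV")


@dataclass(frozen=True)
class SampleImage:
    """One phase-tagged entry of the phantom sample bank."""

    geometry: TargetGeometry
    phase_index: int


def build_sample_bank(
    grid: PhantomGrid | None = None,
    diameters_cm=(2.0, 3.0, 4.0),
    positions_mm=range(SI_RANGE_MM[0], SI_RANGE_MM[1] + 1),
) -> list[SampleImage]:
    """Enumerate the phantom sample bank.

    With the defaults: 31 SI positions x 3 diameters = 93 samples, each
    tagged with its breathing phase.  Masks are voxelized on demand via
    :func:`make_gtv_mask`; the bank itself is pure geometry.
    """
    if grid is None:
        grid = PhantomGrid()
    bank = []
    for d in diameters_cm:
        for i in positions_mm:
            bank.append(SampleImage(TargetGeometry(d, int(i)), map_si_to_phase(int(i))))
    return bank


def save_mask_nifti(mask: VolumeMask, path) -> None:
    """Export a mask as a NIfTI volume (requires nibabel)."""
    import nibabel as nib

    affine = np.diag([mask.grid.voxel_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), str(path))
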