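"""Synthetic CT phantoms: a water-equivalent body in air with material inserts.

Voxels take the HU of the innermost region containing their center; inserts
are applied in list order, so a later insert wins where two overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec, ScalarVolume, VolumeKind
from .materials import MATERIAL_HU

__all__ = ["Insert", "BodySpec", "PhantomSpec", "PhantomSpecError", "build_phantom"]


class PhantomSpecError(ValueError):
    """Invalid phantom specification (e.g. insert outside the body)."""


@dataclass(frozen=True)
class Insert:
    """One material insert.

    ``size_mm`` semantics by shape: box -> full edge lengths (lx, ly, lz);
    sphere -> (radius, -, -); cylinder (axis along z) -> (radius, -, length).
    """

    shape: str  # box | cylinder | sphere
    position_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]
    material: str

    def __post_init__(self):
        if self.shape not in ("box", "cylinder", "sphere"):
            raise PhantomSpecError(f"unknown insert shape {self.shape!r}")
        if self.material not in MATERIAL_HU:
            raise PhantomSpecError(f"unknown material {self.material!r}")

    def mask(self, grid: GridSpec) -> np.ndarray:
        x = grid.axis_coords(0)[:, None, None] - self.position_mm[0]
        y = grid.axis_coords(1)[None, :, None] - self.position_mm[1]
        z = grid.axis_coords(2)[None, None, :] - self.position_mm[2]
        if self.shape == "box":
            hx, hy, hz = (s / 2.0 for s in self.size_mm)
            return (np.abs(x) <= hx) & (np.abs(y) <= hy) & (np.abs(z) <= hz)
        if self.shape == "sphere":
            r = self.size_mm[0]
            return x**2 + y**2 + z**2 <= r**2
        r, _, length = self.size_mm
        return (x**2 + y**2 <= r**2) & (np.abs(z) <= length / 2.0)


@dataclass(frozen=True)
class BodySpec:
    """Water-equivalent outer body: an ellipsoid or box of 0 HU in air."""

    shape: str = "ellipsoid"  # ellipsoid | box
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    size_mm: tuple[float, float, float] = (110.0, 90.0, 1000.0)  # full extents

    def mask(self, grid: GridSpec) -> np.ndarray:
        x = grid.axis_coords(0)[:, None, None] - self.center_mm[0]
        y = grid.axis_coords(1)[None, :, None] - self.center_mm[1]
        z = grid.axis_coords(2)[None, None, :] - self.center_mm[2]
        hx, hy, hz = (s / 2.0 for s in self.size_mm)
        if self.shape == "box":
            return (np.abs(x) <= hx) & (np.abs(y) <= hy) & (np.abs(z) <= hz)
        if self.shape == "ellipsoid":
            return (x / hx) ** 2 + (y / hy) ** 2 + (z / hz) ** 2 <= 1.0
        raise PhantomSpecError(f"unknown body shape {self.shape!r}")


@dataclass(frozen=True)
class PhantomSpec:
    grid: GridSpec
    body: BodySpec = BodySpec()
    inserts: tuple[Insert, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "inserts", tuple(self.inserts))


def build_phantom(spec: PhantomSpec) -> ScalarVolume:
    """Rasterize the phantom to a CT volume (HU by voxel-center membership)."""
    body_mask = spec.body.mask(spec.grid)
    hu = np.full(spec.grid.shape, MATERIAL_HU["air"], dtype=np.float32)
    hu[body_mask] = MATERIAL_HU["water"]
    for ins in spec.inserts:
        m = ins.mask(spec.grid)
        if np.any(m & ~body_mask):
            raise PhantomSpecError(
                f"insert {ins.shape} at {ins.position_mm} extends outside the body"
            )
        hu[m] = MATERIAL_HU[ins.material]
    return ScalarVolume(spec.grid, hu, VolumeKind.CT_HU)
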