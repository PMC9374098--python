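"""Core volume data model: grids, scalar volumes, beam geometry, resampling.

All volumes live on axis-aligned, voxel-center-based grids. Arrays are indexed
``values[ix, iy, iz]`` with ``z`` the superior-inferior (slice) axis; the
physical position of index ``(i, j, k)`` is ``origin + index * spacing`` (mm).
Gantry rotations act within the axial (x-y) plane.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "GridSpec",
    "VolumeKind",
    "ScalarVolume",
    "BeamGeometry",
    "GridMismatchError",
    "resample_volume",
    "rotate_axial",
    "fill_value",
]

#: co-registration tolerance in mm
COREG_TOL_MM = 1e-6

#: default working spacing in mm (in-plane 2 mm, slice axis 2.5 mm)
WORKING_SPACING_MM = (2.0, 2.0, 2.5)


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not."""


class VolumeKind(enum.Enum):
    CT_HU = "ct_hu"
    DOSE_GY = "dose_gy"
    RSP = "rsp"
    NORMALIZED = "normalized"


#: out-of-extent fill per volume kind (air for CT, nothing for dose)
_FILL = {
    VolumeKind.CT_HU: -1000.0,
    VolumeKind.DOSE_GY: 0.0,
    VolumeKind.RSP: 0.001,
    VolumeKind.NORMALIZED: 0.0,
}


def fill_value(kind: VolumeKind) -> float:
    return _FILL[kind]


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned voxel grid: shape, spacing (mm) and origin (mm).

    The origin is the physical position of the *center* of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = WORKING_SPACING_MM
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be three integers >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge-to-edge extent covered by the grid."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def center_mm(self) -> tuple[float, float, float]:
        return tuple(
            o + (n - 1) / 2.0 * s
            for o, n, s in zip(self.origin, self.shape, self.spacing)
        )

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis (mm)."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def index_of(self, point_mm) -> np.ndarray:
        """Continuous voxel index of a physical point."""
        p = np.asarray(point_mm, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_grid(self, other: "GridSpec", tol: float = COREG_TOL_MM) -> bool:
        """Co-registration: equal shape, spacing and origin within `tol` mm."""
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )


@dataclass
class ScalarVolume:
    """A 3D scalar field on a :class:`GridSpec`.

    ``values`` is stored as float32 (clinical dose precision); its shape must
    equal ``grid.shape``.
    """

    grid: GridSpec
    values: np.ndarray
    kind: VolumeKind = VolumeKind.DOSE_GY

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if isinstance(self.kind, str):
            self.kind = VolumeKind(self.kind)

    def validate(self) -> None:
        """Check kind-specific value invariants; raises ValueError on breach."""
        if self.kind is VolumeKind.DOSE_GY and self.values.min() < 0:
            raise ValueError("dose values must be non-negative")
        if self.kind is VolumeKind.CT_HU:
            lo, hi = self.values.min(), self.values.max()
            if lo < -1024 or hi > 4000:
                raise ValueError(f"CT values out of [-1024, 4000]: [{lo}, {hi}]")

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.values.copy(), self.kind)

    def with_values(self, values: np.ndarray, kind: VolumeKind | None = None) -> "ScalarVolume":
        return ScalarVolume(self.grid, values, kind or self.kind)

    def require_same_grid(self, other: "ScalarVolume") -> None:
        if not self.grid.same_grid(other.grid):
            raise GridMismatchError(
                f"volumes are not co-registered: {self.grid} vs {other.grid}"
            )


@dataclass(frozen=True)
class BeamGeometry:
    """Treatment-field orientation: gantry/couch angles (deg) and isocenter (mm).

    Angles are stored modulo 360. The default field orientation used throughout
    the conversion pipeline is gantry 270, couch 0. A beam at gantry angle g
    travels along the in-plane unit vector (cos g, sin g, 0).
    """

    gantry_deg: float
    couch_deg: float = 0.0
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "gantry_deg", float(self.gantry_deg) % 360.0)
        object.__setattr__(self, "couch_deg", float(self.couch_deg) % 360.0)
        object.__setattr__(
            self, "isocenter_mm", tuple(float(v) for v in self.isocenter_mm)
        )

    @property
    def direction(self) -> np.ndarray:
        """Unit vector of beam travel in the axial plane."""
        g = math.radians(self.gantry_deg)
        return np.array([math.cos(g), math.sin(g), 0.0])


DEFAULT_GANTRY_DEG = 270.0
DEFAULT_COUCH_DEG = 0.0


def resample_volume(volume: ScalarVolume, target_spacing) -> ScalarVolume:
    """Trilinearly resample a volume to a new spacing over the same extent.

    The output grid covers the same physical (edge-to-edge) extent; its shape
    is ``ceil(extent / target_spacing)`` and voxel centers are re-positioned so
    the first voxel center sits half a new spacing inside the old boundary.
    Out-of-extent samples take the kind's fill value.
    """
    ts = tuple(float(s) for s in target_spacing)
    if len(ts) != 3 or any(s <= 0 for s in ts):
        raise ValueError(f"target spacing must be three positive numbers, got {ts}")
    g = volume.grid
    if all(abs(a - b) < 1e-12 for a, b in zip(ts, g.spacing)):
        return volume.copy()
    extent = g.extent_mm
    new_shape = tuple(int(math.ceil(e / s - 1e-9)) for e, s in zip(extent, ts))
    # boundary of the old grid (half a voxel before the first center)
    boundary = tuple(o - s / 2.0 for o, s in zip(g.origin, g.spacing))
    new_origin = tuple(b + s / 2.0 for b, s in zip(boundary, ts))
    new_grid = GridSpec(new_shape, ts, new_origin)
    # continuous index of each new voxel center in the old grid
    idx = [
        (new_origin[a] + np.arange(new_shape[a]) * ts[a] - g.origin[a]) / g.spacing[a]
        for a in range(3)
    ]
    ii, jj, kk = np.meshgrid(*idx, indexing="ij")
    vals = ndimage.map_coordinates(
        volume.values.astype(np.float64),
        np.stack([ii, jj, kk]),
        order=1,
        mode="constant",
        cval=fill_value(volume.kind),
    )
    return ScalarVolume(new_grid, vals, volume.kind)


def _rot90_ccw(values: np.ndarray, quarter_turns: int) -> np.ndarray:
    """Exact multiple-of-90-degree CCW content rotation in the (x, y) plane.

    A CCW content rotation by 90 deg maps new(x, y) = old(y, -x); for index
    arrays centered at ((n-1)/2, (n-1)/2) this is an index permutation.
    """
    k = quarter_turns % 4
    out = values
    for _ in range(k):
        # new[i, j] = old[j, n-1-i]
        out = out.transpose(1, 0, 2)[::-1, :, :]
    return np.ascontiguousarray(out)


def rotate_axial(
    volume: ScalarVolume,
    angle_deg: float,
    center_mm=None,
    fill: float | None = None,
) -> ScalarVolume:
    """Rotate volume content CCW by `angle_deg` in the axial plane about a point.

    The output grid is the input grid. Exact index permutations are used for
    multiples of 180 deg (and of 90 deg on square-isotropic in-plane grids)
    when the center coincides with the grid center; otherwise cubic-spline
    interpolation with the kind's fill value, clipped to the input's value
    range (sharp dose falloffs lose visibly less to a cubic resampling than to
    a trilinear one).
    """
    g = volume.grid
    if fill is None:
        fill = fill_value(volume.kind)
    if center_mm is None:
        center_mm = g.center_mm
    a = float(angle_deg) % 360.0
    if a == 0.0:
        return volume.copy()

    c_idx = g.index_of(center_mm)
    centered_xy = all(
        abs(c_idx[ax] - (g.shape[ax] - 1) / 2.0) < 1e-9 for ax in (0, 1)
    )
    if centered_xy and a % 90.0 == 0.0:
        q = int(round(a / 90.0)) % 4
        if q % 2 == 0 or (
            g.shape[0] == g.shape[1] and abs(g.spacing[0] - g.spacing[1]) < 1e-12
        ):
            return volume.with_values(_rot90_ccw(volume.values, q))

    # general case: cubic resampling; physically correct for anisotropic
    # in-plane spacing via index <- S^-1 R(-a) S
    th = math.radians(a)
    r = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    s = np.diag(g.spacing[:2])
    m2 = np.linalg.inv(s) @ r.T @ s  # input_index = m2 @ (output_index - c) + c
    mat = np.eye(3)
    mat[:2, :2] = m2
    offset = np.asarray(c_idx) - mat @ np.asarray(c_idx)
    vals = ndimage.affine_transform(
        volume.values.astype(np.float64),
        mat,
        offset=offset,
        order=3,
        mode="constant",
        cval=fill,
    )
    # limit spline overshoot to the input's value range
    lo = min(float(volume.values.min()), fill)
    hi = max(float(volume.values.max()), fill)
    np.clip(vals, lo, hi, out=vals)
    return volume.with_values(vals)
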