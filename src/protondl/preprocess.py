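"""Preprocessing for the conversion model: orientation, normalization, patches.

Every beam is brought to the default field orientation (gantry 270, couch 0)
before the network sees it, so the model only ever learns one beam direction;
the converted dose is rotated back afterwards. Doses are normalized by the
95th percentile of the pencil-beam dose above 5% of its maximum, and CT by a
fixed (-1000, 2000) HU window. The same pencil-beam-derived factor is applied
to the paired reference dose so the pair stays on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beam import UnsupportedGeometryError
from .grid import (
    DEFAULT_COUCH_DEG,
    DEFAULT_GANTRY_DEG,
    BeamGeometry,
    GridSpec,
    ScalarVolume,
    VolumeKind,
    fill_value,
    rotate_axial,
)

__all__ = [
    "CT_WINDOW_HU",
    "DOSE_PERCENTILE",
    "DOSE_FLOOR_FRACTION",
    "NormalizationRecord",
    "UnsupportedGeometryError",
    "rotate_to_default",
    "rotate_back",
    "rotation_canvas",
    "embed_volume",
    "crop_volume",
    "normalize_ct",
    "normalize_dose",
    "denormalize_dose",
    "sample_patch",
    "patch_grid_corners",
    "compose_beams",
]

#: CT normalization window (HU); maps linearly onto [0, 1]
CT_WINDOW_HU = (-1000.0, 2000.0)
#: dose normalization: this percentile ...
DOSE_PERCENTILE = 95.0
#: ... of the voxels above this fraction of the maximum pencil-beam dose
DOSE_FLOOR_FRACTION = 0.05


@dataclass(frozen=True)
class NormalizationRecord:
    """The scale used to normalize a beam's dose pair (for inversion later)."""

    scale: float

    def __post_init__(self):
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError(f"normalization scale must be positive, got {self.scale}")


def _require_couch_zero(geometry: BeamGeometry) -> None:
    if geometry.couch_deg % 360.0 != DEFAULT_COUCH_DEG:
        raise UnsupportedGeometryError(
            f"only couch {DEFAULT_COUCH_DEG:g} is supported, got {geometry.couch_deg:g}"
        )


def rotation_canvas(grid: GridSpec, center_mm) -> GridSpec:
    """A lattice-aligned enlargement of ``grid`` closed under in-plane rotation.

    The canvas extends the grid's own voxel lattice far enough that any
    in-plane rotation about ``center_mm`` keeps every original voxel inside it
    (no content is clipped away by the rotation).
    """
    c_idx = grid.index_of(center_mm)
    lo = [0, 0, 0]
    hi = [n - 1 for n in grid.shape]
    # largest in-plane distance (in mm) from the center to a grid corner
    r_mm = 0.0
    for i in (0, grid.shape[0] - 1):
        for j in (0, grid.shape[1] - 1):
            dx = (i - c_idx[0]) * grid.spacing[0]
            dy = (j - c_idx[1]) * grid.spacing[1]
            r_mm = max(r_mm, float(np.hypot(dx, dy)))
    for ax in (0, 1):
        r_vox = r_mm / grid.spacing[ax]
        lo[ax] = min(0, int(np.floor(c_idx[ax] - r_vox)) - 1)
        hi[ax] = max(grid.shape[ax] - 1, int(np.ceil(c_idx[ax] + r_vox)) + 1)
    shape = tuple(h - l + 1 for l, h in zip(lo, hi))
    origin = tuple(
        o + l * s for o, l, s in zip(grid.origin, lo, grid.spacing)
    )
    return GridSpec(shape, grid.spacing, origin)


def embed_volume(volume: ScalarVolume, canvas: GridSpec) -> ScalarVolume:
    """Place a volume into a lattice-aligned super-grid (exact index copy)."""
    start = _lattice_offset(canvas, volume.grid)
    vals = np.full(canvas.shape, fill_value(volume.kind), dtype=np.float32)
    sl = tuple(slice(s, s + n) for s, n in zip(start, volume.grid.shape))
    vals[sl] = volume.values
    return ScalarVolume(canvas, vals, volume.kind)


def crop_volume(volume: ScalarVolume, target: GridSpec) -> ScalarVolume:
    """Inverse of :func:`embed_volume`: extract a lattice-aligned sub-grid."""
    start = _lattice_offset(volume.grid, target)
    sl = tuple(slice(s, s + n) for s, n in zip(start, target.shape))
    return ScalarVolume(target, volume.values[sl], volume.kind)


def _lattice_offset(outer: GridSpec, inner: GridSpec) -> tuple[int, int, int]:
    if any(abs(a - b) > 1e-9 for a, b in zip(outer.spacing, inner.spacing)):
        raise ValueError("grids must share the same spacing")
    start = []
    for ax in range(3):
        off = (inner.origin[ax] - outer.origin[ax]) / outer.spacing[ax]
        k = int(round(off))
        if abs(off - k) > 1e-6 or k < 0 or k + inner.shape[ax] > outer.shape[ax]:
            raise ValueError("grids are not lattice-aligned or do not nest")
        start.append(k)
    return tuple(start)


def rotate_to_default(volume: ScalarVolume, geometry: BeamGeometry) -> ScalarVolume:
    """Rotate content so the beam lies at the default orientation (gantry 270).

    The rotation is counter-clockwise by ``(270 - gantry)`` degrees about the
    beam isocenter, performed on an enlarged lattice-aligned canvas so no
    content is rotated out of the volume; the result lives on that canvas
    grid. Only couch 0 is supported.
    """
    _require_couch_zero(geometry)
    angle = (DEFAULT_GANTRY_DEG - geometry.gantry_deg) % 360.0
    canvas = rotation_canvas(volume.grid, geometry.isocenter_mm)
    embedded = embed_volume(volume, canvas)
    return rotate_axial(embedded, angle, center_mm=geometry.isocenter_mm)


def rotate_back(
    volume: ScalarVolume, geometry: BeamGeometry, target_grid: GridSpec | None = None
) -> ScalarVolume:
    """Inverse of :func:`rotate_to_default` for the same geometry.

    Pass the original ``target_grid`` to crop the rotation canvas back down to
    the native grid.
    """
    _require_couch_zero(geometry)
    angle = (geometry.gantry_deg - DEFAULT_GANTRY_DEG) % 360.0
    rotated = rotate_axial(volume, angle, center_mm=geometry.isocenter_mm)
    if target_grid is None:
        return rotated
    return crop_volume(rotated, target_grid)


def normalize_ct(ct: ScalarVolume, window_hu=CT_WINDOW_HU) -> ScalarVolume:
    """Map CT values linearly from ``window_hu`` onto [0, 1], clipped."""
    if ct.kind is not VolumeKind.CT_HU:
        raise ValueError(f"expected a CT_HU volume, got {ct.kind}")
    lo, hi = (float(w) for w in window_hu)
    if hi <= lo:
        raise ValueError(f"invalid CT window {window_hu}")
    vals = np.clip((ct.values.astype(np.float64) - lo) / (hi - lo), 0.0, 1.0)
    return ScalarVolume(ct.grid, vals, VolumeKind.NORMALIZED)


def dose_normalization_scale(pb_dose: ScalarVolume) -> NormalizationRecord:
    """Normalization scale from a pencil-beam dose.

    The scale is the 95th percentile of the dose over voxels exceeding 5% of
    the maximum pencil-beam dose (so the near-zero background does not drag
    the percentile down).
    """
    vals = pb_dose.values.astype(np.float64)
    peak = float(vals.max())
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero dose")
    selected = vals[vals > DOSE_FLOOR_FRACTION * peak]
    scale = float(np.percentile(selected, DOSE_PERCENTILE))
    return NormalizationRecord(scale=scale)


def normalize_dose(
    dose: ScalarVolume, record: NormalizationRecord | None = None
) -> tuple[ScalarVolume, NormalizationRecord]:
    """Divide a dose by the normalization scale.

    With ``record=None`` the scale is computed from ``dose`` itself (the
    pencil-beam case); pass the pencil beam's record to put the paired
    reference dose on the same scale.
    """
    if record is None:
        record = dose_normalization_scale(dose)
    vals = dose.values.astype(np.float64) / record.scale
    return ScalarVolume(dose.grid, vals, VolumeKind.NORMALIZED), record


def denormalize_dose(volume: ScalarVolume, record: NormalizationRecord) -> ScalarVolume:
    """Invert :func:`normalize_dose` back to physical dose (Gy)."""
    vals = np.clip(volume.values.astype(np.float64), 0.0, None) * record.scale
    return ScalarVolume(volume.grid, vals, VolumeKind.DOSE_GY)


def _extract_block(
    values: np.ndarray, corner: tuple[int, int, int], size: tuple[int, int, int], fill: float
) -> np.ndarray:
    """Block ``values[corner : corner+size]`` with out-of-array voxels filled."""
    out = np.full(size, fill, dtype=values.dtype)
    src = []
    dst = []
    for ax in range(3):
        lo = corner[ax]
        hi = corner[ax] + size[ax]
        s_lo, s_hi = max(lo, 0), min(hi, values.shape[ax])
        if s_lo >= s_hi:
            return out
        src.append(slice(s_lo, s_hi))
        dst.append(slice(s_lo - lo, s_hi - lo))
    out[tuple(dst)] = values[tuple(src)]
    return out


def sample_patch(
    volumes: list[ScalarVolume],
    corner: tuple[int, int, int],
    patch_shape: tuple[int, int, int],
) -> list[np.ndarray]:
    """Extract the same patch from co-registered volumes, padding with fills.

    The corner is a voxel index and may be negative or extend past the array;
    out-of-volume voxels take each volume kind's fill value.
    """
    base = volumes[0]
    for v in volumes[1:]:
        base.require_same_grid(v)
    return [
        _extract_block(v.values, tuple(corner), tuple(patch_shape), np.float32(fill_value(v.kind)))
        for v in volumes
    ]


def dose_bounding_box(
    dose: ScalarVolume, floor_fraction: float = DOSE_FLOOR_FRACTION
) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """Inclusive index bounding box of voxels above ``floor_fraction * max``."""
    mask = dose.values > floor_fraction * float(dose.values.max())
    if not mask.any():
        raise ValueError("dose has no voxels above the floor fraction")
    idx = np.nonzero(mask)
    lo = tuple(int(i.min()) for i in idx)
    hi = tuple(int(i.max()) for i in idx)
    return lo, hi


def random_patch_corner(
    rng: np.random.Generator,
    dose: ScalarVolume,
    patch_shape: tuple[int, int, int],
    floor_fraction: float = DOSE_FLOOR_FRACTION,
) -> tuple[int, int, int]:
    """Random patch corner guaranteed to cover part of the treated region.

    A voxel is drawn uniformly from the region above ``floor_fraction`` of the
    maximum dose, and the patch is placed uniformly at random among all patch
    positions containing that voxel. Patches therefore always include treated
    voxels, with coverage concentrated where dose actually is.
    """
    mask = dose.values > floor_fraction * float(dose.values.max())
    if not mask.any():
        raise ValueError("dose has no voxels above the floor fraction")
    flat = rng.integers(0, int(mask.sum()))
    idx = np.argwhere(mask)[flat]
    corner = []
    for ax in range(3):
        offset = int(rng.integers(0, patch_shape[ax]))
        corner.append(int(idx[ax]) - offset)
    return tuple(corner)


def patch_grid_corners(
    shape: tuple[int, int, int],
    patch_shape: tuple[int, int, int],
    overlap_fraction: float = 0.5,
) -> list[tuple[int, int, int]]:
    """Sliding-window corners covering ``shape`` with the given overlap.

    Corners are clipped so patches stay inside the volume where possible
    (patches larger than the volume get a single centered corner).
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError(f"overlap fraction must be in [0, 1), got {overlap_fraction}")
    axes = []
    for ax in range(3):
        n, p = shape[ax], patch_shape[ax]
        if p >= n:
            axes.append([-(p - n) // 2])
            continue
        step = max(1, int(round(p * (1.0 - overlap_fraction))))
        starts = list(range(0, n - p, step)) + [n - p]
        axes.append(sorted(set(starts)))
    return [(i, j, k) for i in axes[0] for j in axes[1] for k in axes[2]]


def compose_beams(doses: list[ScalarVolume]) -> ScalarVolume:
    """Sum per-beam doses on a common grid into a composite plan dose."""
    if not doses:
        raise ValueError("need at least one beam dose")
    base = doses[0]
    total = np.zeros(base.grid.shape, dtype=np.float64)
    for d in doses:
        base.require_same_grid(d)
        if d.kind is not VolumeKind.DOSE_GY:
            raise ValueError(f"expected DOSE_GY volumes, got {d.kind}")
        total += d.values
    return ScalarVolume(base.grid, total, VolumeKind.DOSE_GY)
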