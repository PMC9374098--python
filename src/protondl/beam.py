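"""Proton beam model and the paired dose engines.

Two deterministic dose engines share one field decomposition and one
parametric depth-dose curve but differ exactly where pencil-beam (PB)
algorithms and Monte Carlo (MC) differ in practice:

* :func:`pb_dose` ray-traces water-equivalent path length (WEPL) only along
  each pencil's central axis and spreads the deposited dose laterally with a
  Gaussian whose width grows with *geometric* depth. Heterogeneity off the
  pencil axis is invisible to it (the PB approximation: the medium is assumed
  laterally infinite and homogeneous around each axis).
* :func:`pseudo_mc_dose` transports the same field as a fluence distribution
  marched layer by layer along the beam axis on a lateral lattice at least
  twice as fine as the pencil lattice. Every transported fluence element
  accumulates the WEPL of the material it actually traverses (so lateral
  heterogeneity shifts the local range), and the lateral spreading is a
  conservative diffusion whose coefficient is weighted by the local relative
  stopping power (scatter grows faster through high-RSP material). Because
  fluence that drifts across an interface carries its upstream WEPL with it,
  the engine produces the interface range-mixing a pencil superposition
  cannot. The result is renormalized to the PB integral dose of the beam.

In homogeneous media the two constructions coincide; at density interfaces
they diverge through range shifts and lateral dose distortion, which is the
training signal for the conversion model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import nnls

from .grid import BeamGeometry, GridSpec, ScalarVolume, VolumeKind, rotate_axial
from .materials import DEFAULT_TABLE, MaterialTable, hu_to_rsp

__all__ = [
    "BeamSpec",
    "RayProfile",
    "depth_dose",
    "wepl_raytrace",
    "pb_dose",
    "pseudo_mc_dose",
    "UnsupportedGeometryError",
]

#: peak-to-entrance ratio of the pristine Bragg curve
PEAK_TO_ENTRANCE = 3.5
#: distal-falloff width as a fraction of range
DISTAL_SIGMA_FRACTION = 0.012
#: proximal-shoulder width as a fraction of range
PROXIMAL_SIGMA_FRACTION = 0.07
#: lateral-spread growth per unit depth (multiple Coulomb scattering analogue)
SCATTER_GROWTH = 0.02
#: RSP below which a voxel counts as "outside the body" for depth bookkeeping
BODY_RSP_THRESHOLD = 0.05

DEFAULT_PB_PITCH_MM = (2.0, 2.5)
DEFAULT_MC_PITCH_MM = (1.0, 1.25)


class UnsupportedGeometryError(ValueError):
    """Beam geometry the engines/pipeline do not support (nonzero couch)."""


def _pristine_peak(wepl_mm: np.ndarray, range_mm: float) -> np.ndarray:
    """Parametric pristine Bragg curve, peak value 1 at ``wepl == range``.

    A flat entrance plateau at 1/3.5 rises through a Gaussian shoulder to the
    peak; beyond the peak the dose falls as a Gaussian of width
    0.012 * range and is cut to zero past five widths.
    """
    w = np.asarray(wepl_mm, dtype=float)
    entrance = 1.0 / PEAK_TO_ENTRANCE
    sig_d = DISTAL_SIGMA_FRACTION * range_mm
    sig_p = PROXIMAL_SIGMA_FRACTION * range_mm
    proximal = entrance + (1.0 - entrance) * np.exp(-0.5 * ((w - range_mm) / sig_p) ** 2)
    distal = np.exp(-0.5 * ((w - range_mm) / sig_d) ** 2)
    out = np.where(w <= range_mm, proximal, distal)
    out = np.where(w > range_mm + 5.0 * sig_d, 0.0, out)
    return out


def _sobp_components(range_mm: float, mod_width_mm: float):
    """Ranges and least-squares weights flattening the spread-out peak.

    Pristine peaks with ranges uniformly spaced over [R - mod, R] are combined;
    non-negative weights are fit so the summed curve is 1 over the modulated
    plateau.
    """
    n = max(4, int(math.ceil(mod_width_mm / 2.0)) + 1)
    ranges = np.linspace(range_mm - mod_width_mm, range_mm, n)
    w_grid = np.arange(range_mm - mod_width_mm, range_mm + 0.25, 0.25)
    a = np.stack([_pristine_peak(w_grid, r) for r in ranges], axis=1)
    weights, _ = nnls(a, np.ones_like(w_grid))
    return ranges, weights


@dataclass(frozen=True)
class BeamSpec:
    """One treatment field: geometry plus range/modulation/lateral parameters.

    ``field_size_mm`` is the (in-plane lateral, slice-axis) aperture;
    ``nominal_range_mm`` is the water-equivalent range R of the distal peak;
    ``mod_width_mm`` > 0 spreads the peak over [R - mod, R];
    ``entrance_sigma_mm`` is the initial lateral Gaussian width.
    """

    geometry: BeamGeometry
    field_size_mm: tuple[float, float] = (40.0, 25.0)
    nominal_range_mm: float = 60.0
    mod_width_mm: float = 0.0
    entrance_sigma_mm: float = 4.0
    weight: float = 1.0

    def __post_init__(self):
        if self.nominal_range_mm <= 0:
            raise ValueError("nominal_range_mm must be positive")
        if not (0.0 <= self.mod_width_mm <= self.nominal_range_mm):
            raise ValueError("mod_width_mm must lie in [0, nominal_range_mm]")
        if self.mod_width_mm > 0:
            ranges, weights = _sobp_components(self.nominal_range_mm, self.mod_width_mm)
        else:
            ranges, weights = np.array([self.nominal_range_mm]), np.array([1.0])
        object.__setattr__(self, "_sobp_ranges", ranges)
        object.__setattr__(self, "_sobp_weights", weights)
        # antiderivative of the depth-dose curve, for within-voxel averaging
        r = self.nominal_range_mm
        w_grid = np.arange(0.0, r + 6.0 * DISTAL_SIGMA_FRACTION * r + 2.0, 0.05)
        dd = np.zeros_like(w_grid)
        for rr, cc in zip(ranges, weights):
            if cc > 0:
                dd += cc * _pristine_peak(w_grid, rr)
        integral = np.concatenate([[0.0], np.cumsum((dd[1:] + dd[:-1]) / 2.0) * 0.05])
        object.__setattr__(self, "_bp_wgrid", w_grid)
        object.__setattr__(self, "_bp_integral", integral)

    @property
    def sobp_weights(self) -> np.ndarray:
        return self._sobp_weights

    def scaled(self, factor: float) -> "BeamSpec":
        return BeamSpec(
            self.geometry,
            self.field_size_mm,
            self.nominal_range_mm,
            self.mod_width_mm,
            self.entrance_sigma_mm,
            self.weight * factor,
        )


def mean_depth_dose(wepl_in_mm, wepl_out_mm, beam: BeamSpec) -> np.ndarray:
    """Average of the depth-dose curve over a WEPL interval.

    Computed from the precomputed antiderivative, so narrow Bragg-peak
    structure inside one voxel is integrated rather than point-sampled.
    """
    w0 = np.asarray(wepl_in_mm, dtype=float)
    w1 = np.asarray(wepl_out_mm, dtype=float)
    i0 = np.interp(w0, beam._bp_wgrid, beam._bp_integral)
    i1 = np.interp(w1, beam._bp_wgrid, beam._bp_integral)
    dw = w1 - w0
    safe = dw > 1e-9
    out = np.where(safe, (i1 - i0) / np.where(safe, dw, 1.0), depth_dose(np.maximum(w0, 0.0), beam))
    return out


def depth_dose(wepl_mm, beam: BeamSpec) -> np.ndarray:
    """Relative central-axis dose at water-equivalent depth ``wepl_mm``."""
    w = np.asarray(wepl_mm, dtype=float)
    if np.any(w < 0):
        raise ValueError("wepl must be non-negative")
    out = np.zeros_like(w)
    for r, c in zip(beam._sobp_ranges, beam._sobp_weights):
        if c > 0:
            out = out + c * _pristine_peak(w, r)
    return out


@dataclass(frozen=True)
class RayProfile:
    """Cumulative WEPL sampled along a ray (distances from the entry point)."""

    distance_mm: np.ndarray
    wepl_mm: np.ndarray

    @property
    def empty(self) -> bool:
        return self.distance_mm.size == 0

    def wepl_at(self, distance_mm: float) -> float:
        return float(np.interp(distance_mm, self.distance_mm, self.wepl_mm))


def wepl_raytrace(
    rsp: ScalarVolume,
    entry_point_mm,
    direction,
    step_mm: float = 0.5,
) -> RayProfile:
    """Step-wise cumulative WEPL along a straight ray through an RSP volume.

    WEPL(t) approximates the path integral of RSP from the entry point to
    distance t by midpoint accumulation; the profile is monotone
    non-decreasing. A ray that never intersects the grid yields an empty
    profile.
    """
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if not np.isclose(norm, 1.0, atol=1e-6):
        raise ValueError("direction must be a unit vector")
    p0 = np.asarray(entry_point_mm, dtype=float)
    g = rsp.grid
    lo = np.asarray(g.origin) - np.asarray(g.spacing) / 2.0
    hi = lo + np.asarray(g.extent_mm)
    # slab intersection of the ray with the grid bounding box
    tmin, tmax = 0.0, np.inf
    for a in range(3):
        if abs(d[a]) < 1e-12:
            if not (lo[a] <= p0[a] <= hi[a]):
                return RayProfile(np.empty(0), np.empty(0))
        else:
            t1 = (lo[a] - p0[a]) / d[a]
            t2 = (hi[a] - p0[a]) / d[a]
            tmin = max(tmin, min(t1, t2))
            tmax = min(tmax, max(t1, t2))
    if tmax <= tmin:
        return RayProfile(np.empty(0), np.empty(0))
    t = np.arange(tmin + step_mm / 2.0, tmax, step_mm)
    if t.size == 0:
        return RayProfile(np.empty(0), np.empty(0))
    pts = p0[None, :] + t[:, None] * d[None, :]
    idx = (pts - np.asarray(g.origin)) / np.asarray(g.spacing)
    vals = ndimage.map_coordinates(
        rsp.values.astype(np.float64), idx.T, order=1, mode="nearest"
    )
    wepl = np.cumsum(vals) * step_mm
    return RayProfile(t - tmin, wepl)


# ------------------------------------------------------------------ engines


def _ray_offsets(field_extent: float, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    """Ray-center offsets covering [-f/2, f/2] at `pitch`, with cell-overlap weights."""
    half = field_extent / 2.0
    n = int(math.ceil(field_extent / pitch))
    centers = (np.arange(n) - (n - 1) / 2.0) * pitch
    lo = np.maximum(centers - pitch / 2.0, -half)
    hi = np.minimum(centers + pitch / 2.0, half)
    w = np.clip(hi - lo, 0.0, None)
    keep = w > 0
    return centers[keep], w[keep]


def _pb_canonical(
    rsp_c: np.ndarray,
    grid: GridSpec,
    beam: BeamSpec,
    pitch_mm: tuple[float, float],
) -> np.ndarray:
    """Pencil-beam dose in the canonical frame (beam travels along +x).

    Each pencil ray-traces only its own central axis; the deposited dose is
    spread laterally with a Gaussian whose width grows with geometric depth,
    using the central-axis WEPL everywhere in the footprint.
    """
    nx, ny, nz = grid.shape
    sx, sy, sz = grid.spacing
    iso = np.asarray(beam.geometry.isocenter_mm)

    offs_y, wy = _ray_offsets(beam.field_size_mm[0], pitch_mm[0])
    offs_z, wz = _ray_offsets(beam.field_size_mm[1], pitch_mm[1])
    yc = iso[1] + offs_y
    zc = iso[2] + offs_z
    yy, zz = np.meshgrid(yc, zc, indexing="ij")
    ww = np.outer(wy, wz)
    ray_y = yy.ravel()
    ray_z = zz.ravel()
    ray_w = ww.ravel() * beam.weight
    n_ray = ray_y.size

    # trace all rays in one interpolation call: rsp along x at each (y, z)
    ix = np.arange(nx, dtype=float)
    iy = (ray_y - grid.origin[1]) / sy
    iz = (ray_z - grid.origin[2]) / sz
    coords = np.stack(
        [
            np.broadcast_to(ix, (n_ray, nx)),
            np.broadcast_to(iy[:, None], (n_ray, nx)),
            np.broadcast_to(iz[:, None], (n_ray, nx)),
        ]
    )
    lines = ndimage.map_coordinates(
        rsp_c.astype(np.float64), coords.reshape(3, -1), order=1, mode="nearest"
    ).reshape(n_ray, nx)

    wepl_out = np.cumsum(lines, axis=1) * sx
    wepl_in = wepl_out - lines * sx
    inside = lines > BODY_RSP_THRESHOLD
    depth_geo = np.cumsum(inside, axis=1) * sx

    axis_dose = mean_depth_dose(wepl_in, wepl_out, beam) * ray_w[:, None]
    sigma = np.sqrt(beam.entrance_sigma_mm**2 + (SCATTER_GROWTH * depth_geo) ** 2)

    ygrid = grid.axis_coords(1)
    zgrid = grid.axis_coords(2)
    dose = np.zeros(grid.shape, dtype=np.float64)
    tiny = axis_dose.max() * 1e-4 if axis_dose.size else 0.0
    for r in range(n_ray):
        act = np.nonzero(axis_dose[r] > tiny)[0]
        if act.size == 0:
            continue
        sig = sigma[r, act][:, None]
        gy = np.exp(-0.5 * ((ygrid[None, :] - ray_y[r]) / sig) ** 2)
        gy /= gy.sum(axis=1, keepdims=True)
        gz = np.exp(-0.5 * ((zgrid[None, :] - ray_z[r]) / sig) ** 2)
        gz /= gz.sum(axis=1, keepdims=True)
        dose[act] += axis_dose[r, act, None, None] * gy[:, :, None] * gz[:, None, :]
    return dose


def _diffuse_2d(fields: list[np.ndarray], ds2: np.ndarray, h: tuple[float, float]) -> None:
    """One conservative explicit diffusion step, in place, on each field.

    ``ds2`` is the per-cell added variance (mm^2) for this step; fluxes use
    face-averaged coefficients and no-flux boundaries, so each field's total
    is conserved.
    """
    for axis, hh in enumerate(h):
        c = np.minimum(0.5 * ds2 / hh**2, 0.45)  # explicit-stability guard
        if axis == 0:
            cf = 0.5 * (c[:-1, :] + c[1:, :])
            for f in fields:
                d = cf * (f[1:, :] - f[:-1, :])
                f[:-1, :] += d
                f[1:, :] -= d
        else:
            cf = 0.5 * (c[:, :-1] + c[:, 1:])
            for f in fields:
                d = cf * (f[:, 1:] - f[:, :-1])
                f[:, :-1] += d
                f[:, 1:] -= d


def _box_gauss_profile(coords: np.ndarray, center: float, width: float, sigma: float) -> np.ndarray:
    """Uniform aperture of `width` about `center`, blurred by a Gaussian."""
    from scipy.special import erf

    s = math.sqrt(2.0) * max(sigma, 1e-6)
    return 0.5 * (
        erf((coords - (center - width / 2.0)) / s)
        - erf((coords - (center + width / 2.0)) / s)
    )


def _mc_transport_canonical(
    rsp_c: np.ndarray,
    grid: GridSpec,
    beam: BeamSpec,
    pitch_mm: tuple[float, float],
) -> np.ndarray:
    """Reference dose in the canonical frame by layered fluence transport.

    The lateral fluence F and its carried WEPL (transported as G = F * W) are
    marched layer by layer along +x on a lateral lattice of pitch at most
    ``pitch_mm``. Each layer deposits F times the within-layer mean of the
    depth-dose curve at the locally accumulated WEPL, then F and G diffuse
    with a coefficient proportional to the local stopping power, giving
    in water exactly the quadratic lateral-variance growth the PB engine
    assumes, and more scatter through dense material.
    """
    nx, ny, nz = grid.shape
    sx, sy, sz = grid.spacing
    iso = beam.geometry.isocenter_mm

    fy = max(1, int(math.ceil(sy / pitch_mm[0])))
    fz = max(1, int(math.ceil(sz / pitch_mm[1])))
    hy, hz = sy / fy, sz / fz
    yf = grid.origin[1] - sy / 2.0 + (np.arange(ny * fy) + 0.5) * hy
    zf = grid.origin[2] - sz / 2.0 + (np.arange(nz * fz) + 0.5) * hz

    prof_y = _box_gauss_profile(yf, iso[1], beam.field_size_mm[0], beam.entrance_sigma_mm)
    prof_z = _box_gauss_profile(zf, iso[2], beam.field_size_mm[1], beam.entrance_sigma_mm)
    f_map = beam.weight * np.outer(prof_y, prof_z)
    g_map = np.zeros_like(f_map)  # F * W
    w_map = np.zeros_like(f_map)

    dose = np.zeros(grid.shape, dtype=np.float64)
    for k in range(nx):
        r = np.repeat(np.repeat(rsp_c[k], fy, axis=0), fz, axis=1)
        w_out = w_map + r * sx
        layer = f_map * mean_depth_dose(w_map, w_out, beam)
        dose[k] = layer.reshape(ny, fy, nz, fz).mean(axis=(1, 3))
        w_mid = w_map + 0.5 * r * sx
        ds2 = 2.0 * SCATTER_GROWTH**2 * w_mid * r * sx
        g_map = f_map * w_out
        _diffuse_2d([f_map, g_map], ds2, (hy, hz))
        w_map = g_map / np.maximum(f_map, 1e-12)
    return dose


def _canonicalize(volume: ScalarVolume, geometry: BeamGeometry) -> ScalarVolume:
    """Rotate content so the beam travels along +x (gantry-0 orientation)."""
    return rotate_axial(volume, -geometry.gantry_deg, geometry.isocenter_mm)


def _decanonicalize(volume: ScalarVolume, geometry: BeamGeometry) -> ScalarVolume:
    return rotate_axial(volume, geometry.gantry_deg, geometry.isocenter_mm)


def _check_geometry(beam: BeamSpec) -> None:
    if beam.geometry.couch_deg % 360.0 != 0.0:
        raise UnsupportedGeometryError("nonzero couch angles are not supported")


def pb_dose(
    ct: ScalarVolume,
    beam: BeamSpec,
    table: MaterialTable = DEFAULT_TABLE,
    pencil_pitch_mm: tuple[float, float] = DEFAULT_PB_PITCH_MM,
) -> ScalarVolume:
    """Pencil-beam dose: central-axis WEPL per pencil, geometric-depth scatter."""
    _check_geometry(beam)
    rsp = hu_to_rsp(ct, table)
    rsp_c = _canonicalize(rsp, beam.geometry)
    vals = _pb_canonical(rsp_c.values, ct.grid, beam, pencil_pitch_mm)
    dose_c = ScalarVolume(ct.grid, vals, VolumeKind.DOSE_GY)
    out = _decanonicalize(dose_c, beam.geometry)
    if beam.weight > 0 and out.values.max() <= 0:
        warnings.warn("beam misses the phantom: zero dose returned", stacklevel=2)
    return out


def pseudo_mc_dose(
    ct: ScalarVolume,
    beam: BeamSpec,
    table: MaterialTable = DEFAULT_TABLE,
    subray_pitch_mm: tuple[float, float] = DEFAULT_MC_PITCH_MM,
    pb_reference: ScalarVolume | None = None,
    pencil_pitch_mm: tuple[float, float] = DEFAULT_PB_PITCH_MM,
) -> ScalarVolume:
    """Fluence-transport reference dose: locally accumulated WEPL with
    RSP-weighted lateral scatter and interface range memory.

    The output is renormalized to the integral dose of :func:`pb_dose` for the
    same beam (pass ``pb_reference`` to reuse an already computed PB dose).
    """
    _check_geometry(beam)
    for s, p in zip(subray_pitch_mm, pencil_pitch_mm):
        if s > p / 2.0 + 1e-9:
            raise ValueError("subray pitch must be at most half the pencil pitch")
    rsp = hu_to_rsp(ct, table)
    rsp_c = _canonicalize(rsp, beam.geometry)
    vals = _mc_transport_canonical(rsp_c.values, ct.grid, beam, subray_pitch_mm)
    dose_c = ScalarVolume(ct.grid, vals, VolumeKind.DOSE_GY)
    out = _decanonicalize(dose_c, beam.geometry)
    if pb_reference is None:
        pb_reference = pb_dose(ct, beam, table, pencil_pitch_mm)
    total_pb = float(pb_reference.values.sum())
    total_mc = float(out.values.sum())
    if total_mc > 0 and total_pb > 0:
        out = out.with_values(out.values * (total_pb / total_mc))
    if beam.weight > 0 and out.values.max() <= 0:
        warnings.warn("beam misses the phantom: zero dose returned", stacklevel=2)
    return out
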