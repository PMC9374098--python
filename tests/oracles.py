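"""Independent reference implementations used as test oracles.

These are deliberately naive: the brute-force gamma searches every offset for
every voxel with no sorting, shell grouping or early termination, and builds
its fine sampling of the evaluated dose through scipy interpolation rather
than the production upsampling code.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from protondl.evaluation import GammaCriteria
from protondl.grid import ScalarVolume


def brute_force_gamma(
    reference: ScalarVolume,
    evaluated: ScalarVolume,
    criteria: GammaCriteria,
) -> tuple[np.ndarray, float]:
    """Exhaustive gamma search. Returns (gamma values over mask, passing %)."""
    ref = reference.values.astype(np.float64)
    spacing = reference.grid.spacing
    max_ref = float(ref.max())
    mask = ref > criteria.low_dose_threshold_fraction * max_ref
    dd = criteria.dose_tolerance_fraction * max_ref
    dta2 = criteria.distance_tolerance_mm**2

    # fine sampling lattice: same step rule as production, but values obtained
    # via scipy map_coordinates on the coarse evaluated dose
    target = criteria.distance_tolerance_mm * criteria.search_step_fraction
    factors = tuple(int(math.ceil(s / target)) for s in spacing)
    steps = tuple(s / f for s, f in zip(spacing, factors))
    fine_shape = tuple((n - 1) * f + 1 for n, f in zip(ref.shape, factors))
    coords = np.meshgrid(
        *[np.arange(fs, dtype=np.float64) / f for fs, f in zip(fine_shape, factors)],
        indexing="ij",
    )
    fine = ndimage.map_coordinates(
        evaluated.values.astype(np.float64), np.stack(coords), order=1, mode="nearest"
    )
    fmax = tuple(s - 1 for s in fine.shape)

    radius = criteria.radius_mm
    nmax = [int(math.floor(radius / st)) for st in steps]
    idx = np.nonzero(mask)
    base = [idx[a] * factors[a] for a in range(3)]
    ref_vals = ref[mask]

    # every lattice offset within the search sphere, in raw lexicographic
    # order (no sorting, no pruning); evaluated in vectorized chunks
    grids = np.meshgrid(*[np.arange(-n, n + 1) for n in nmax], indexing="ij")
    all_off = np.stack([g.ravel() for g in grids], axis=1)
    d2_all = ((all_off * np.asarray(steps)) ** 2).sum(axis=1)
    inside = d2_all <= radius**2 + 1e-12
    all_off = all_off[inside]
    d2_all = d2_all[inside]

    fine_flat = np.ascontiguousarray(fine.ravel(), dtype=np.float64)
    stride_y = fine.shape[2]
    stride_x = fine.shape[1] * fine.shape[2]
    gamma2 = np.full(ref_vals.size, np.inf)
    for off, d2 in zip(all_off, d2_all):
        flat = (
            np.clip(base[0] + off[0], 0, fmax[0]) * stride_x
            + np.clip(base[1] + off[1], 0, fmax[1]) * stride_y
            + np.clip(base[2] + off[2], 0, fmax[2])
        )
        dose_term = (fine_flat[flat] - ref_vals) / dd
        np.minimum(gamma2, d2 / dta2 + dose_term * dose_term, out=gamma2)
    gamma_vals = np.sqrt(gamma2)
    passing = 100.0 * float(np.mean(gamma_vals <= 1.0))
    return gamma_vals, passing


def slab_wepl(segments_mm: list[tuple[float, float]]) -> float:
    """Piecewise water-equivalent path length of a ray crossing slabs.

    ``segments_mm`` is a list of (geometric length mm, relative stopping
    power) pairs.
    """
    return float(sum(length * rsp for length, rsp in segments_mm))


def smooth_random_dose(rng: np.random.Generator, shape, smooth_vox=3.0) -> np.ndarray:
    """A positive, smoothly varying random dose field."""
    raw = rng.random(shape)
    sm = ndimage.gaussian_filter(raw, smooth_vox)
    sm -= sm.min()
    m = sm.max()
    return (sm / m if m > 0 else sm) + 0.05


def random_dose_blobs(rng: np.random.Generator, shape, n_blobs=4) -> np.ndarray:
    """A dose-like field: a few smooth high-dose blobs over a low background."""
    vals = np.zeros(shape, dtype=np.float64)
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    for _ in range(n_blobs):
        center = [rng.uniform(0.2 * n, 0.8 * n) for n in shape]
        width = [rng.uniform(0.08 * n, 0.25 * n) for n in shape]
        amp = rng.uniform(0.4, 1.0)
        r2 = sum(((g - c) / w) ** 2 for g, c, w in zip(grids, center, width))
        vals += amp * np.exp(-r2)
    return vals + 0.01


def perturbed_pair(rng: np.random.Generator, grid) -> tuple[ScalarVolume, ScalarVolume]:
    """A reference dose and a realistically perturbed evaluated dose."""
    ref = random_dose_blobs(rng, grid.shape)
    pert = 1.0 + rng.uniform(0.01, 0.06) * ndimage.gaussian_filter(
        rng.standard_normal(grid.shape), rng.uniform(1.5, 3.0)
    )
    shift = [rng.uniform(-1.0, 1.0) / s for s in grid.spacing]
    ev = ndimage.shift(ref * pert, shift, order=1, mode="nearest")
    return (
        ScalarVolume(grid, ref, "dose_gy"),
        ScalarVolume(grid, ev, "dose_gy"),
    )
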