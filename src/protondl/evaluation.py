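"""Dosimetric evaluation: 3D gamma index, masked MSE, DVH, dose-difference
histogram, and the per-case report.

The gamma index of a reference/evaluated dose pair is, per reference voxel,

    gamma(r) = min over r' of sqrt( |r - r'|^2 / dta^2  +  (D_e(r') - D_r(r))^2 / dd^2 )

with distance-to-agreement tolerance ``dta`` (mm) and dose tolerance ``dd``
expressed globally as a fraction of the maximum reference dose. The minimum is
searched over a sub-voxel lattice (step at most dta/3 per axis) within a
sphere of radius ``search_radius_mm``, with the evaluated dose trilinearly
interpolated. Only voxels whose reference dose exceeds the low-dose threshold
(default 10% of the maximum reference dose) are evaluated; a voxel passes if
gamma <= 1. The evaluation is intentionally asymmetric: the reference volume
defines both the mask and the normalization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grid import ScalarVolume, VolumeKind

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "DegenerateInputError",
    "gamma_index_3d",
    "mse_above_threshold",
    "DVHCurve",
    "compute_dvh",
    "DoseDiffHistogram",
    "dose_diff_histogram",
    "evaluate_case",
]


class DegenerateInputError(ValueError):
    """Raised when an evaluation has no usable input (e.g. all-zero reference)."""


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma tolerances; the package default is the clinical 1%/1 mm pair."""

    dose_tolerance_fraction: float = 0.01
    distance_tolerance_mm: float = 1.0
    low_dose_threshold_fraction: float = 0.10
    search_radius_mm: float | None = None  # default: 3 x distance tolerance
    #: maximum sub-voxel search step as a fraction of the distance tolerance
    search_step_fraction: float = 1.0 / 3.0
    #: 'global' normalizes dose differences by the max reference dose
    normalization: str = "global"

    def __post_init__(self):
        if min(self.dose_tolerance_fraction, self.distance_tolerance_mm) <= 0:
            raise ValueError("tolerances must be positive")
        radius = self.radius_mm
        if radius < 2 * self.distance_tolerance_mm:
            raise ValueError("search radius must be at least 2 x distance tolerance")
        if self.normalization not in ("global", "local"):
            raise ValueError("normalization must be 'global' or 'local'")

    @property
    def radius_mm(self) -> float:
        if self.search_radius_mm is not None:
            return self.search_radius_mm
        return 3.0 * self.distance_tolerance_mm


@dataclass
class GammaResult:
    gamma_map: ScalarVolume
    evaluated_mask: np.ndarray
    passing_rate: float
    criteria: GammaCriteria

    @property
    def n_evaluated(self) -> int:
        return int(self.evaluated_mask.sum())


def _upsample_linear(values: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    """Linear upsampling placing fine sample i at original index i/f per axis.

    Output length per axis is (n - 1) * f + 1, so original voxel centers sit
    exactly on fine indices that are multiples of f.
    """
    out = values.astype(np.float64)
    for axis, f in enumerate(factors):
        if f == 1:
            continue
        n = out.shape[axis]
        a = np.moveaxis(out, axis, 0)
        fine = np.empty(((n - 1) * f + 1,) + a.shape[1:], dtype=np.float64)
        fine[::f] = a
        for s in range(1, f):
            t = s / f
            fine[s::f] = (1.0 - t) * a[:-1] + t * a[1:]
        out = np.moveaxis(fine, 0, axis)
    return out


def _search_offsets(spacing, criteria: GammaCriteria):
    """Integer fine-lattice offsets within the search sphere, with fine steps."""
    target = criteria.distance_tolerance_mm * criteria.search_step_fraction
    factors = tuple(int(math.ceil(s / target)) for s in spacing)
    steps = tuple(s / f for s, f in zip(spacing, factors))
    radius = criteria.radius_mm
    nmax = [int(math.floor(radius / st)) for st in steps]
    ox, oy, oz = np.meshgrid(
        *[np.arange(-n, n + 1) for n in nmax], indexing="ij"
    )
    d2 = (ox * steps[0]) ** 2 + (oy * steps[1]) ** 2 + (oz * steps[2]) ** 2
    keep = d2 <= radius**2 + 1e-12
    offsets = np.stack([ox[keep], oy[keep], oz[keep]], axis=1)
    d2 = d2[keep]
    order = np.argsort(d2, kind="stable")
    return factors, offsets[order], d2[order]


def gamma_index_3d(
    reference: ScalarVolume,
    evaluated: ScalarVolume,
    criteria: GammaCriteria = GammaCriteria(),
) -> GammaResult:
    """3D gamma of an evaluated dose against a reference dose.

    Offsets are visited in order of increasing distance, so the search can stop
    updating a voxel once its running gamma is below the pure-distance term of
    all remaining offsets.
    """
    reference.require_same_grid(evaluated)
    ref = reference.values.astype(np.float64)
    max_ref = float(ref.max())
    if max_ref <= 0:
        raise DegenerateInputError("reference dose is identically zero")
    mask = ref > criteria.low_dose_threshold_fraction * max_ref
    dd = criteria.dose_tolerance_fraction * max_ref
    dta2 = criteria.distance_tolerance_mm**2

    factors, offsets, d2 = _search_offsets(reference.grid.spacing, criteria)
    fine = _upsample_linear(evaluated.values, factors)
    fmax = tuple(s - 1 for s in fine.shape)

    idx = np.nonzero(mask)
    base = [idx[a] * factors[a] for a in range(3)]
    ref_vals = ref[mask]
    if criteria.normalization == "local":
        denom = np.maximum(np.abs(ref_vals) * criteria.dose_tolerance_fraction, 1e-12)
    else:
        denom = dd

    n = ref_vals.size
    gamma2 = np.full(n, np.inf)
    active = np.arange(n)
    # group offsets by identical geometric distance (shells)
    shell_starts = np.flatnonzero(np.r_[True, np.diff(d2) > 1e-12])
    shell_ends = np.r_[shell_starts[1:], d2.size]
    for s0, s1 in zip(shell_starts, shell_ends):
        geom = d2[s0] / dta2
        keep = gamma2[active] > geom
        active = active[keep]
        if active.size == 0:
            break
        bx, by, bz = (b[active] for b in base)
        rv = ref_vals[active]
        dn = denom if np.isscalar(denom) else denom[active]
        g2a = gamma2[active]
        for o in offsets[s0:s1]:
            ev = fine[
                np.clip(bx + o[0], 0, fmax[0]),
                np.clip(by + o[1], 0, fmax[1]),
                np.clip(bz + o[2], 0, fmax[2]),
            ]
            g2a = np.minimum(g2a, geom + ((ev - rv) / dn) ** 2)
        gamma2[active] = g2a

    gamma_vals = np.sqrt(gamma2)
    gmap = np.full(reference.grid.shape, np.nan, dtype=np.float32)
    gmap[mask] = gamma_vals
    passing = 100.0 * float(np.mean(gamma_vals <= 1.0)) if n else float("nan")
    return GammaResult(
        gamma_map=ScalarVolume(reference.grid, gmap, VolumeKind.NORMALIZED),
        evaluated_mask=mask,
        passing_rate=passing,
        criteria=criteria,
    )


def mse_above_threshold(
    reference: ScalarVolume,
    evaluated: ScalarVolume,
    threshold_fraction: float = 0.10,
) -> float:
    """Mean squared dose difference over voxels where the reference dose
    exceeds ``threshold_fraction`` of its maximum (Gy^2)."""
    reference.require_same_grid(evaluated)
    ref = reference.values.astype(np.float64)
    max_ref = float(ref.max())
    if max_ref <= 0:
        raise DegenerateInputError("reference dose is identically zero")
    mask = ref > threshold_fraction * max_ref
    if not mask.any():
        raise DegenerateInputError("threshold mask is empty")
    diff = evaluated.values.astype(np.float64)[mask] - ref[mask]
    return float(np.mean(diff**2))


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    dose_bins_gy: np.ndarray
    volume_fraction_pct: np.ndarray
    structure_name: str = ""

    def volume_at(self, dose_gy: float) -> float:
        """Percentage of the structure receiving at least ``dose_gy``."""
        return float(
            np.interp(dose_gy, self.dose_bins_gy, self.volume_fraction_pct)
        )


def compute_dvh(
    dose: ScalarVolume,
    structure_mask: np.ndarray,
    bin_width_gy: float = 0.1,
    structure_name: str = "",
) -> DVHCurve:
    """Cumulative DVH: fraction of masked voxels receiving at least each dose."""
    mask = np.asarray(structure_mask, dtype=bool)
    if mask.shape != dose.grid.shape:
        raise ValueError("structure mask shape must match the dose grid")
    vals = dose.values[mask].astype(np.float64)
    if vals.size == 0:
        raise ValueError("structure mask is empty")
    top = max(float(vals.max()), bin_width_gy)
    edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    frac = 100.0 * np.array([(vals >= e).mean() for e in edges])
    return DVHCurve(edges, frac, structure_name)


@dataclass
class DoseDiffHistogram:
    """Histogram of signed dose differences over qualifying voxels.

    A voxel qualifies when the candidate dose exceeds ``qualify_fraction`` of
    the maximum reference dose AND its absolute difference with the reference
    exceeds ``diff_fraction`` of that maximum (the 3%/3% rule by default).
    """

    bin_edges_gy: np.ndarray
    counts: np.ndarray
    qualify_fraction: float
    diff_fraction: float

    @property
    def n_qualifying(self) -> int:
        return int(self.counts.sum())


def dose_diff_histogram(
    candidate: ScalarVolume,
    reference: ScalarVolume,
    qualify_fraction: float = 0.03,
    diff_fraction: float = 0.03,
    bins: int | np.ndarray = 50,
) -> DoseDiffHistogram:
    candidate.require_same_grid(reference)
    ref = reference.values.astype(np.float64)
    max_ref = float(ref.max())
    if max_ref <= 0:
        raise DegenerateInputError("reference dose is identically zero")
    cand = candidate.values.astype(np.float64)
    diff = cand - ref
    qual = (cand > qualify_fraction * max_ref) & (
        np.abs(diff) > diff_fraction * max_ref
    )
    data = diff[qual]
    if np.isscalar(bins) and data.size == 0:
        edges = np.linspace(-1.0, 1.0, int(bins) + 1)
        counts = np.zeros(int(bins), dtype=int)
    else:
        counts, edges = np.histogram(data, bins=bins)
    return DoseDiffHistogram(edges, counts, qualify_fraction, diff_fraction)


def _volume_stats(candidate: ScalarVolume, reference: ScalarVolume) -> dict:
    diff = candidate.values.astype(np.float64) - reference.values.astype(np.float64)
    return {
        "max_abs_diff_gy": float(np.abs(diff).max()),
        "mean_diff_gy": float(diff.mean()),
        "rms_diff_gy": float(np.sqrt(np.mean(diff**2))),
    }


def _compare(candidate, reference, criteria, structures, bin_width_gy):
    gamma = gamma_index_3d(reference, candidate, criteria)
    hist = dose_diff_histogram(candidate, reference)
    out = {
        "gamma_passing_rate_pct": gamma.passing_rate,
        "gamma_voxels_evaluated": gamma.n_evaluated,
        "mse_gy2": mse_above_threshold(
            reference, candidate, criteria.low_dose_threshold_fraction
        ),
        "diff_histogram_qualifying_voxels": hist.n_qualifying,
        "stats": _volume_stats(candidate, reference),
        "dvh": {
            name: compute_dvh(candidate, m, bin_width_gy, name)
            for name, m in structures.items()
        },
    }
    return out, gamma, hist


def evaluate_case(
    case,
    converted: ScalarVolume,
    criteria: GammaCriteria = GammaCriteria(),
    structures: dict[str, np.ndarray] | None = None,
    out_dir=None,
    dvh_bin_width_gy: float = 0.1,
) -> dict:
    """Full report comparing PB-vs-MC and Converted-vs-MC for one case.

    Returns a dictionary (and optionally writes report.json, metrics.csv and
    DVH/gamma plots under ``out_dir``). The MC composite is the reference for
    both halves of the report.
    """
    mc = case.mc_composite
    pb = case.pb_composite
    mc.require_same_grid(converted)
    structures = structures if structures is not None else dict(case.structures)

    pb_report, pb_gamma, _ = _compare(pb, mc, criteria, structures, dvh_bin_width_gy)
    conv_report, conv_gamma, _ = _compare(
        converted, mc, criteria, structures, dvh_bin_width_gy
    )
    mc_dvh = {
        name: compute_dvh(mc, m, dvh_bin_width_gy, name)
        for name, m in structures.items()
    }
    report = {
        "case_id": case.case_id,
        "site": case.site,
        "criteria": {
            "dose_tolerance_pct": 100 * criteria.dose_tolerance_fraction,
            "distance_tolerance_mm": criteria.distance_tolerance_mm,
            "low_dose_threshold_pct": 100 * criteria.low_dose_threshold_fraction,
        },
        "pb_vs_mc": pb_report,
        "converted_vs_mc": conv_report,
    }
    if out_dir is not None:
        _write_case_report(
            report, pb_gamma, conv_gamma, mc_dvh, Path(out_dir), case
        )
    return report


def _strip_dvh(report_half: dict) -> dict:
    out = {k: v for k, v in report_half.items() if k != "dvh"}
    out["dvh"] = {
        name: {
            "dose_bins_gy": c.dose_bins_gy.tolist(),
            "volume_fraction_pct": c.volume_fraction_pct.tolist(),
        }
        for name, c in report_half["dvh"].items()
    }
    return out


def _write_case_report(report, pb_gamma, conv_gamma, mc_dvh, out_dir: Path, case):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .io import write_volume

    out_dir.mkdir(parents=True, exist_ok=True)
    serializable = dict(report)
    serializable["pb_vs_mc"] = _strip_dvh(report["pb_vs_mc"])
    serializable["converted_vs_mc"] = _strip_dvh(report["converted_vs_mc"])
    with open(out_dir / "report.json", "w") as f:
        json.dump(serializable, f, indent=2)

    with open(out_dir / "metrics.csv", "w") as f:
        f.write("comparison,gamma_passing_rate_pct,mse_gy2,qualifying_voxels\n")
        for key in ("pb_vs_mc", "converted_vs_mc"):
            r = report[key]
            f.write(
                f"{key},{r['gamma_passing_rate_pct']:.4f},{r['mse_gy2']:.6f},"
                f"{r['diff_histogram_qualifying_voxels']}\n"
            )

    write_volume(pb_gamma.gamma_map, out_dir / "gamma_pb_vs_mc.nii.gz")
    write_volume(conv_gamma.gamma_map, out_dir / "gamma_converted_vs_mc.nii.gz")

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, curve in mc_dvh.items():
        (line,) = ax.plot(curve.dose_bins_gy, curve.volume_fraction_pct, "-", label=f"{name} (MC)")
        for key, style in (("pb_vs_mc", "--"), ("converted_vs_mc", ":")):
            c = report[key]["dvh"][name]
            ax.plot(c.dose_bins_gy, c.volume_fraction_pct, style, color=line.get_color())
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel("volume (%)")
    ax.legend(fontsize=7)
    ax.set_title(f"DVH {report['case_id']} (solid MC, dashed PB, dotted converted)")
    fig.tight_layout()
    fig.savefig(out_dir / "dvh.png", dpi=120)
    plt.close(fig)
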