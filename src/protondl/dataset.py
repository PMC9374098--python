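"""Synthetic patient generation: site-like phantom families with paired
pencil-beam and pseudo-Monte-Carlo dose volumes.

Each generated case is one "patient": a heterogeneous CT phantom, one or more
treatment fields with per-beam PB and pseudo-MC doses, their composites, and a
pair of synthetic structure masks (target, distal organ-at-risk) so DVH
comparisons are exercisable. The four families emulate the qualitative
heterogeneity and beam-configuration structure of different anatomical sites:

* ``headneck_like``  - many small air/bone inserts, 2-4 beams at random angles
* ``liver_like``     - large soft-tissue-contrast blobs, 1-3 beams
* ``lung_like``      - large low-density inserts plus rib-like bone, 1-2 beams
* ``prostate_like``  - deep central target between bone, beams only at
  gantry 90 or 270 (lateral opposed fields)

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .beam import (
    DEFAULT_MC_PITCH_MM,
    DEFAULT_PB_PITCH_MM,
    BeamSpec,
    pb_dose,
    pseudo_mc_dose,
    wepl_raytrace,
)
from .grid import BeamGeometry, GridSpec, ScalarVolume, VolumeKind
from .materials import DEFAULT_TABLE, MaterialTable, hu_to_rsp
from .phantom import BodySpec, Insert, PhantomSpec, build_phantom

__all__ = [
    "SITES",
    "BeamRecord",
    "CaseRecord",
    "default_grid",
    "water_phantom",
    "lateral_slab_phantom",
    "reference_beam",
    "generate_case",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]

SITES = ("headneck_like", "liver_like", "lung_like", "prostate_like")

#: per-beam target-mean dose (Gy), a clinically plausible fraction dose
TARGET_MEAN_DOSE_PER_BEAM_GY = 2.0


@dataclass
class BeamRecord:
    spec: BeamSpec
    pb: ScalarVolume
    mc: ScalarVolume


@dataclass
class CaseRecord:
    case_id: str
    site: str
    ct: ScalarVolume
    beams: list[BeamRecord]
    pb_composite: ScalarVolume
    mc_composite: ScalarVolume
    structures: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def pb_beams(self):
        return [(b.spec, b.pb) for b in self.beams]

    @property
    def mc_beams(self):
        return [(b.spec, b.mc) for b in self.beams]


def default_grid(shape=(64, 64, 16), spacing=(2.0, 2.0, 2.5)) -> GridSpec:
    """Desk-scale working grid, centered so the grid center is at the origin."""
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    return GridSpec(shape, spacing, origin)


# ----------------------------------------------------------------- fixtures


def water_phantom(grid: GridSpec | None = None) -> ScalarVolume:
    """Homogeneous water box in air (flat entry surfaces): the agreement fixture."""
    grid = grid or default_grid()
    body = BodySpec("box", grid.center_mm, (100.0, 90.0, 1000.0))
    return build_phantom(PhantomSpec(grid, body))


def lateral_slab_phantom(
    grid: GridSpec | None = None, slab_thickness_mm: float = 20.0
) -> ScalarVolume:
    """Water box with lateral heterogeneity slabs: the divergence fixture.

    Upstream of the peak of the reference beam (gantry 270, entering from +y)
    sit a bone half-slab covering the x > 0 half of the field and a narrow air
    ridge in the open half. Rays through the bone half acquire an excess
    water-equivalent thickness of ``0.4 * slab_thickness_mm`` (measurable far
    from the slab edge, where lateral mixing is negligible), while the three
    lateral interfaces (air|water, water|air, water|bone) drive the
    pencil-beam engine's blind spot: its pencils spread dose across each
    interface with the wrong range, where the transport reference mixes ranges
    locally.
    """
    grid = grid or default_grid()
    c = grid.center_mm
    body = BodySpec("box", c, (100.0, 90.0, 1000.0))
    t = slab_thickness_mm
    inserts = (
        Insert("box", (c[0] + 25.0, c[1] + 20.0, c[2]), (50.0, t, 1000.0), "bone"),
        Insert("box", (c[0] - 9.0, c[1] + 20.0, c[2]), (10.0, t, 1000.0), "air"),
    )
    return build_phantom(PhantomSpec(grid, body, inserts))


def reference_beam(
    grid: GridSpec | None = None,
    gantry_deg: float = 270.0,
    nominal_range_mm: float = 60.0,
    mod_width_mm: float = 15.0,
) -> BeamSpec:
    grid = grid or default_grid()
    geom = BeamGeometry(gantry_deg, 0.0, grid.center_mm)
    return BeamSpec(geom, (40.0, 25.0), nominal_range_mm, mod_width_mm, 4.0)


# ------------------------------------------------------------- generation


def _beam_for_target(
    rsp: ScalarVolume,
    gantry_deg: float,
    isocenter_mm,
    target_radius_mm: float,
    field_size_mm,
    entrance_sigma_mm: float,
) -> BeamSpec:
    """Build a beam whose spread-out peak covers the target sphere."""
    geom = BeamGeometry(gantry_deg, 0.0, tuple(isocenter_mm))
    d = geom.direction
    entry = np.asarray(isocenter_mm) - 300.0 * d
    prof = wepl_raytrace(rsp, entry, d, step_mm=1.0)
    if prof.empty:
        raise ValueError("beam axis does not intersect the grid")
    dist_iso = 300.0
    r = target_radius_mm
    wepl_distal = prof.wepl_at(dist_iso + r)
    wepl_proximal = prof.wepl_at(dist_iso - r)
    nominal_range = max(wepl_distal + 2.0, 10.0)
    mod = min(max(wepl_distal - wepl_proximal + 4.0, 6.0), nominal_range)
    return BeamSpec(geom, tuple(field_size_mm), nominal_range, mod, entrance_sigma_mm)


def _sphere_mask(grid: GridSpec, center_mm, radius_mm: float) -> np.ndarray:
    x = grid.axis_coords(0)[:, None, None] - center_mm[0]
    y = grid.axis_coords(1)[None, :, None] - center_mm[1]
    z = grid.axis_coords(2)[None, None, :] - center_mm[2]
    return x**2 + y**2 + z**2 <= radius_mm**2


def _site_phantom(site: str, grid: GridSpec, rng: np.random.Generator):
    """Phantom spec + isocenter + target radius for one site family."""
    c = np.asarray(grid.center_mm)
    body = BodySpec("ellipsoid", tuple(c), (110.0, 90.0, 1000.0))
    inserts: list[Insert] = []
    iso = c.copy()
    iso[2] += rng.uniform(-4.0, 4.0)
    target_radius = rng.uniform(8.0, 12.0)

    def _inside(pos, margin):
        # keep an insert of lateral size `margin` inside the body ellipsoid
        return ((pos[0] - c[0]) / (55.0 - margin)) ** 2 + (
            (pos[1] - c[1]) / (45.0 - margin)
        ) ** 2 <= 1.0

    if site == "headneck_like":
        # many small high-contrast cavities/bones crowded around the target,
        # so most beam paths cross several lateral interfaces
        n_ins = rng.integers(6, 10)
        for _ in range(n_ins):
            while True:
                rad = rng.uniform(14.0, 34.0)
                ang = rng.uniform(0, 2 * math.pi)
                pos = c + np.array(
                    [rad * math.cos(ang), rad * math.sin(ang), rng.uniform(-8, 8)]
                )
                size = rng.uniform(8.0, 16.0)
                if _inside(pos, size / 2 + 2):
                    break
            material = rng.choice(["air", "bone"])
            shape = rng.choice(["sphere", "box"])
            dims = (size / 2, size / 2, size / 2) if shape == "sphere" else (size, size, size)
            inserts.append(Insert(shape, tuple(pos), dims, str(material)))
        n_beams = int(rng.integers(2, 5))
        angles = rng.uniform(0.0, 360.0, n_beams)
    elif site == "liver_like":
        # soft-tissue-contrast blobs around the target plus rib-like bone and a
        # lung-like low-density region at the body edge (diaphragm neighbourhood)
        for _ in range(int(rng.integers(2, 5))):
            while True:
                pos = c + np.array(
                    [rng.uniform(-30, 30), rng.uniform(-24, 24), rng.uniform(-6, 6)]
                )
                r = rng.uniform(12.0, 20.0)
                if _inside(pos, r + 2):
                    break
            inserts.append(
                Insert("sphere", tuple(pos), (r, r, r), str(rng.choice(["adipose", "muscle"])))
            )
        side = rng.choice([-1.0, 1.0])
        inserts.append(
            Insert("cylinder", (c[0] + side * 38.0, c[1], c[2]), (12.0, 12.0, 1000.0), "lung")
        )
        for _ in range(int(rng.integers(1, 4))):
            ang = rng.uniform(0, 2 * math.pi)
            pos = c + np.array([44.0 * math.cos(ang), 36.0 * math.sin(ang), rng.uniform(-10, 10)])
            if _inside(pos, 5.0):
                inserts.append(Insert("box", tuple(pos), (8.0, 8.0, 10.0), "bone"))
        n_beams = int(rng.integers(1, 4))
        # at least one field enters through the lung-like region (source on the
        # ``side`` flank means a travel direction with x-component of -side)
        through_lung = (180.0 if side > 0 else 0.0) + rng.uniform(-35.0, 35.0, n_beams)
        free = rng.uniform(0.0, 360.0, n_beams)
        pick = rng.random(n_beams) < 0.6
        pick[0] = True
        angles = np.where(pick, through_lung, free)
    elif site == "lung_like":
        # large low-density regions flanking a mediastinum-adjacent target
        for sign in (-1.0, 1.0):
            r = rng.uniform(15.0, 19.0)
            inserts.append(
                Insert("cylinder", (c[0] + sign * 23.0, c[1], c[2]), (r, r, 1000.0), "lung")
            )
        for _ in range(int(rng.integers(3, 6))):  # rib-like bone
            ang = rng.uniform(0, 2 * math.pi)
            pos = c + np.array([46.0 * math.cos(ang), 38.0 * math.sin(ang), rng.uniform(-10, 10)])
            if _inside(pos, 4.0):
                inserts.append(Insert("box", tuple(pos), (7.0, 7.0, 9.0), "bone"))
        iso[0] += rng.choice([-1.0, 1.0]) * rng.uniform(10.0, 16.0)
        n_beams = int(rng.integers(1, 3))
        angles = rng.uniform(0.0, 360.0, n_beams)
    elif site == "prostate_like":
        # deep central target; bone on the lateral beam axes so the opposed
        # fields traverse it (femoral-head analogue for this beam convention)
        for sign in (-1.0, 1.0):
            inserts.append(
                Insert(
                    "cylinder",
                    (c[0] + rng.uniform(-4, 4), c[1] + sign * 29.0, c[2]),
                    (rng.uniform(9.0, 11.0), 10.0, 26.0),
                    "bone",
                )
            )
        target_radius = rng.uniform(8.0, 10.0)
        n_beams = 2
        angles = rng.choice([90.0, 270.0], size=n_beams)
    else:
        raise ValueError(f"unknown site {site!r}")
    return PhantomSpec(grid, body, tuple(inserts)), iso, target_radius, np.asarray(angles, dtype=float)


def generate_case(
    site: str,
    case_id: str,
    rng: np.random.Generator,
    grid: GridSpec | None = None,
    table: MaterialTable = DEFAULT_TABLE,
    pb_pitch=DEFAULT_PB_PITCH_MM,
    mc_pitch=DEFAULT_MC_PITCH_MM,
) -> CaseRecord:
    grid = grid or default_grid()
    spec, iso, target_radius, angles = _site_phantom(site, grid, rng)
    ct = build_phantom(spec)
    rsp = hu_to_rsp(ct, table)

    beams: list[BeamRecord] = []
    for g in angles:
        field = (rng.uniform(30.0, 42.0), rng.uniform(20.0, 28.0))
        sigma = rng.uniform(3.0, 5.0)
        bspec = _beam_for_target(rsp, float(g), iso, target_radius, field, sigma)
        pb = pb_dose(ct, bspec, table, pb_pitch)
        mc = pseudo_mc_dose(ct, bspec, table, mc_pitch, pb_reference=pb, pencil_pitch_mm=pb_pitch)
        beams.append(BeamRecord(bspec, pb, mc))

    target_mask = _sphere_mask(grid, iso, target_radius)
    mc_sum = np.sum([b.mc.values for b in beams], axis=0)
    mean_target = float(mc_sum[target_mask].mean()) if target_mask.any() else 0.0
    scale = (
        TARGET_MEAN_DOSE_PER_BEAM_GY * len(beams) / mean_target if mean_target > 0 else 1.0
    )
    for b in beams:
        b.pb = b.pb.with_values(b.pb.values * scale)
        b.mc = b.mc.with_values(b.mc.values * scale)
        b.spec = b.spec.scaled(scale)

    pb_comp = ScalarVolume(
        grid, np.sum([b.pb.values for b in beams], axis=0), VolumeKind.DOSE_GY
    )
    mc_comp = ScalarVolume(
        grid, np.sum([b.mc.values for b in beams], axis=0), VolumeKind.DOSE_GY
    )

    d0 = beams[0].spec.geometry.direction
    oar_center = iso + d0 * (target_radius + 14.0)
    structures = {
        "target": target_mask,
        "distal_oar": _sphere_mask(grid, oar_center, 7.0),
    }
    return CaseRecord(case_id, site, ct, beams, pb_comp, mc_comp, structures)


def _largest_remainder_counts(n_cases: int, site_mix: dict[str, float]) -> dict[str, int]:
    total = sum(site_mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError(f"site mix fractions must sum to 1, got {total}")
    for s in site_mix:
        if s not in SITES:
            raise ValueError(f"unknown site {s!r}")
    exact = {s: n_cases * f for s, f in site_mix.items()}
    counts = {s: int(math.floor(v)) for s, v in exact.items()}
    remaining = n_cases - sum(counts.values())
    order = sorted(site_mix, key=lambda s: (-(exact[s] - counts[s]), SITES.index(s)))
    for s in order[:remaining]:
        counts[s] += 1
    return counts


def generate_dataset(
    n_cases: int,
    site_mix: dict[str, float] | None = None,
    seed: int = 0,
    grid: GridSpec | None = None,
    table: MaterialTable = DEFAULT_TABLE,
) -> list[CaseRecord]:
    """Generate a reproducible synthetic dataset.

    Fractional per-site case counts are resolved by largest-remainder rounding,
    so the realized mix is as close to the requested one as integers allow.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    site_mix = site_mix or {s: 0.25 for s in SITES}
    counts = _largest_remainder_counts(n_cases, site_mix)
    rng = np.random.default_rng(seed)
    cases = []
    i = 0
    for site in SITES:
        for _ in range(counts.get(site, 0)):
            cases.append(generate_case(site, f"case_{i:03d}", rng, grid, table))
            i += 1
    return cases


# ------------------------------------------------------------ persistence


def save_dataset(cases: list[CaseRecord], out_dir) -> None:
    from .io import ensure_dir, write_manifest, write_volume

    out = ensure_dir(out_dir)
    index = []
    for case in cases:
        cdir = ensure_dir(out / case.case_id)
        write_volume(case.ct, cdir / "ct.nii.gz")
        write_volume(case.pb_composite, cdir / "pb_composite.nii.gz")
        write_volume(case.mc_composite, cdir / "mc_composite.nii.gz")
        beams = []
        for i, b in enumerate(case.beams):
            write_volume(b.pb, cdir / f"beam_{i}_pb.nii.gz")
            write_volume(b.mc, cdir / f"beam_{i}_mc.nii.gz")
            beams.append(
                {
                    "gantry_deg": b.spec.geometry.gantry_deg,
                    "couch_deg": b.spec.geometry.couch_deg,
                    "isocenter_mm": list(b.spec.geometry.isocenter_mm),
                    "field_size_mm": list(b.spec.field_size_mm),
                    "nominal_range_mm": b.spec.nominal_range_mm,
                    "mod_width_mm": b.spec.mod_width_mm,
                    "entrance_sigma_mm": b.spec.entrance_sigma_mm,
                    "weight": b.spec.weight,
                    "pb_file": f"beam_{i}_pb.nii.gz",
                    "mc_file": f"beam_{i}_mc.nii.gz",
                }
            )
        structures = {}
        for name, mask in case.structures.items():
            vol = ScalarVolume(case.ct.grid, mask.astype(np.float32), VolumeKind.NORMALIZED)
            write_volume(vol, cdir / f"structure_{name}.nii.gz")
            structures[name] = f"structure_{name}.nii.gz"
        write_manifest(
            {
                "case_id": case.case_id,
                "site": case.site,
                "ct_file": "ct.nii.gz",
                "pb_composite_file": "pb_composite.nii.gz",
                "mc_composite_file": "mc_composite.nii.gz",
                "beams": beams,
                "structures": structures,
            },
            cdir / "manifest.json",
        )
        index.append(case.case_id)
    write_manifest({"cases": index}, out / "dataset.json")


def load_case(case_dir) -> CaseRecord:
    from .io import read_manifest, read_volume

    cdir = Path(case_dir)
    man = read_manifest(cdir / "manifest.json")
    ct = read_volume(cdir / man["ct_file"], kind=VolumeKind.CT_HU)
    beams = []
    for b in man["beams"]:
        geom = BeamGeometry(b["gantry_deg"], b["couch_deg"], tuple(b["isocenter_mm"]))
        spec = BeamSpec(
            geom,
            tuple(b["field_size_mm"]),
            b["nominal_range_mm"],
            b["mod_width_mm"],
            b["entrance_sigma_mm"],
            b["weight"],
        )
        beams.append(
            BeamRecord(
                spec,
                read_volume(cdir / b["pb_file"]),
                read_volume(cdir / b["mc_file"]),
            )
        )
    structures = {
        name: read_volume(cdir / fname, kind=VolumeKind.NORMALIZED).values > 0.5
        for name, fname in man.get("structures", {}).items()
    }
    return CaseRecord(
        man["case_id"],
        man["site"],
        ct,
        beams,
        read_volume(cdir / man["pb_composite_file"]),
        read_volume(cdir / man["mc_composite_file"]),
        structures,
    )


def load_dataset(data_dir) -> list[CaseRecord]:
    from .io import read_manifest

    root = Path(data_dir)
    index = read_manifest(root / "dataset.json")
    return [load_case(root / cid) for cid in index["cases"]]
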