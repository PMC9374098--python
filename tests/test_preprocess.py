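import numpy as np
import pytest

from protondl.grid import BeamGeometry, GridSpec, ScalarVolume
from protondl.preprocess import (
    CT_WINDOW_HU,
    NormalizationRecord,
    UnsupportedGeometryError,
    compose_beams,
    crop_volume,
    denormalize_dose,
    dose_bounding_box,
    embed_volume,
    normalize_ct,
    normalize_dose,
    patch_grid_corners,
    random_patch_corner,
    rotate_back,
    rotate_to_default,
    rotation_canvas,
    sample_patch,
)

from oracles import random_dose_blobs


def centered_grid(shape=(32, 32, 8), spacing=(2.0, 2.0, 2.5)):
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    return GridSpec(shape, spacing, origin)


def blob_dose(seed=0, shape=(32, 32, 8)):
    g = centered_grid(shape)
    rng = np.random.default_rng(seed)
    return ScalarVolume(g, random_dose_blobs(rng, shape), "dose_gy")


class TestNormalization:
    def test_dose_roundtrip_exact(self):
        dose = blob_dose()
        norm, rec = normalize_dose(dose)
        back = denormalize_dose(norm, rec)
        assert np.max(np.abs(back.values - dose.values)) < 1e-6

    def test_paired_dose_shares_scale(self):
        pb = blob_dose(0)
        mc = blob_dose(1)
        _, rec = normalize_dose(pb)
        mc_norm, rec2 = normalize_dose(mc, rec)
        assert rec2 is rec
        assert np.allclose(mc_norm.values * rec.scale, mc.values)

    def test_high_dose_region_near_unity(self):
        dose = blob_dose()
        norm, _ = normalize_dose(dose)
        # the 95th-percentile scaling puts the treated region at O(1)
        assert 0.9 < float(norm.values.max()) < 2.0

    def test_zero_dose_rejected(self):
        g = centered_grid()
        zero = ScalarVolume(g, np.zeros(g.shape), "dose_gy")
        with pytest.raises(ValueError):
            normalize_dose(zero)
        with pytest.raises(ValueError):
            NormalizationRecord(0.0)

    def test_ct_window_maps_to_unit_interval(self):
        g = centered_grid()
        vals = np.full(g.shape, CT_WINDOW_HU[0])
        vals[0] = CT_WINDOW_HU[1]
        vals[1] = 5000.0  # above window: clipped
        vals[2] = 500.0
        ct = ScalarVolume(g, vals, "ct_hu")
        out = normalize_ct(ct)
        assert out.values.min() == 0.0
        assert out.values.max() == 1.0
        expect = (500.0 - CT_WINDOW_HU[0]) / (CT_WINDOW_HU[1] - CT_WINDOW_HU[0])
        assert np.allclose(out.values[2], expect)

    def test_ct_kind_enforced(self):
        with pytest.raises(ValueError):
            normalize_ct(blob_dose())


class TestRotation:
    def test_canvas_contains_grid_and_shares_lattice(self):
        g = centered_grid()
        canvas = rotation_canvas(g, (10.0, -5.0, 0.0))
        v = blob_dose()
        emb = embed_volume(v, canvas)
        back = crop_volume(emb, g)
        assert np.array_equal(back.values, v.values)

    def test_rotate_roundtrip_gantry_45(self):
        v = blob_dose()
        geom = BeamGeometry(45.0, 0.0, (0.0, 0.0, 0.0))
        rot = rotate_to_default(v, geom)
        back = rotate_back(rot, geom, target_grid=v.grid)
        body = v.values > 0.05 * v.values.max()
        num = np.sqrt(np.mean((back.values[body] - v.values[body]) ** 2))
        den = np.sqrt(np.mean(v.values[body] ** 2))
        assert num / den < 0.02

    def test_rotate_roundtrip_gantry_90_exact_square(self):
        # square isotropic in-plane grid: quarter turns are index permutations
        v = blob_dose(shape=(32, 32, 8))
        geom = BeamGeometry(90.0, 0.0, (0.0, 0.0, 0.0))
        rot = rotate_to_default(v, geom)
        back = rotate_back(rot, geom, target_grid=v.grid)
        assert np.allclose(back.values, v.values, atol=1e-6)

    def test_gantry_270_is_canvas_embedding(self):
        v = blob_dose()
        geom = BeamGeometry(270.0, 0.0, (0.0, 0.0, 0.0))
        rot = rotate_to_default(v, geom)
        assert np.array_equal(crop_volume(rot, v.grid).values, v.values)

    def test_off_center_isocenter_content_preserved(self):
        # rotation about a far corner must not clip dose off the canvas
        v = blob_dose()
        geom = BeamGeometry(135.0, 0.0, (25.0, 25.0, 0.0))
        rot = rotate_to_default(v, geom)
        assert rot.values.sum() == pytest.approx(v.values.sum(), rel=0.01)

    def test_nonzero_couch_rejected(self):
        v = blob_dose()
        with pytest.raises(UnsupportedGeometryError):
            rotate_to_default(v, BeamGeometry(0.0, 90.0))


class TestPatches:
    def test_sample_patch_interior_matches_slice(self):
        v = blob_dose()
        patch = sample_patch([v], (4, 4, 2), (8, 8, 4))[0]
        assert np.array_equal(patch, v.values[4:12, 4:12, 2:6])

    def test_sample_patch_pads_with_fill(self):
        v = blob_dose()
        ct = ScalarVolume(v.grid, np.zeros(v.grid.shape), "ct_hu")
        dose_p, ct_p = sample_patch([v, ct], (-4, 0, 0), (8, 8, 4))
        assert np.all(dose_p[:4] == 0.0)  # dose fill
        assert np.all(ct_p[:4] == -1000.0)  # air fill
        assert np.array_equal(dose_p[4:], v.values[:4, 0:8, 0:4])

    def test_random_corner_always_covers_treated_voxel(self):
        v = blob_dose()
        rng = np.random.default_rng(0)
        mask = v.values > 0.05 * v.values.max()
        patch_shape = (8, 8, 4)
        for _ in range(50):
            c = random_patch_corner(rng, v, patch_shape)
            block = sample_patch([v], c, patch_shape)[0]
            assert block.max() > 0.05 * v.values.max()

    def test_patch_grid_covers_volume(self):
        shape = (32, 32, 8)
        patch = (8, 8, 4)
        counts = np.zeros(shape)
        for c in patch_grid_corners(shape, patch, 0.5):
            sl = tuple(slice(max(x, 0), x + p) for x, p in zip(c, patch))
            counts[sl] += 1
        assert counts.min() >= 1

    def test_patch_larger_than_volume_single_centered(self):
        corners = patch_grid_corners((8, 8, 4), (16, 16, 8))
        assert len(corners) == 1

    def test_bounding_box(self):
        g = centered_grid()
        vals = np.zeros(g.shape)
        vals[10:14, 5:9, 2:6] = 1.0
        lo, hi = dose_bounding_box(ScalarVolume(g, vals, "dose_gy"))
        assert lo == (10, 5, 2)
        assert hi == (13, 8, 5)


class TestCompose:
    def test_sum_of_beams(self):
        a, b = blob_dose(0), blob_dose(1)
        comp = compose_beams([a, b])
        assert np.allclose(comp.values, a.values + b.values)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compose_beams([])
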