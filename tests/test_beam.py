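import numpy as np
import pytest

from protondl.beam import (
    BeamSpec,
    UnsupportedGeometryError,
    depth_dose,
    pb_dose,
    pseudo_mc_dose,
    wepl_raytrace,
)
from protondl.grid import BeamGeometry, GridSpec, ScalarVolume
from protondl.materials import DEFAULT_TABLE, MATERIAL_HU

from oracles import slab_wepl


def water_ct(shape=(60, 40, 10), spacing=(2.0, 2.0, 2.5)):
    grid = GridSpec(shape, spacing)
    grid = GridSpec(shape, spacing, tuple(-e / 2 + s / 2 for e, s in zip(grid.extent_mm, spacing)))
    return ScalarVolume(grid, np.zeros(shape), "ct_hu")


class TestDepthDose:
    def test_peak_at_range(self):
        beam = BeamSpec(BeamGeometry(0.0), nominal_range_mm=60.0)
        w = np.linspace(0.0, 80.0, 801)
        dd = depth_dose(w, beam)
        assert abs(w[np.argmax(dd)] - 60.0) < 0.5

    def test_entrance_to_peak_ratio(self):
        beam = BeamSpec(BeamGeometry(0.0), nominal_range_mm=60.0)
        entrance = float(depth_dose(np.array([0.5]), beam)[0])
        peak = float(depth_dose(np.array([60.0]), beam)[0])
        assert peak / entrance == pytest.approx(3.5, rel=0.02)

    def test_distal_falloff_to_zero(self):
        beam = BeamSpec(BeamGeometry(0.0), nominal_range_mm=60.0)
        assert depth_dose(np.array([70.0]), beam)[0] == 0.0

    def test_sobp_plateau_flat(self):
        beam = BeamSpec(BeamGeometry(0.0), nominal_range_mm=60.0, mod_width_mm=20.0)
        w = np.linspace(41.0, 59.0, 100)
        dd = depth_dose(w, beam)
        assert np.all(np.abs(dd - 1.0) < 0.05)

    def test_negative_wepl_rejected(self):
        beam = BeamSpec(BeamGeometry(0.0))
        with pytest.raises(ValueError):
            depth_dose(np.array([-1.0]), beam)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            BeamSpec(BeamGeometry(0.0), nominal_range_mm=-5.0)
        with pytest.raises(ValueError):
            BeamSpec(BeamGeometry(0.0), nominal_range_mm=60.0, mod_width_mm=70.0)


class TestWeplRaytrace:
    def test_water_wepl_equals_distance(self):
        ct = water_ct()
        from protondl.materials import hu_to_rsp

        rsp = hu_to_rsp(ct)
        prof = wepl_raytrace(rsp, (-70.0, 0.0, 0.0), (1.0, 0.0, 0.0))
        # inside water, WEPL grows ~1 mm per mm
        d = 40.0
        assert prof.wepl_at(prof.distance_mm[-1]) == pytest.approx(
            prof.distance_mm[-1], rel=0.02
        )
        assert prof.wepl_at(d) == pytest.approx(d, rel=0.03)

    def test_slab_wepl_matches_closed_form(self):
        ct = water_ct()
        vals = ct.values.copy()
        # a 20 mm bone slab from x = 0 to 20 (indices given spacing 2, origin -59)
        x = ct.grid.axis_coords(0)
        slab = (x >= 0.0) & (x < 20.0)
        vals[slab, :, :] = MATERIAL_HU["bone"]
        from protondl.materials import hu_to_rsp

        rsp = hu_to_rsp(ScalarVolume(ct.grid, vals, "ct_hu"))
        bone_rsp = DEFAULT_TABLE.rsp_of(MATERIAL_HU["bone"])
        prof = wepl_raytrace(rsp, (-70.0, 0.0, 0.0), (1.0, 0.0, 0.0), step_mm=0.25)
        # entry at grid edge x = -60: water 60mm, bone 20mm, water 20mm
        expect = slab_wepl([(60.0, 1.0), (20.0, float(bone_rsp)), (20.0, 1.0)])
        assert prof.wepl_at(100.0) == pytest.approx(expect, rel=0.02)

    def test_monotone_nondecreasing(self):
        ct = water_ct()
        from protondl.materials import hu_to_rsp

        prof = wepl_raytrace(hu_to_rsp(ct), (-70.0, -10.0, 0.0), (1.0, 0.0, 0.0))
        assert np.all(np.diff(prof.wepl_mm) >= 0)

    def test_miss_returns_empty(self):
        ct = water_ct()
        from protondl.materials import hu_to_rsp

        prof = wepl_raytrace(hu_to_rsp(ct), (-70.0, 500.0, 0.0), (1.0, 0.0, 0.0))
        assert prof.empty

    def test_bad_inputs_rejected(self):
        ct = water_ct()
        from protondl.materials import hu_to_rsp

        rsp = hu_to_rsp(ct)
        with pytest.raises(ValueError):
            wepl_raytrace(rsp, (0, 0, 0), (2.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            wepl_raytrace(rsp, (0, 0, 0), (1.0, 0.0, 0.0), step_mm=0.0)


class TestEngines:
    def test_engines_agree_in_water(self):
        # homogeneous medium with the field (and its penumbra) fully inside
        # the grid: the PB approximation is exact by construction
        ct = water_ct((60, 40, 20))
        beam = BeamSpec(
            BeamGeometry(0.0), field_size_mm=(30.0, 20.0), nominal_range_mm=60.0,
            mod_width_mm=20.0,
        )
        pb = pb_dose(ct, beam)
        mc = pseudo_mc_dose(ct, beam, pb_reference=pb)
        from protondl.evaluation import GammaCriteria, gamma_index_3d

        res = gamma_index_3d(mc, pb, GammaCriteria())
        assert res.passing_rate >= 99.0

    def test_engines_diverge_at_lateral_interface(self):
        # the shipped lateral-slab fixture puts air and bone interfaces
        # across the field: the PB blind spot drives the engines apart
        from protondl.dataset import lateral_slab_phantom, reference_beam

        ct = lateral_slab_phantom()
        beam = reference_beam()
        pb = pb_dose(ct, beam)
        mc = pseudo_mc_dose(ct, beam, pb_reference=pb)
        from protondl.evaluation import GammaCriteria, gamma_index_3d

        res = gamma_index_3d(mc, pb, GammaCriteria())
        assert res.passing_rate <= 90.0

    def test_mc_normalized_to_pb_integral(self):
        ct = water_ct((40, 30, 8))
        beam = BeamSpec(BeamGeometry(0.0), nominal_range_mm=50.0)
        pb = pb_dose(ct, beam)
        mc = pseudo_mc_dose(ct, beam, pb_reference=pb)
        assert mc.values.sum() == pytest.approx(pb.values.sum(), rel=1e-6)

    def test_dose_nonnegative_and_finite(self):
        ct = water_ct((40, 30, 8))
        beam = BeamSpec(BeamGeometry(90.0), nominal_range_mm=40.0, mod_width_mm=10.0)
        for vol in (pb_dose(ct, beam), pseudo_mc_dose(ct, beam)):
            assert np.all(np.isfinite(vol.values))
            assert vol.values.min() >= 0.0

    def test_beam_weight_scales_dose_linearly(self):
        ct = water_ct((40, 30, 8))
        beam = BeamSpec(BeamGeometry(0.0), nominal_range_mm=50.0)
        d1 = pb_dose(ct, beam)
        d2 = pb_dose(ct, beam.scaled(2.0))
        assert np.allclose(d2.values, 2.0 * d1.values, rtol=1e-6, atol=1e-9)

    def test_nonzero_couch_rejected(self):
        ct = water_ct((20, 20, 4))
        beam = BeamSpec(BeamGeometry(0.0, couch_deg=10.0))
        with pytest.raises(UnsupportedGeometryError):
            pb_dose(ct, beam)
        with pytest.raises(UnsupportedGeometryError):
            pseudo_mc_dose(ct, beam)

    def test_subray_pitch_guard(self):
        ct = water_ct((20, 20, 4))
        beam = BeamSpec(BeamGeometry(0.0))
        with pytest.raises(ValueError):
            pseudo_mc_dose(ct, beam, subray_pitch_mm=(2.0, 2.5))

    def test_range_shift_through_slab(self):
        # a bone slab covering the whole field pulls the PB peak upstream by
        # (rsp - 1) * thickness; both engines must show it
        ct = water_ct((80, 40, 10))
        vals = ct.values.copy()
        x = ct.grid.axis_coords(0)
        thick = 20.0
        slab = (x >= -50.0) & (x < -50.0 + thick)
        vals[slab, :, :] = MATERIAL_HU["bone"]
        ct2 = ScalarVolume(ct.grid, vals, "ct_hu")
        beam = BeamSpec(BeamGeometry(0.0), nominal_range_mm=80.0, field_size_mm=(30, 20))
        pb_w = pb_dose(ct, beam)
        pb_s = pb_dose(ct2, beam)
        j, k = (s // 2 for s in ct.grid.shape[1:])
        peak_w = x[np.argmax(pb_w.values[:, j, k])]
        peak_s = x[np.argmax(pb_s.values[:, j, k])]
        bone_rsp = float(DEFAULT_TABLE.rsp_of(MATERIAL_HU["bone"]))
        expect = (bone_rsp - 1.0) * thick
        assert (peak_w - peak_s) == pytest.approx(expect, abs=1.1 * ct.grid.spacing[0])
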