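from dataclasses import replace

import numpy as np
import pytest

from drusenlab import synthetic
from drusenlab.geometry import DrusenGeometry, make_region_spec
from drusenlab.morphometrics import classify_modality
from drusenlab.synthetic import (
    MonolayerPhantomParams,
    MosaicParams,
    generate_bead_pair,
    generate_cell_mosaic,
    generate_focus_stack_pair,
    generate_indentation_curve,
    generate_monolayer_stack,
    generate_swelling_series,
    get_preset,
    make_disc_traction,
)

from conftest import make_flat_params


class TestMonolayerStack:
    def test_determinism(self):
        params, geom = get_preset("medium-drusen", seed=7)
        s1, t1 = generate_monolayer_stack(params, geom)
        s2, t2 = generate_monolayer_stack(params, geom)
        assert np.array_equal(s1.voxels, s2.voxels)
        assert np.array_equal(t1, t2)

    def test_flat_phantom_ground_truth(self, flat_stack):
        params, geom, stack, truth = flat_stack
        assert np.all(truth == params.baseline_thickness_um)

    def test_ground_truth_is_analytic(self, medium_preset):
        # exact multiplier values, no discretization in the truth channel
        params, geom, stack, truth = medium_preset
        assert set(np.unique(truth)) == {12.0, 12.0 * 1.03, 12.0 * 1.05}

    @pytest.mark.parametrize(
        "preset,expected_ratio",
        [("medium-drusen", 1.05), ("large-drusen", 0.95)],
    )
    def test_preset_top_outside_ratio(self, preset, expected_ratio):
        params, geom = get_preset(preset, seed=0)
        _, truth = generate_monolayer_stack(params, geom)
        n = truth.shape[0]
        coords = (np.arange(n) + 0.5) * params.pixel_pitch_um
        xg, yg = np.meshgrid(coords, coords)
        r = np.hypot(xg - geom.center_xy[0], yg - geom.center_xy[1])
        top = truth[r < 25].mean()
        outside = truth[(r >= 150) & (r < 175)].mean()
        assert top / outside == pytest.approx(expected_ratio, rel=1e-12)

    def test_medium_edge_ratio(self):
        params, geom = get_preset("medium-drusen")
        _, truth = generate_monolayer_stack(params, geom)
        n = truth.shape[0]
        coords = (np.arange(n) + 0.5) * params.pixel_pitch_um
        xg, yg = np.meshgrid(coords, coords)
        r = np.hypot(xg - geom.center_xy[0], yg - geom.center_xy[1])
        edge = truth[(r >= 25) & (r < 50)].mean()
        outside = truth[(r >= 150) & (r < 175)].mean()
        assert edge / outside == pytest.approx(1.03, rel=1e-12)

    def test_apex_too_tall_rejected(self):
        with pytest.raises(ValueError, match="stack depth"):
            make_flat_params(bulge_apex_um=50.0, stack_depth_um=40.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            make_flat_params(baseline_thickness_um=-1.0)
        with pytest.raises(ValueError):
            make_flat_params(thickness_modifiers={"Top": 0.0})
        with pytest.raises(ValueError):
            make_flat_params(z_step_um=7.0)  # thickness unresolvable
        with pytest.raises(ValueError):
            make_flat_params(band_width_um=6.5)  # bands would overlap

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset"):
            get_preset("tiny-drusen")

    def test_gaussian_profile_option(self):
        params = make_flat_params(
            bulge_apex_um=5.0, bulge_profile="gaussian", stack_depth_um=25.0
        )
        geom = DrusenGeometry((30.0, 30.0), 100.0)
        stack, truth = generate_monolayer_stack(params, geom)
        assert stack.n_planes == 100


class TestCellMosaic:
    def test_determinism(self, mosaic_default):
        params, geom, mask, gt = mosaic_default
        mask2, gt2 = generate_cell_mosaic(params, geom)
        assert np.array_equal(mask.labels, mask2.labels)
        assert gt.equals(gt2)

    def test_ring_cells_circumferential(self):
        params = MosaicParams(
            orientation_field="circumferential_ring",
            ring_inner_um=25.0,
            ring_outer_um=50.0,
            seed=5,
        )
        geom = DrusenGeometry((150.0, 150.0), 100.0)
        _, gt = generate_cell_mosaic(params, geom)
        ring = gt[gt["angle_class"] == "circumferential"]
        assert len(ring) > 5
        assert ring["angle_to_origin_deg"].median() >= 80.0

    def test_radial_cap_cells(self):
        params = MosaicParams(orientation_field="radial_cap", cap_radius_um=50.0, seed=5)
        geom = DrusenGeometry((150.0, 150.0), 100.0)
        _, gt = generate_cell_mosaic(params, geom)
        cap = gt[gt["angle_class"] == "radial"]
        assert len(cap) > 5
        assert cap["angle_to_origin_deg"].median() <= 10.0

    def test_unimodal_ground_truth_areas(self, mosaic_default):
        _, _, _, gt = mosaic_default
        result = classify_modality(gt["target_area_um2"].to_numpy())
        assert result.classification == "unimodal"

    def test_bimodal_ground_truth_areas(self):
        params = MosaicParams(
            n_cells=500,
            frame_size_um=500.0,
            area_modality="bimodal",
            mean_area_um2=150.0,
            mode2_mean_area_um2=700.0,
            area_cv=0.2,
            seed=11,
        )
        geom = DrusenGeometry((250.0, 250.0), 100.0)
        _, gt = generate_cell_mosaic(params, geom)
        assert set(gt["area_mode"]) == {1, 2}
        result = classify_modality(gt["target_area_um2"].to_numpy())
        assert result.classification == "bimodal"

    def test_random_field_mean_angle_near_45(self):
        # sampling-limited check on the ground-truth table; the tight 45° ± 1°
        # Monte-Carlo limit is asserted on the angle metric itself elsewhere
        params = MosaicParams(n_cells=400, frame_size_um=350.0, seed=2)
        geom = DrusenGeometry((175.0, 175.0), 100.0)
        _, gt = generate_cell_mosaic(params, geom)
        assert gt["angle_to_origin_deg"].mean() == pytest.approx(45.0, abs=5.0)

    def test_realized_areas_recorded(self, mosaic_default):
        params, _, mask, gt = mosaic_default
        counts = np.bincount(mask.labels.ravel(), minlength=params.n_cells + 1)[1:]
        assert np.array_equal(gt["n_pixels"].to_numpy(), counts)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            MosaicParams(mixing_fraction=1.5)
        with pytest.raises(ValueError):
            MosaicParams(ring_inner_um=50.0, ring_outer_um=25.0)
        with pytest.raises(ValueError):
            MosaicParams(n_cells=100000)  # does not fit the frame
        with pytest.raises(ValueError):
            MosaicParams(orientation_field="spiral")


class TestBeadPair:
    def test_zero_traction_identical_images(self):
        tf = make_disc_traction(32, 4.0, 20.0, 0.0)
        ref, dfm, truth = generate_bead_pair(tf, image_size_px=128, n_beads=200, seed=4)
        assert np.array_equal(ref, dfm)
        assert np.all(truth.u == 0) and np.all(truth.v == 0)

    def test_determinism(self):
        tf = make_disc_traction(32, 4.0, 20.0, 300.0)
        a = generate_bead_pair(tf, image_size_px=128, n_beads=200, seed=4)
        b = generate_bead_pair(tf, image_size_px=128, n_beads=200, seed=4)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_displacement_decays_outside_disc(self):
        # forward half-space solution: magnitude decreases moving out from the rim
        tf = make_disc_traction(64, 2.0, 16.0, 500.0)
        _, _, truth = generate_bead_pair(tf, image_size_px=64, n_beads=10, seed=0)
        mag = np.hypot(truth.u, truth.v)
        center_idx = 32
        row = mag[center_idx, :]
        x = truth.x
        cx = x[center_idx]
        outside = (x - cx) > 16.0
        profile = row[outside]
        assert np.all(np.diff(profile) < 1e-9)


class TestIndentationCurve:
    def test_zero_depth_zero_force(self):
        curve = generate_indentation_curve()
        assert curve.force_n[0] == 0.0

    def test_closed_form_value_at_full_depth(self):
        # hand calculation: (4/3) * 4000 Pa * sqrt(10e-6 m) * (3.5e-6 m)^1.5
        curve = generate_indentation_curve(E_eff_pa=4000.0, tip_radius_um=10.0,
                                           depth_max_um=3.5)
        assert curve.force_n[-1] == pytest.approx(1.1043e-7, rel=1e-3)

    def test_linear_in_modulus(self):
        c1 = generate_indentation_curve(E_eff_pa=2000.0)
        c2 = generate_indentation_curve(E_eff_pa=4000.0)
        np.testing.assert_allclose(c2.force_n, 2.0 * c1.force_n, rtol=1e-12)

    def test_determinism_with_noise(self):
        a = generate_indentation_curve(multiplicative_noise=0.2, seed=9)
        b = generate_indentation_curve(multiplicative_noise=0.2, seed=9)
        np.testing.assert_array_equal(a.force_n, b.force_n)


class TestSwellingSeries:
    def test_zero_at_t0(self):
        s = generate_swelling_series(plateau_um=100.0, tau_h=2.0)
        assert s.heights_raw_um[s.times_h == 0.0][0] == 0.0

    def test_plateau_approached(self):
        s = generate_swelling_series(
            plateau_um=100.0, tau_h=2.0, sample_times_h=np.array([0.0, 100.0])
        )
        assert s.heights_raw_um[-1] == pytest.approx(100.0, rel=1e-6)

    def test_determinism(self):
        a = generate_swelling_series(noise_sd_um=1.0, seed=3)
        b = generate_swelling_series(noise_sd_um=1.0, seed=3)
        np.testing.assert_array_equal(a.heights_raw_um, b.heights_raw_um)


class TestFocusStackPair:
    def test_apex_not_representable(self):
        with pytest.raises(ValueError, match="not representable"):
            generate_focus_stack_pair(apex_height_um=200.0)

    def test_shapes_and_calibration(self):
        ref, post = generate_focus_stack_pair(seed=1)
        assert ref.n_planes == 40 and post.n_planes == 40
        assert ref.z_step == 4.0
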