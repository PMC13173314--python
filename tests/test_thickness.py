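import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from drusenlab.geometry import DrusenGeometry, make_region_spec
from drusenlab.io import ImageStack
from drusenlab.synthetic import generate_monolayer_stack
from drusenlab.thickness import (
    fractional_indices,
    measure_monolayer,
    normalize_heights,
    profile_height,
    reslice_stack,
)

from conftest import make_flat_params


# --- independent oracle: the threshold rule implemented literally -----------

def oracle_boundaries(profile, z_step):
    """Exhaustive scan: mean threshold, strictly-greater crossings, no interp."""
    profile = np.asarray(profile, dtype=float)
    threshold = profile.mean()
    basal = apical = None
    for i in range(len(profile)):
        if profile[i] > threshold:
            basal = (i + 0.5) * z_step
            break
    for i in range(len(profile) - 1, -1, -1):
        if profile[i] > threshold:
            apical = (i + 0.5) * z_step
            break
    if basal is None or apical is None or not apical > basal:
        return None
    return basal, apical


class TestFractionalIndices:
    def test_1000_rows(self):
        assert fractional_indices(1000) == [50, 150, 250, 350, 450, 550, 650, 750, 850, 950]

    def test_10_rows_degenerate(self):
        # ties at .5 round down: 0.15*10 = 1.5 -> 1, etc.
        assert fractional_indices(10) == list(range(10))

    def test_round_half_down(self):
        # 0.05 * 30 = 1.5 rounds down to 1
        assert fractional_indices(30)[0] == 1

    def test_too_small(self):
        with pytest.raises(ValueError):
            fractional_indices(9)


class TestReslice:
    def test_plane_positions_and_count(self):
        stack = ImageStack(np.zeros((4, 40, 15)), 2.0, 1.0)
        planes = reslice_stack(stack)
        assert len(planes) == 10
        rows = [p[0] for p in planes]
        assert rows == [2, 6, 10, 14, 18, 22, 26, 30, 34, 38]
        assert planes[0][1] == pytest.approx(2.5 * 2.0)
        assert planes[0][2].shape == (4, 15)

    def test_count_independent_of_z_depth(self):
        shallow = ImageStack(np.zeros((2, 40, 12)), 1.0, 1.0)
        deep = ImageStack(np.zeros((64, 40, 12)), 1.0, 1.0)
        assert len(reslice_stack(shallow)) == len(reslice_stack(deep)) == 10

    def test_too_few_rows(self):
        stack = ImageStack(np.zeros((4, 8, 12)), 1.0, 1.0)
        with pytest.raises(ValueError):
            reslice_stack(stack)


class TestProfileHeight:
    def test_two_band_profile_hand_oracle(self):
        # bands centered at z = 4 and 16 µm, equal shape. Expected values were
        # computed by hand-tracing the rule on this printed profile: the mean
        # threshold is 9.1743 and linear interpolation between the bracketing
        # samples puts the crossings at 2.6988 and 17.3012.
        z_step = 1.0
        z = (np.arange(20) + 0.5) * z_step
        profile = 100.0 * (
            np.exp(-((z - 4.0) ** 2) / (2 * 0.4**2))
            + np.exp(-((z - 16.0) ** 2) / (2 * 0.4**2))
        )
        basal, apical = profile_height(profile[:, None], 0, z_step)
        assert basal == pytest.approx(2.6988, abs=1e-3)
        assert apical == pytest.approx(17.3012, abs=1e-3)
        # equal band shapes: crossings are symmetric about the band midpoint
        assert (basal + apical) / 2 == pytest.approx(10.0, abs=1e-9)

    def test_all_zero_undetected(self):
        plane = np.zeros((30, 3))
        assert profile_height(plane, 1, 0.5) is None

    def test_constant_undetected(self):
        plane = np.full((30, 3), 7.0)
        assert profile_height(plane, 0, 0.5) is None

    def test_single_band_degenerate_height(self):
        z = (np.arange(40) + 0.5) * 0.5
        profile = 100.0 * np.exp(-((z - 10.0) ** 2) / (2 * 0.3**2))
        result = profile_height(profile[:, None], 0, 0.5)
        assert result is None or (result[1] - result[0]) < 2.0

    def test_intensity_scale_invariance(self):
        rng = np.random.default_rng(0)
        profile = rng.uniform(0, 100, 50)
        a = profile_height(profile[:, None], 0, 0.25)
        b = profile_height((profile * 37.5)[:, None], 0, 0.25)
        assert a == pytest.approx(b)

    @given(
        profile=st.lists(
            st.floats(0, 1000, allow_nan=False), min_size=4, max_size=60
        ),
        z_step=st.floats(0.1, 2.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_oracle_equivalence_no_interp(self, profile, z_step):
        plane = np.asarray(profile)[:, None]
        got = profile_height(plane, 0, z_step, interpolate=False)
        expected = oracle_boundaries(profile, z_step)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)

    def test_interpolation_hand_example(self):
        # profile 0,0,10,10,0,0 with mean 10/3: crossing between samples 1 and 2
        # at fraction (10/3)/10 = 1/3 above sample 1
        profile = np.array([0.0, 0.0, 10.0, 10.0, 0.0, 0.0])
        basal, apical = profile_height(profile[:, None], 0, 1.0)
        assert basal == pytest.approx(1.5 + 1.0 / 3.0)
        assert apical == pytest.approx(4.5 - 1.0 / 3.0)


class TestMeasureMonolayer:
    def test_flat_phantom_exactness(self, flat_stack):
        params, geometry, stack, truth = flat_stack
        spec = make_region_spec(100.0)
        df = measure_monolayer(stack, geometry, spec)
        assert len(df) == 100
        assert df.attrs["n_undetected"] == 0
        np.testing.assert_allclose(
            df["height_um"], params.baseline_thickness_um, atol=params.z_step_um
        )

    def test_scaling_thickness(self):
        geometry = DrusenGeometry((30.0, 30.0), 100.0)
        spec = make_region_spec(100.0)
        heights = {}
        for t in (8.0, 12.0):
            params = make_flat_params(baseline_thickness_um=t)
            stack, _ = generate_monolayer_stack(params, geometry)
            heights[t] = measure_monolayer(stack, geometry, spec)["height_um"].to_numpy()
        np.testing.assert_allclose(
            heights[12.0], 1.5 * heights[8.0], atol=3 * 0.25
        )

    def test_medium_phantom_ratio_noise_off(self, medium_noiseless):
        params, geometry, stack, truth = medium_noiseless
        spec = make_region_spec(geometry.illumination_diameter)
        df = measure_monolayer(stack, geometry, spec)
        means = df.groupby("region")["height_um"].mean()
        assert means["Top"] / means["Outside"] == pytest.approx(1.05, abs=0.01)

    def test_distance_zero_at_center(self):
        params = make_flat_params()
        # center on the grid point at fractional position 0.45 of a 60 px frame
        idx = fractional_indices(60)[4]
        center = ((idx + 0.5) * 1.0, (idx + 0.5) * 1.0)
        geometry = DrusenGeometry(center, 100.0)
        stack, _ = generate_monolayer_stack(params, geometry)
        df = measure_monolayer(stack, geometry, make_region_spec(100.0))
        assert df["distance_um"].min() == pytest.approx(0.0, abs=1e-9)

    def test_stack_intensity_scaling_leaves_heights(self, flat_stack):
        params, geometry, stack, _ = flat_stack
        spec = make_region_spec(100.0)
        scaled = ImageStack(
            stack.voxels.astype(np.float64) * 2.5, stack.pixel_pitch, stack.z_step
        )
        a = measure_monolayer(stack, geometry, spec)
        b = measure_monolayer(scaled, geometry, spec)
        np.testing.assert_allclose(a["height_um"], b["height_um"], rtol=1e-12)


class TestNormalizeHeights:
    def test_simple_arithmetic(self):
        df = pd.DataFrame({"height_um": [10.0, 12.0, 14.0], "replicate": ["a"] * 3})
        out = normalize_heights(df)
        np.testing.assert_allclose(
            out["height_norm"], [0.833333, 1.0, 1.166667], rtol=1e-5
        )

    def test_single_measurement(self):
        df = pd.DataFrame({"height_um": [42.0], "replicate": ["a"]})
        assert normalize_heights(df)["height_norm"].iloc[0] == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            normalize_heights(pd.DataFrame({"height_um": []}))

    def test_group_means_exactly_one(self, measured_medium):
        means = measured_medium.groupby("replicate")["height_norm"].mean()
        np.testing.assert_allclose(means, 1.0, rtol=1e-12)

    @given(
        heights=st.lists(st.floats(1.0, 100.0), min_size=1, max_size=30),
        heights_b=st.lists(st.floats(1.0, 100.0), min_size=1, max_size=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_per_group_unit_mean_property(self, heights, heights_b):
        df = pd.DataFrame(
            {
                "height_um": heights + heights_b,
                "replicate": ["a"] * len(heights) + ["b"] * len(heights_b),
            }
        )
        out = normalize_heights(df)
        means = out.groupby("replicate")["height_norm"].mean()
        np.testing.assert_allclose(means, 1.0, rtol=1e-9)
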