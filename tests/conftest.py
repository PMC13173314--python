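"""Shared fixtures: small, seeded phantoms generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from drusenlab import synthetic, thickness
from drusenlab.geometry import DrusenGeometry, make_region_spec


@pytest.fixture(scope="session")
def medium_preset():
    """Default medium-drusen phantom (noise on), seed 1."""
    params, geometry = synthetic.get_preset("medium-drusen", seed=1)
    stack, truth = synthetic.generate_monolayer_stack(params, geometry)
    return params, geometry, stack, truth


@pytest.fixture(scope="session")
def medium_noiseless():
    from dataclasses import replace

    params, geometry = synthetic.get_preset("medium-drusen", seed=1)
    params = replace(params, noise_sd=0.0)
    stack, truth = synthetic.generate_monolayer_stack(params, geometry)
    return params, geometry, stack, truth


def make_flat_params(**overrides):
    """Small, fast, flat (unit-modifier) phantom for slab tests."""
    defaults = dict(
        frame_size_um=60.0,
        pixel_pitch_um=1.0,
        z_step_um=0.25,
        stack_depth_um=20.0,
        bulge_diameter_um=100.0,
        bulge_apex_um=0.001,
        baseline_thickness_um=12.0,
        thickness_modifiers={},
        noise_sd=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return synthetic.MonolayerPhantomParams(**defaults)


@pytest.fixture(scope="session")
def flat_stack():
    params = make_flat_params()
    geometry = DrusenGeometry((30.0, 30.0), 100.0)
    stack, truth = synthetic.generate_monolayer_stack(params, geometry)
    return params, geometry, stack, truth


@pytest.fixture(scope="session")
def mosaic_default():
    params = synthetic.MosaicParams(seed=3)
    geometry = DrusenGeometry((150.0, 150.0), 100.0)
    mask, gt = synthetic.generate_cell_mosaic(params, geometry)
    return params, geometry, mask, gt


@pytest.fixture(scope="session")
def measured_medium(medium_preset):
    """Thickness measurements on the default medium phantom."""
    params, geometry, stack, truth = medium_preset
    spec = make_region_spec(geometry.illumination_diameter)
    df = thickness.measure_monolayer(stack, geometry, spec)
    df["replicate"] = "rep-1"
    return thickness.normalize_heights(df)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
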