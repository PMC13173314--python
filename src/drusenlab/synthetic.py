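"""Seeded phantom generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and seed — identical
inputs give bit-identical outputs — and emits ground truth alongside the
rendered data so downstream recovery can be tested without real microscopy:

* ``generate_monolayer_stack`` — two-band (basal/apical) actin-like z-stack
  over a dome-shaped bulge, plus the exact thickness map;
* ``generate_cell_mosaic`` — anisotropic power-diagram cell mosaic with
  controllable area modality and orientation field, plus a per-cell table;
* ``generate_bead_pair`` — fiducial bead images displaced by the forward
  elastic half-space solution of a known traction field;
* ``generate_indentation_curve`` — forward spherical-contact force curve;
* ``generate_swelling_series`` — saturating-exponential bulge growth;
* ``generate_focus_stack_pair`` — textured focus stacks before/after bulging
  for the apex-height method.

The named presets ``medium-drusen`` (100 µm bulge; thickness +5% Top, +3%
Edge) and ``large-drusen`` (300 µm bulge; -5% Top) carry the target effect
sizes as ground-truth multipliers, so pipeline acceptance reduces to
parameter recovery. The absolute baseline thickness (12 µm) is a free
choice: no reference value is asserted for it anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .geometry import DrusenGeometry, RegionSpec, make_region_spec
from .hertz import IndentationCurve, hertz_force
from .io import ImageStack, LabelMask
from .swelling import SwellingSeries
from .traction import DisplacementField, TractionField, forward_displacement

__all__ = [
    "MonolayerPhantomParams",
    "MosaicParams",
    "generate_monolayer_stack",
    "generate_cell_mosaic",
    "generate_bead_pair",
    "generate_indentation_curve",
    "generate_swelling_series",
    "generate_focus_stack_pair",
    "make_disc_traction",
    "get_preset",
    "PRESET_NAMES",
    "HYDROGEL_DEFAULT_E_PA",
    "DEFAULT_TIP_RADIUS_UM",
    "DEFAULT_MAX_DEPTH_UM",
]

#: Default substrate stiffness (Pa) and indentation preset.
HYDROGEL_DEFAULT_E_PA = 4000.0
DEFAULT_TIP_RADIUS_UM = 10.0  # 20 µm spherical tip => radius 10 µm
DEFAULT_MAX_DEPTH_UM = 3.5

#: Gap between the stack floor and the undeformed substrate surface, µm.
#: Deliberately incommensurate with the default z step so the flat far-field
#: does not sit at a privileged sub-voxel phase of the z grid.
_SUBSTRATE_MARGIN_UM = 2.137


def _rng(seed: int, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(seed)


def _dome_profile(
    r: np.ndarray, diameter: float, apex: float, kind: str = "spherical_cap"
) -> np.ndarray:
    """Bulge surface height (µm) vs radial distance (µm).

    ``spherical_cap`` (default): the cap through radius D/2 with the given
    apex height, zero outside the illuminated disc. ``gaussian``: a dome
    ``apex * exp(-r^2 / (2 sigma^2))`` with ``sigma = D/4``.
    """
    a = diameter / 2.0
    if kind == "spherical_cap":
        big_r = (a**2 + apex**2) / (2.0 * apex)
        inside = r < a
        z = np.zeros_like(r, dtype=float)
        z[inside] = np.sqrt(big_r**2 - r[inside] ** 2) - (big_r - apex)
        return z
    if kind == "gaussian":
        sigma = diameter / 4.0
        return apex * np.exp(-(r**2) / (2.0 * sigma**2))
    raise ValueError(f"unknown bulge profile {kind!r}")


# ---------------------------------------------------------------------------
# monolayer thickness phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonolayerPhantomParams:
    """Parameters of the two-band monolayer phantom.

    The rendered monolayer occupies ``[z_s, z_s + t]`` above the (possibly
    bulged) substrate surface ``z_s``; bright bands of width ``band_width_um``
    sit just inside its basal and apical faces so the band outer edges mark
    the true monolayer boundaries. ``thickness_modifiers`` multiply the
    baseline thickness per region name; unlisted regions (and unassigned
    points) keep the baseline.
    """

    frame_size_um: float = 300.0
    pixel_pitch_um: float = 1.0
    z_step_um: float = 0.25
    stack_depth_um: float = 40.0
    bulge_diameter_um: float = 100.0
    bulge_apex_um: float = 20.0
    baseline_thickness_um: float = 12.0
    thickness_modifiers: dict[str, float] = field(default_factory=dict)
    band_width_um: float = 3.0
    band_intensity: float = 300.0
    cytoplasm_intensity: float = 260.0
    background_intensity: float = 20.0
    band_edge_sigma_um: float = 0.0
    #: Total substrate-plane rise across the frame diagonal, µm. A real gel
    #: is never perfectly level; a gentle tilt also spreads the sub-voxel
    #: phase of the band edges so no region sits at a privileged phase.
    surface_tilt_um: float = 1.37
    noise_sd: float = 8.0
    poisson_noise: bool = False
    bulge_profile: str = "spherical_cap"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frame_size_um", "pixel_pitch_um", "z_step_um", "stack_depth_um",
            "bulge_diameter_um", "bulge_apex_um", "baseline_thickness_um",
            "band_width_um",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if any(m <= 0 for m in self.thickness_modifiers.values()):
            raise ValueError("thickness modifiers must be positive")
        if not self.baseline_thickness_um > 2.0 * self.z_step_um:
            raise ValueError("baseline thickness not resolvable at this z step")
        t_min = self.baseline_thickness_um * min(
            [1.0, *self.thickness_modifiers.values()]
        )
        if not t_min > 2.0 * self.band_width_um:
            raise ValueError("bands overlap: thickness must exceed twice band width")
        t_max = self.baseline_thickness_um * max(
            [1.0, *self.thickness_modifiers.values()]
        )
        needed = _SUBSTRATE_MARGIN_UM + self.bulge_apex_um + t_max + self.band_width_um
        if needed > self.stack_depth_um:
            raise ValueError(
                f"stack depth {self.stack_depth_um} µm cannot hold bulge apex plus "
                f"monolayer (needs >= {needed:.1f} µm)"
            )


def _region_modifier_map(
    r: np.ndarray, spec: RegionSpec, modifiers: dict[str, float]
) -> np.ndarray:
    mod = np.ones_like(r, dtype=float)
    for annulus in spec.annuli:
        factor = modifiers.get(annulus.name)
        if factor is not None:
            mod[(r >= annulus.inner) & (r < annulus.outer)] = factor
    return mod


def generate_monolayer_stack(
    params: MonolayerPhantomParams,
    geometry: DrusenGeometry,
    rng: np.random.Generator | None = None,
) -> tuple[ImageStack, np.ndarray]:
    """Render the monolayer phantom and return it with its ground truth.

    Voxels are box-sampled along z (each voxel holds the coverage-weighted
    intensity of its physical extent), so band edges land at their exact
    analytic positions rather than snapping to the z grid; an optional
    Gaussian ``band_edge_sigma_um`` softens the edges further. Returns
    ``(stack, thickness_map)`` where ``thickness_map`` is the exact analytic
    thickness t(x, y) in µm (no discretization).
    """
    rng = _rng(params.seed, rng)
    pitch = params.pixel_pitch_um
    dz = params.z_step_um
    n_xy = int(round(params.frame_size_um / pitch))
    n_z = int(round(params.stack_depth_um / dz))
    coords = (np.arange(n_xy) + 0.5) * pitch
    xg, yg = np.meshgrid(coords, coords)
    r = np.hypot(xg - geometry.center_xy[0], yg - geometry.center_xy[1])

    spec = make_region_spec(geometry.illumination_diameter)
    thickness = params.baseline_thickness_um * _region_modifier_map(
        r, spec, params.thickness_modifiers
    )
    z_surface = _SUBSTRATE_MARGIN_UM + _dome_profile(
        r, params.bulge_diameter_um, params.bulge_apex_um, params.bulge_profile
    )
    if params.surface_tilt_um:
        z_surface = z_surface + params.surface_tilt_um * (xg + yg) / (
            2.0 * params.frame_size_um
        )

    zc = ((np.arange(n_z, dtype=np.float32) + 0.5) * dz)[:, None, None]
    z_s = z_surface.astype(np.float32)[None, :, :]
    z_a = (z_surface + thickness).astype(np.float32)[None, :, :]
    w = params.band_width_um

    def rise(edge):  # fraction of each voxel's z extent above `edge`
        return np.clip((zc + dz / 2 - edge) / dz, 0.0, 1.0)

    bg = params.background_intensity
    band = params.band_intensity - bg
    cyto = params.cytoplasm_intensity - bg
    img = np.full((n_z, n_xy, n_xy), bg, dtype=np.float32)
    r_bas, r_bas_in = rise(z_s), rise(z_s + w)
    r_api_in, r_api = rise(z_a - w), rise(z_a)
    img += band * (r_bas - r_bas_in)
    img += cyto * (r_bas_in - r_api_in)
    img += band * (r_api_in - r_api)
    if params.band_edge_sigma_um > 0:
        from scipy.ndimage import gaussian_filter1d

        img = gaussian_filter1d(
            img, params.band_edge_sigma_um / dz, axis=0, mode="nearest"
        )
    if params.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float32)
    if params.noise_sd > 0:
        img = img + params.noise_sd * rng.standard_normal(img.shape, dtype=np.float32)
    img = np.clip(img, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    stack = ImageStack(img, pitch, dz, channel="F-actin")
    return stack, thickness


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_PRESETS: dict[str, MonolayerPhantomParams] = {
    "medium-drusen": MonolayerPhantomParams(
        bulge_diameter_um=100.0,
        thickness_modifiers={"Top": 1.05, "Edge": 1.03},
    ),
    "large-drusen": MonolayerPhantomParams(
        bulge_diameter_um=300.0,
        thickness_modifiers={"Top": 0.95, "Edge": 1.00},
    ),
}
PRESET_NAMES = tuple(_PRESETS)


def get_preset(
    name: str, seed: int = 0, noise_sd: float | None = None
) -> tuple[MonolayerPhantomParams, DrusenGeometry]:
    """Named phantom preset and its matching geometry (center mid-frame)."""
    try:
        base = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}") from None
    params = replace(
        base, seed=seed, noise_sd=base.noise_sd if noise_sd is None else noise_sd
    )
    half = params.frame_size_um / 2.0
    geometry = DrusenGeometry(
        center_xy=(half, half),
        illumination_diameter=params.bulge_diameter_um,
        condition_label=name,
    )
    return params, geometry


# ---------------------------------------------------------------------------
# cell mosaic phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MosaicParams:
    """Parameters of the anisotropic cell-mosaic phantom.

    Cell areas are drawn from a one- or two-component lognormal mixture
    (modality ``unimodal``/``bimodal``); sizes enter an additively weighted
    (power-diagram) nearest-seed assignment, and per-cell orientation is
    imposed by an anisotropic distance metric elongating each cell along its
    intended axis. Orientation fields: ``random`` (uniform axial),
    ``circumferential_ring`` (tangential inside ``ring_inner..ring_outer``),
    ``radial_cap`` (radial inside ``cap_radius``).
    """

    n_cells: int = 300
    frame_size_um: float = 300.0
    pixel_pitch_um: float = 1.0
    mean_area_um2: float = 250.0
    area_modality: str = "unimodal"
    mode2_mean_area_um2: float = 550.0
    mixing_fraction: float = 0.5
    area_cv: float = 0.25
    orientation_field: str = "random"
    ring_inner_um: float = 25.0
    ring_outer_um: float = 50.0
    cap_radius_um: float = 25.0
    elongation: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.area_modality not in ("unimodal", "bimodal"):
            raise ValueError(f"unknown area_modality {self.area_modality!r}")
        if not 0 < self.mixing_fraction < 1:
            raise ValueError("mixing_fraction must be in (0, 1)")
        if not self.ring_inner_um < self.ring_outer_um:
            raise ValueError("ring radii must be ordered inner < outer")
        if self.orientation_field not in (
            "random", "circumferential_ring", "radial_cap"
        ):
            raise ValueError(f"unknown orientation_field {self.orientation_field!r}")
        if self.n_cells * self.mean_area_um2 > self.frame_size_um**2:
            raise ValueError("n_cells too large for the frame at this mean area")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")


def _draw_areas(params: MosaicParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Target areas (µm²) and mode index (1 or 2) per cell."""
    sigma = np.sqrt(np.log(1.0 + params.area_cv**2))
    modes = np.ones(params.n_cells, dtype=int)
    if params.area_modality == "bimodal":
        modes = np.where(rng.random(params.n_cells) < params.mixing_fraction, 2, 1)
    mode_mean = np.where(modes == 2, params.mode2_mean_area_um2, params.mean_area_um2)
    mu = np.log(mode_mean) - 0.5 * sigma**2
    areas = rng.lognormal(mean=0.0, sigma=sigma, size=params.n_cells) * np.exp(mu)
    return areas, modes


def _intended_orientations(
    params: MosaicParams,
    seeds_xy: np.ndarray,
    geometry: DrusenGeometry,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Axial orientation (deg, [0, 180)) and angle-class label per seed."""
    n = seeds_xy.shape[0]
    orientations = rng.uniform(0.0, 180.0, size=n)
    klass = np.array(["random"] * n, dtype=object)
    dx = geometry.center_xy[0] - seeds_xy[:, 0]
    dy = geometry.center_xy[1] - seeds_xy[:, 1]
    r = np.hypot(dx, dy)
    radial_deg = np.degrees(np.arctan2(dy, dx)) % 180.0
    if params.orientation_field == "circumferential_ring":
        sel = (r >= params.ring_inner_um) & (r < params.ring_outer_um)
        orientations[sel] = (radial_deg[sel] + 90.0) % 180.0
        klass[sel] = "circumferential"
    elif params.orientation_field == "radial_cap":
        sel = r < params.cap_radius_um
        orientations[sel] = radial_deg[sel]
        klass[sel] = "radial"
    return orientations, klass


def generate_cell_mosaic(
    params: MosaicParams,
    geometry: DrusenGeometry,
    rng: np.random.Generator | None = None,
) -> tuple[LabelMask, pd.DataFrame]:
    """Render the mosaic mask and its per-cell ground-truth table.

    The table carries, per cell: seed position, target and realized area,
    area mode, intended axial orientation, intended angle class, intended
    angle-to-origin, and region of the seed point. Realized areas are exact
    pixel counts times pitch². No pipeline stage may read this table.
    """
    rng = _rng(params.seed, rng)
    pitch = params.pixel_pitch_um
    n_px = int(round(params.frame_size_um / pitch))

    # perturbed square lattice of seed points
    ns = int(np.ceil(np.sqrt(params.n_cells)))
    spacing = params.frame_size_um / ns
    jj, ii = np.meshgrid(np.arange(ns), np.arange(ns))
    sx = (jj.ravel() + 0.5) * spacing
    sy = (ii.ravel() + 0.5) * spacing
    order = rng.permutation(sx.size)[: params.n_cells]
    seeds = np.column_stack([sx[order], sy[order]])
    seeds += rng.uniform(-0.3 * spacing, 0.3 * spacing, size=seeds.shape)
    seeds = np.clip(seeds, 0.0, params.frame_size_um - 1e-9)

    areas, modes = _draw_areas(params, rng)
    orientations, klass = _intended_orientations(params, seeds, geometry, rng)
    theta = np.radians(orientations)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    elong = np.where(np.asarray(klass, dtype=object) == "random", 1.0, params.elongation)
    if params.orientation_field == "random":
        elong = np.full(params.n_cells, params.elongation)
    weights = areas / np.pi  # power-diagram radius², favors larger targets

    coords = (np.arange(n_px) + 0.5) * pitch
    xg, yg = np.meshgrid(coords, coords)
    labels = np.zeros((n_px, n_px), dtype=np.int32)
    best = np.full((n_px, n_px), np.inf)
    chunk = 64
    px = xg.ravel()
    py = yg.ravel()
    flat_best = best.ravel()
    flat_label = labels.ravel()
    for start in range(0, params.n_cells, chunk):
        sl = slice(start, min(start + chunk, params.n_cells))
        dx = px[:, None] - seeds[sl, 0][None, :]
        dy = py[:, None] - seeds[sl, 1][None, :]
        along = dx * cos_t[None, sl] + dy * sin_t[None, sl]
        across = -dx * sin_t[None, sl] + dy * cos_t[None, sl]
        d2 = (along / elong[None, sl]) ** 2 + (across * elong[None, sl]) ** 2
        d2 -= weights[None, sl]
        idx = np.argmin(d2, axis=1)
        val = d2[np.arange(d2.shape[0]), idx]
        better = val < flat_best
        flat_best[better] = val[better]
        flat_label[better] = start + idx[better] + 1
    labels = flat_label.reshape(n_px, n_px)

    counts = np.bincount(labels.ravel(), minlength=params.n_cells + 1)[1:]
    spec = make_region_spec(geometry.illumination_diameter)
    records = []
    for i in range(params.n_cells):
        seed_xy = (float(seeds[i, 0]), float(seeds[i, 1]))
        r = geometry.distance_to_center(seed_xy)
        if r > 0:
            dxc = geometry.center_xy[0] - seed_xy[0]
            dyc = geometry.center_xy[1] - seed_xy[1]
            radial = np.degrees(np.arctan2(dyc, dxc)) % 180.0
            diff = np.radians(orientations[i] - radial)
            angle = float(np.degrees(np.arccos(min(abs(np.cos(diff)), 1.0))))
        else:
            angle = float("nan")
        records.append(
            {
                "label": i + 1,
                "seed_x_um": seed_xy[0],
                "seed_y_um": seed_xy[1],
                "target_area_um2": float(areas[i]),
                "area_mode": int(modes[i]),
                "orientation_deg": float(orientations[i]),
                "angle_class": str(klass[i]),
                "angle_to_origin_deg": angle,
                "region": spec.assign(r),
                "area_um2": float(counts[i]) * pitch**2,
                "n_pixels": int(counts[i]),
            }
        )
    return LabelMask(labels.astype(np.int64), pitch), pd.DataFrame(records)


# ---------------------------------------------------------------------------
# bead pair for traction microscopy
# ---------------------------------------------------------------------------

def make_disc_traction(
    n_grid: int,
    spacing_um: float,
    disc_radius_um: float,
    magnitude_pa: float,
    center_um: tuple[float, float] | None = None,
    direction: tuple[float, float] = (1.0, 0.0),
    E: float = HYDROGEL_DEFAULT_E_PA,
    nu: float = 0.5,
) -> TractionField:
    """Uniform in-plane traction confined to a disc; a smooth test phantom."""
    coords = (np.arange(n_grid) + 0.5) * spacing_um
    if center_um is None:
        c = n_grid * spacing_um / 2.0
        center_um = (c, c)
    xg, yg = np.meshgrid(coords, coords)
    inside = np.hypot(xg - center_um[0], yg - center_um[1]) <= disc_radius_um
    norm = float(np.hypot(*direction))
    tx = np.where(inside, magnitude_pa * direction[0] / norm, 0.0)
    ty = np.where(inside, magnitude_pa * direction[1] / norm, 0.0)
    return TractionField(coords, coords, tx, ty, E=E, nu=nu)


def generate_bead_pair(
    traction: TractionField,
    image_size_px: int = 256,
    pixel_pitch_um: float = 0.5,
    n_beads: int = 3000,
    bead_sigma_px: float = 1.2,
    bead_amplitude: float = 500.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, DisplacementField]:
    """Reference and deformed bead images for a known traction field.

    Beads are random point sources rendered with a Gaussian PSF; the deformed
    image displaces each bead by the forward half-space surface-displacement
    solution of ``traction`` interpolated at the bead position. Returns
    ``(reference, deformed, ground_truth_displacement)`` — the images are 2D
    float arrays, the ground truth lives on the traction grid in µm.
    """
    rng = _rng(seed, rng)
    spacing = float(traction.x[1] - traction.x[0]) if traction.x.size > 1 else pixel_pitch_um
    ux, uy = forward_displacement(
        traction.tx, traction.ty, spacing, E=traction.E, nu=traction.nu
    )
    truth = DisplacementField(traction.x, traction.y, ux, uy)
    interp_u = RegularGridInterpolator(
        (traction.y, traction.x), ux, bounds_error=False, fill_value=0.0
    )
    interp_v = RegularGridInterpolator(
        (traction.y, traction.x), uy, bounds_error=False, fill_value=0.0
    )

    extent = image_size_px * pixel_pitch_um
    beads = rng.uniform(0.0, extent, size=(n_beads, 2))  # (x, y) µm
    du = interp_u(beads[:, [1, 0]])
    dv = interp_v(beads[:, [1, 0]])

    reference = _render_beads(beads, image_size_px, pixel_pitch_um, bead_sigma_px, bead_amplitude)
    moved = beads + np.column_stack([du, dv])
    deformed = _render_beads(moved, image_size_px, pixel_pitch_um, bead_sigma_px, bead_amplitude)
    if noise_sd > 0:
        reference = reference + rng.normal(0, noise_sd, reference.shape)
        deformed = deformed + rng.normal(0, noise_sd, deformed.shape)
    return reference, deformed, truth


def _render_beads(
    beads_xy_um: np.ndarray,
    size_px: int,
    pitch: float,
    sigma_px: float,
    amplitude: float,
) -> np.ndarray:
    """Sum of sub-pixel-positioned Gaussian spots on a square image."""
    img = np.zeros((size_px, size_px), dtype=float)
    half = int(np.ceil(4 * sigma_px))
    offsets = np.arange(-half, half + 1)
    for x_um, y_um in beads_xy_um:
        cx = x_um / pitch - 0.5
        cy = y_um / pitch - 0.5
        ix, iy = int(round(cx)), int(round(cy))
        cols = ix + offsets
        rows = iy + offsets
        ok_c = (cols >= 0) & (cols < size_px)
        ok_r = (rows >= 0) & (rows < size_px)
        if not (ok_c.any() and ok_r.any()):
            continue
        gx = np.exp(-((cols[ok_c] - cx) ** 2) / (2 * sigma_px**2))
        gy = np.exp(-((rows[ok_r] - cy) ** 2) / (2 * sigma_px**2))
        img[np.ix_(rows[ok_r], cols[ok_c])] += amplitude * np.outer(gy, gx)
    return img


# ---------------------------------------------------------------------------
# indentation, swelling, focus stacks
# ---------------------------------------------------------------------------

def generate_indentation_curve(
    E_eff_pa: float = HYDROGEL_DEFAULT_E_PA,
    tip_radius_um: float = DEFAULT_TIP_RADIUS_UM,
    depth_max_um: float = DEFAULT_MAX_DEPTH_UM,
    n_samples: int = 100,
    contact_point_um: float = 0.0,
    noise_sd_n: float = 0.0,
    multiplicative_noise: float = 0.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> IndentationCurve:
    """Forward spherical-contact curve sampled on a uniform depth grid.

    ``contact_point_um`` prepends a pre-contact baseline (zero force before
    the contact depth); additive noise is in newtons, multiplicative noise is
    a relative standard deviation.
    """
    rng = _rng(seed, rng)
    depth = np.linspace(0.0, depth_max_um + contact_point_um, n_samples)
    force = hertz_force(depth, E_eff_pa, tip_radius_um, contact_point_um)
    if multiplicative_noise > 0:
        force = force * (1.0 + rng.normal(0.0, multiplicative_noise, force.shape))
    if noise_sd_n > 0:
        force = force + rng.normal(0.0, noise_sd_n, force.shape)
    return IndentationCurve(depth, force, tip_radius_um)


def generate_swelling_series(
    plateau_um: float = 20.0,
    tau_h: float = 2.0,
    sample_times_h: np.ndarray | None = None,
    noise_sd_um: float = 0.0,
    druse_id: str = "synthetic",
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> SwellingSeries:
    """Saturating-exponential bulge height vs time (t = 0 at illumination).

    ``h(t) = plateau * (1 - exp(-t / tau))`` for t >= 0, zero before.
    """
    rng = _rng(seed, rng)
    if sample_times_h is None:
        sample_times_h = np.array([-1.0, 0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0])
    times = np.asarray(sample_times_h, dtype=float)
    heights = np.where(times >= 0, plateau_um * (1.0 - np.exp(-np.maximum(times, 0) / tau_h)), 0.0)
    if noise_sd_um > 0:
        heights = heights + rng.normal(0.0, noise_sd_um, heights.shape)
    return SwellingSeries(druse_id, times, heights)


def generate_focus_stack_pair(
    apex_height_um: float = 20.0,
    bulge_diameter_um: float = 100.0,
    n_slices: int = 40,
    z_step_um: float = 4.0,
    frame_size_um: float = 64.0,
    pixel_pitch_um: float = 1.0,
    surface_z_um: float = 40.0,
    focus_sigma_um: float = 6.0,
    texture_amplitude: float = 200.0,
    background: float = 50.0,
    noise_sd: float = 0.0,
    bulge_profile: str = "spherical_cap",
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[ImageStack, ImageStack]:
    """Brightfield-like focus stacks before and after bulge formation.

    A fixed random surface texture is rendered with a Gaussian focus envelope
    around the local surface height: flat at ``surface_z_um`` in the
    reference, domed by ``apex_height_um`` at the frame center afterwards.
    """
    rng = _rng(seed, rng)
    n_px = int(round(frame_size_um / pixel_pitch_um))
    if surface_z_um + apex_height_um >= n_slices * z_step_um:
        raise ValueError("apex not representable within the stack depth")
    texture = rng.uniform(0.0, 1.0, size=(n_px, n_px))
    coords = (np.arange(n_px) + 0.5) * pixel_pitch_um
    xg, yg = np.meshgrid(coords, coords)
    center = frame_size_um / 2.0
    r = np.hypot(xg - center, yg - center)
    dome = _dome_profile(r, bulge_diameter_um, apex_height_um, bulge_profile)
    zc = ((np.arange(n_slices) + 0.5) * z_step_um)[:, None, None]

    stacks = []
    for surface in (np.full_like(r, surface_z_um), surface_z_um + dome):
        envelope = np.exp(-((zc - surface[None]) ** 2) / (2.0 * focus_sigma_um**2))
        img = background + texture_amplitude * texture[None] * envelope
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        img = np.clip(img, 0, np.iinfo(np.uint16).max).astype(np.uint16)
        stacks.append(ImageStack(img, pixel_pitch_um, z_step_um, channel="brightfield"))
    return stacks[0], stacks[1]
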