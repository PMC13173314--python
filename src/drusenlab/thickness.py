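"""Monolayer-thickness profiling from an F-actin z-stack.

The stack is resliced into XZ planes at fixed fractional y positions (10%
intervals, 5% offset from the frame edge), and within each plane a vertical
(z) intensity line profile is drawn at the same fractional x positions,
yielding a 10x10 measurement grid. Each profile is thresholded at its own
arithmetic mean; the basal boundary is the first threshold crossing scanning
up from the substrate side and the apical boundary the first crossing
scanning down from the far side. The monolayer height is the vertical
distance between the two crossings. Heights are finally normalized by the
mean height of their replicate, so each replicate has unit mean by
construction.

Conventions (recorded in output metadata):

* fractional positions map to pixel indices by round-half-down;
* crossings are strictly greater-than the threshold;
* crossings are refined to sub-voxel precision by linear interpolation
  between the bracketing samples (disable with ``interpolate=False``);
* detections below a minimum plausible height (default 2 µm, single-band
  degenerate profiles) are dropped and counted, never silently discarded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DrusenGeometry, RegionSpec, assign_region
from .io import ImageStack

__all__ = [
    "ThicknessMeasurement",
    "reslice_stack",
    "fractional_indices",
    "profile_height",
    "measure_monolayer",
    "normalize_heights",
    "DEFAULT_MIN_HEIGHT_UM",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_HEIGHT_UM = 2.0
N_GRID = 10  # fractional positions 0.05, 0.15, ..., 0.95


@dataclass
class ThicknessMeasurement:
    """One line-profile result on the measurement grid."""

    plane_index: int  # index of the resliced XZ plane (y row)
    row: int  # pixel row of the plane
    col: int  # pixel column of the profile
    x_um: float
    y_um: float
    distance_um: float
    region: str
    basal_z_um: float
    apical_z_um: float
    height_um: float

    def __post_init__(self) -> None:
        if not self.apical_z_um > self.basal_z_um:
            raise ValueError("apical boundary must lie above the basal boundary")


def fractional_indices(n: int) -> list[int]:
    """Pixel indices for fractions (2k+1)/20, k = 0..9, rounding half down.

    A 1000-row frame yields rows 50, 150, ..., 950. The product is formed in
    integer arithmetic before the single division so ties land exactly on
    .5 and round down deterministically.
    """
    if n < N_GRID:
        raise ValueError(f"need at least {N_GRID} pixels, got {n}")
    return [
        min(math.ceil((2 * k + 1) * n / 20 - 0.5), n - 1) for k in range(N_GRID)
    ]


def reslice_stack(stack: ImageStack) -> list[tuple[int, float, np.ndarray]]:
    """Extract XZ planes at 10% y intervals with a 5% edge offset.

    Returns ``(row, y_um, plane)`` triples where ``plane`` has shape
    ``(n_z, n_x)``. The number of planes (10) is independent of z-depth.
    """
    n_rows = stack.voxels.shape[1]
    rows = fractional_indices(n_rows)
    return [
        (row, (row + 0.5) * stack.pixel_pitch, np.asarray(stack.voxels[:, row, :]))
        for row in rows
    ]


def _first_crossing_up(profile: np.ndarray, threshold: float, z_step: float) -> float | None:
    """z (µm) of the first strictly-above-threshold crossing from index 0."""
    above = profile > threshold
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    z = (i + 0.5) * z_step
    if i > 0:
        frac = (threshold - profile[i - 1]) / (profile[i] - profile[i - 1])
        z = (i - 1 + 0.5 + frac) * z_step
    return z


def profile_height(
    plane: np.ndarray,
    x_index: int,
    z_step: float,
    interpolate: bool = True,
) -> tuple[float, float] | None:
    """Basal and apical boundary z (µm) of one vertical intensity profile.

    The threshold is the arithmetic mean of the profile itself, which makes
    the rule invariant to any positive rescaling of the intensities. The
    basal boundary is found scanning from the substrate side (z index 0) and
    the apical boundary scanning from the opposite end. Returns ``None``
    ("undetected") when the profile never crosses its mean (e.g. constant) or
    when the two crossings do not bracket a positive height.
    """
    profile = np.asarray(plane[:, x_index], dtype=float)
    threshold = profile.mean()
    above = profile > threshold
    if not above.any():
        return None
    if interpolate:
        basal = _first_crossing_up(profile, threshold, z_step)
        apical_rev = _first_crossing_up(profile[::-1], threshold, z_step)
        assert basal is not None and apical_rev is not None
        apical = (profile.size * z_step) - apical_rev
    else:
        idx = np.nonzero(above)[0]
        basal = (int(idx[0]) + 0.5) * z_step
        apical = (int(idx[-1]) + 0.5) * z_step
    if not apical > basal:
        return None
    return basal, apical


def measure_monolayer(
    stack: ImageStack,
    geometry: DrusenGeometry,
    spec: RegionSpec,
    min_height_um: float = DEFAULT_MIN_HEIGHT_UM,
    interpolate: bool = True,
) -> pd.DataFrame:
    """Run the full thickness measurement grid over one stack.

    Returns one row per detected measurement with physical position, distance
    to the drusen center, region, boundary z positions and raw height. The
    number of undetected or sub-minimum profiles is logged and attached as
    ``df.attrs["n_undetected"]`` / ``df.attrs["n_below_min_height"]``.
    """
    planes = reslice_stack(stack)
    cols = fractional_indices(stack.voxels.shape[2])
    records: list[ThicknessMeasurement] = []
    n_undetected = 0
    n_below_min = 0
    for plane_index, (row, y_um, plane) in enumerate(planes):
        for col in cols:
            result = profile_height(plane, col, stack.z_step, interpolate)
            if result is None:
                n_undetected += 1
                continue
            basal, apical = result
            height = apical - basal
            if height < min_height_um:
                n_below_min += 1
                continue
            x_um = (col + 0.5) * stack.pixel_pitch
            records.append(
                ThicknessMeasurement(
                    plane_index=plane_index,
                    row=row,
                    col=col,
                    x_um=x_um,
                    y_um=y_um,
                    distance_um=geometry.distance_to_center((x_um, y_um)),
                    region=assign_region((x_um, y_um), geometry, spec),
                    basal_z_um=basal,
                    apical_z_um=apical,
                    height_um=height,
                )
            )
    if n_undetected or n_below_min:
        logger.info(
            "thickness grid: %d undetected, %d below min height %g um",
            n_undetected, n_below_min, min_height_um,
        )
    df = pd.DataFrame([vars(m) for m in records])
    df.attrs["n_undetected"] = n_undetected
    df.attrs["n_below_min_height"] = n_below_min
    df.attrs["min_height_um"] = min_height_um
    df.attrs["interpolate"] = interpolate
    df.attrs["rounding"] = "half-down"
    return df


def normalize_heights(
    measurements: pd.DataFrame, group_col: str | None = "replicate"
) -> pd.DataFrame:
    """Add ``height_norm`` = height / mean height of the same replicate.

    With ``group_col=None`` (or a column absent from the frame) all rows form
    one group. By construction the mean normalized height per group is
    exactly 1.
    """
    if measurements.empty:
        raise ValueError("no measurements to normalize")
    df = measurements.copy()
    if group_col is not None and group_col in df.columns:
        group_means = df.groupby(group_col)["height_um"].transform("mean")
    else:
        group_means = df["height_um"].mean()
    df["height_norm"] = df["height_um"] / group_means
    return df
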