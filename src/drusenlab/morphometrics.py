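"""Per-cell morphometrics from integer-labeled segmentation masks.

For every labeled cell the module reports physical area, a corner-corrected
(Crofton) perimeter, the dimensionless shape factor ``P / sqrt(A)``, the
axial orientation of the principal axis, the distance of the centroid to the
drusen center, the region it falls in, and the "angle to origin":

    theta = arccos(|u . v|)   in degrees,

where ``u`` is the unit vector along the cell's major axis and ``v`` the unit
vector from the centroid towards the drusen center. The angle is axial
(0 = radial, 90 = circumferential) and always lies in [0, 90].

Area distributions are pooled per region after per-replicate mean
normalization; modality of the (log) area distribution is classified by
comparing one- and two-component Gaussian mixtures with a BIC margin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from skimage.measure import regionprops
from sklearn.mixture import GaussianMixture

from .geometry import DrusenGeometry, RegionSpec, assign_region
from .io import LabelMask

__all__ = [
    "measure_cells",
    "angle_to_origin",
    "normalize_areas",
    "area_distribution",
    "AreaDistribution",
    "classify_modality",
    "ModalityResult",
    "MIN_CELLS_FOR_MODALITY",
]

logger = logging.getLogger(__name__)

MIN_CELL_PIXELS = 4
MIN_CELLS_FOR_MODALITY = 30
DELTA_BIC_THRESHOLD = 10.0


def _axial_orientation_deg(rp) -> float:
    """Major-axis angle in [0, 180) degrees, x-axis = columns, y = rows.

    Computed from the second central moments of the filled region; for a
    region with equal principal moments (e.g. a square) the angle is
    reported as 0.
    """
    mu = rp.moments_central
    m00 = mu[0, 0]
    var_x = mu[0, 2] / m00
    var_y = mu[2, 0] / m00
    cov_xy = mu[1, 1] / m00
    if math.isclose(var_x, var_y, abs_tol=1e-12) and math.isclose(cov_xy, 0.0, abs_tol=1e-12):
        return 0.0
    theta = 0.5 * math.atan2(2.0 * cov_xy, var_x - var_y)
    return math.degrees(theta) % 180.0


def angle_to_origin(
    orientation_deg: float,
    centroid_xy: tuple[float, float],
    center_xy: tuple[float, float],
) -> float:
    """Axial angle (degrees, [0, 90]) between cell axis and center direction.

    Undefined when the centroid coincides with the center (raises).
    """
    dx = center_xy[0] - centroid_xy[0]
    dy = center_xy[1] - centroid_xy[1]
    norm = math.hypot(dx, dy)
    if norm == 0:
        raise ValueError("angle_to_origin undefined: centroid at the drusen center")
    theta = math.radians(orientation_deg)
    axis = (math.cos(theta), math.sin(theta))
    dot = abs(axis[0] * dx / norm + axis[1] * dy / norm)
    return math.degrees(math.acos(min(dot, 1.0)))


def measure_cells(
    mask: LabelMask,
    geometry: DrusenGeometry,
    spec: RegionSpec,
    min_pixels: int = MIN_CELL_PIXELS,
) -> pd.DataFrame:
    """Per-cell records for every labeled cell in a mask.

    Cells touching the image border are measured but flagged
    (``touches_border``) so they can be excluded from area/shape statistics
    while still being countable. Labels below ``min_pixels`` are skipped with
    a log message. Cells whose centroid lands exactly on the drusen center
    get ``angle_to_origin = NaN`` and ``angle_defined = False``.
    """
    pitch = mask.pixel_pitch
    nrows, ncols = mask.labels.shape
    records = []
    n_skipped = 0
    for rp in regionprops(mask.labels):
        if rp.area < min_pixels:
            n_skipped += 1
            continue
        area = float(rp.area) * pitch**2
        # Crofton estimate measures the pixel-center set; cells occupy pixel
        # extents, and dilating a convex set by the unit pixel square adds
        # exactly 4 side-halves to the boundary length.
        perimeter = (float(rp.perimeter_crofton) + 4.0) * pitch
        r0, c0, r1, c1 = rp.bbox
        touches = r0 == 0 or c0 == 0 or r1 == nrows or c1 == ncols
        crow, ccol = rp.centroid
        centroid = ((ccol + 0.5) * pitch, (crow + 0.5) * pitch)
        orientation = _axial_orientation_deg(rp)
        distance = geometry.distance_to_center(centroid)
        try:
            angle = angle_to_origin(orientation, centroid, geometry.center_xy)
            angle_defined = True
        except ValueError:
            angle = float("nan")
            angle_defined = False
        records.append(
            {
                "label": int(rp.label),
                "area_um2": area,
                "perimeter_um": perimeter,
                "shape_factor": perimeter / math.sqrt(area),
                "centroid_x_um": centroid[0],
                "centroid_y_um": centroid[1],
                "orientation_deg": orientation,
                "distance_um": distance,
                "angle_to_origin_deg": angle,
                "angle_defined": angle_defined,
                "region": assign_region(centroid, geometry, spec),
                "touches_border": touches,
            }
        )
    if n_skipped:
        logger.info("measure_cells: skipped %d labels with < %d px", n_skipped, min_pixels)
    df = pd.DataFrame(records)
    df.attrs["n_skipped_small"] = n_skipped
    return df


def normalize_areas(
    records: pd.DataFrame, group_col: str | None = "replicate"
) -> pd.DataFrame:
    """Add ``area_normalized`` = area / mean area within the same replicate.

    Border-touching cells are excluded from the group mean (and receive a
    normalized value relative to the interior-cell mean).
    """
    if records.empty:
        raise ValueError("no cells to normalize")
    df = records.copy()
    interior = df[~df["touches_border"]]
    if interior.empty:
        raise ValueError("no interior cells to define the normalization mean")
    if group_col is not None and group_col in df.columns:
        means = interior.groupby(group_col)["area_um2"].mean()
        df["area_normalized"] = df["area_um2"] / df[group_col].map(means)
    else:
        df["area_normalized"] = df["area_um2"] / interior["area_um2"].mean()
    return df


@dataclass
class AreaDistribution:
    """Relative-frequency histogram and KDE of normalized areas."""

    region: str | None
    bin_edges: np.ndarray
    rel_freq: np.ndarray  # sums to 1
    density_x: np.ndarray
    density_y: np.ndarray
    n: int

    def n_modes(self, prominence_fraction: float = 0.05) -> int:
        """Local maxima of the smoothed density with non-trivial prominence.

        Maxima whose prominence is below ``prominence_fraction`` of the peak
        density are treated as smoothing ripple, not modes.
        """
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(
            self.density_y, prominence=prominence_fraction * self.density_y.max()
        )
        return int(len(peaks))


def area_distribution(
    records: pd.DataFrame,
    region: str | None = None,
    bins: int = 30,
    density_points: int = 256,
) -> AreaDistribution:
    """Pooled normalized-area distribution, optionally for one region.

    The histogram reports relative frequencies (summing to 1); the smoothed
    density is a Gaussian KDE with Silverman bandwidth.
    """
    if "area_normalized" not in records.columns:
        raise ValueError("records lack 'area_normalized'; call normalize_areas first")
    df = records[~records["touches_border"]]
    if region is not None:
        df = df[df["region"] == region]
    values = df["area_normalized"].to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError(f"no cells in region {region!r}")
    counts, edges = np.histogram(values, bins=bins)
    rel = counts / counts.sum()
    kde = gaussian_kde(values, bw_method="silverman")
    xs = np.linspace(values.min(), values.max(), density_points)
    return AreaDistribution(
        region=region,
        bin_edges=edges,
        rel_freq=rel,
        density_x=xs,
        density_y=kde(xs),
        n=int(values.size),
    )


@dataclass
class ModalityResult:
    """Outcome of the one- vs two-component mixture comparison."""

    classification: str  # "unimodal" | "bimodal" | "insufficient-n"
    score: float  # delta BIC = BIC(1) - BIC(2); NaN when insufficient
    n: int
    means: tuple[float, ...] = ()
    pooled_sd: float = float("nan")


def classify_modality(
    normalized_areas: np.ndarray, seed: int = 0
) -> ModalityResult:
    """Classify an area distribution as unimodal or bimodal.

    One- and two-component Gaussian mixtures are fitted to log areas;
    "bimodal" requires both a BIC improvement above 10 and fitted component
    means separated by more than the pooled fitted standard deviation.
    Samples below 30 cells return "insufficient-n".
    """
    values = np.asarray(normalized_areas, dtype=float)
    values = values[np.isfinite(values) & (values > 0)]
    if values.size < MIN_CELLS_FOR_MODALITY:
        return ModalityResult("insufficient-n", float("nan"), int(values.size))
    x = np.log(values).reshape(-1, 1)
    fits = {}
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, n_init=3, random_state=seed)
        gm.fit(x)
        fits[k] = gm
    delta_bic = float(fits[1].bic(x) - fits[2].bic(x))
    gm2 = fits[2]
    means = tuple(float(m) for m in gm2.means_.ravel())
    sds = np.sqrt(gm2.covariances_.ravel())
    weights = gm2.weights_.ravel()
    pooled_sd = float(np.sqrt(np.sum(weights * sds**2)))
    separated = abs(means[0] - means[1]) > pooled_sd
    classification = "bimodal" if (delta_bic > DELTA_BIC_THRESHOLD and separated) else "unimodal"
    return ModalityResult(classification, delta_bic, int(values.size), means, pooled_sd)
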