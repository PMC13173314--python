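"""Bulge swelling kinetics: dose arithmetic, series normalization, apex height.

Swelling of an illuminated spot is tracked as the height of the forming bulge
over time. Heights are normalized per druse by min-max scaling (0 = minimum,
1 = maximum observed height) and also expressed as a percentage. The height
itself is read from a pair of focus stacks: the surface plane is the z-plane
maximizing an intensity-variance focus metric inside a small window over the
apex, and the bulge height is the difference between the post- and
pre-illumination surface planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ImageStack

__all__ = [
    "IlluminationProtocol",
    "SwellingSeries",
    "dose",
    "normalize_series",
    "apex_height",
    "time_to_fraction",
]


@dataclass(frozen=True)
class IlluminationProtocol:
    """One illumination schedule.

    intensity_mw_cm2 : LED intensity, mW/cm².
    exposure_s       : illumination time per cycle, seconds.
    cycles           : number of illumination cycles.
    gap_h            : equilibration break between cycles, hours.
    """

    intensity_mw_cm2: float
    exposure_s: float
    cycles: int = 1
    gap_h: float = 0.0

    def __post_init__(self) -> None:
        if self.intensity_mw_cm2 < 0 or self.exposure_s < 0:
            raise ValueError("intensity and exposure must be non-negative")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.gap_h < 0:
            raise ValueError("gap_h must be non-negative")


def dose(protocol: IlluminationProtocol) -> tuple[float, float]:
    """Radiant dose per cycle and in total, mJ/cm².

    Per-cycle dose = intensity (mW/cm²) x exposure (s); total multiplies by
    the cycle count, so split protocols with the same cumulative exposure
    deliver the same total dose.
    """
    per_cycle = protocol.intensity_mw_cm2 * protocol.exposure_s
    return per_cycle, per_cycle * protocol.cycles


@dataclass
class SwellingSeries:
    """Height-over-time record for one druse; t = 0 is the illumination."""

    druse_id: str
    times_h: np.ndarray
    heights_raw_um: np.ndarray
    heights_norm: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.heights_raw_um = np.asarray(self.heights_raw_um, dtype=float)
        if self.times_h.shape != self.heights_raw_um.shape:
            raise ValueError("times and heights must have equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def heights_pct(self) -> np.ndarray:
        if self.heights_norm is None:
            raise ValueError("call normalize_series first")
        return 100.0 * self.heights_norm


def normalize_series(series: SwellingSeries) -> SwellingSeries:
    """Min-max normalize one druse's heights in place (0 = min, 1 = max).

    Raises on a constant series, for which the scaling is undefined.
    """
    h = series.heights_raw_um
    lo, hi = h.min(), h.max()
    if hi == lo:
        raise ValueError(f"degenerate series {series.druse_id!r}: max equals min")
    series.heights_norm = (h - lo) / (hi - lo)
    return series


def time_to_fraction(series: SwellingSeries, fraction: float = 0.9) -> float:
    """First time (h) at which the normalized height reaches ``fraction``.

    Linear interpolation between the bracketing samples; NaN if never reached.
    """
    if series.heights_norm is None:
        raise ValueError("call normalize_series first")
    hn = series.heights_norm
    above = np.nonzero(hn >= fraction)[0]
    if above.size == 0:
        return float("nan")
    i = int(above[0])
    if i == 0:
        return float(series.times_h[0])
    t0, t1 = series.times_h[i - 1], series.times_h[i]
    h0, h1 = hn[i - 1], hn[i]
    return float(t0 + (fraction - h0) / (h1 - h0) * (t1 - t0))


def _focus_plane(
    stack: ImageStack,
    center_xy: tuple[float, float],
    window_um: float,
    refine: bool,
) -> float:
    """z (µm) of the plane of maximal intensity variance inside the window."""
    pitch = stack.pixel_pitch
    half = window_um / 2.0
    c0 = int(round(center_xy[0] / pitch))
    r0 = int(round(center_xy[1] / pitch))
    w = max(int(round(half / pitch)), 1)
    rows = slice(max(r0 - w, 0), min(r0 + w, stack.voxels.shape[1]))
    cols = slice(max(c0 - w, 0), min(c0 + w, stack.voxels.shape[2]))
    patch = np.asarray(stack.voxels[:, rows, cols], dtype=float)
    metric = patch.var(axis=(1, 2))
    if metric.max() <= 0 or np.ptp(metric) == 0:
        raise ValueError("no focus contrast in the apex window")
    k = int(np.argmax(metric))
    z = float(k)
    if refine and 0 < k < metric.size - 1:
        denom = metric[k - 1] - 2 * metric[k] + metric[k + 1]
        if denom < 0:
            z += float(np.clip(0.5 * (metric[k - 1] - metric[k + 1]) / denom, -1, 1))
    return z * stack.z_step


def apex_height(
    reference: ImageStack,
    post: ImageStack,
    center_xy: tuple[float, float],
    window_um: float = 20.0,
    refine: bool = False,
) -> float:
    """Bulge height (µm) from a pre/post focus-stack pair.

    Estimates the surface plane at the apex window in each stack by the
    per-plane intensity-variance focus metric (optionally refined to sub-plane
    precision by parabolic interpolation) and returns the difference
    ``z_post - z_reference``.
    """
    if reference.z_step != post.z_step:
        raise ValueError("stacks must share the same z step")
    z_ref = _focus_plane(reference, center_xy, window_um, refine)
    z_post = _focus_plane(post, center_xy, window_um, refine)
    return z_post - z_ref
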