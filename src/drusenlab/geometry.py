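"""Radial coordinate handling and region partitioning around a drusen center.

All physical distances are micrometres. A circular bulge ("artificial druse")
defines a polar coordinate system; measurements are pooled into three named
annuli — ``Top``, ``Edge`` and ``Outside`` — by their Euclidean distance to
the bulge center. Annulus membership uses half-open intervals
``[inner, outer)`` so that touching annuli never double-count a point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "DrusenGeometry",
    "Annulus",
    "RegionSpec",
    "make_region_spec",
    "assign_region",
    "UNASSIGNED",
]

#: Region name returned for points that fall outside every annulus.
UNASSIGNED = "unassigned"

TOP_NAME = "Top"
EDGE_NAME = "Edge"
OUTSIDE_NAME = "Outside"

#: Radial half-width of the Top disc and of the Edge band, µm.
TOP_OUTER_RADIUS = 25.0
EDGE_BAND_WIDTH = 25.0
#: The reference annulus far from the bulge, µm.
OUTSIDE_INNER_RADIUS = 150.0
OUTSIDE_OUTER_RADIUS = 175.0


@dataclass(frozen=True)
class DrusenGeometry:
    """Location and size of one illuminated bulge.

    Parameters
    ----------
    center_xy:
        Physical ``(x, y)`` coordinates of the bulge center, µm.
    illumination_diameter:
        Diameter of the illuminated disc, µm (typically 100 or 300).
    condition_label:
        Free-text tag for the experimental condition.
    """

    center_xy: tuple[float, float]
    illumination_diameter: float
    condition_label: str = ""

    def __post_init__(self) -> None:
        if not self.illumination_diameter > 0:
            raise ValueError(
                f"illumination_diameter must be positive, "
                f"got {self.illumination_diameter}"
            )
        if len(self.center_xy) != 2:
            raise ValueError("center_xy must be a pair of coordinates")

    def distance_to_center(self, point_xy: Sequence[float]) -> float:
        """Euclidean distance (µm) from ``point_xy`` to the bulge center."""
        dx = point_xy[0] - self.center_xy[0]
        dy = point_xy[1] - self.center_xy[1]
        return math.hypot(dx, dy)


@dataclass(frozen=True)
class Annulus:
    """One named radial band with half-open extent ``[inner, outer)`` µm."""

    name: str
    inner: float
    outer: float

    def __post_init__(self) -> None:
        if not self.inner < self.outer:
            raise ValueError(
                f"annulus {self.name!r}: inner radius {self.inner} must be "
                f"strictly less than outer radius {self.outer}"
            )
        if self.inner < 0:
            raise ValueError(f"annulus {self.name!r}: negative inner radius")

    def contains(self, radius: float) -> bool:
        return self.inner <= radius < self.outer


@dataclass(frozen=True)
class RegionSpec:
    """An ordered, pairwise-disjoint set of named annuli."""

    annuli: tuple[Annulus, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [a.name for a in self.annuli]
        if len(set(names)) != len(names):
            raise ValueError(f"annulus names must be unique, got {names}")
        ordered = sorted(self.annuli, key=lambda a: a.inner)
        for lo, hi in zip(ordered, ordered[1:]):
            if hi.inner < lo.outer:
                raise ValueError(
                    f"annuli {lo.name!r} [{lo.inner}, {lo.outer}) and "
                    f"{hi.name!r} [{hi.inner}, {hi.outer}) overlap"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.annuli)

    def assign(self, radius: float) -> str:
        """Region name for a radial distance, or ``"unassigned"``."""
        for annulus in self.annuli:
            if annulus.contains(radius):
                return annulus.name
        return UNASSIGNED

    def to_dict(self) -> dict:
        return {
            "annuli": [
                {"name": a.name, "inner_um": a.inner, "outer_um": a.outer}
                for a in self.annuli
            ]
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RegionSpec":
        annuli = tuple(
            Annulus(d["name"], float(d["inner_um"]), float(d["outer_um"]))
            for d in payload["annuli"]
        )
        return cls(annuli)


def make_region_spec(illumination_diameter: float) -> RegionSpec:
    """Build the Top/Edge/Outside partition for one illumination diameter.

    ``Top`` is always the central disc ``[0, 25)`` µm and ``Outside`` the
    reference band ``[150, 175)`` µm. ``Edge`` extends 25 µm radially inwards
    from the illumination radius: ``[D/2 - 25, D/2)``. For the two standard
    conditions this gives ``[25, 50)`` (100 µm) and ``[125, 150)`` (300 µm).

    Raises
    ------
    ValueError
        If the diameter is non-positive, or if the generic Edge rule would
        overlap Top (``D <= 50`` µm) or Outside (``D > 300`` µm).
    """
    if not illumination_diameter > 0:
        raise ValueError(
            f"illumination_diameter must be positive, got {illumination_diameter}"
        )
    radius = illumination_diameter / 2.0
    annuli = (
        Annulus(TOP_NAME, 0.0, TOP_OUTER_RADIUS),
        Annulus(EDGE_NAME, radius - EDGE_BAND_WIDTH, radius),
        Annulus(OUTSIDE_NAME, OUTSIDE_INNER_RADIUS, OUTSIDE_OUTER_RADIUS),
    )
    # RegionSpec validation rejects Edge/Top and Edge/Outside overlap.
    return RegionSpec(annuli)


def assign_region(
    point_xy: Sequence[float], geometry: DrusenGeometry, spec: RegionSpec
) -> str:
    """Region of a physical point (µm), or ``"unassigned"``."""
    return spec.assign(geometry.distance_to_center(point_xy))
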