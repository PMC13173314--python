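"""Image containers and TIFF round-tripping.

``ImageStack`` holds a 3D intensity grid ordered ``(z, y, x)`` with z index 0
on the substrate side; ``LabelMask`` holds a 2D integer segmentation where 0
is background. Physical calibration (lateral pixel pitch and z step, µm)
travels with the arrays and is persisted in ImageJ-style TIFF metadata so
files written here re-open with their calibration intact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "LabelMask",
    "read_stack",
    "write_stack",
    "read_label_mask",
    "write_label_mask",
]


@dataclass
class ImageStack:
    """3D intensity array ``(z, y, x)`` with physical voxel spacing."""

    voxels: np.ndarray
    pixel_pitch: float  # µm per pixel, lateral
    z_step: float  # µm per z-plane
    channel: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x), got {self.voxels.ndim}D")
        if self.voxels.shape[0] < 2:
            raise ValueError("stack needs at least 2 z-planes")
        if not (self.pixel_pitch > 0 and self.z_step > 0):
            raise ValueError("pixel_pitch and z_step must be positive")

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def pixel_center_um(self, row: int, col: int) -> tuple[float, float]:
        """Physical ``(x, y)`` of a pixel center (pixel-center convention)."""
        return ((col + 0.5) * self.pixel_pitch, (row + 0.5) * self.pixel_pitch)

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        return replace(self, voxels=voxels)


@dataclass
class LabelMask:
    """2D integer-labeled mask; 0 = background, k > 0 = cell k."""

    labels: np.ndarray
    pixel_pitch: float  # µm per pixel

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def n_cells(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a multi-page TIFF with calibration in ImageJ metadata tags."""
    path = Path(path)
    tifffile.imwrite(
        path,
        np.asarray(stack.voxels),
        imagej=stack.voxels.dtype in (np.dtype("uint8"), np.dtype("uint16")),
        resolution=(1.0 / stack.pixel_pitch, 1.0 / stack.pixel_pitch),
        metadata={"spacing": stack.z_step, "unit": "um", "channel": stack.channel},
    )


def read_stack(
    path: str | Path,
    pixel_pitch: float | None = None,
    z_step: float | None = None,
    channel: str = "",
) -> ImageStack:
    """Read a multi-page TIFF; calibration from tags unless overridden."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        voxels = tif.asarray()
        if voxels.ndim == 2:
            voxels = voxels[None]
        if pixel_pitch is None:
            pixel_pitch = _pitch_from_tags(tif)
        if z_step is None:
            z_step = _z_step_from_tags(tif)
        if not channel:
            channel = _channel_from_tags(tif)
    if pixel_pitch is None or z_step is None:
        raise ValueError(
            f"{path}: no calibration in TIFF metadata; pass pixel_pitch/z_step"
        )
    return ImageStack(voxels, pixel_pitch, z_step, channel)


def _pitch_from_tags(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0:
        return None
    return den / num


def _z_step_from_tags(tif: tifffile.TiffFile) -> float | None:
    meta = tif.imagej_metadata or {}
    spacing = meta.get("spacing")
    return float(spacing) if spacing else None


def _channel_from_tags(tif: tifffile.TiffFile) -> str:
    meta = tif.imagej_metadata or {}
    return str(meta.get("channel", ""))


def write_label_mask(path: str | Path, mask: LabelMask) -> None:
    """Write a 16-bit label TIFF plus a JSON sidecar with the pixel pitch."""
    path = Path(path)
    labels = mask.labels
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot write 16-bit mask")
    tifffile.imwrite(
        path,
        labels.astype(np.uint16),
        resolution=(1.0 / mask.pixel_pitch, 1.0 / mask.pixel_pitch),
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"pixel_pitch_um": mask.pixel_pitch}))


def read_label_mask(path: str | Path, pixel_pitch: float | None = None) -> LabelMask:
    path = Path(path)
    labels = tifffile.imread(path)
    if pixel_pitch is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            pixel_pitch = float(json.loads(sidecar.read_text())["pixel_pitch_um"])
        else:
            with tifffile.TiffFile(path) as tif:
                pixel_pitch = _pitch_from_tags(tif)
    if pixel_pitch is None:
        raise ValueError(f"{path}: pixel pitch unavailable; pass pixel_pitch")
    return LabelMask(np.asarray(labels).astype(np.int64), pixel_pitch)
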