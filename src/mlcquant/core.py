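"""Shared domain types: scan geometry, en face images, thickness maps.

An en face OCT slab is a planar (C-scan) image extracted from a 3-D OCT
volume parallel to the internal limiting membrane. The macrophage-like
cell (MLC) slab analyzed here is a thin section just above the ILM, exported
as an 8-bit grayscale image with a known physical pixel pitch (6 mm / 512 px
for the default scan protocol). Retinal thickness maps share the same grid
but hold per-pixel thickness in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "DEFAULT_ANALYZED_AREA_MM2",
    "ImageGeometry",
    "EnFaceImage",
    "ThicknessMap",
    "default_geometry",
]

#: Whole-image analyzed area (mm²) after border cropping of the 6×6 mm scan,
#: the constant against which cell counts are converted to densities in the
#: report tables. Consistent to ±0.01 cells/mm² with all published
#: count/density pairs (see tests).
DEFAULT_ANALYZED_AREA_MM2 = 33.66


@dataclass(frozen=True)
class ImageGeometry:
    """Pixel grid plus its physical extent.

    Parameters
    ----------
    width_px, height_px:
        Grid size in pixels (columns, rows).
    scan_width_mm, scan_height_mm:
        Physical extent covered by the grid.
    analyzed_area_mm2:
        Area used when converting counts to densities. Defaults to the full
        physical extent; override to use a reported analyzed area.
    """

    width_px: int
    height_px: int
    scan_width_mm: float
    scan_height_mm: float
    analyzed_area_mm2: float | None = None

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("pixel dimensions must be positive")
        if self.scan_width_mm <= 0 or self.scan_height_mm <= 0:
            raise ValueError("scan extent must be positive")
        if self.analyzed_area_mm2 is not None:
            if not 0 < self.analyzed_area_mm2 <= self.scan_width_mm * self.scan_height_mm + 1e-9:
                raise ValueError("analyzed_area_mm2 must be in (0, scan area]")

    @property
    def pixel_pitch_mm(self) -> float:
        return self.scan_width_mm / self.width_px

    @property
    def pixel_area_mm2(self) -> float:
        return (self.scan_width_mm / self.width_px) * (self.scan_height_mm / self.height_px)

    @property
    def area_mm2(self) -> float:
        """Analyzed area: explicit override if set, else the full extent."""
        if self.analyzed_area_mm2 is not None:
            return self.analyzed_area_mm2
        return self.scan_width_mm * self.scan_height_mm

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    def crop(self, margin_px: int) -> "ImageGeometry":
        """Geometry after removing ``margin_px`` pixels from every side.

        The pixel pitch is preserved; the physical extent shrinks.
        """
        if margin_px < 0:
            raise ValueError("margin_px must be >= 0")
        w = self.width_px - 2 * margin_px
        h = self.height_px - 2 * margin_px
        if w <= 0 or h <= 0:
            raise ValueError("margin_px too large for this geometry")
        pw = self.scan_width_mm / self.width_px
        ph = self.scan_height_mm / self.height_px
        return ImageGeometry(w, h, w * pw, h * ph)


def default_geometry() -> ImageGeometry:
    """The study's scan protocol: 512×512 px covering 6×6 mm."""
    return ImageGeometry(512, 512, 6.0, 6.0)


def _check_shape(pixels: np.ndarray, geometry: ImageGeometry) -> None:
    if pixels.ndim != 2:
        raise ValueError("expected a 2-D array")
    if pixels.shape != geometry.shape:
        raise ValueError(
            f"array shape {pixels.shape} does not match geometry {geometry.shape}"
        )


@dataclass
class EnFaceImage:
    """A 2-D en face slab image with physical pixel pitch.

    ``pixels`` is uint8 for raw images; enhancement stages may carry float
    values in [0, 255].
    """

    pixels: np.ndarray
    geometry: ImageGeometry

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        _check_shape(self.pixels, self.geometry)

    def with_pixels(self, pixels: np.ndarray, geometry: ImageGeometry | None = None) -> "EnFaceImage":
        return EnFaceImage(pixels, geometry if geometry is not None else self.geometry)

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.round(self.pixels), 0, 255).astype(np.uint8)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arr = self.to_uint8()
        if path.suffix.lower() in {".tif", ".tiff"}:
            tifffile.imwrite(path, arr)
        else:
            Image.fromarray(arr).save(path)

    @classmethod
    def load(cls, path: str | Path, geometry: ImageGeometry) -> "EnFaceImage":
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path).convert("L"))
        return cls(arr, geometry)


@dataclass
class ThicknessMap:
    """Per-pixel retinal thickness in micrometres on the scan grid."""

    values_um: np.ndarray
    geometry: ImageGeometry

    def __post_init__(self) -> None:
        self.values_um = np.asarray(self.values_um, dtype=np.float32)
        _check_shape(self.values_um, self.geometry)

    def crop(self, margin_px: int) -> "ThicknessMap":
        g = self.geometry.crop(margin_px)
        m = margin_px
        v = self.values_um[m : m + g.height_px, m : m + g.width_px]
        return ThicknessMap(v, g)

    def save(self, path: str | Path) -> None:
        tifffile.imwrite(Path(path), self.values_um.astype(np.float32))

    @classmethod
    def load(cls, path: str | Path, geometry: ImageGeometry) -> "ThicknessMap":
        return cls(tifffile.imread(Path(path)), geometry)
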