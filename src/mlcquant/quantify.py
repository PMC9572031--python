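"""Binarization and particle analysis of segmented cell images.

Mirrors an "analyze particles" step: the probability map (or enhanced
intensity image) is converted to 8-bit, thresholded, and its connected
components are counted and measured. Densities are counts over the analyzed
area in mm².
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd
from skimage import measure

from .classify import otsu_threshold
from .core import ImageGeometry

__all__ = ["BinaryMask", "Particle", "ParticleSet", "binarize", "analyze_particles", "mlc_density"]


@dataclass
class BinaryMask:
    mask: np.ndarray
    geometry: ImageGeometry
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.geometry.shape:
            raise ValueError("mask shape does not match geometry")


class Particle(NamedTuple):
    id: int
    pixel_count: int
    area_mm2: float
    centroid_rowcol: tuple[float, float]
    bbox: tuple[int, int, int, int]  # min_row, min_col, max_row, max_col (exclusive)


@dataclass
class ParticleSet:
    """Connected components surviving the size filter (the cell readout)."""

    particles: list[Particle]
    geometry: ImageGeometry

    @property
    def total_count(self) -> int:
        return len(self.particles)

    @property
    def total_area_mm2(self) -> float:
        return float(sum(p.pixel_count for p in self.particles) * self.geometry.pixel_area_mm2)

    @property
    def percent_area(self) -> float:
        """Fraction of the analyzed area covered by particles, in [0, 1]."""
        return self.total_area_mm2 / self.geometry.area_mm2

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": p.id,
                    "pixel_count": p.pixel_count,
                    "area_mm2": p.area_mm2,
                    "centroid_row": p.centroid_rowcol[0],
                    "centroid_col": p.centroid_rowcol[1],
                }
                for p in self.particles
            ],
            columns=["id", "pixel_count", "area_mm2", "centroid_row", "centroid_col"],
        )


def binarize(
    source: np.ndarray,
    geometry: ImageGeometry,
    method: Literal["probability_cut", "otsu"] = "probability_cut",
    level: float = 0.5,
) -> BinaryMask:
    """Threshold a probability map or intensity image into a binary mask.

    probability_cut:
        The map is first scaled to 8-bit (``round(p × 255)``) and the mask is
        true where the scaled value is ``>= level × 255``. A pixel at exactly
        p = 0.5 with the default level is therefore true.
    otsu:
        The intensity image (values in [0, 255]) is thresholded at the Otsu
        level; the mask is true strictly above the threshold bin.
    """
    arr = np.asarray(source, dtype=float)
    if arr.shape != geometry.shape:
        raise ValueError("source shape does not match geometry")
    if method == "probability_cut":
        if not 0.0 < level < 1.0:
            raise ValueError("level must be in (0, 1) for probability_cut")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("probability map values must be in [0, 1]")
        scaled = np.round(arr * 255.0)
        mask = scaled >= level * 255.0
        prov = f"probability_cut(level={level})"
    elif method == "otsu":
        binned = np.clip(np.floor(arr), 0, 255)
        if binned.min() == binned.max():
            # constant image: nothing to separate, empty mask
            mask = np.zeros(arr.shape, dtype=bool)
            prov = "otsu(degenerate constant image)"
        else:
            t = otsu_threshold(arr)
            mask = binned > t
            prov = f"otsu(threshold={t})"
    else:
        raise ValueError(f"unknown method {method!r}")
    return BinaryMask(mask, geometry, prov)


def analyze_particles(
    mask: BinaryMask,
    min_area_px: int = 2,
    max_area_px: int | None = None,
    connectivity: Literal[4, 8] = 8,
) -> ParticleSet:
    """Connected components of the mask, size-filtered and measured.

    Components with pixel count outside ``[min_area_px, max_area_px]`` are
    discarded. Particles are ordered by the (top, left) corner of their
    bounding box; centroids are arithmetic means of pixel coordinates.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    if max_area_px is not None and max_area_px < min_area_px:
        raise ValueError("max_area_px must be >= min_area_px")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labeled = measure.label(mask.mask, connectivity=1 if connectivity == 4 else 2)
    pix_area = mask.geometry.pixel_area_mm2
    raw = []
    for rp in measure.regionprops(labeled):
        n = int(rp.area)
        if n < min_area_px or (max_area_px is not None and n > max_area_px):
            continue
        raw.append((tuple(int(v) for v in rp.bbox), n, tuple(float(c) for c in rp.centroid)))
    raw.sort(key=lambda t: (t[0][0], t[0][1]))
    particles = [
        Particle(
            id=i + 1,
            pixel_count=n,
            area_mm2=n * pix_area,
            centroid_rowcol=centroid,
            bbox=bbox,
        )
        for i, (bbox, n, centroid) in enumerate(raw)
    ]
    return ParticleSet(particles, mask.geometry)


def mlc_density(particles, area_mm2: float) -> float:
    """Cell density in cells/mm²: count over the analyzed area.

    ``particles`` may be a :class:`ParticleSet` or a plain count (a published
    median count works directly).
    """
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be > 0")
    count = particles.total_count if isinstance(particles, ParticleSet) else float(particles)
    return count / area_mm2
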