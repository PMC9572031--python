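"""Preprocessing chain that enhances point-like bright cells.

The chain mirrors an ImageJ-style macro: crop the screenshot border, apply a
sequence of white top-hat filters (square r=5, then 1-px-thick digital lines
of half-length 10 at 0°, 90°, 45° and 135°), subtract a rolling-ball
background (radius 10), and finally subtract a Gaussian blur (σ=10) to remove
the remaining low-frequency field.

A white top-hat is ``image − grayscale_opening(image, se)``: it keeps bright
structures that do not contain the structuring element and suppresses
everything larger. The line elements remove curvilinear vessel artifacts in
their own direction while a point-like cell, smaller than every element,
survives each stage. The rolling-ball background is the grayscale opening
with a non-flat spherical-cap element. All boundaries are handled by
reflection to avoid spurious border particles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage as ndi

from .core import EnFaceImage

__all__ = [
    "SEShape",
    "StructuringElement",
    "PreprocessConfig",
    "default_tophat_elements",
    "ball_element",
    "white_top_hat",
    "tophat_chain",
    "rolling_ball_subtract",
    "gaussian_highpass",
    "preprocess",
]

log = logging.getLogger(__name__)


class SEShape(str, Enum):
    square = "square"
    line_0deg = "line_0deg"
    line_45deg = "line_45deg"
    line_90deg = "line_90deg"
    line_135deg = "line_135deg"


@dataclass(frozen=True)
class StructuringElement:
    """Flat structuring element: a square or a 1-px digital line.

    ``radius`` follows the ImageJ convention: a square of radius r spans
    (2r+1)×(2r+1) pixels; a line of radius r has 2r+1 pixels along its
    direction. The 45°/135° lines are exact diagonals (the Bresenham
    rasterization of a 45° segment).
    """

    shape: SEShape
    radius: int

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("structuring element radius must be >= 1")

    @property
    def footprint(self) -> np.ndarray:
        n = 2 * self.radius + 1
        r = self.radius
        fp = np.zeros((n, n), dtype=bool)
        if self.shape == SEShape.square:
            fp[:, :] = True
        elif self.shape == SEShape.line_0deg:
            fp[r, :] = True
        elif self.shape == SEShape.line_90deg:
            fp[:, r] = True
        elif self.shape == SEShape.line_45deg:
            # bottom-left to top-right: row decreases as column increases
            fp[np.arange(n)[::-1], np.arange(n)] = True
        elif self.shape == SEShape.line_135deg:
            fp[np.arange(n), np.arange(n)] = True
        else:  # pragma: no cover
            raise ValueError(f"unknown shape {self.shape}")
        return fp

    @property
    def offsets(self) -> set[tuple[int, int]]:
        """Integer displacements relative to the origin (symmetric set)."""
        fp = self.footprint
        r = self.radius
        return {(int(i) - r, int(j) - r) for i, j in np.argwhere(fp)}


def default_tophat_elements() -> list[StructuringElement]:
    """The published sequence: square r=5, then lines r=10 at 0°, 90°, 45°, 135°."""
    return [
        StructuringElement(SEShape.square, 5),
        StructuringElement(SEShape.line_0deg, 10),
        StructuringElement(SEShape.line_90deg, 10),
        StructuringElement(SEShape.line_45deg, 10),
        StructuringElement(SEShape.line_135deg, 10),
    ]


@dataclass
class PreprocessConfig:
    crop_margin_px: int = 9
    tophat_elements: list[StructuringElement] = field(default_factory=default_tophat_elements)
    rolling_ball_radius: int = 10
    gaussian_sigma: float = 10.0

    def __post_init__(self) -> None:
        if self.crop_margin_px < 0:
            raise ValueError("crop_margin_px must be >= 0")
        if self.rolling_ball_radius < 1:
            raise ValueError("rolling_ball_radius must be >= 1")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")

    def to_dict(self) -> dict:
        return {
            "crop_margin_px": self.crop_margin_px,
            "tophat_elements": [
                {"shape": se.shape.value, "radius": se.radius} for se in self.tophat_elements
            ],
            "rolling_ball_radius": self.rolling_ball_radius,
            "gaussian_sigma": self.gaussian_sigma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(
            crop_margin_px=d["crop_margin_px"],
            tophat_elements=[
                StructuringElement(SEShape(e["shape"]), e["radius"])
                for e in d["tophat_elements"]
            ],
            rolling_ball_radius=d["rolling_ball_radius"],
            gaussian_sigma=d["gaussian_sigma"],
        )


def _as_array(image) -> np.ndarray:
    arr = image.pixels if isinstance(image, EnFaceImage) else np.asarray(image)
    if arr.size == 0:
        raise ValueError("image is empty")
    return arr


def white_top_hat(image, se: StructuringElement) -> np.ndarray:
    """``image − grayscale_opening(image, se)`` with reflecting boundaries.

    Anti-extensive and non-negative: ``0 <= result <= image`` pointwise for
    non-negative input.
    """
    arr = _as_array(image)
    fp = se.footprint
    opened = ndi.grey_opening(arr, footprint=fp, mode="reflect")
    return arr - opened


def tophat_chain(image, elements: list[StructuringElement]) -> np.ndarray:
    """Sequential composition of white top-hats, in list order."""
    if not elements:
        raise ValueError("element list must be nonempty")
    arr = _as_array(image)
    for se in elements:
        arr = white_top_hat(arr, se)
    return arr


def ball_element(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Spherical-cap heights and footprint for the rolling-ball element."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    d2 = yy * yy + xx * xx
    fp = d2 <= radius * radius
    heights = np.where(fp, np.sqrt(np.maximum(radius * radius - d2, 0.0)), 0.0)
    return heights, fp


def rolling_ball_subtract(image, radius: int) -> np.ndarray:
    """Subtract the background estimated by a grayscale opening with a ball.

    The background is the non-flat opening of the image with a spherical-cap
    element of the given radius (the surface traced by the top of a ball
    rolled under the intensity landscape). The result is
    ``clip(image − background, 0, 255)``.
    """
    arr = _as_array(image).astype(float)
    heights, fp = ball_element(radius)
    eroded = ndi.grey_erosion(arr, structure=heights, footprint=fp, mode="reflect")
    background = ndi.grey_dilation(eroded, structure=heights, footprint=fp, mode="reflect")
    return np.clip(arr - background, 0.0, 255.0)


def gaussian_highpass(image, sigma: float) -> np.ndarray:
    """``clip(image − gaussian_blur(image, sigma), 0, 255)``.

    The blur uses reflecting boundaries with the kernel truncated at 4σ.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    arr = _as_array(image).astype(float)
    blur = ndi.gaussian_filter(arr, sigma, mode="reflect", truncate=4.0)
    return np.clip(arr - blur, 0.0, 255.0)


def preprocess(image: EnFaceImage, config: PreprocessConfig | None = None) -> EnFaceImage:
    """Full enhancement chain: crop → top-hat chain → rolling ball → high-pass.

    Returns a float-valued :class:`EnFaceImage` on the cropped geometry.
    """
    if config is None:
        config = PreprocessConfig()
    m = config.crop_margin_px
    geom = image.geometry.crop(m) if m > 0 else image.geometry
    arr = image.pixels
    if m > 0:
        arr = arr[m : m + geom.height_px, m : m + geom.width_px]
    log.info("crop: margin %d px -> %s", m, arr.shape)
    arr = tophat_chain(arr.astype(float), config.tophat_elements)
    log.info("tophat_chain: %d elements, max %.1f", len(config.tophat_elements), arr.max(initial=0))
    arr = rolling_ball_subtract(arr, config.rolling_ball_radius)
    log.info("rolling_ball_subtract: radius %d", config.rolling_ball_radius)
    arr = gaussian_highpass(arr, config.gaussian_sigma)
    log.info("gaussian_highpass: sigma %.1f", config.gaussian_sigma)
    return EnFaceImage(arr, geom)
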