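from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mlcquant.core import ImageGeometry
from mlcquant.synthesize import (
    CellAppearance,
    CellTruth,
    NoiseSpec,
    gen_enface_image,
    place_cells,
)

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def small_geometry() -> ImageGeometry:
    """64×64 px over 0.75×0.75 mm: same pixel pitch as the 512 px / 6 mm scan."""
    return ImageGeometry(64, 64, 0.75, 0.75)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_benchmark_eye(seed: int, n_cells: int = 200, size_px: int = 512):
    """The default synthetic benchmark: a 512×512 / 6 mm eye with well
    separated bright cells at contrast well above the noise level.

    Returns (EnFaceImage, centers). Centers avoid the 9 px border frame that
    preprocessing crops.
    """
    geometry = ImageGeometry(size_px, size_px, 6.0 * size_px / 512, 6.0 * size_px / 512)
    rng = np.random.default_rng(seed)
    centers = place_cells(
        n_cells, geometry, rng, margin_px=12.0, min_separation_px=8.0
    )
    appearance = CellAppearance()
    lo, hi = appearance.radius_px_range
    truth = CellTruth(
        centers,
        rng.uniform(lo, hi, n_cells),
        appearance.amplitude * rng.uniform(0.8, 1.2, n_cells),
        np.array(["non_edematous"] * n_cells),
    )
    image = gen_enface_image(
        geometry,
        truth,
        noise_spec=NoiseSpec(),
        border_margin_px=9,
        seed=seed + 1,
    )
    return image, centers
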