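"""Enhance one synthetic en face slab and show what each stage does.

Builds a 256×256 px (3×3 mm) eye with 60 planted cells, runs the
enhancement chain (crop, white top-hats, rolling ball, Gaussian high-pass),
and prints the image statistics before and after. The mean collapses toward
zero because everything larger than a cell — vessels, background shading —
is removed, while the bright cell peaks survive.
"""

import numpy as np

from mlcquant import ImageGeometry, PreprocessConfig, preprocess
from mlcquant.synthesize import CellAppearance, CellTruth, NoiseSpec, gen_enface_image, place_cells

geometry = ImageGeometry(256, 256, 3.0, 3.0)
rng = np.random.default_rng(0)
centers = place_cells(60, geometry, rng, margin_px=12.0, min_separation_px=8.0)
appearance = CellAppearance()
truth = CellTruth(
    centers,
    rng.uniform(*appearance.radius_px_range, 60),
    appearance.amplitude * rng.uniform(0.8, 1.2, 60),
    np.array(["non_edematous"] * 60),
)
image = gen_enface_image(geometry, truth, noise_spec=NoiseSpec(), border_margin_px=9, seed=1)

enhanced = preprocess(image, PreprocessConfig())
print(f"raw image:      shape {image.pixels.shape}, mean {image.pixels.mean():6.1f}, "
      f"max {image.pixels.max()}")
print(f"enhanced image: shape {enhanced.pixels.shape}, mean {enhanced.pixels.mean():6.1f}, "
      f"max {enhanced.pixels.max():5.1f}")
print("The 9 px border frame is cropped; cells remain as isolated bright peaks "
      "on a near-zero background.")
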