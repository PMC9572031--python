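"""Synthetic en face slabs, thickness maps and whole cohorts with ground truth.

The generator emulates the data the analysis expects without any download:

- **Images**: a smooth background field, curvilinear vessel structures
  (random-walk streaks), bright isotropic Gaussian blobs for the
  macrophage-like cells (σ 1–2 px, the smallest resolvable bright feature at
  ~11.7 μm/px), multiplicative speckle plus additive read noise, and a bright
  screenshot-style border frame that the preprocessing crop removes.
- **Thickness maps**: a smooth field = baseline + foveal-pit depression +
  non-negative Gaussian edema bumps, so the 440 μm edema threshold can be
  crossed and the >440 μm level set is analytically known for planted bumps.
- **Cohorts**: three groups (control / acute / chronic) whose per-eye planted
  densities follow right-skewed log-normal marginals matched to the reported
  medians and interquartile ranges; cell count and central foveal thickness
  (CFT) are coupled through a Gaussian copula so rank correlations approach
  the group targets; within an eye, the planted density in the edematous
  region is the non-edematous density times a group ratio.

Everything is reproducible: one seed determines images, maps and truth
bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import EnFaceImage, ImageGeometry, ThicknessMap, default_geometry

__all__ = [
    "EdemaBlob",
    "CellTruth",
    "VesselSpec",
    "NoiseSpec",
    "BackgroundSpec",
    "CellAppearance",
    "ThicknessSpec",
    "GroupMarginals",
    "CohortSpec",
    "SyntheticEye",
    "gen_thickness_map",
    "gen_enface_image",
    "place_cells",
    "sample_group_covariates",
    "sample_region_triples",
    "gen_cohort",
]


@dataclass(frozen=True)
class EdemaBlob:
    """A smooth thickness bump: Gaussian of the given peak height and scale."""

    row: float
    col: float
    amplitude_um: float
    sigma_px: float

    def __post_init__(self) -> None:
        if self.amplitude_um < 0:
            raise ValueError("blob amplitude must be >= 0")
        if self.sigma_px <= 0:
            raise ValueError("blob sigma must be > 0")


@dataclass
class CellTruth:
    """Planted ground truth: one center/scale/amplitude/region per cell."""

    centers: np.ndarray      # (n, 2) float, (row, col)
    radii_px: np.ndarray     # (n,)
    amplitudes: np.ndarray   # (n,)
    region_label: np.ndarray  # (n,) of {"edematous", "non_edematous"}

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.size == 0:
            self.centers = self.centers.reshape(0, 2)
        self.radii_px = np.asarray(self.radii_px, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.region_label = np.asarray(self.region_label)
        n = len(self.centers)
        if not (len(self.radii_px) == len(self.amplitudes) == len(self.region_label) == n):
            raise ValueError("truth arrays must have equal length")
        if n and (self.radii_px <= 0).any():
            raise ValueError("radii must be > 0")
        if n and (self.amplitudes <= 0).any():
            raise ValueError("amplitudes must be > 0")

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    def validate_bounds(self, geometry: ImageGeometry) -> None:
        if self.n_cells == 0:
            return
        r, c = self.centers[:, 0], self.centers[:, 1]
        if (r < 0).any() or (c < 0).any() or (r >= geometry.height_px).any() or (c >= geometry.width_px).any():
            raise ValueError("cell centers fall outside the image bounds")

    def shifted(self, d_row: float, d_col: float) -> "CellTruth":
        return CellTruth(
            self.centers + np.array([d_row, d_col]), self.radii_px, self.amplitudes, self.region_label
        )


@dataclass(frozen=True)
class VesselSpec:
    n_vessels: int = 8
    amplitude: float = 30.0
    sigma_px: float = 1.2


@dataclass(frozen=True)
class NoiseSpec:
    speckle_sigma: float = 0.15   # multiplicative fraction
    additive_sigma: float = 4.0   # gray levels


@dataclass(frozen=True)
class BackgroundSpec:
    level: float = 40.0
    variation: float = 10.0   # amplitude of the smooth background field
    scale_px: float = 30.0


@dataclass(frozen=True)
class CellAppearance:
    amplitude: float = 120.0          # peak intensity above background
    amplitude_jitter: float = 0.2     # ± fraction, uniform
    radius_px_range: tuple[float, float] = (1.0, 2.0)


@dataclass(frozen=True)
class ThicknessSpec:
    pit_depth_um: float = 60.0
    pit_sigma_mm: float = 0.35
    ripple_um: float = 2.0
    ripple_scale_px: float = 40.0
    central_blob_sigma_px: float = 100.0
    satellite_blob_count_max: int = 3
    satellite_amplitude_range: tuple[float, float] = (50.0, 150.0)
    satellite_sigma_px_range: tuple[float, float] = (40.0, 90.0)


@dataclass(frozen=True)
class GroupMarginals:
    """Log-normal / normal marginal parameters of one cohort group.

    Log-normal scales (``*_sigma_log``) are matched to the reported
    median (IQR) pairs by solving ``IQR/median = 2·sinh(0.6745·σ)``.
    """

    density_median: float            # cells/mm²
    density_sigma_log: float
    cft_median_um: float
    cft_sigma_log: float
    mrt_baseline_um: float           # thickness away from edema
    mrt_baseline_sigma_log: float
    vd_dcp_mean: float
    vd_dcp_sd: float
    vd_scp_mean: float
    vd_scp_sd: float
    duration_median_days: float | None
    duration_sigma_log: float | None
    edema_density_ratio: float       # edematous / non-edematous planted density
    rho_count_cft: float             # Spearman target for (count, CFT)
    has_edema: bool


def default_group_marginals() -> dict[str, GroupMarginals]:
    """Study conditions: medians/IQRs and correlation targets per group."""
    return {
        "control": GroupMarginals(
            density_median=6.55, density_sigma_log=0.711,
            cft_median_um=207.84, cft_sigma_log=0.066,
            mrt_baseline_um=291.52, mrt_baseline_sigma_log=0.042,
            vd_dcp_mean=56.60, vd_dcp_sd=3.88,
            vd_scp_mean=51.48, vd_scp_sd=5.08,
            duration_median_days=None, duration_sigma_log=None,
            edema_density_ratio=1.0, rho_count_cft=0.0, has_edema=False,
        ),
        "acute": GroupMarginals(
            density_median=11.53, density_sigma_log=0.648,
            cft_median_um=555.31, cft_sigma_log=0.502,
            mrt_baseline_um=305.0, mrt_baseline_sigma_log=0.05,
            vd_dcp_mean=38.82, vd_dcp_sd=11.14,
            vd_scp_mean=55.76, vd_scp_sd=6.90,
            duration_median_days=33.0, duration_sigma_log=0.910,
            edema_density_ratio=0.6, rho_count_cft=-0.352, has_edema=True,
        ),
        "chronic": GroupMarginals(
            density_median=12.53, density_sigma_log=0.669,
            cft_median_um=276.65, cft_sigma_log=1.195,
            mrt_baseline_um=305.0, mrt_baseline_sigma_log=0.05,
            vd_dcp_mean=43.90, vd_dcp_sd=9.45,
            vd_scp_mean=50.23, vd_scp_sd=8.12,
            duration_median_days=265.0, duration_sigma_log=1.319,
            edema_density_ratio=0.9, rho_count_cft=0.406, has_edema=True,
        ),
    }


@dataclass
class CohortSpec:
    """Cohort structure and generator parameters (defaults = study conditions)."""

    n_control: int = 64
    n_acute: int = 43
    n_chronic: int = 29
    marginals: dict[str, GroupMarginals] = field(default_factory=default_group_marginals)
    thickness: ThicknessSpec = field(default_factory=ThicknessSpec)
    vessels: VesselSpec = field(default_factory=VesselSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    cells: CellAppearance = field(default_factory=CellAppearance)
    edema_threshold_um: float = 440.0
    min_separation_px: float = 8.0
    border_margin_px: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_acute, self.n_chronic) < 0:
            raise ValueError("group sizes must be >= 0")
        for name, m in self.marginals.items():
            if m.density_median < 0:
                raise ValueError(f"{name}: density median must be >= 0")
            if m.edema_density_ratio < 0:
                raise ValueError(f"{name}: edema density ratio must be >= 0")
            if not -1.0 <= m.rho_count_cft <= 1.0:
                raise ValueError(f"{name}: correlation target must be in [-1, 1]")


@dataclass
class SyntheticEye:
    """One generated eye: image, thickness map, truth, and device covariates."""

    eye_id: str
    group: str
    image: EnFaceImage | None
    thickness: ThicknessMap
    truth: CellTruth
    covariates: dict
    analyzed_area_mm2: float

    @property
    def planted_count(self) -> int:
        return self.truth.n_cells

    @property
    def planted_density(self) -> float:
        return self.truth.n_cells / self.analyzed_area_mm2


def gen_thickness_map(
    geometry: ImageGeometry,
    baseline_um: float,
    edema_blobs: list[EdemaBlob] | tuple = (),
    seed: int = 0,
    *,
    pit_depth_um: float = 60.0,
    pit_sigma_mm: float = 0.35,
    ripple_um: float = 2.0,
    ripple_scale_px: float = 40.0,
) -> ThicknessMap:
    """Smooth thickness field: baseline + foveal pit + edema bumps (+ ripple).

    The pit is a negative Gaussian at the image center; each edema blob is a
    non-negative Gaussian bump. ``ripple_um`` adds a small smooth random
    undulation (seeded) so maps are not analytically flat. Values are
    positive and finite; deterministic for a fixed seed.
    """
    if baseline_um <= 0:
        raise ValueError("baseline_um must be > 0")
    h, w = geometry.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    pit_sigma_px = pit_sigma_mm / geometry.pixel_pitch_mm
    values = np.full((h, w), float(baseline_um))
    values -= pit_depth_um * np.exp(-(((rows - cr) ** 2 + (cols - cc) ** 2) / (2 * pit_sigma_px**2)))
    for blob in edema_blobs:
        values += blob.amplitude_um * np.exp(
            -(((rows - blob.row) ** 2 + (cols - blob.col) ** 2) / (2 * blob.sigma_px**2))
        )
    if ripple_um > 0:
        rng = np.random.default_rng(seed)
        noise = ndi.gaussian_filter(rng.standard_normal((h, w)), ripple_scale_px, mode="reflect")
        sd = noise.std()
        if sd > 0:
            values += ripple_um * noise / sd
    values = np.maximum(values, 1.0)
    return ThicknessMap(values.astype(np.float32), geometry)


def _draw_vessels(shape: tuple[int, int], spec: VesselSpec, rng: np.random.Generator) -> np.ndarray:
    """Bright curvilinear streaks from smoothed random walks."""
    h, w = shape
    canvas = np.zeros(shape)
    for k in range(spec.n_vessels):
        if k % 2 == 0:
            r, c, ang = rng.uniform(0, h), 0.0, rng.uniform(-0.5, 0.5)
        else:
            r, c, ang = 0.0, rng.uniform(0, w), rng.uniform(np.pi / 2 - 0.5, np.pi / 2 + 0.5)
        while 0 <= r < h and 0 <= c < w:
            canvas[int(r), int(c)] = 1.0
            ang += rng.normal(0, 0.15)
            r += np.sin(ang)
            c += np.cos(ang)
    if spec.n_vessels == 0:
        return canvas
    profile = ndi.gaussian_filter(canvas, spec.sigma_px, mode="reflect")
    return spec.amplitude * profile * math.sqrt(2 * math.pi * spec.sigma_px**2)


def _stamp_cells(shape: tuple[int, int], truth: CellTruth) -> np.ndarray:
    h, w = shape
    out = np.zeros(shape)
    for (row, col), sigma, amp in zip(truth.centers, truth.radii_px, truth.amplitudes):
        half = int(np.ceil(4 * sigma)) + 1
        r0, r1 = max(int(row) - half, 0), min(int(row) + half + 1, h)
        c0, c1 = max(int(col) - half, 0), min(int(col) + half + 1, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        out[r0:r1, c0:c1] += amp * np.exp(-(((yy - row) ** 2 + (xx - col) ** 2) / (2 * sigma**2)))
    return out


def gen_enface_image(
    geometry: ImageGeometry,
    truth: CellTruth,
    vessel_spec: VesselSpec | None = None,
    noise_spec: NoiseSpec | None = None,
    background_spec: BackgroundSpec | None = None,
    border_margin_px: int = 0,
    seed: int = 0,
) -> EnFaceImage:
    """Render an 8-bit en face slab from planted truth.

    ``background + vessels + cell blobs``, multiplied by speckle, plus read
    noise, with an optional bright screenshot-style frame of
    ``border_margin_px`` pixels; clipped to [0, 255]. Deterministic per seed.
    """
    vessel_spec = vessel_spec or VesselSpec()
    noise_spec = noise_spec or NoiseSpec()
    background_spec = background_spec or BackgroundSpec()
    truth.validate_bounds(geometry)
    rng = np.random.default_rng(seed)
    h, w = geometry.shape
    img = np.full((h, w), float(background_spec.level))
    if background_spec.variation > 0:
        f = ndi.gaussian_filter(rng.standard_normal((h, w)), background_spec.scale_px, mode="reflect")
        sd = f.std()
        if sd > 0:
            img += background_spec.variation * f / sd
    img += _draw_vessels((h, w), vessel_spec, rng)
    img += _stamp_cells((h, w), truth)
    if noise_spec.speckle_sigma > 0:
        img *= 1.0 + noise_spec.speckle_sigma * rng.standard_normal((h, w))
    if noise_spec.additive_sigma > 0:
        img += noise_spec.additive_sigma * rng.standard_normal((h, w))
    m = border_margin_px
    if m > 0:
        img[:m, :] = 255.0
        img[-m:, :] = 255.0
        img[:, :m] = 255.0
        img[:, -m:] = 255.0
    return EnFaceImage(np.clip(np.round(img), 0, 255).astype(np.uint8), geometry)


def place_cells(
    n: int,
    geometry: ImageGeometry,
    rng: np.random.Generator,
    *,
    region_mask: np.ndarray | None = None,
    inside: bool = True,
    margin_px: float = 12.0,
    min_separation_px: float = 8.0,
    existing: np.ndarray | None = None,
    max_tries: int = 200_000,
) -> np.ndarray:
    """Uniform random cell centers with a hard-core minimum separation.

    If ``region_mask`` is given, centers are constrained to pixels where the
    mask equals ``inside``. Raises if the region cannot accommodate ``n``
    centers at the requested separation.
    """
    pts: list[np.ndarray] = []
    all_pts = [] if existing is None else [np.asarray(existing)]
    min_sep = float(min_separation_px)
    min_sep2 = min_sep**2
    h, w = geometry.shape
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            # crowded region: progressively relax the hard-core separation
            if min_sep > 1.0:
                min_sep = max(min_sep / 2.0, 1.0)
                min_sep2 = min_sep**2
                tries = 0
                continue
            raise RuntimeError(
                f"could not place {n} cells at separation {min_separation_px} px"
            )
        p = rng.uniform([margin_px, margin_px], [h - margin_px, w - margin_px])
        if region_mask is not None and bool(region_mask[int(p[0]), int(p[1])]) != inside:
            continue
        ok = True
        for arr in all_pts:
            if len(arr) and ((arr - p) ** 2).sum(axis=1).min() < min_sep2:
                ok = False
                break
        if ok and pts:
            if min((q - p) @ (q - p) for q in pts) < min_sep2:
                ok = False
        if ok:
            pts.append(p)
    return np.array(pts).reshape(-1, 2)


def _latent_rho(rho_spearman: float) -> float:
    """Gaussian-copula latent correlation hitting a Spearman target."""
    return 2.0 * math.sin(math.pi * rho_spearman / 6.0)


def sample_group_covariates(
    group: str, n: int, spec: CohortSpec, rng: np.random.Generator, analyzed_area_mm2: float
) -> pd.DataFrame:
    """Statistical core of the cohort: coupled (density, CFT) plus VD/duration.

    The planted density is log-normal with the group median; CFT is
    log-normal and coupled to the density through a Gaussian copula with the
    group's rank-correlation target. Counts are densities times the analyzed
    area, rounded.
    """
    m = spec.marginals[group]
    rho_l = _latent_rho(m.rho_count_cft)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    z_cft = rho_l * z1 + math.sqrt(max(1.0 - rho_l**2, 0.0)) * z2
    density = m.density_median * np.exp(m.density_sigma_log * z1)
    cft = m.cft_median_um * np.exp(m.cft_sigma_log * z_cft)
    count = np.round(density * analyzed_area_mm2).astype(int)
    if m.duration_median_days is None:
        duration = np.full(n, np.nan)
    else:
        duration = m.duration_median_days * np.exp(m.duration_sigma_log * rng.standard_normal(n))
    return pd.DataFrame(
        {
            "group": group,
            "planted_density": density,
            "planted_count": count,
            "cft_um": cft,
            "mrt_baseline_um": m.mrt_baseline_um
            * np.exp(m.mrt_baseline_sigma_log * rng.standard_normal(n)),
            "vd_dcp_pct": m.vd_dcp_mean + m.vd_dcp_sd * rng.standard_normal(n),
            "vd_scp_pct": m.vd_scp_mean + m.vd_scp_sd * rng.standard_normal(n),
            "duration_days": duration,
        }
    )


def sample_region_triples(
    n: int,
    ratio: float,
    rng: np.random.Generator,
    *,
    density_median: float = 11.53,
    density_sigma_log: float = 0.648,
    edema_area_median_mm2: float = 9.14,
    edema_area_sigma_log: float = 0.99,
    whole_area_mm2: float = 33.66,
) -> np.ndarray:
    """Per-eye (edematous, non-edematous, whole) densities, counting noise included.

    The edematous share of each eye's count is binomial with success
    probability ``ratio·A_e / (A_ne + ratio·A_e)`` so the expected edematous
    density is ``ratio`` times the non-edematous one. Used for power and
    calibration studies without rendering images.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    d_whole = density_median * np.exp(density_sigma_log * rng.standard_normal(n))
    a_e = np.clip(
        edema_area_median_mm2 * np.exp(edema_area_sigma_log * rng.standard_normal(n)),
        0.5,
        whole_area_mm2 - 0.5,
    )
    a_ne = whole_area_mm2 - a_e
    counts = np.round(d_whole * whole_area_mm2).astype(int)
    p_e = ratio * a_e / (a_ne + ratio * a_e)
    n_e = rng.binomial(counts, p_e)
    out = np.column_stack([n_e / a_e, (counts - n_e) / a_ne, counts / whole_area_mm2])
    return out


def _eye_thickness(
    group_m: GroupMarginals,
    spec: CohortSpec,
    geometry: ImageGeometry,
    baseline: float,
    cft_target: float,
    rng: np.random.Generator,
    seed: int,
) -> ThicknessMap:
    """Build a thickness map whose center value equals the CFT draw."""
    t = spec.thickness
    cr, cc = (geometry.height_px - 1) / 2.0, (geometry.width_px - 1) / 2.0
    cft_map = float(np.clip(cft_target, 80.0, 1200.0))
    blobs: list[EdemaBlob] = []
    if cft_map >= baseline - t.pit_depth_um:
        pit = t.pit_depth_um
        amp = cft_map - baseline + pit
        if amp > 0:
            blobs.append(EdemaBlob(cr, cc, amp, t.central_blob_sigma_px))
    else:
        pit = baseline - cft_map
    if group_m.has_edema:
        for _ in range(rng.integers(0, t.satellite_blob_count_max + 1)):
            blobs.append(
                EdemaBlob(
                    row=rng.uniform(0.25 * geometry.height_px, 0.75 * geometry.height_px),
                    col=rng.uniform(0.25 * geometry.width_px, 0.75 * geometry.width_px),
                    amplitude_um=rng.uniform(*t.satellite_amplitude_range),
                    sigma_px=rng.uniform(*t.satellite_sigma_px_range),
                )
            )
    return gen_thickness_map(
        geometry,
        baseline,
        blobs,
        seed=seed,
        pit_depth_um=pit,
        pit_sigma_mm=t.pit_sigma_mm,
        ripple_um=t.ripple_um,
        ripple_scale_px=t.ripple_scale_px,
    )


def gen_cohort(
    spec: CohortSpec,
    geometry: ImageGeometry | None = None,
    render_images: bool = True,
) -> list[SyntheticEye]:
    """Generate the full synthetic cohort with exact ground truth.

    Cells are planted only inside the analyzed (post-crop) region; the bright
    border frame is what the preprocessing crop removes. With
    ``render_images=False`` only thickness maps, truth and covariates are
    produced (fast path for statistical studies).
    """
    geometry = geometry or default_geometry()
    inner = geometry.crop(spec.border_margin_px) if spec.border_margin_px else geometry
    analyzed_area = inner.area_mm2
    root = np.random.SeedSequence(spec.seed)
    groups = [("control", spec.n_control), ("acute", spec.n_acute), ("chronic", spec.n_chronic)]
    cov_rng = np.random.default_rng(root.spawn(1)[0])
    eyes: list[SyntheticEye] = []
    for group, n in groups:
        if n == 0:
            continue
        m = spec.marginals[group]
        cov = sample_group_covariates(group, n, spec, cov_rng, analyzed_area)
        eye_seeds = root.spawn(n)
        for i in range(n):
            ss = eye_seeds[i]
            rng = np.random.default_rng(ss)
            row = cov.iloc[i]
            map_seed = int(rng.integers(2**31))
            thickness = _eye_thickness(
                m, spec, geometry, float(row.mrt_baseline_um), float(row.cft_um), rng, map_seed
            )
            edema = thickness.values_um > spec.edema_threshold_um
            n_cells = int(row.planted_count)
            margin = spec.border_margin_px + 3.0
            interior = np.zeros(geometry.shape, dtype=bool)
            mi = int(margin)
            interior[mi:-mi or None, mi:-mi or None] = True
            # split the count by placeable pixel areas so both sub-counts fit
            n_pix_e = int((edema & interior).sum())
            n_pix_ne = int((~edema & interior).sum())
            ratio = m.edema_density_ratio
            if m.has_edema and n_pix_e > 0:
                if n_pix_ne == 0:
                    n_e = n_cells
                else:
                    n_e = int(round(n_cells * ratio * n_pix_e / (n_pix_ne + ratio * n_pix_e)))
            else:
                n_e = 0
            pts_e = place_cells(
                n_e, geometry, rng, region_mask=edema, inside=True,
                margin_px=margin, min_separation_px=spec.min_separation_px,
            )
            pts_ne = place_cells(
                n_cells - n_e, geometry, rng, region_mask=edema, inside=False,
                margin_px=margin, min_separation_px=spec.min_separation_px,
                existing=pts_e,
            )
            centers = np.vstack([pts_e, pts_ne]) if n_cells else np.zeros((0, 2))
            lo, hi = spec.cells.radius_px_range
            radii = rng.uniform(lo, hi, n_cells)
            j = spec.cells.amplitude_jitter
            amps = spec.cells.amplitude * rng.uniform(1 - j, 1 + j, n_cells)
            labels = np.array(["edematous"] * n_e + ["non_edematous"] * (n_cells - n_e))
            truth = CellTruth(centers, radii, amps, labels)
            image = None
            if render_images:
                image = gen_enface_image(
                    geometry,
                    truth,
                    vessel_spec=spec.vessels,
                    noise_spec=spec.noise,
                    background_spec=spec.background,
                    border_margin_px=spec.border_margin_px,
                    seed=int(rng.integers(2**31)),
                )
            h, w = geometry.shape
            cft_measured = float(thickness.values_um[(h - 1) // 2, (w - 1) // 2])
            eyes.append(
                SyntheticEye(
                    eye_id=f"{group}_{i:03d}",
                    group=group,
                    image=image,
                    thickness=thickness,
                    truth=truth,
                    covariates={
                        "cft_um": cft_measured,
                        "mrt_um": float(thickness.values_um.mean()),
                        "vd_dcp_pct": float(row.vd_dcp_pct),
                        "vd_scp_pct": float(row.vd_scp_pct),
                        "duration_days": float(row.duration_days),
                    },
                    analyzed_area_mm2=analyzed_area,
                )
            )
    return eyes
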