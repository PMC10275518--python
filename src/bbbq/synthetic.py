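"""Synthetic brain-photograph and MSI phantoms with known ground truth.

The phantoms stand in for data that cannot be bundled: gross photographs
of trypan-blue-stained rat brains and DESI imaging runs of drug-dosed
brain sections.  Each generator plants a known per-hemisphere signal and
records it, so every downstream quantification stage can be tested for
exact recovery.

Brain phantom geometry: two mirror-image elliptical hemispheres on a
black background, separated by a vertical midline gap.  A configurable
fraction of each hemisphere's pixels is recolored toward a
trypan-blue-like stain color; per-channel Gaussian noise is then added to
tissue pixels only (the background stays black so a brightness threshold
recovers the tissue mask exactly).  The same noise field is applied to
both hemispheres in mirrored order, so with zero stain the two
hemispheres have identical pixel populations and the planted ratio is
exactly 1.

MSI phantom: a rectangular pixel grid (left half contralateral, right
half ipsilateral) of centroided spectra, each holding one drug peak at
the target m/z plus Gaussian mass error and hemisphere-dependent
intensity, and uniform background peaks kept at least 1 Da away from the
drug m/z so extraction-window tests are never contaminated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .hue import TIMEPOINT_ORDER, _hue_chroma, corrected_hue
from .imaging import RasterImage, RegionSet
from .msi import MSIDataset

#: Default phantom colors: pale pinkish tissue and a trypan-blue stain.
DEFAULT_BASE_COLOR = (200, 150, 140)
DEFAULT_STAIN_COLOR = (60, 70, 200)


@dataclass(frozen=True)
class SyntheticImageConfig:
    """Parameters of the two-hemisphere stained-brain phantom."""

    width_px: int = 160
    height_px: int = 120
    base_color: tuple[int, int, int] = DEFAULT_BASE_COLOR
    stain_color: tuple[int, int, int] = DEFAULT_STAIN_COLOR
    stain_fraction_ipsi: float = 0.0
    stain_fraction_contra: float = 0.0
    blend_weight: float = 1.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 32 or self.height_px < 32:
            raise ConfigurationError("phantom dimensions must be >= 32 px")
        for name in ("stain_fraction_ipsi", "stain_fraction_contra", "blend_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for c in (*self.base_color, *self.stain_color):
            if not 0 <= c <= 255:
                raise ConfigurationError("colors must be 8-bit RGB triples")


@dataclass(frozen=True)
class ImageGroundTruth:
    """Planted per-hemisphere mean corrected hue of a brain phantom."""

    mean_corrected_hue_ipsi: float
    mean_corrected_hue_contra: float

    @property
    def ratio(self) -> float:
        return self.mean_corrected_hue_ipsi / self.mean_corrected_hue_contra


def _hemisphere_masks(width: int, height: int) -> tuple[np.ndarray, np.ndarray]:
    """Mirror-symmetric elliptical hemisphere masks with a midline gap."""
    ys, xs = np.mgrid[0:height, 0:width]
    cx, cy = 0.28 * width, 0.5 * height
    a, b = 0.18 * width, 0.38 * height
    left = ((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2 <= 1.0
    right = np.fliplr(left)
    return left, right


def _mean_corrected_hue(rgb_u8: np.ndarray) -> float:
    """Mean corrected hue of an (n, 3) uint8 pixel array, chromatic pixels only."""
    hue, chroma = _hue_chroma(rgb_u8.astype(float))
    keep = chroma > 0
    return float(np.mean(corrected_hue(hue[keep])))


def _render_hemisphere(
    count: int,
    config: SyntheticImageConfig,
    fraction: float,
    noise: np.ndarray,
    stain_rng: np.random.Generator,
) -> np.ndarray:
    base = np.tile(np.asarray(config.base_color, dtype=float), (count, 1))
    n_stained = int(round(fraction * count))
    if n_stained:
        idx = stain_rng.choice(count, size=n_stained, replace=False)
        stain = np.asarray(config.stain_color, dtype=float)
        base[idx] = (1.0 - config.blend_weight) * base[idx] + config.blend_weight * stain
    return np.clip(np.rint(base + noise), 0, 255).astype(np.uint8)


def make_brain_image(
    config: SyntheticImageConfig,
) -> tuple[RasterImage, RegionSet, ImageGroundTruth]:
    """Generate the stained-brain phantom, its ROI masks and ground truth.

    The recorded ground truth is each hemisphere's exact mean corrected
    hue computed from the generated pixels (after staining, noise and
    8-bit quantization), so downstream recovery can be asserted to
    floating-point tolerance.  Deterministic: the same config (including
    seed) yields a bit-identical image.
    """
    left, right = _hemisphere_masks(config.width_px, config.height_px)
    count = int(left.sum())
    noise_rng, ipsi_rng, contra_rng = np.random.default_rng(config.seed).spawn(3)
    if config.noise_sd > 0:
        noise = noise_rng.normal(0.0, config.noise_sd, size=(count, 3))
    else:
        noise = np.zeros((count, 3))

    contra_px = _render_hemisphere(
        count, config, config.stain_fraction_contra, noise, contra_rng
    )
    ipsi_px = _render_hemisphere(
        count, config, config.stain_fraction_ipsi, noise, ipsi_rng
    )

    img = np.zeros((config.height_px, config.width_px, 3), dtype=np.uint8)
    img[left] = contra_px  # left = contralateral (treated side is image-right)
    img[right] = ipsi_px
    regions = RegionSet(
        tissue=left | right,
        ipsilateral=right,
        contralateral=left,
        provenance="generator_ground_truth",
    )
    truth = ImageGroundTruth(
        mean_corrected_hue_ipsi=_mean_corrected_hue(ipsi_px),
        mean_corrected_hue_contra=_mean_corrected_hue(contra_px),
    )
    return RasterImage(img), regions, truth


def stain_fraction_for_ratio(
    target_ratio: float, config: SyntheticImageConfig
) -> float:
    """Stain fraction planting a given ipsi/contra corrected-hue ratio.

    With an unstained contralateral hemisphere the phantom's mean
    corrected hue is linear in the stained fraction f:

        mean(f) = (1 - f) * C_base + f * C_stain

    where C_base and C_stain are the corrected hues of the base and
    (blended) stain colors.  Solving mean(f) / C_base = target gives f.
    Noise perturbs the realized ratio only at the sub-percent level.
    """
    base = np.asarray(config.base_color, dtype=float)
    stain = np.asarray(config.stain_color, dtype=float)
    blended = (1.0 - config.blend_weight) * base + config.blend_weight * stain
    c_base = _mean_corrected_hue(base[None, :].astype(np.uint8))
    c_stain = _mean_corrected_hue(np.rint(blended)[None, :].astype(np.uint8))
    f = c_base * (target_ratio - 1.0) / (c_stain - c_base)
    if not 0.0 <= f <= 1.0:
        raise ConfigurationError(
            f"target ratio {target_ratio} unreachable with these colors (f={f:.3f})"
        )
    return float(f)


def make_timecourse_series(
    configs: Sequence[tuple[str, str, SyntheticImageConfig]],
) -> list[tuple[str, str, RasterImage, RegionSet, ImageGroundTruth]]:
    """Generate a labeled (group, timepoint) series of brain phantoms.

    Emulates the study design of one photograph per animal at 30 min,
    1 h and 2 h post-infusion per treatment group.  Duplicate
    (group, timepoint) labels are a configuration error.
    """
    if not configs:
        raise ConfigurationError("need at least one labeled config")
    labels = [(g, t) for g, t, _ in configs]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("duplicate (group, timepoint) labels")
    for _, t, _ in configs:
        if t not in TIMEPOINT_ORDER:
            raise ConfigurationError(f"timepoint must be one of {TIMEPOINT_ORDER}")
    out = []
    for group, timepoint, cfg in configs:
        image, regions, truth = make_brain_image(cfg)
        out.append((group, timepoint, image, regions, truth))
    return out


@dataclass(frozen=True)
class SyntheticMSIConfig:
    """Parameters of the centroided MSI phantom (m/z 50-700 by default)."""

    grid_nx: int = 20
    grid_ny: int = 16
    pixel_size_um: float = 100.0
    mz_min: float = 50.0
    mz_max: float = 700.0
    drug_mz: float = 217.0
    drug_intensity_ipsi: float = 100.0
    drug_intensity_contra: float = 10.0
    mass_error_sd_da: float = 0.003
    n_background_peaks: int = 50
    background_intensity_max: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_nx < 2 or self.grid_ny < 2:
            raise ConfigurationError("grid dimensions must be >= 2")
        if not self.mz_min < self.drug_mz < self.mz_max:
            raise ConfigurationError("drug_mz must lie inside (mz_min, mz_max)")
        if self.drug_intensity_ipsi < 0 or self.drug_intensity_contra < 0:
            raise ConfigurationError("drug intensities must be >= 0")
        if self.mass_error_sd_da < 0 or self.background_intensity_max < 0:
            raise ConfigurationError("noise parameters must be >= 0")
        if self.n_background_peaks < 0:
            raise ConfigurationError("n_background_peaks must be >= 0")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")


@dataclass(frozen=True)
class MSIGroundTruth:
    """Planted per-hemisphere drug peak intensity."""

    drug_intensity_ipsi: float
    drug_intensity_contra: float

    @property
    def ratio(self) -> float:
        return self.drug_intensity_ipsi / self.drug_intensity_contra


def _draw_background_mz(
    rng: np.random.Generator, n: int, config: SyntheticMSIConfig
) -> np.ndarray:
    """Uniform background m/z in range, excluding drug_mz +/- 1 Da."""
    out = np.empty(0)
    while len(out) < n:
        cand = rng.uniform(config.mz_min, config.mz_max, size=2 * n)
        cand = cand[np.abs(cand - config.drug_mz) > 1.0]
        out = np.concatenate([out, cand])
    return out[:n]


def make_msi_dataset(
    config: SyntheticMSIConfig,
) -> tuple[MSIDataset, RegionSet, MSIGroundTruth]:
    """Generate the MSI phantom, hemisphere masks on the grid, and truth.

    Every pixel carries a centroid spectrum with one drug peak at
    ``drug_mz + N(0, mass_error_sd_da)`` (clipped to the m/z range) whose
    intensity depends on the hemisphere, plus ``n_background_peaks``
    uniform-m/z peaks outside drug_mz +/- 1 Da.  The left half of the
    grid is contralateral and the right half ipsilateral; with odd grid
    width the middle column belongs to neither hemisphere.
    """
    rng = np.random.default_rng(config.seed)
    nx, ny = config.grid_nx, config.grid_ny
    coords = []
    spectra = []
    half = nx // 2
    ipsi_start = nx - half  # middle column (odd nx) excluded from both
    for y in range(1, ny + 1):
        for x in range(1, nx + 1):
            if x <= half:
                drug_int = config.drug_intensity_contra
            elif x > ipsi_start:
                drug_int = config.drug_intensity_ipsi
            else:
                drug_int = 0.5 * (
                    config.drug_intensity_ipsi + config.drug_intensity_contra
                )
            drug_pos = config.drug_mz + (
                rng.normal(0.0, config.mass_error_sd_da)
                if config.mass_error_sd_da > 0
                else 0.0
            )
            drug_pos = float(np.clip(drug_pos, config.mz_min, config.mz_max))
            mzs = [drug_pos]
            ints = [drug_int]
            if config.n_background_peaks:
                bg_mz = _draw_background_mz(rng, config.n_background_peaks, config)
                bg_int = rng.uniform(
                    0.0, config.background_intensity_max, size=config.n_background_peaks
                )
                mzs.extend(bg_mz)
                ints.extend(bg_int)
            order = np.argsort(mzs, kind="stable")
            coords.append((x, y))
            spectra.append(
                (np.asarray(mzs)[order], np.asarray(ints, dtype=float)[order])
            )

    dataset = MSIDataset(
        coordinates=coords,
        spectra=spectra,
        pixel_size_um=config.pixel_size_um,
        mz_range=(config.mz_min, config.mz_max),
    )
    xs = np.arange(1, nx + 1)
    contra_cols = xs <= half
    ipsi_cols = xs > ipsi_start
    tissue = np.ones((ny, nx), dtype=bool)
    regions = RegionSet(
        tissue=tissue,
        ipsilateral=np.broadcast_to(ipsi_cols, (ny, nx)).copy(),
        contralateral=np.broadcast_to(contra_cols, (ny, nx)).copy(),
        provenance="generator_ground_truth",
    )
    truth = MSIGroundTruth(
        drug_intensity_ipsi=config.drug_intensity_ipsi,
        drug_intensity_contra=config.drug_intensity_contra,
    )
    return dataset, regions, truth
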