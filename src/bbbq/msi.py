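"""Mass-spectrometry-imaging containers, imzML I/O and ion-image extraction.

An :class:`MSIDataset` holds one centroid spectrum per pixel on a regular
grid (imzML convention: 1-based integer coordinates, x rightward, y
downward).  An ion image is extracted by summing, per pixel, all centroid
intensities within a narrow m/z window around a target ion — the window
is interpreted as a FULL width (the default 0.02 Da means target
+/- 0.01 Da, closed interval at both ends).  Pixels absent from the
dataset, or lost to a zero normalization denominator, are NaN ("missing"),
which is distinct from an extracted intensity of zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .errors import ExtractionError, MSIFormatError
from .imaging import RegionSet

DEFAULT_WINDOW_DA = 0.02  # full width; §half-width users should pass 0.04


@dataclass(frozen=True)
class MSIDataset:
    """Centroided spectra on a pixel grid with a physical pixel size.

    ``coordinates`` are unique 1-based integer (x, y) pairs;
    ``spectra[i]`` is the ``(mz, intensity)`` pair of ascending float
    arrays for ``coordinates[i]``.  Every m/z must lie inside
    ``mz_range`` and intensities are non-negative.
    """

    coordinates: list[tuple[int, int]]
    spectra: list[tuple[np.ndarray, np.ndarray]]
    pixel_size_um: float = 100.0
    mz_range: tuple[float, float] = (50.0, 700.0)

    def __post_init__(self) -> None:
        if len(self.coordinates) != len(self.spectra):
            raise MSIFormatError("coordinates and spectra length mismatch")
        if not self.coordinates:
            raise MSIFormatError("dataset must contain at least one pixel")
        if len(set(self.coordinates)) != len(self.coordinates):
            raise MSIFormatError("duplicate pixel coordinates")
        lo, hi = self.mz_range
        for (x, y), (mz, inten) in zip(self.coordinates, self.spectra):
            if x < 1 or y < 1:
                raise MSIFormatError("coordinates are 1-based positive integers")
            if len(mz) != len(inten):
                raise MSIFormatError("m/z and intensity arrays differ in length")
            if len(mz) and (np.any(np.diff(mz) < 0)):
                raise MSIFormatError("m/z arrays must be sorted ascending")
            if len(mz) and (mz[0] < lo - 1e-6 or mz[-1] > hi + 1e-6):
                raise MSIFormatError("m/z value outside declared range")
            if np.any(inten < 0):
                raise MSIFormatError("negative intensity")

    @property
    def grid_extent(self) -> tuple[int, int]:
        """(nx, ny) spanned by the coordinates (max x, max y)."""
        xs = [c[0] for c in self.coordinates]
        ys = [c[1] for c in self.coordinates]
        return max(xs), max(ys)


@dataclass(frozen=True)
class IonImage:
    """Extracted intensity grid for one target m/z.

    ``grid`` has shape (ny, nx); entry [y-1, x-1] is the summed window
    intensity at pixel (x, y).  Grid positions not covered by the
    dataset, or dropped during normalization, hold NaN.
    """

    grid: np.ndarray
    target_mz: float
    window_da: float = DEFAULT_WINDOW_DA
    normalization: str = "none"  # none | tic | lockmass
    n_missing_normalized: int = 0

    def __post_init__(self) -> None:
        if np.any(self.grid[~np.isnan(self.grid)] < 0):
            raise MSIFormatError("ion-image intensities must be >= 0")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.grid)


def write_msi(dataset: MSIDataset, path: str | Path) -> None:
    """Write as processed-mode imzML (+ .ibd companion), float32 binary."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(
        str(path),
        mz_dtype=np.float32,
        intensity_dtype=np.float32,
        mode="processed",
        spec_type="centroid",
        polarity="positive",
    ) as writer:
        for (x, y), (mz, inten) in zip(dataset.coordinates, dataset.spectra):
            writer.addSpectrum(mz, inten, (x, y, 1))


def read_msi(path: str | Path, pixel_size_um: float = 100.0) -> MSIDataset:
    """Read a processed-mode imzML file back into an :class:`MSIDataset`.

    Round trip with :func:`write_msi` is lossless at float32 precision
    for coordinates, m/z and intensities.  The physical pixel size is
    taken from the file's scan settings when present; files written by
    :func:`write_msi` do not embed it, so ``pixel_size_um`` supplies the
    value then (default 100 um, the acquisition geometry emulated here).
    Raises :class:`MSIFormatError` for a missing .ibd companion or
    duplicate coordinates.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.with_suffix(".ibd").exists():
        raise MSIFormatError(f"missing binary companion for {path}")
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:
        raise MSIFormatError(f"cannot parse imzML {path}: {exc}") from exc
    coords: list[tuple[int, int]] = []
    spectra: list[tuple[np.ndarray, np.ndarray]] = []
    mz_lo, mz_hi = math.inf, -math.inf
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(inten, dtype=float)
        coords.append((int(x), int(y)))
        spectra.append((mz, inten))
        if len(mz):
            mz_lo = min(mz_lo, float(mz[0]))
            mz_hi = max(mz_hi, float(mz[-1]))
    if len(set(coords)) != len(coords):
        raise MSIFormatError("duplicate pixel coordinates in imzML file")
    if not math.isfinite(mz_lo):
        mz_lo, mz_hi = 0.0, 0.0
    try:
        pixel_size = float(parser.imzmldict.get("pixel size x", pixel_size_um))
    except Exception:
        pixel_size = pixel_size_um
    return MSIDataset(
        coordinates=coords,
        spectra=spectra,
        pixel_size_um=pixel_size,
        mz_range=(mz_lo, mz_hi),
    )


def _window_sum(mz: np.ndarray, inten: np.ndarray, lo: float, hi: float) -> float:
    """Sum of intensities with m/z in the closed interval [lo, hi].

    Binary search on the sorted m/z axis; 'left'/'right' sides make both
    endpoints inclusive.
    """
    i = np.searchsorted(mz, lo, side="left")
    j = np.searchsorted(mz, hi, side="right")
    return float(inten[i:j].sum())


def extract_ion_image(
    dataset: MSIDataset, target_mz: float, window_da: float = DEFAULT_WINDOW_DA
) -> IonImage:
    """Extract the ion image for a target m/z with a full-width mass window.

    Per pixel the value is the sum of centroid intensities within
    ``target_mz +/- window_da / 2`` (closed on both ends); a pixel with
    no peak in the window reads 0, while grid positions with no acquired
    spectrum are NaN.
    """
    lo_r, hi_r = dataset.mz_range
    if not lo_r <= target_mz <= hi_r:
        raise ExtractionError(
            f"target m/z {target_mz} outside acquired range [{lo_r}, {hi_r}]"
        )
    if window_da <= 0:
        raise ExtractionError("window_da must be positive")
    half = window_da / 2.0
    nx, ny = dataset.grid_extent
    grid = np.full((ny, nx), np.nan)
    for (x, y), (mz, inten) in zip(dataset.coordinates, dataset.spectra):
        grid[y - 1, x - 1] = _window_sum(mz, inten, target_mz - half, target_mz + half)
    return IonImage(grid=grid, target_mz=target_mz, window_da=window_da)


def normalize_ion_image(
    image: IonImage,
    dataset: MSIDataset,
    method: str = "none",
    lock_mz: float | None = None,
) -> IonImage:
    """Normalize per pixel by TIC or by the lock-mass window intensity.

    ``method`` is one of ``none`` (identity), ``tic`` (divide by the
    pixel's total ion current) or ``lockmass`` (divide by the intensity
    extracted at ``lock_mz`` with the same window rule).  Pixels with a
    zero denominator become NaN and are counted in
    ``n_missing_normalized``.
    """
    if method == "none":
        return image
    nx, ny = dataset.grid_extent
    if image.grid.shape != (ny, nx):
        raise MSIFormatError("ion image does not match dataset grid")
    denom = np.full((ny, nx), np.nan)
    if method == "tic":
        for (x, y), (_mz, inten) in zip(dataset.coordinates, dataset.spectra):
            denom[y - 1, x - 1] = float(inten.sum())
    elif method == "lockmass":
        if lock_mz is None:
            raise ValueError("lockmass normalization requires lock_mz")
        half = image.window_da / 2.0
        for (x, y), (mz, inten) in zip(dataset.coordinates, dataset.spectra):
            denom[y - 1, x - 1] = _window_sum(mz, inten, lock_mz - half, lock_mz + half)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    zero = denom == 0
    denom[zero] = np.nan
    grid = image.grid / denom
    n_missing = int(np.sum(zero & ~np.isnan(image.grid)))
    return IonImage(
        grid=grid,
        target_mz=image.target_mz,
        window_da=image.window_da,
        normalization=method,
        n_missing_normalized=n_missing,
    )


@dataclass(frozen=True)
class HemisphereRatio:
    """Ipsi/contra mean-intensity ratio with the underlying means."""

    ratio: float  # math.inf when the contralateral mean is zero
    ipsi_mean: float
    contra_mean: float
    n_ipsi: int
    n_contra: int

    @property
    def infinite(self) -> bool:
        return math.isinf(self.ratio)


def hemisphere_intensity_ratio(image: IonImage, regions: RegionSet) -> HemisphereRatio:
    """Mean ipsilateral over mean contralateral extracted intensity.

    Missing (NaN) pixels are excluded from both means.  A zero
    contralateral mean yields an infinite-ratio flag (``math.inf``)
    rather than an exception, with both means still reported.
    """
    if regions.tissue.shape != image.grid.shape:
        raise MSIFormatError("RegionSet does not match ion-image grid")
    ipsi_vals = image.grid[regions.ipsilateral]
    contra_vals = image.grid[regions.contralateral]
    ipsi_vals = ipsi_vals[~np.isnan(ipsi_vals)]
    contra_vals = contra_vals[~np.isnan(contra_vals)]
    if len(ipsi_vals) == 0 or len(contra_vals) == 0:
        raise MSIFormatError("a hemisphere mask has no valid pixels on the grid")
    ipsi_mean = float(ipsi_vals.mean())
    contra_mean = float(contra_vals.mean())
    ratio = math.inf if contra_mean == 0 else ipsi_mean / contra_mean
    return HemisphereRatio(
        ratio=ratio,
        ipsi_mean=ipsi_mean,
        contra_mean=contra_mean,
        n_ipsi=len(ipsi_vals),
        n_contra=len(contra_vals),
    )


def render_ion_image(image: IonImage, path: str | Path, title: str = "") -> None:
    """Save a heat-map PNG with a color bar; missing pixels render gray."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("0.7")
    masked = np.ma.masked_invalid(image.grid)
    im = ax.imshow(masked, cmap=cmap, origin="upper", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="intensity")
    ax.set_title(title or f"m/z {image.target_mz:g} (window {image.window_da:g} Da)")
    ax.set_xlabel("x (pixel)")
    ax.set_ylabel("y (pixel)")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def ion_image_to_csv(image: IonImage, path: str | Path) -> None:
    """Write the intensity grid as a CSV matrix (NaN for missing pixels)."""
    np.savetxt(path, image.grid, delimiter=",", fmt="%.6g")
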