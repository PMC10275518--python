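"""Semiquantitative trypan-blue staining statistic based on corrected hue.

The readout for blood-brain-barrier opening is the ratio of mean
*corrected hue* between the treated (ipsilateral) and untreated
(contralateral) hemispheres of a gross brain photograph.  Raw HSV hue H
places red near 0 deg and blue near 240 deg, but wraps at 360, so a plain
average is not ordered by "blueness".  The piecewise corrected-hue
transform

    H' = 99 - H    for 0 <= H < 100
    H' = 459 - H   for 100 <= H < 360

maps red-family hues into (-1, 99] and blue/green-family hues into
(99, 359], producing a single scale that increases with blue staining, so
an arithmetic mean (and the ipsi/contra ratio of means) is meaningful.
A ratio above 1.0 indicates stronger trypan-blue staining on the treated
side, i.e. barrier opening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateSummaryError, UndefinedRatioError
from .imaging import RasterImage

TIMEPOINT_ORDER = ("30min", "1h", "2h")

#: Histogram layout: 36 bins of 10 corrected-hue units spanning (-1, 359].
HIST_BINS = 36
HIST_RANGE = (-1.0, 359.0)


def rgb_to_hue(r: int, g: int, b: int) -> float | None:
    """Hexagonal HSV hue in degrees [0, 360), or None for achromatic input.

    Achromatic means zero chroma (r == g == b), where hue is undefined.
    """
    for v in (r, g, b):
        if not 0 <= v <= 255:
            raise ValueError(f"channel value {v} outside [0, 255]")
    hue, chroma = _hue_chroma(np.array([[r, g, b]], dtype=float))
    if chroma[0] == 0:
        return None
    return float(hue[0])


def _hue_chroma(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized hue (degrees) and chroma for an (n, 3) float RGB array.

    Hue entries where chroma is zero are arbitrary and must be masked by
    the caller.
    """
    r, g, b = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    mx = rgb.max(axis=1)
    mn = rgb.min(axis=1)
    c = mx - mn
    safe_c = np.where(c == 0, 1.0, c)
    h = np.empty(len(rgb))
    is_r = (mx == r)
    is_g = (mx == g) & ~is_r
    is_b = ~is_r & ~is_g
    h[is_r] = np.mod((g[is_r] - b[is_r]) / safe_c[is_r], 6.0)
    h[is_g] = (b[is_g] - r[is_g]) / safe_c[is_g] + 2.0
    h[is_b] = (r[is_b] - g[is_b]) / safe_c[is_b] + 4.0
    return 60.0 * h, c


def corrected_hue(h):
    """Piecewise corrected hue: 99 - H for H < 100, 459 - H for H >= 100.

    Accepts a scalar or ndarray of raw hues in [0, 360).  The map is
    injective (branch 1 covers (-1, 99], branch 2 covers (99, 359]) and
    deliberately discontinuous at H = 100; values in (99, 100) produce
    small negative outputs, which are kept as-is.
    """
    arr = np.asarray(h, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 360):
        raise ValueError("raw hue must lie in [0, 360)")
    out = np.where(arr < 100.0, 99.0 - arr, 459.0 - arr)
    if np.isscalar(h) or arr.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class HueSummary:
    """Per-ROI corrected-hue statistics.

    ``sd_corrected_hue`` is the population standard deviation.  The
    histogram has 36 bins of 10 units covering the corrected-hue range;
    its counts sum to ``n_pixels``.
    """

    n_pixels: int
    n_excluded_achromatic: int
    mean_corrected_hue: float
    sd_corrected_hue: float
    histogram: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise DegenerateSummaryError("summary requires at least one pixel")
        assert self.histogram.sum() == self.n_pixels
        assert self.sd_corrected_hue >= 0


def roi_hue_summary(
    image: RasterImage, mask: np.ndarray, saturation_min: float = 0.0
) -> HueSummary:
    """Mean, SD and histogram of corrected hue over the masked pixels.

    Achromatic pixels (zero chroma, undefined hue) are always excluded
    and counted; ``saturation_min`` additionally excludes near-achromatic
    pixels with HSV saturation below the threshold (default 0 = off),
    useful for pale unstained tissue.  Raises
    :class:`DegenerateSummaryError` when nothing remains.
    """
    if mask.shape != image.pixels.shape[:2]:
        raise ValueError("mask does not match image dimensions")
    if not mask.any():
        raise DegenerateSummaryError("empty mask")
    rgb = image.pixels[mask].astype(float)
    hue, chroma = _hue_chroma(rgb)
    mx = rgb.max(axis=1)
    sat = np.where(mx == 0, 0.0, chroma / np.where(mx == 0, 1.0, mx))
    keep = (chroma > 0) & (sat >= saturation_min)
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise DegenerateSummaryError("all pixels excluded as achromatic")
    ch = corrected_hue(hue[keep])
    hist, _ = np.histogram(ch, bins=HIST_BINS, range=HIST_RANGE)
    return HueSummary(
        n_pixels=int(keep.sum()),
        n_excluded_achromatic=n_excluded,
        mean_corrected_hue=float(ch.mean()),
        sd_corrected_hue=float(ch.std()),  # population SD
        histogram=hist,
    )


@dataclass(frozen=True)
class StainRatio:
    """Ipsilateral/contralateral corrected-hue ratio for one group x timepoint."""

    group: str
    timepoint: str
    ratio: float
    n_animals: int = 1

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINT_ORDER:
            raise ValueError(f"timepoint must be one of {TIMEPOINT_ORDER}")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")


def stain_ratio(
    ipsi: HueSummary | Sequence[HueSummary],
    contra: HueSummary | Sequence[HueSummary],
    group: str = "",
    timepoint: str = "30min",
    aggregation: str = "mean_of_ratios",
) -> StainRatio:
    """Ipsi/contra ratio of mean corrected hue, optionally across animals.

    For per-animal lists the default aggregation is the arithmetic mean
    of per-animal ratios; ``aggregation="ratio_of_pooled_means"`` instead
    divides the pixel-count-weighted pooled means.  A non-positive
    contralateral mean raises :class:`UndefinedRatioError` rather than
    being silently dropped.
    """
    ipsi_list = [ipsi] if isinstance(ipsi, HueSummary) else list(ipsi)
    contra_list = [contra] if isinstance(contra, HueSummary) else list(contra)
    if len(ipsi_list) != len(contra_list) or not ipsi_list:
        raise ValueError("ipsi and contra must be non-empty lists of equal length")
    for s in contra_list:
        if s.mean_corrected_hue <= 0:
            raise UndefinedRatioError(
                f"contralateral mean {s.mean_corrected_hue} <= 0; ratio undefined"
            )
    if aggregation == "mean_of_ratios":
        ratios = [
            i.mean_corrected_hue / c.mean_corrected_hue
            for i, c in zip(ipsi_list, contra_list)
        ]
        value = float(np.mean(ratios))
    elif aggregation == "ratio_of_pooled_means":
        pool = lambda xs: float(
            np.average(
                [s.mean_corrected_hue for s in xs],
                weights=[s.n_pixels for s in xs],
            )
        )
        value = pool(ipsi_list) / pool(contra_list)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return StainRatio(group, timepoint, value, n_animals=len(ipsi_list))


def timecourse_table(ratios: Sequence[StainRatio]) -> pd.DataFrame:
    """Tidy group x timepoint ratio table with per-group peak annotation.

    Sorted by group then timepoint order (30min, 1h, 2h); the row holding
    each group's maximum ratio is flagged ``is_peak``.  Duplicate
    (group, timepoint) cells are an error.
    """
    if not ratios:
        raise ValueError("need at least one ratio")
    keys = [(r.group, r.timepoint) for r in ratios]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (group, timepoint) cell")
    df = pd.DataFrame(
        {
            "group": [r.group for r in ratios],
            "timepoint": pd.Categorical(
                [r.timepoint for r in ratios],
                categories=list(TIMEPOINT_ORDER),
                ordered=True,
            ),
            "ratio": [r.ratio for r in ratios],
            "n_animals": [r.n_animals for r in ratios],
        }
    ).sort_values(["group", "timepoint"], ignore_index=True)
    peak_idx = df.groupby("group", observed=True)["ratio"].idxmax()
    df["is_peak"] = False
    df.loc[peak_idx, "is_peak"] = True
    return df


def peak_timepoints(table: pd.DataFrame) -> dict[str, str]:
    """Map each group to its annotated peak timepoint."""
    peaks = table[table["is_peak"]]
    return {row.group: str(row.timepoint) for row in peaks.itertuples()}
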