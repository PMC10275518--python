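"""Raster-image I/O and hemisphere region-of-interest construction.

Coordinate convention: pixel (0, 0) is the top-left corner, x increases
rightward (columns), y downward (rows).  All masks are boolean arrays of
shape ``(height, width)`` in image coordinates.

The default ROI method splits the tissue mask at a vertical midline (the
treated hemisphere is image-right unless flipped); manually drawn polygon
ROIs are supported for real photographs where a midline split is too
crude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path as _Path

import numpy as np
import shapely
from PIL import Image, UnidentifiedImageError
from shapely.geometry import Polygon

from .errors import DegenerateROIError, InputFormatError, ROIFormatError


@dataclass(frozen=True)
class RasterImage:
    """8-bit RGB image; ``pixels`` has shape (height, width, 3), dtype uint8."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3 or p.dtype != np.uint8:
            raise InputFormatError("pixels must be (h, w, 3) uint8")
        if p.shape[0] < 1 or p.shape[1] < 1:
            raise InputFormatError("image dimensions must be >= 1")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RegionSet:
    """Tissue / ipsilateral / contralateral boolean masks on one grid.

    Invariants (checked on construction): the hemisphere masks are
    disjoint and contained in the tissue mask, and all grids share one
    shape.
    """

    tissue: np.ndarray
    ipsilateral: np.ndarray
    contralateral: np.ndarray
    provenance: str  # midline_split | polygon_file | generator_ground_truth

    def __post_init__(self) -> None:
        shapes = {self.tissue.shape, self.ipsilateral.shape, self.contralateral.shape}
        if len(shapes) != 1:
            raise DegenerateROIError("mask shapes differ")
        for m in (self.tissue, self.ipsilateral, self.contralateral):
            if m.dtype != bool:
                raise DegenerateROIError("masks must be boolean")
        if np.any(self.ipsilateral & self.contralateral):
            raise DegenerateROIError("hemisphere masks overlap")
        if np.any(self.ipsilateral & ~self.tissue) or np.any(
            self.contralateral & ~self.tissue
        ):
            raise DegenerateROIError("hemisphere masks extend outside tissue")


def read_image(path: str | _Path) -> RasterImage:
    """Read a PNG or JPEG file as an 8-bit RGB image.

    Grayscale inputs are promoted to RGB by channel replication; alpha
    channels are dropped.  Unreadable or truncated files raise
    :class:`InputFormatError`.
    """
    try:
        with Image.open(path) as im:
            if im.format not in ("PNG", "JPEG"):
                raise InputFormatError(f"unsupported image format {im.format!r}")
            arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except (OSError, UnidentifiedImageError, SyntaxError) as exc:
        raise InputFormatError(f"cannot read image {path}: {exc}") from exc
    return RasterImage(arr)


def write_image(image: RasterImage, path: str | _Path) -> None:
    """Write as PNG (lossless, so read/write round-trips pixel-exactly)."""
    Image.fromarray(image.pixels, mode="RGB").save(path, format="PNG")


def tissue_mask(image: RasterImage, brightness_threshold: int = 30) -> np.ndarray:
    """Pixels with max(R, G, B) strictly above the threshold.

    Intended to drop dark photographic background around the brain.
    """
    if not 0 <= brightness_threshold <= 255:
        raise ValueError("brightness_threshold must be in [0, 255]")
    return image.pixels.max(axis=2) > brightness_threshold


def split_hemispheres(
    image: RasterImage,
    tissue: np.ndarray,
    midline_x: int | str = "auto",
    treated_side: str = "right",
) -> RegionSet:
    """Assign tissue columns left/right of a vertical midline to hemispheres.

    ``midline_x="auto"`` places the midline at the tissue-mask centroid
    column.  Columns strictly left of the midline go to one hemisphere,
    strictly right to the other; the midline column itself belongs to
    neither.  By default the treated (ipsilateral) side is image-right.
    """
    if tissue.shape != image.pixels.shape[:2]:
        raise DegenerateROIError("tissue mask does not match image dimensions")
    if not tissue.any():
        raise DegenerateROIError("tissue mask is empty")
    if treated_side not in ("left", "right"):
        raise ValueError("treated_side must be 'left' or 'right'")

    if midline_x == "auto":
        cols = np.nonzero(tissue)[1]
        mid = int(round(cols.mean()))
    else:
        mid = int(midline_x)

    xs = np.arange(tissue.shape[1])
    left = tissue & (xs[None, :] < mid)
    right = tissue & (xs[None, :] > mid)
    if not left.any() or not right.any():
        raise DegenerateROIError(
            f"all tissue lies on one side of midline column {mid}"
        )
    if treated_side == "right":
        ipsi, contra = right, left
    else:
        ipsi, contra = left, right
    return RegionSet(tissue, ipsi, contra, provenance="midline_split")


def _parse_polygon_file(path: str | _Path) -> dict[str, list[tuple[float, float]]]:
    """Parse the plain-text ROI format: ``label: x1,y1 x2,y2 ...`` per line."""
    polys: dict[str, list[tuple[float, float]]] = {}
    for lineno, raw in enumerate(_Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ROIFormatError(f"{path}:{lineno}: expected 'label: x,y x,y ...'")
        label, rest = line.split(":", 1)
        label = label.strip().lower()
        try:
            verts = [
                (float(x), float(y))
                for x, y in (pair.split(",") for pair in rest.split())
            ]
        except ValueError as exc:
            raise ROIFormatError(f"{path}:{lineno}: bad vertex list") from exc
        if len(verts) < 3:
            raise ROIFormatError(f"{path}:{lineno}: polygon needs >= 3 vertices")
        polys[label] = verts
    return polys


def _rasterize(poly: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    inside = shapely.contains_xy(poly, xs.ravel() + 0.0, ys.ravel() + 0.0)
    return inside.reshape(h, w)


def read_roi_polygons(path: str | _Path, image: RasterImage) -> RegionSet:
    """Build a RegionSet from a two-polygon ROI file.

    The file must contain exactly one ``ipsilateral`` and one
    ``contralateral`` polygon.  Masks are rasterized on pixel centers,
    intersected with the tissue mask, and any overlap between the two
    polygons is assigned to neither hemisphere (with a warning).
    """
    polys = _parse_polygon_file(path)
    for label in ("ipsilateral", "contralateral"):
        if label not in polys:
            raise ROIFormatError(f"missing polygon {label!r} in {path}")

    masks = {}
    for label in ("ipsilateral", "contralateral"):
        poly = Polygon(polys[label])
        if not poly.is_valid:
            raise ROIFormatError(f"polygon {label!r} is invalid (self-intersecting?)")
        masks[label] = _rasterize(poly, image.pixels.shape[:2])

    tis = tissue_mask(image)
    ipsi = masks["ipsilateral"] & tis
    contra = masks["contralateral"] & tis
    overlap = ipsi & contra
    if overlap.any():
        warnings.warn(
            f"{int(overlap.sum())} pixels in both ROIs assigned to neither",
            stacklevel=2,
        )
        ipsi &= ~overlap
        contra &= ~overlap
    return RegionSet(tis, ipsi, contra, provenance="polygon_file")


def write_mask_png(mask: np.ndarray, path: str | _Path) -> None:
    """Export a boolean mask as a bilevel PNG (255 inside, 0 outside)."""
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(
        path, format="PNG"
    )
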