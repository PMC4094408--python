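"""One-pixel mucosal-interface outline extraction.

The absorptive surface of the fish intestine is a set of longitudinal
mucosal folds; its complexity is measured on the *outline* — the
one-pixel-wide boundary between mucosal tissue and lumen, traced on an
H&E image or on a pre-made binary tissue mask.  Extraction is
threshold -> hole fill -> largest component -> 4-neighbour boundary ->
conditional thinning, so the result is an 8-connected curve exactly one
pixel wide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import filters as skfilters
from skimage import measure as skmeasure
from skimage import morphology as skmorph

__all__ = [
    "MucosalOutline",
    "extract_outline",
    "is_one_pixel_wide",
    "load_outline_raster",
    "save_outline",
]


@dataclass
class MucosalOutline:
    """A one-pixel-wide 8-connected curve on a binary raster."""

    raster: np.ndarray  # bool (H, W)
    provenance: dict = field(default_factory=dict)
    connectivity: int = 8

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=bool)
        if self.raster.ndim != 2:
            raise ValueError("outline raster must be 2-D")
        if self.n_foreground < 2:
            raise ValueError("outline must contain at least 2 foreground pixels")

    @property
    def n_foreground(self) -> int:
        return int(self.raster.sum())


_NEIGHBOUR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def is_one_pixel_wide(mask: np.ndarray) -> bool:
    """True if the foreground contains no fully-occupied 2x2 block.

    A curve is one pixel wide when it has no solid 2x2 patch; right-angle
    corners and self-contact points are allowed (their pixels can have 3
    neighbours without the curve being thick). Rasters failing this get
    a thinning pass before being accepted as outlines.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return False
    solid = mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, :-1] & mask[1:, 1:]
    return not solid.any()


def _to_grey(tissue) -> np.ndarray:
    arr = np.asarray(getattr(tissue, "pixels", tissue))
    if arr.ndim == 3:
        return skcolor.rgb2gray(arr) * 255.0
    return arr.astype(float)


def extract_outline(
    tissue,
    threshold: float | None = None,
    tissue_is_dark: bool = True,
    min_hole_area: int = 256,
    min_component_fraction: float = 0.9,
) -> MucosalOutline:
    """Extract the luminal tissue/lumen interface as a one-pixel curve.

    Parameters
    ----------
    tissue : RGBField, greyscale image, or boolean tissue mask
        Boolean input is taken as the tissue mask directly (True =
        tissue). Grey/RGB input is thresholded.
    threshold : float, optional
        Manual grey-level threshold (0-255), mirroring the blinded
        manual operation of the original workflow.  When None, an
        automatic histogram-based (Otsu) threshold is used.
    tissue_is_dark : bool
        Whether tissue is darker than the lumen (true for H&E on a
        bright-field background).
    min_hole_area : int
        Holes in the tissue mask below this area (px^2) are filled
        before the boundary is traced, so internal vacuoles do not
        contribute spurious contours.
    min_component_fraction : float
        If the largest connected tissue component holds less than this
        fraction of the foreground a warning is issued; the outline is
        still traced on the largest component only.

    Returns
    -------
    MucosalOutline
        8-connected, one pixel wide; the serosal/outer image border is
        never part of the curve (pixels on the canvas edge are treated
        as interior).
    """
    arr = np.asarray(getattr(tissue, "pixels", tissue))
    if arr.dtype == bool or (arr.ndim == 2 and set(np.unique(arr)) <= {0, 1}):
        fg = arr.astype(bool)
        params = {"threshold": "mask input"}
    else:
        grey = _to_grey(tissue)
        if threshold is None:
            threshold = float(skfilters.threshold_otsu(grey))
            params = {"threshold": threshold, "mode": "auto-otsu"}
        else:
            params = {"threshold": float(threshold), "mode": "manual"}
        fg = grey < threshold if tissue_is_dark else grey > threshold
    if not fg.any():
        raise ValueError("empty foreground after thresholding")

    if min_hole_area > 0:
        fg = skmorph.remove_small_holes(fg, max_size=min_hole_area)
    labels = skmeasure.label(fg, connectivity=2)
    if labels.max() > 1:
        areas = np.bincount(labels.ravel())[1:]
        main = int(np.argmax(areas)) + 1
        if areas.max() < min_component_fraction * areas.sum():
            warnings.warn(
                "largest tissue component holds only "
                f"{areas.max() / areas.sum():.0%} of the foreground; "
                "check the threshold",
                stacklevel=2,
            )
        fg = labels == main

    # boundary: tissue pixels with >=1 lumen 4-neighbour; canvas border
    # counts as tissue so the image frame is never traced.
    interior = ndi.binary_erosion(fg, structure=_CROSS, border_value=1)
    boundary = fg & ~interior
    if not boundary.any():
        raise ValueError("tissue mask has no interface with the lumen")
    if not is_one_pixel_wide(boundary):
        boundary = skmorph.thin(boundary)
    meta = dict(params, min_hole_area=min_hole_area)
    if hasattr(tissue, "metadata"):
        meta["field_id"] = tissue.metadata.get("field_id")
    return MucosalOutline(raster=boundary, provenance=meta)


def load_outline_raster(path: str | Path) -> np.ndarray:
    """Read an 8-bit GIF/PNG outline image as a boolean raster."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > (arr.max() / 2 if arr.max() > 1 else 0)


def save_outline(outline: MucosalOutline | np.ndarray, path: str | Path) -> None:
    """Write an outline as an 8-bit binary PNG/GIF (255 = curve)."""
    raster = np.asarray(getattr(outline, "raster", outline), dtype=bool)
    iio.imwrite(Path(path), raster.astype(np.uint8) * 255)
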