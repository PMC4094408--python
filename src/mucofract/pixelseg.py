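"""Four-class colour segmentation of stained fields.

Every non-excluded pixel of an IHC/TUNEL field is assigned to the
nearest of four operator-anchored reference colours — DAB-brown
positive nuclei, haematoxylin-blue negative nuclei, eosin/enterocyte
cytoplasm, and white background — and the percentage of area occupied
by each class is reported.  Classification is by nearest neighbour in
CIELAB by default (D65), because raw-RGB distance conflates luminance
with the brown/blue hue contrast that separates DAB from haematoxylin;
plain RGB distance is available as a switch.  No spatial regularisation
is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor
from skimage import measure as skmeasure

from .field import RGBField

__all__ = ["CLASS_NAMES", "EXCLUDED_LABEL", "ClassPalette", "ClassMap", "segment_field", "apply_exclusion"]

#: Fixed class order; ties in colour distance resolve to the earliest class.
CLASS_NAMES: tuple[str, ...] = ("positive_nucleus", "negative_nucleus", "cytoplasm", "background")

#: Label value marking excluded (lamina propria) pixels in a ClassMap.
EXCLUDED_LABEL: int = 255


@dataclass(frozen=True)
class ClassPalette:
    """Operator-chosen reference colour (RGB, 0-255) for each class."""

    positive_nucleus: tuple[int, int, int]
    negative_nucleus: tuple[int, int, int]
    cytoplasm: tuple[int, int, int]
    background: tuple[int, int, int]

    def __post_init__(self) -> None:
        cols = self.as_array()
        if len({tuple(c) for c in cols}) != len(CLASS_NAMES):
            raise ValueError("palette reference colours must be pairwise distinct")
        if cols.min() < 0 or cols.max() > 255:
            raise ValueError("palette colours must be RGB triples in 0-255")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.positive_nucleus, self.negative_nucleus, self.cytoplasm, self.background],
            dtype=float,
        )

    @classmethod
    def default_ihc(cls) -> "ClassPalette":
        """Typical DAB / haematoxylin / eosin-cytoplasm / background anchors."""
        return cls(
            positive_nucleus=(125, 79, 46),
            negative_nucleus=(70, 85, 160),
            cytoplasm=(228, 180, 190),
            background=(255, 255, 255),
        )


@dataclass
class ClassMap:
    """Per-pixel class assignment and per-class area percentages.

    ``labels`` holds the class index (order of :data:`CLASS_NAMES`) or
    :data:`EXCLUDED_LABEL`; ``area_percent`` is computed over
    non-excluded pixels only and sums to 100.
    """

    labels: np.ndarray
    area_percent: dict[str, float]
    n_pixels_total: int
    n_pixels_excluded: int

    def class_mask(self, name: str) -> np.ndarray:
        return self.labels == CLASS_NAMES.index(name)


def _palette_distances(pixels: np.ndarray, palette: ClassPalette, color_space: str) -> np.ndarray:
    """(N, 4) squared colour distances of flat uint8 pixels to the anchors."""
    refs = palette.as_array()
    if color_space == "lab":
        px = skcolor.rgb2lab(pixels.reshape(1, -1, 3).astype(np.uint8)).reshape(-1, 3)
        rf = skcolor.rgb2lab(refs.reshape(1, -1, 3).astype(np.uint8)).reshape(-1, 3)
    elif color_space == "rgb":
        px, rf = pixels.astype(float), refs
    else:
        raise ValueError(f"unknown color_space {color_space!r}; use 'lab' or 'rgb'")
    d = px[:, None, :] - rf[None, :, :]
    return np.einsum("nkc,nkc->nk", d, d)


def segment_field(
    field: RGBField | np.ndarray,
    palette: ClassPalette,
    exclusion_mask: np.ndarray | None = None,
    color_space: str = "lab",
    min_blob_size: int = 0,
) -> ClassMap:
    """Assign every non-excluded pixel to the nearest palette colour.

    Parameters
    ----------
    field : RGBField or uint8 (H, W, 3) array
    palette : ClassPalette
    exclusion_mask : bool array, optional
        True = excluded.  If omitted and ``field`` carries its own
        exclusion (see :func:`apply_exclusion`), that one is used.
    color_space : {'lab', 'rgb'}
        Distance space for nearest-colour classification.
    min_blob_size : int
        If > 0, connected blobs of the two nucleus classes smaller than
        this are reassigned to each pixel's second-nearest class
        (optional clean-up; off by default).

    Raises
    ------
    ValueError
        On mask/field dimension mismatch or when every pixel is excluded.
    """
    px = np.asarray(getattr(field, "pixels", field))
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("field must be an RGB raster")
    if exclusion_mask is None:
        exclusion_mask = getattr(field, "exclusion", None)
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask).astype(bool)
        if exclusion_mask.shape != px.shape[:2]:
            raise ValueError(
                f"mask shape {exclusion_mask.shape} does not match field {px.shape[:2]}"
            )
    else:
        exclusion_mask = np.zeros(px.shape[:2], dtype=bool)

    n_total = px.shape[0] * px.shape[1]
    n_excl = int(exclusion_mask.sum())
    if n_excl == n_total:
        raise ValueError("empty field after exclusion")

    dist = _palette_distances(px.reshape(-1, 3), palette, color_space)
    labels = np.argmin(dist, axis=1).astype(np.uint8).reshape(px.shape[:2])

    if min_blob_size > 0:
        second = np.argsort(dist, axis=1, kind="stable")[:, 1].astype(np.uint8).reshape(px.shape[:2])
        for cls in (0, 1):  # nucleus classes only
            comp = skmeasure.label(labels == cls, connectivity=2)
            if comp.max():
                areas = np.bincount(comp.ravel())
                small = np.isin(comp, np.nonzero(areas < min_blob_size)[0][1:])
                labels[small & (labels == cls)] = second[small & (labels == cls)]

    labels[exclusion_mask] = EXCLUDED_LABEL
    keep = ~exclusion_mask
    n_keep = n_total - n_excl
    area_percent = {
        name: 100.0 * float(np.count_nonzero(labels[keep] == i)) / n_keep
        for i, name in enumerate(CLASS_NAMES)
    }
    return ClassMap(
        labels=labels,
        area_percent=area_percent,
        n_pixels_total=n_total,
        n_pixels_excluded=n_excl,
    )


def apply_exclusion(field: RGBField, mask: np.ndarray) -> RGBField:
    """Attach a lamina-propria exclusion mask to a field.

    Masked pixels are flagged as excluded — not recoloured — and all
    downstream area percentages ignore them.  The mask must be binary
    (boolean, or two-valued 0/255 as read from a mask file) and match
    the field's dimensions.
    """
    m = np.asarray(mask)
    if m.dtype != bool:
        vals = np.unique(m)
        if not np.isin(vals, (0, 1, 255)).all():
            raise ValueError("exclusion mask must be binary (0 = keep, 255 = exclude)")
        m = m > 0
    if m.shape != field.pixels.shape[:2]:
        raise ValueError(f"mask shape {m.shape} does not match field {field.pixels.shape[:2]}")
    return RGBField(pixels=field.pixels, exclusion=m, metadata=dict(field.metadata))
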