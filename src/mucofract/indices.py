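"""Trophism indices: PCNA proliferation index and apoptotic index.

Both indices are area/count ratios per 20x field:

    PCNA index      = 100 * %area_positive / (%area_positive + %area_negative)
    apoptotic index = 100 * n_apoptotic / (n_negative + n_apoptotic)

where the number of haematoxylin-stained negative nuclei per field is
recovered stereologically from the negative area percentage:

    n_negative = field_area * (%negative / 100) / mean_nucleus_area

The conversion is unit-invariant: field_area and mean_nucleus_area may
both be px^2 or both um^2.  Apoptotic (TUNEL-positive) events are
counted from operator annotation points, never automatically, because
TUNEL produces nonspecific cytoplasmic signal on intestinal sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from skimage import measure as skmeasure

from .pixelseg import ClassMap

__all__ = [
    "pcna_index",
    "negative_nuclei_count",
    "apoptotic_index",
    "count_apoptotic",
    "ApoptoticCount",
    "estimate_mean_nucleus_area",
    "count_apoptotic_blobs",
]


def pcna_index(pct_positive: float, pct_negative: float) -> float:
    """Proliferation index (%) from the two nuclear area percentages."""
    if pct_positive < 0 or pct_negative < 0:
        raise ValueError("area percentages must be non-negative")
    if pct_positive + pct_negative == 0:
        raise ValueError("no nuclear signal in field")
    return 100.0 * pct_positive / (pct_positive + pct_negative)


def negative_nuclei_count(field_area: float, pct_negative: float, mean_nucleus_area: float) -> float:
    """Stereological negative-nucleus count (real-valued) for one field."""
    if field_area <= 0 or mean_nucleus_area <= 0:
        raise ValueError("field_area and mean_nucleus_area must be positive")
    if not 0 <= pct_negative <= 100:
        raise ValueError("pct_negative must be a percentage in [0, 100]")
    return field_area * (pct_negative / 100.0) / mean_nucleus_area


def apoptotic_index(n_apoptotic: float, n_negative: float) -> float:
    """Apoptotic index (%) from the apoptotic and negative nucleus counts."""
    if n_apoptotic < 0 or n_negative < 0:
        raise ValueError("counts must be non-negative")
    if n_apoptotic + n_negative == 0:
        raise ValueError("no nuclei in field: apoptotic index undefined")
    return 100.0 * n_apoptotic / (n_negative + n_apoptotic)


@dataclass
class ApoptoticCount:
    """Manual apoptotic count with the rejected annotation points."""

    count: int
    rejected: list[tuple[int, int]] = dc_field(default_factory=list)

    def __int__(self) -> int:
        return self.count


def count_apoptotic(field, annotations: Sequence[tuple[float, float]]) -> ApoptoticCount:
    """Count operator-annotated apoptotic events on one field.

    ``annotations`` are (x, y) click points, 0-based, origin top-left.
    Points falling in the field's exclusion mask are rejected and
    reported; points outside the raster raise.
    """
    px = np.asarray(getattr(field, "pixels", field))
    h, w = px.shape[:2]
    mask = getattr(field, "exclusion", None)
    accepted, rejected = 0, []
    for x, y in annotations:
        xi, yi = int(round(x)), int(round(y))
        if not (0 <= xi < w and 0 <= yi < h):
            raise ValueError(f"annotation point ({x}, {y}) outside {w}x{h} raster")
        if mask is not None and mask[yi, xi]:
            rejected.append((xi, yi))
        else:
            accepted += 1
    return ApoptoticCount(count=accepted, rejected=rejected)


def estimate_mean_nucleus_area(class_map: ClassMap, min_area: int = 5) -> float:
    """Mean connected-component area (px^2) of the negative-nucleus class.

    A calibration helper: run it on a few representative fields and use
    the average as the per-batch ``mean_nucleus_area`` constant.
    Components below ``min_area`` are treated as colour-noise speckle
    and ignored.
    """
    comp = skmeasure.label(class_map.class_mask("negative_nucleus"), connectivity=2)
    if comp.max() == 0:
        raise ValueError("no negative nuclei found on the calibration field")
    areas = np.bincount(comp.ravel())[1:]
    areas = areas[areas >= min_area]
    if areas.size == 0:
        raise ValueError("all negative-nucleus blobs below min_area")
    return float(areas.mean())


def count_apoptotic_blobs(class_map: ClassMap, max_fragment_area: int = 40, merge_radius: int = 4) -> int:
    """Automatic apoptotic-event count for SYNTHETIC fields only.

    Groups small positive-class fragments within ``merge_radius`` pixels
    into single events.  This mode exists to close the loop against the
    synthetic generator's ground truth; it is NOT suitable for real
    TUNEL slides, whose nonspecific signal demands manual counting.
    """
    from scipy import ndimage as ndi

    pos = class_map.class_mask("positive_nucleus")
    comp = skmeasure.label(pos, connectivity=2)
    areas = np.bincount(comp.ravel())
    small = np.isin(comp, np.nonzero(areas[: comp.max() + 1] <= max_fragment_area)[0][1:]) & pos
    if not small.any():
        return 0
    merged = ndi.binary_dilation(small, iterations=merge_radius)
    return int(skmeasure.label(merged, connectivity=2).max())
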