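"""Box-counting fractal dimension of one-pixel outlines.

The box-counting dimension of a planar curve is the slope of
``ln N(s)`` against ``ln(1/s)``, where ``N(s)`` is the number of cells
of an ``s``-pixel grid that intersect the curve. A rectifiable (smooth)
curve gives a slope of 1; increasingly convoluted curves fill more of
the plane and the slope rises towards 2.

The default box-size ladder is 2, 3, 4, 6, 8, 12, 16, 32, 64, 128, 256,
512, 1024, 2048 pixels, evaluated on a single fixed grid anchored at the
top-left corner of the curve's bounding box, with partial boxes at the
far edges included.  Anchoring the grid at the object rather than the
image corner makes the counts exactly invariant under translation of
the outline within the canvas.

Two classes of ladder points carry no scaling information and are
dropped before the fit: once the curve fits in a single box the counts
saturate at 1 (sizes past the first fully saturated one are removed —
saturation trimming), and boxes so coarse that the curve occupies fewer
than :data:`MIN_BOX_OCCUPANCY` of them measure only the grid phase, not
the curve (they are removed whenever at least 3 ladder points remain).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "DEFAULT_LADDER",
    "BoxCountCurve",
    "FDEstimate",
    "box_count",
    "estimate_fd",
    "fd_pipeline",
]

#: Box-edge lengths (pixels) used by default for the log-log fit.
DEFAULT_LADDER: tuple[int, ...] = (2, 3, 4, 6, 8, 12, 16, 32, 64, 128, 256, 512, 1024, 2048)

#: Ladder points where the curve occupies fewer boxes than this are
#: dominated by grid phase and are excluded from the fit.
MIN_BOX_OCCUPANCY: int = 4


@dataclass(frozen=True)
class BoxCountCurve:
    """Occupied-box counts N(s) for each box size s of the ladder."""

    box_sizes: np.ndarray  # ascending, pixels
    counts: np.ndarray  # occupied boxes per size, same length
    grid_origin: tuple[int, int] = (0, 0)  # (row, col) anchor of the grid

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"size": self.box_sizes, "count": self.counts})


@dataclass(frozen=True)
class FDEstimate:
    """Fitted box-counting dimension.

    ``fd`` is the OLS slope of ln N(s) on ln(1/s) over ``sizes_used``;
    ``r_squared`` the coefficient of determination of that fit.
    """

    fd: float
    intercept: float
    r_squared: float
    sizes_used: tuple[int, ...]


def _as_bool_raster(outline) -> np.ndarray:
    raster = getattr(outline, "raster", outline)
    raster = np.asarray(raster)
    if raster.ndim != 2:
        raise ValueError("outline must be a 2-D binary raster")
    return raster != 0


def box_count(outline, box_sizes=DEFAULT_LADDER, n_offsets: int = 1) -> BoxCountCurve:
    """Count grid boxes of each ladder size containing >= 1 foreground pixel.

    The grid is a single fixed lattice anchored at the top-left corner
    of the foreground bounding box; boxes that only partially overlap
    the curve extent at the far edges still count.  With ``n_offsets``
    > 1 the grid is additionally shifted over an ``n_offsets x
    n_offsets`` lattice of sub-box offsets and the minimum count per
    size is kept (optional tight-covering mode, off by default).

    Raises
    ------
    ValueError
        If the outline has no foreground pixels or the ladder is not
        ascending with all sizes >= 2.
    """
    mask = _as_bool_raster(outline)
    sizes = np.asarray(box_sizes, dtype=np.int64)
    if sizes.size == 0 or np.any(sizes < 2) or np.any(np.diff(sizes) <= 0):
        raise ValueError("box_sizes must be strictly ascending with sizes >= 2")
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty outline: no foreground pixels to count")
    if n_offsets < 1:
        raise ValueError("n_offsets must be >= 1")
    origin = (int(ys.min()), int(xs.min()))
    ys = ys - origin[0]
    xs = xs - origin[1]
    w = int(xs.max()) + 1
    counts = np.empty(sizes.size, dtype=np.int64)
    for k, s in enumerate(sizes):
        best = None
        for i in range(n_offsets):
            for j in range(n_offsets):
                oy, ox = (i * s) // n_offsets, (j * s) // n_offsets
                ncols = (w + ox) // s + 1
                keys = ((ys + oy) // s) * ncols + (xs + ox) // s
                n = np.unique(keys).size
                best = n if best is None else min(best, n)
        counts[k] = best
    return BoxCountCurve(box_sizes=sizes, counts=counts, grid_origin=origin)


def estimate_fd(curve: BoxCountCurve) -> FDEstimate:
    """OLS fit of ln N(s) versus ln(1/s); the slope is the dimension.

    Saturated sizes (N = 1) beyond the first one are dropped, then
    sizes where the curve occupies fewer than
    :data:`MIN_BOX_OCCUPANCY` boxes are dropped whenever at least 3
    ladder points survive.  At least 3 usable sizes and 2 distinct
    counts are required.
    """
    sizes = np.asarray(curve.box_sizes, dtype=float)
    counts = np.asarray(curve.counts, dtype=float)
    if np.any(counts < 1):
        raise ValueError("box counts must be strictly positive")
    saturated = np.nonzero(counts == 1)[0]
    if saturated.size > 1:
        keep = slice(0, saturated[0] + 1)  # keep the first saturated size only
        sizes, counts = sizes[keep], counts[keep]
    occupied = counts >= MIN_BOX_OCCUPANCY
    if occupied.sum() >= 3:
        sizes, counts = sizes[occupied], counts[occupied]
    if sizes.size < 3:
        raise ValueError("fewer than 3 usable box sizes after saturation trimming")
    if np.unique(counts).size < 2:
        raise ValueError("degenerate outline: box counts carry no scaling information")
    fit = _sps.linregress(np.log(1.0 / sizes), np.log(counts))
    return FDEstimate(
        fd=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        sizes_used=tuple(int(s) for s in sizes),
    )


def fd_pipeline(
    source,
    box_sizes=DEFAULT_LADDER,
    out_dir: str | Path | None = None,
    image_id: str | None = None,
    threshold: float | None = None,
) -> tuple[FDEstimate, BoxCountCurve]:
    """Outline -> box counts -> FD for one image, with optional CSV artifacts.

    ``source`` may be a binary outline raster / :class:`MucosalOutline`,
    a path to an outline image, or a tissue image / RGBField from which
    the outline is first extracted (see :func:`outline.extract_outline`).
    When ``out_dir`` is given, appends a row (image_id, fd, intercept,
    r_squared, sizes_used) to ``fd.csv`` and writes the box-count table
    to ``<image_id>_boxcount.csv``.
    """
    from . import outline as _outline  # deferred: avoid import cycle

    if isinstance(source, (str, Path)):
        raster = _outline.load_outline_raster(source)
        if image_id is None:
            image_id = Path(source).stem
        source = raster
    raster = getattr(source, "raster", None)
    if raster is None:
        arr = np.asarray(getattr(source, "pixels", source))
        if arr.ndim == 3 or not _outline.is_one_pixel_wide(arr != 0):
            source = _outline.extract_outline(source, threshold=threshold)
    curve = box_count(source, box_sizes)
    est = estimate_fd(curve)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        image_id = image_id or "image"
        row = pd.DataFrame(
            [
                {
                    "image_id": image_id,
                    "fd": est.fd,
                    "intercept": est.intercept,
                    "r_squared": est.r_squared,
                    "sizes_used": " ".join(str(s) for s in est.sizes_used),
                }
            ]
        )
        results = out_dir / "fd.csv"
        row.to_csv(results, mode="a", header=not results.exists(), index=False)
        curve.to_frame().to_csv(out_dir / f"{image_id}_boxcount.csv", index=False)
    return est, curve
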