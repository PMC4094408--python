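"""Synthetic study inputs with known ground truth.

Two families of test inputs stand in for the undeposited slides:

* **IHC-like fields** — elliptical fold cross-sections with DAB-brown
  positive nuclei, haematoxylin-blue negative nuclei, pink enterocyte
  cytoplasm, white background, a lamina-propria core recorded in an
  exclusion mask, and optional apoptotic fragment clusters.  The
  per-pixel class membership is stored losslessly before colour noise,
  so the reported ground truth is an exact pixel census of the render.

* **One-pixel outlines** — straight lines and circles (rectifiable,
  dimension 1), Koch and quadric-Koch curves (similarity dimensions
  log4/log3 and log8/log4), and midpoint-displacement "fold curves"
  whose contour complexity rises monotonically with a roughness knob,
  emulating mucosal folding of varying trophic state.

Everything is driven by ``numpy.random.default_rng`` seeds: identical
parameters and seed give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage import draw as skdraw
from skimage import measure as skmeasure
from skimage import morphology as skmorph

from .outline import MucosalOutline, is_one_pixel_wide
from .pixelseg import CLASS_NAMES, ClassPalette

__all__ = [
    "FieldTruth",
    "IhcField",
    "OutlineSpec",
    "PackingError",
    "generate_ihc_field",
    "generate_outline",
    "KOCH_DIMENSION",
    "QUADRIC_KOCH_DIMENSION",
]

#: Similarity dimension of the triadic Koch curve (4 copies at scale 1/3).
KOCH_DIMENSION: float = math.log(4) / math.log(3)
#: Similarity dimension of the quadric Koch curve (8 copies at scale 1/4).
QUADRIC_KOCH_DIMENSION: float = math.log(8) / math.log(4)


class PackingError(RuntimeError):
    """Requested nuclei cannot be placed without exceeding the area budget."""


# --------------------------------------------------------------------------
# IHC fields
# --------------------------------------------------------------------------


@dataclass
class FieldTruth:
    """Ground truth for one synthetic stained field.

    ``class_area_fractions`` is the exact census of the rendered class
    map over non-excluded pixels (sums to 1); ``mean_nucleus_area`` is
    the realized mean pixel area of the negative epithelial nuclei —
    the constant the stereological count formula divides by.
    """

    n_positive_nuclei: int
    n_negative_nuclei: int
    n_apoptotic: int
    mean_nucleus_area: float
    class_area_fractions: dict[str, float]
    field_area: int
    rng_seed: int

    def __post_init__(self) -> None:
        if min(self.n_positive_nuclei, self.n_negative_nuclei, self.n_apoptotic) < 0:
            raise ValueError("counts must be non-negative")
        if self.mean_nucleus_area <= 0 and (self.n_positive_nuclei or self.n_negative_nuclei):
            raise ValueError("mean_nucleus_area must be positive")
        total = sum(self.class_area_fractions[c] for c in CLASS_NAMES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class area fractions sum to {total}, not 1")

    @property
    def true_pcna_index(self) -> float:
        n = self.n_positive_nuclei + self.n_negative_nuclei
        return 100.0 * self.n_positive_nuclei / n if n else float("nan")


@dataclass
class IhcField:
    """A rendered synthetic field bundled with its ground truth.

    ``image`` (RGBField-compatible uint8 RGB), ``truth``, and the
    lamina-propria ``exclusion_mask`` are the primary outputs;
    ``labels`` is the lossless pre-noise class map (class index per
    pixel, 255 outside the tissue logic never occurs here) and
    ``apoptotic_points`` the auto-exported (x, y) annotation points.
    """

    image: "RGBField"
    truth: FieldTruth
    exclusion_mask: np.ndarray
    labels: np.ndarray
    apoptotic_points: list[tuple[int, int]] = dc_field(default_factory=list)


def _ellipse_mask(shape, center, axes, rotation=0.0):
    rr, cc = skdraw.ellipse(center[0], center[1], axes[0], axes[1], shape=shape, rotation=rotation)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def _place_nuclei(rng, region, n, axes_range, occupied, max_tries=4000):
    """Rejection-sample n non-overlapping ellipses inside ``region``.

    Returns (list of pixel-index tuples, per-nucleus areas). Mutates
    ``occupied``. Raises PackingError when placement stalls.
    """
    h, w = region.shape
    ys, xs = np.nonzero(region)
    placed, areas = [], []
    for _ in range(n):
        for attempt in range(max_tries):
            j = rng.integers(0, ys.size)
            cy, cx = int(ys[j]), int(xs[j])
            a = rng.uniform(*axes_range)
            b = rng.uniform(*axes_range)
            rot = rng.uniform(0, np.pi)
            rr, cc = skdraw.ellipse(cy, cx, a, b, shape=(h, w), rotation=rot)
            if rr.size == 0:
                continue
            if region[rr, cc].all() and not occupied[rr, cc].any():
                occupied[rr, cc] = True
                placed.append((rr, cc))
                areas.append(rr.size)
                break
        else:
            raise PackingError(
                f"could not place nucleus {len(placed) + 1}/{n} after {max_tries} tries; "
                "reduce counts or nucleus size"
            )
    return placed, areas


def generate_ihc_field(
    n_positive: int = 50,
    n_negative: int = 150,
    n_apoptotic: int = 0,
    canvas: tuple[int, int] = (512, 512),
    palette: ClassPalette | None = None,
    noise_sigma: float = 8.0,
    nucleus_axes: tuple[float, float] = (3.5, 7.0),
    n_lamina_nuclei: int = 12,
    seed: int = 0,
) -> IhcField:
    """Render one synthetic IHC/TUNEL field with exact ground truth.

    The field is an elliptical mucosal-fold cross-section: white lumen
    background, a cytoplasm annulus carrying the epithelial nuclei, and
    a lamina-propria core (recorded in the exclusion mask) seeded with
    distractor blue nuclei that must not leak into the counts.
    Apoptotic events are 1-3 small DAB-brown fragments each, distinct
    from whole-nucleus PCNA-like staining; their centres are exported
    as annotation points.

    Parameters are desk-scale defaults; ``canvas`` is (width, height).

    Raises
    ------
    PackingError
        If the requested nuclei exceed ~60% of the epithelial area or
        cannot be placed without overlap.
    """
    from .field import RGBField

    palette = palette or ClassPalette.default_ihc()
    w, h = canvas
    shape = (h, w)
    rng = np.random.default_rng(seed)

    outer = _ellipse_mask(shape, (h / 2, w / 2), (0.44 * h, 0.46 * w))
    lamina = _ellipse_mask(shape, (h / 2, w / 2), (0.20 * h, 0.22 * w))
    annulus = outer & ~lamina

    mean_req_area = np.pi * ((nucleus_axes[0] + nucleus_axes[1]) / 2) ** 2
    budget = (n_positive + n_negative) * mean_req_area
    if budget > 0.6 * annulus.sum():
        raise PackingError(
            f"requested nuclei need ~{budget:.0f} px^2, over 60% of the "
            f"{annulus.sum()} px^2 epithelial band"
        )

    labels = np.full(shape, CLASS_NAMES.index("background"), dtype=np.uint8)
    labels[annulus] = CLASS_NAMES.index("cytoplasm")
    labels[lamina] = CLASS_NAMES.index("cytoplasm")  # stroma rendered cytoplasm-like

    occupied = np.zeros(shape, dtype=bool)
    # shrink the admissible band so ellipses stay wholly epithelial
    inner_margin = _ellipse_mask(
        shape, (h / 2, w / 2), (0.20 * h + nucleus_axes[1], 0.22 * w + nucleus_axes[1])
    )
    outer_margin = _ellipse_mask(
        shape, (h / 2, w / 2), (0.44 * h - nucleus_axes[1], 0.46 * w - nucleus_axes[1])
    )
    band = outer_margin & ~inner_margin

    pos_px, _ = _place_nuclei(rng, band, n_positive, nucleus_axes, occupied)
    neg_px, neg_areas = _place_nuclei(rng, band, n_negative, nucleus_axes, occupied)
    for rr, cc in pos_px:
        labels[rr, cc] = CLASS_NAMES.index("positive_nucleus")
    for rr, cc in neg_px:
        labels[rr, cc] = CLASS_NAMES.index("negative_nucleus")

    # apoptotic events: clusters of 1-3 tiny high-intensity brown fragments
    apoptotic_points: list[tuple[int, int]] = []
    ys, xs = np.nonzero(band & ~occupied)
    for _ in range(n_apoptotic):
        j = rng.integers(0, ys.size)
        cy, cx = int(ys[j]), int(xs[j])
        apoptotic_points.append((cx, cy))
        for _frag in range(int(rng.integers(1, 4))):
            fy = int(np.clip(cy + rng.integers(-4, 5), 0, h - 1))
            fx = int(np.clip(cx + rng.integers(-4, 5), 0, w - 1))
            rr, cc = skdraw.disk((fy, fx), rng.uniform(1.0, 2.2), shape=shape)
            if not lamina[rr, cc].any():
                labels[rr, cc] = CLASS_NAMES.index("positive_nucleus")

    # distractor nuclei inside the lamina propria (excluded region only)
    lam_band = skmorph.erosion(lamina, skmorph.disk(int(nucleus_axes[1]) + 1))
    if lam_band.any() and n_lamina_nuclei:
        lam_occ = np.zeros(shape, dtype=bool)
        try:
            lam_px, _ = _place_nuclei(rng, lam_band, n_lamina_nuclei, nucleus_axes, lam_occ)
        except PackingError:
            lam_px = []
        for rr, cc in lam_px:
            labels[rr, cc] = CLASS_NAMES.index("negative_nucleus")

    # render: palette colour per class + clipped Gaussian RGB noise
    colours = palette.as_array().astype(np.float64)
    img = colours[labels]
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    keep = ~lamina
    n_keep = int(keep.sum())
    fractions = {
        name: float(np.count_nonzero(labels[keep] == i)) / n_keep
        for i, name in enumerate(CLASS_NAMES)
    }
    truth = FieldTruth(
        n_positive_nuclei=n_positive,
        n_negative_nuclei=n_negative,
        n_apoptotic=n_apoptotic,
        mean_nucleus_area=float(np.mean(neg_areas)) if neg_areas else 1.0,
        class_area_fractions=fractions,
        field_area=n_keep,
        rng_seed=seed,
    )
    image = RGBField(pixels=img, exclusion=lamina, metadata={"rng_seed": seed, "synthetic": True})
    return IhcField(
        image=image,
        truth=truth,
        exclusion_mask=lamina,
        labels=labels,
        apoptotic_points=apoptotic_points,
    )


# --------------------------------------------------------------------------
# Outlines and reference fractals
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class OutlineSpec:
    """Recipe for one synthetic one-pixel outline.

    base_shape : {'line', 'circle', 'fold_curve', 'koch', 'quadric_koch'}
    roughness : float >= 0 (fold_curve only)
        Scales the midpoint-displacement perturbation of the smooth
        baseline; 0 gives a rectifiable contour.
    iterations : int (fractal generators only)
    canvas : (width, height) pixels, each >= 256
    """

    base_shape: str
    roughness: float = 0.0
    iterations: int = 4
    canvas: tuple[int, int] = (1024, 1024)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.base_shape not in {"line", "circle", "fold_curve", "koch", "quadric_koch"}:
            raise ValueError(f"unknown base_shape {self.base_shape!r}")
        if self.canvas[0] < 256 or self.canvas[1] < 256:
            raise ValueError("canvas must be at least 256x256")
        if self.roughness < 0:
            raise ValueError("roughness must be >= 0")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


def _rasterize_polyline(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Draw an 8-connected polyline through integer (row, col) points."""
    mask = np.zeros(shape, dtype=bool)
    pts = np.rint(points).astype(int)
    pts[:, 0] = np.clip(pts[:, 0], 0, shape[0] - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, shape[1] - 1)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = skdraw.line(r0, c0, r1, c1)
        mask[rr, cc] = True
    return mask


def _lsystem(axiom: str, rule: str, iterations: int) -> str:
    s = axiom
    for _ in range(iterations):
        s = "".join(rule if ch == "F" else ch for ch in s)
    return s


def _turtle_points(program: str, turn_deg: float) -> np.ndarray:
    ang = 0.0
    x = y = 0.0
    pts = [(0.0, 0.0)]
    for ch in program:
        if ch == "F":
            x += math.cos(math.radians(ang))
            y += math.sin(math.radians(ang))
            pts.append((x, y))
        elif ch == "+":
            ang += turn_deg
        elif ch == "-":
            ang -= turn_deg
    return np.asarray(pts)


def _fit_points_to_canvas(pts: np.ndarray, canvas: tuple[int, int], margin: int = 8) -> np.ndarray:
    """Uniformly scale/centre (x, y) turtle points into (row, col) space."""
    w, h = canvas
    span = pts.max(axis=0) - pts.min(axis=0)
    span[span == 0] = 1.0
    scale = min((w - 2 * margin) / span[0], (h - 2 * margin) / span[1])
    xy = (pts - pts.min(axis=0)) * scale
    offx = (w - xy[:, 0].max()) / 2
    offy = (h - xy[:, 1].max()) / 2
    rows = (h - 1) - (xy[:, 1] + offy)  # image rows grow downward
    cols = xy[:, 0] + offx
    return np.column_stack([rows, cols]), scale


def _midpoint_displacement(n_levels: int, sigma0: float, hurst: float, rng) -> np.ndarray:
    """Fractional-Brownian-style profile on 2**n_levels + 1 points."""
    y = np.zeros(2)
    for level in range(n_levels):
        mids = (y[:-1] + y[1:]) / 2
        if sigma0 > 0:
            mids = mids + rng.normal(0.0, sigma0 * 2.0 ** (-(level + 1) * hurst), mids.size)
        out = np.empty(y.size + mids.size)
        out[0::2], out[1::2] = y, mids
        y = out
    return y


def generate_outline(spec: OutlineSpec) -> MucosalOutline:
    """Rasterize the requested curve as a one-pixel 8-connected outline.

    Raises
    ------
    ValueError
        If the fractal iteration depth drives the smallest segment
        below one pixel on the requested canvas.
    """
    w, h = spec.canvas
    shape = (h, w)
    rng = np.random.default_rng(spec.rng_seed)

    if spec.base_shape == "line":
        mask = np.zeros(shape, dtype=bool)
        rr, cc = skdraw.line(h // 2, 0, h // 2, w - 1)
        mask[rr, cc] = True
    elif spec.base_shape == "circle":
        r = int(0.42 * min(w, h))
        rr, cc = skdraw.circle_perimeter(h // 2, w // 2, r, method="bresenham", shape=shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
    elif spec.base_shape == "koch":
        if (w - 16) / 3**spec.iterations < 1.0:
            raise ValueError(f"{spec.iterations} Koch iterations too deep for a {w}-px canvas")
        program = _lsystem("F", "F+F--F+F", spec.iterations)
        pts, scale = _fit_points_to_canvas(_turtle_points(program, 60.0), spec.canvas)
        if scale < 1.0:
            raise ValueError("Koch segment shorter than one pixel; reduce iterations")
        mask = _rasterize_polyline(pts, shape)
    elif spec.base_shape == "quadric_koch":
        if (w - 16) / 4**spec.iterations < 1.0:
            raise ValueError(
                f"{spec.iterations} quadric-Koch iterations too deep for a {w}-px canvas"
            )
        program = _lsystem("F", "F+F-F-FF+F+F-F", spec.iterations)
        pts, scale = _fit_points_to_canvas(_turtle_points(program, 90.0), spec.canvas)
        if scale < 1.0:
            raise ValueError("quadric-Koch segment shorter than one pixel; reduce iterations")
        mask = _rasterize_polyline(pts, shape)
    else:  # fold_curve
        n_levels = 8  # 257 control points across the width
        baseline_amp = 0.06 * h
        t = np.linspace(0.0, 1.0, 2**n_levels + 1)
        baseline = h / 2 + baseline_amp * np.sin(2 * np.pi * 1.5 * t)
        pert = _midpoint_displacement(n_levels, sigma0=spec.roughness * 0.35 * h, hurst=0.55, rng=rng)
        ys = np.clip(baseline + pert, 2, h - 3)
        xs = t * (w - 1)
        mask = _rasterize_polyline(np.column_stack([ys, xs]), shape)

    if not is_one_pixel_wide(mask):
        mask = skmorph.thin(mask)
    n_components = int(skmeasure.label(mask, connectivity=2).max())
    if n_components != 1:
        raise RuntimeError(f"generated outline is not a single curve ({n_components} components)")
    if mask.sum() < 2:
        raise RuntimeError("generated outline shorter than 2 pixels")
    return MucosalOutline(
        raster=mask,
        provenance={
            "base_shape": spec.base_shape,
            "roughness": spec.roughness,
            "iterations": spec.iterations,
            "rng_seed": spec.rng_seed,
        },
    )
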