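"""Raster micrograph container and image/mask file I/O.

A field is one 24-bit RGB photomicrograph of a stained intestinal
section, optionally carrying a pixel-exclusion mask (the lamina-propria
region erased before counting) and study-design metadata (diet group,
intestinal segment, fish/tank id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["RGBField", "load_field", "save_field", "load_mask", "save_mask"]


@dataclass
class RGBField:
    """An RGB micrograph plus optional exclusion mask and metadata.

    Parameters
    ----------
    pixels : uint8 array of shape (H, W, 3)
        The raster.
    exclusion : bool array of shape (H, W), optional
        True where pixels are excluded from all downstream counting
        (e.g. the lamina propria).
    metadata : dict
        Free-form study labels (field_id, diet, segment, tank, fish,
        magnification ...).
    """

    pixels: np.ndarray
    exclusion: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise ValueError("field must be a 24-bit RGB raster (H, W, 3) uint8")
        self.pixels = px
        if self.exclusion is not None:
            m = np.asarray(self.exclusion)
            if m.shape != px.shape[:2]:
                raise ValueError(
                    f"exclusion mask shape {m.shape} does not match field {px.shape[:2]}"
                )
            self.exclusion = m.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.pixels.shape[:2]

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0] * self.pixels.shape[1]


def load_field(path: str | Path, **metadata) -> RGBField:
    """Read a TIFF/PNG/JPEG micrograph from disk as an :class:`RGBField`."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 2:  # greyscale promoted to RGB
        px = np.stack([px] * 3, axis=-1)
    if px.shape[-1] == 4:  # drop alpha
        px = px[..., :3]
    return RGBField(px.astype(np.uint8), metadata=dict(metadata, source=str(path)))


def save_field(field_: RGBField, path: str | Path) -> None:
    """Write a field as 24-bit TIFF (or PNG/JPEG by extension)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, field_.pixels, photometric="rgb")
    else:
        iio.imwrite(path, field_.pixels)


def load_mask(path: str | Path) -> np.ndarray:
    """Read an exclusion mask: single-channel image, 0 = keep, nonzero = exclude."""
    m = np.asarray(iio.imread(path))
    if m.ndim == 3:
        m = m[..., 0]
    return m > 0


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean exclusion mask as 8-bit PNG/GIF (0 = keep, 255 = exclude)."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))
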