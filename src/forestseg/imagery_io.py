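"""Reading, assembling, cutting, and persisting 4-band aerial imagery.

The imagery model is an 8-bit H×W×4 raster in fixed (R, G, B, NIR) band
order, assembled from a natural-color RGB product and a color-infrared
(CIR) product that share the red and green bands.  Only the NIR band is
taken from the CIR raster (by convention its first band).  Large source
extents are cut into square working regions; label masks are rendered in
the fixed two-color convention (forest green on black) when exported as
TIFF.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import tifffile

BAND_ORDER: Tuple[str, str, str, str] = ("R", "G", "B", "NIR")

#: RGB rendering of a binary forest mask: forest / non-forest.
FOREST_COLOR: Tuple[int, int, int] = (34, 139, 34)
BACKGROUND_COLOR: Tuple[int, int, int] = (0, 0, 0)


class DimensionError(ValueError):
    """Raised when raster shapes are incompatible."""


class FormatError(ValueError):
    """Raised when a raster has the wrong band count or dtype."""


@dataclass
class MultiBandImage:
    """An H×W×4 unsigned 8-bit raster in (R, G, B, NIR) band order."""

    pixels: np.ndarray
    resolution_m: Optional[float] = None
    band_order: Tuple[str, str, str, str] = BAND_ORDER

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 4:
            raise FormatError(f"expected H×W×4 raster, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise DimensionError("raster must have H ≥ 1 and W ≥ 1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise FormatError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def flat_pixels(self) -> np.ndarray:
        """Return an N×4 float view of the raster for statistical fitting."""
        return self.pixels.reshape(-1, 4).astype(np.float64)


@dataclass
class RegionSet:
    """Ordered square regions cut from a larger raster, row-major."""

    regions: List[MultiBandImage]
    source_id: str
    region_size: int
    offsets: List[Tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)


def assemble_rgbn(rgb: np.ndarray, cir: np.ndarray, nir_band: int = 0) -> MultiBandImage:
    """Stack an RGB raster with the NIR band of a CIR raster into RGBN.

    Both inputs must be H×W×3 8-bit rasters of identical extent.  The CIR
    product is a (NIR, R, G) false-color composite, so its first band is
    near-infrared by default; ``nir_band`` selects another band for CIR
    dialects that order bands differently.
    """
    rgb = np.asarray(rgb)
    cir = np.asarray(cir)
    for name, arr in (("rgb", rgb), ("cir", cir)):
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise FormatError(f"{name} must be a 3-band raster, got shape {arr.shape}")
    if rgb.shape[:2] != cir.shape[:2]:
        raise DimensionError(
            f"rgb extent {rgb.shape[:2]} does not match cir extent {cir.shape[:2]}"
        )
    if not 0 <= nir_band < 3:
        raise FormatError(f"nir_band must be in [0, 3), got {nir_band}")
    rgbn = np.concatenate([rgb, cir[:, :, nir_band : nir_band + 1]], axis=2)
    return MultiBandImage(rgbn)


def cut_regions(
    image: MultiBandImage, region_size: int, source_id: str = ""
) -> RegionSet:
    """Cut an image into non-overlapping square regions, row-major.

    Trailing rows/columns that do not fill a whole region are discarded,
    mirroring the convention used for tiling.  Regions are views into the
    source raster (no copy).
    """
    if region_size < 1:
        raise ValueError("region_size must be ≥ 1")
    h, w = image.height, image.width
    n_rows, n_cols = h // region_size, w // region_size
    if n_rows == 0 or n_cols == 0:
        raise DimensionError(
            f"region_size {region_size} exceeds image extent {h}×{w}"
        )
    regions: List[MultiBandImage] = []
    offsets: List[Tuple[int, int]] = []
    for i in range(n_rows):
        for j in range(n_cols):
            r0, c0 = i * region_size, j * region_size
            sub = image.pixels[r0 : r0 + region_size, c0 : c0 + region_size]
            regions.append(MultiBandImage(sub, resolution_m=image.resolution_m))
            offsets.append((r0, c0))
    return RegionSet(regions=regions, source_id=source_id,
                     region_size=region_size, offsets=offsets)


def count_regions(height: int, width: int, region_size: int) -> int:
    """Number of whole square regions a H×W extent yields (remainder discarded)."""
    if region_size < 1:
        raise ValueError("region_size must be ≥ 1")
    return (height // region_size) * (width // region_size)


def save_array(path: str, array: np.ndarray) -> None:
    """Persist a raster losslessly; format chosen by extension (.npy / .tif)."""
    ext = os.path.splitext(path)[1].lower()
    arr = array.pixels if isinstance(array, MultiBandImage) else np.asarray(array)
    if ext == ".npy":
        np.save(path, arr)
    elif ext in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        raise IOError(f"unsupported raster extension for {path!r}")


def load_array(path: str) -> np.ndarray:
    """Load a raster previously written by :func:`save_array`."""
    if not os.path.exists(path):
        raise IOError(f"no such raster file: {path!r}")
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext == ".npy":
            return np.load(path)
        if ext in (".tif", ".tiff"):
            return tifffile.imread(path)
    except Exception as exc:  # corrupt header etc.
        raise IOError(f"failed to read raster {path!r}: {exc}") from exc
    raise IOError(f"unsupported raster extension for {path!r}")


def load_image(path: str) -> MultiBandImage:
    """Load an RGBN raster from NPY/TIFF as a :class:`MultiBandImage`."""
    return MultiBandImage(load_array(path))


def render_mask(mask: np.ndarray) -> np.ndarray:
    """Render a binary forest mask as a 3-band RGB array (forest green / black)."""
    mask = np.asarray(mask)
    out = np.zeros(mask.shape + (3,), dtype=np.uint8)
    out[mask.astype(bool)] = FOREST_COLOR
    return out


def save_mask_tiff(path: str, mask: np.ndarray) -> None:
    """Export a binary mask as a 3-band TIFF in the fixed color convention."""
    tifffile.imwrite(path, render_mask(mask))
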