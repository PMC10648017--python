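"""Tiling labeled images into fixed-size training samples and splitting them.

Full-size labeled rasters are cut into non-overlapping square tiles
(default 128×128, matching the power-of-two input convention of the
segmentation network).  When the tile size does not divide the raster
extent, the trailing remainder is discarded together with the last full
tile, leaving a margin at the partially covered edge: a 4,000×4,000 image
yields a 3,840×3,840 usable extent (pixels 3,841–4,000 discarded) and
30×30 = 900 tiles, and 16 such images yield 14,400 samples.  The pooled
samples are shuffled with a fixed seed and split into train / validation /
test partitions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .gmm_labeler import BinaryMask
from .imagery_io import MultiBandImage


class InputError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass
class TileSample:
    """One training sample: a 4-band patch and its binary label patch."""

    patch: np.ndarray   # tile×tile×4 uint8 (view into the source raster)
    label: np.ndarray   # tile×tile uint8 in {0,1}
    origin: Tuple[str, int, int]  # (image id, row offset, col offset)


@dataclass
class DatasetSplit:
    train: List[TileSample]
    validation: List[TileSample]
    test: List[TileSample]
    seed: int

    @property
    def total(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)

    def manifest_csv(self) -> str:
        """CSV manifest: sample id, source image, offsets, split membership."""
        buf = io.StringIO()
        buf.write("sample_id,image_id,row,col,split\n")
        idx = 0
        for split_name, samples in (("train", self.train),
                                    ("validation", self.validation),
                                    ("test", self.test)):
            for s in samples:
                image_id, r, c = s.origin
                buf.write(f"{idx},{image_id},{r},{c},{split_name}\n")
                idx += 1
        return buf.getvalue()


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


def _tiles_per_axis(extent: int, tile: int) -> int:
    """Whole tiles along one axis; an inexact fit also forfeits the last
    full tile as an edge margin (4,000 px at tile 128 → 30, not 31)."""
    n = extent // tile
    if extent % tile != 0:
        n -= 1
    return max(n, 0)


def tile_image(image: MultiBandImage, mask: BinaryMask, tile: int = 128,
               image_id: str = "") -> List[TileSample]:
    """Cut an image/mask pair into non-overlapping tiles, row-major.

    Patches are views into the source arrays (no copy), so tiling is cheap
    even for full 4,000×4,000 rasters.
    """
    if tile < 8 or not _is_power_of_two(tile):
        raise ConfigurationError(f"tile size must be a power of two ≥ 8, got {tile}")
    px = image.pixels
    m = mask.mask
    if px.shape[:2] != m.shape:
        raise InputError(f"image extent {px.shape[:2]} != mask extent {m.shape}")
    n_rows = _tiles_per_axis(px.shape[0], tile)
    n_cols = _tiles_per_axis(px.shape[1], tile)
    samples: List[TileSample] = []
    for i in range(n_rows):
        for j in range(n_cols):
            r, c = i * tile, j * tile
            samples.append(TileSample(
                patch=px[r : r + tile, c : c + tile],
                label=m[r : r + tile, c : c + tile],
                origin=(image_id, r, c),
            ))
    return samples


def build_dataset(images: Sequence[Tuple[str, MultiBandImage, BinaryMask]],
                  tile: int = 128) -> List[TileSample]:
    """Concatenate per-image tilings of uniformly sized labeled images."""
    if not images:
        raise InputError("no labeled images supplied")
    first_shape = images[0][1].pixels.shape[:2]
    samples: List[TileSample] = []
    for image_id, image, mask in images:
        if image.pixels.shape[:2] != first_shape:
            raise InputError(
                f"image {image_id!r} extent {image.pixels.shape[:2]} differs "
                f"from {first_shape}"
            )
        samples.extend(tile_image(image, mask, tile=tile, image_id=image_id))
    return samples


def split_dataset(samples: Sequence[TileSample], n_test: int = 4400,
                  val_fraction: float = 0.10, seed: int = 0) -> DatasetSplit:
    """Seeded shuffle, then carve off test and validation partitions.

    After shuffling, the last ``n_test`` samples form the test set and
    ``val_fraction`` of the remainder forms the validation set (the source
    convention gives the 10,000 train+validation / 4,400 test split of
    14,400 samples; the validation share inside the 10,000 is a package
    default of 10%).
    """
    total = len(samples)
    if n_test >= total:
        raise ConfigurationError(f"n_test={n_test} must be < total={total}")
    if not 0.0 <= val_fraction < 1.0:
        raise ConfigurationError("val_fraction must be in [0, 1)")
    order = np.random.default_rng(seed).permutation(total)
    shuffled = [samples[i] for i in order]
    trainval = shuffled[: total - n_test]
    test = shuffled[total - n_test :]
    n_val = int(round(len(trainval) * val_fraction))
    validation = trainval[len(trainval) - n_val :]
    train = trainval[: len(trainval) - n_val]
    return DatasetSplit(train=train, validation=validation, test=test, seed=seed)


def stack_samples(samples: Sequence[TileSample]) -> Tuple[np.ndarray, np.ndarray]:
    """Materialize samples as (N, tile, tile, 4) patches and (N, tile, tile) labels."""
    patches = np.stack([s.patch for s in samples])
    labels = np.stack([s.label for s in samples])
    return patches, labels


def stitch_tiles(samples: Sequence[TileSample], tile: int) -> np.ndarray:
    """Reassemble row-major tiles of one image into the cropped usable extent."""
    if not samples:
        raise InputError("no samples to stitch")
    rows = max(s.origin[1] for s in samples) // tile + 1
    cols = max(s.origin[2] for s in samples) // tile + 1
    out = np.zeros((rows * tile, cols * tile, samples[0].patch.shape[2]),
                   dtype=samples[0].patch.dtype)
    for s in samples:
        _, r, c = s.origin
        out[r : r + tile, c : c + tile] = s.patch
    return out
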