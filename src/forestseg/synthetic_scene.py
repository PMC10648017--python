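"""Synthetic 4-band aerial scenes with known forest ground truth.

Real source imagery for this workflow is proprietary, so the package ships
a generator that reproduces the statistical structure the labeling
pipeline relies on: contiguous land-cover patches, per-class 4-band
Gaussian pixel distributions, forest split into a bright-NIR lit canopy
and a dark shadow subpopulation, and occasional small withered-tree holes
inside forest areas.

The spatial layout is a seeded smoothed-noise field thresholded at the
class-proportion quantiles, which yields blobby contiguous regions similar
to real land-cover patches.  Pixel values are drawn from each class's
multivariate Gaussian and clipped to the 8-bit range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy import ndimage

from .imagery_io import MultiBandImage


class SceneSpecError(ValueError):
    """Raised for invalid scene specifications."""


@dataclass
class ClassSpec:
    """One land-cover class: a 4-band Gaussian, optionally a mixture.

    ``subpopulations`` (mean, covariance, weight) overrides the top-level
    Gaussian with a within-class mixture; forest uses this to model lit
    canopy and cast shadow.
    """

    name: str
    mean: Sequence[float]
    covariance: np.ndarray
    is_forest: bool = False
    proportion: float = 0.0
    subpopulations: Optional[List[Tuple[np.ndarray, np.ndarray, float]]] = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.covariance = np.asarray(self.covariance, dtype=np.float64)
        if self.mean.shape != (4,):
            raise SceneSpecError(f"class {self.name}: mean must be a 4-vector")
        if np.any(self.mean < 0) or np.any(self.mean > 255):
            raise SceneSpecError(f"class {self.name}: mean outside [0, 255]")
        _check_spd(self.covariance, self.name)
        if self.subpopulations is not None:
            subs = []
            for m, c, w in self.subpopulations:
                m = np.asarray(m, dtype=np.float64)
                c = np.asarray(c, dtype=np.float64)
                _check_spd(c, f"{self.name} subpopulation")
                subs.append((m, c, float(w)))
            total = sum(w for _, _, w in subs)
            if not np.isclose(total, 1.0):
                raise SceneSpecError(
                    f"class {self.name}: subpopulation weights sum to {total}, not 1"
                )
            self.subpopulations = subs


def _check_spd(cov: np.ndarray, name: str) -> None:
    cov = np.asarray(cov, dtype=np.float64)
    if cov.shape != (4, 4) or not np.allclose(cov, cov.T):
        raise SceneSpecError(f"{name}: covariance must be symmetric 4×4")
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise SceneSpecError(f"{name}: covariance not positive-definite") from exc


@dataclass
class GroundTruth:
    """Pixel-level truth for a generated scene."""

    mask: np.ndarray        # H×W uint8, 1 = forest
    class_map: np.ndarray   # H×W int class ids (index into SceneSpec.classes)


@dataclass
class SceneSpec:
    """Full description of a synthetic scene."""

    size: int
    classes: List[ClassSpec]
    forest_shadow_fraction: float = 0.35
    hole_rate: float = 0.2          # expected holes per 1,000 forest pixels
    noise_sd: float = 0.0           # extra additive per-band noise
    seed: int = 0
    layout_smoothness: float = 8.0  # Gaussian-filter sigma of the layout field

    def __post_init__(self) -> None:
        if self.size < 32:
            raise SceneSpecError("scene size must be ≥ 32")
        if len(self.classes) < 2:
            raise SceneSpecError("need ≥ 2 classes")
        n_forest = sum(c.is_forest for c in self.classes)
        if n_forest != 1:
            raise SceneSpecError(f"exactly one class must be forest, got {n_forest}")
        if not 0.0 <= self.forest_shadow_fraction <= 1.0:
            raise SceneSpecError("forest_shadow_fraction must be in [0, 1]")

    @property
    def forest_id(self) -> int:
        return next(i for i, c in enumerate(self.classes) if c.is_forest)

    def to_yaml(self) -> str:
        doc = {
            "size": self.size,
            "forest_shadow_fraction": self.forest_shadow_fraction,
            "hole_rate": self.hole_rate,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "layout_smoothness": self.layout_smoothness,
            "classes": [
                {
                    "name": c.name,
                    "mean": np.asarray(c.mean).tolist(),
                    "covariance": np.asarray(c.covariance).tolist(),
                    "is_forest": bool(c.is_forest),
                    "proportion": float(c.proportion),
                    "subpopulations": None
                    if c.subpopulations is None
                    else [
                        {"mean": m.tolist(), "covariance": cv.tolist(), "weight": w}
                        for m, cv, w in c.subpopulations
                    ],
                }
                for c in self.classes
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SceneSpec":
        doc = yaml.safe_load(text)
        classes = []
        for c in doc["classes"]:
            subs = c.get("subpopulations")
            classes.append(
                ClassSpec(
                    name=c["name"],
                    mean=c["mean"],
                    covariance=np.asarray(c["covariance"]),
                    is_forest=c.get("is_forest", False),
                    proportion=c.get("proportion", 0.0),
                    subpopulations=None
                    if subs is None
                    else [
                        (np.asarray(s["mean"]), np.asarray(s["covariance"]), s["weight"])
                        for s in subs
                    ],
                )
            )
        return cls(
            size=doc["size"],
            classes=classes,
            forest_shadow_fraction=doc.get("forest_shadow_fraction", 0.35),
            hole_rate=doc.get("hole_rate", 0.2),
            noise_sd=doc.get("noise_sd", 0.0),
            seed=doc.get("seed", 0),
            layout_smoothness=doc.get("layout_smoothness", 8.0),
        )


def _diag(*sds: float) -> np.ndarray:
    return np.diag(np.square(np.asarray(sds, dtype=np.float64)))


def default_spec(size: int, seed: int = 0, noise_sd: float = 0.0,
                 forest_shadow_fraction: float = 0.35,
                 hole_rate: float = 0.2) -> SceneSpec:
    """Default five-class scene: forest, orchard, crops, bare land, settlement.

    The numeric class statistics are package-defined and stylized rather
    than radiometrically calibrated: they are placed so the pixel
    distribution has four roughly equidistant effective modes — lit forest
    canopy (the brightest NIR surface of any class), dark forest shadow,
    a vegetation mode shared by crops and orchard, and a built/bare mode
    shared by bare land and settlement.  That is the cluster structure the
    labeling workflow is designed around: a 4-component mixture resolves
    the scene into two forest clusters plus two non-forest clusters.
    """
    lit_mean = np.array([55.0, 75.0, 45.0, 175.0])
    lit_cov = _diag(9, 9, 9, 9)
    shadow_mean = np.array([15.0, 28.0, 12.0, 78.0])
    shadow_cov = _diag(9, 9, 9, 9)
    forest = ClassSpec(
        name="forest",
        mean=lit_mean,
        covariance=lit_cov,
        is_forest=True,
        proportion=0.40,
        subpopulations=[
            (lit_mean, lit_cov, 1.0 - forest_shadow_fraction),
            (shadow_mean, shadow_cov, forest_shadow_fraction),
        ],
    )
    # crops and orchard sit a few levels apart around the vegetation mode;
    # bare land and settlement likewise around the built mode
    crops = ClassSpec("crops", [60.0, 138.0, 32.0, 76.0], _diag(9, 9, 9, 9),
                      proportion=0.17)
    orchard = ClassSpec("orchard", [47.0, 150.0, 21.0, 88.0], _diag(9, 9, 9, 9),
                        proportion=0.17)
    bare = ClassSpec("bare_land", [121.0, 66.0, 75.0, 73.0], _diag(9, 9, 9, 9),
                     proportion=0.14)
    settlement = ClassSpec("settlement", [106.0, 55.0, 88.0, 82.0],
                           _diag(9, 9, 9, 9), proportion=0.12)
    return SceneSpec(
        size=size,
        classes=[forest, crops, orchard, bare, settlement],
        forest_shadow_fraction=forest_shadow_fraction,
        hole_rate=hole_rate,
        noise_sd=noise_sd,
        seed=seed,
    )


def two_class_spec(size: int, seed: int = 0, noise_sd: float = 0.0) -> SceneSpec:
    """Forest-vs-bare-land scene with no shadow and no holes.

    The two class means are ~120 digital levels apart against a spread of
    9, so a 2-component Gaussian mixture must separate them almost
    perfectly; the downstream tests use this as their oracle scene.
    """
    forest = ClassSpec("forest", [55.0, 75.0, 45.0, 175.0], _diag(9, 9, 9, 9),
                       is_forest=True, proportion=0.5)
    bare = ClassSpec("bare_land", [121.0, 66.0, 75.0, 73.0], _diag(9, 9, 9, 9),
                     proportion=0.5)
    return SceneSpec(size=size, classes=[forest, bare],
                     forest_shadow_fraction=0.0, hole_rate=0.0,
                     noise_sd=noise_sd, seed=seed)


def four_class_spec(size: int, seed: int = 0, noise_sd: float = 0.0) -> SceneSpec:
    """Four equidistant well-separated classes, no forest subpopulations.

    The means form a regular simplex (pairwise distance ≈120 levels) on
    the NIR/G/R/B axes, so the pixel distribution has exactly four equally
    separated Gaussian modes; used to probe cluster-count selection.
    """
    forest = ClassSpec("forest", [68.75, 68.75, 53.75, 168.75], _diag(9, 9, 9, 9),
                       is_forest=True, proportion=0.25)
    crops = ClassSpec("crops", [68.75, 153.75, 53.75, 83.75], _diag(9, 9, 9, 9),
                      proportion=0.25)
    bare = ClassSpec("bare_land", [153.75, 68.75, 53.75, 83.75], _diag(9, 9, 9, 9),
                     proportion=0.25)
    settlement = ClassSpec("settlement", [68.75, 68.75, 138.75, 83.75],
                           _diag(9, 9, 9, 9), proportion=0.25)
    return SceneSpec(size=size, classes=[forest, crops, bare, settlement],
                     forest_shadow_fraction=0.0, hole_rate=0.0,
                     noise_sd=noise_sd, seed=seed)


def _layout(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Blobby class layout: smoothed noise thresholded at proportion quantiles."""
    n = spec.size
    props = np.array([max(c.proportion, 0.0) for c in spec.classes], dtype=np.float64)
    if props.sum() <= 0:
        props = np.ones(len(spec.classes))
    props = props / props.sum()
    field_ = ndimage.gaussian_filter(rng.standard_normal((n, n)),
                                     sigma=spec.layout_smoothness, mode="wrap")
    # Shuffle which class occupies which layout band so class adjacency
    # varies across seeds; each band's width is that class's proportion.
    perm = rng.permutation(len(spec.classes))
    # Rank-transform so quantile cuts hit the proportions exactly.
    order = np.argsort(field_, axis=None)
    ranks = np.empty(n * n, dtype=np.int64)
    ranks[order] = np.arange(n * n)
    cuts = np.floor(np.cumsum(props[perm])[:-1] * n * n).astype(np.int64)
    band_map = np.searchsorted(cuts, ranks, side="right").reshape(n, n)
    return perm[band_map]


def _punch_holes(spec: SceneSpec, class_map: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Reassign small disks inside forest to bare ground (withered trees)."""
    if spec.hole_rate <= 0:
        return class_map
    fid = spec.forest_id
    non_forest = [i for i in range(len(spec.classes)) if i != fid]
    # prefer a bare-land-like class for hole interiors
    target = next((i for i in non_forest
                   if "bare" in spec.classes[i].name), non_forest[0])
    forest_px = np.argwhere(class_map == fid)
    if len(forest_px) == 0:
        return class_map
    n_holes = rng.poisson(spec.hole_rate * len(forest_px) / 1000.0)
    if n_holes == 0:
        return class_map
    out = class_map.copy()
    h, w = class_map.shape
    yy, xx = np.mgrid[0:h, 0:w]
    centers = forest_px[rng.integers(0, len(forest_px), size=n_holes)]
    for (cy, cx) in centers:
        r = rng.integers(1, 4)  # disk radius 1–3 px
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        out[disk & (class_map == fid)] = target
    return out


def generate_scene(spec: SceneSpec) -> Tuple[MultiBandImage, GroundTruth]:
    """Draw a seeded scene and its ground truth from a :class:`SceneSpec`.

    The same spec (including seed) always yields bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    class_map = _layout(spec, rng)
    class_map = _punch_holes(spec, class_map, rng)
    n = spec.size
    values = np.zeros((n, n, 4), dtype=np.float64)
    for cid, cls in enumerate(spec.classes):
        sel = class_map == cid
        count = int(sel.sum())
        if count == 0:
            continue
        if cls.subpopulations:
            weights = np.array([w for _, _, w in cls.subpopulations])
            choice = rng.choice(len(weights), size=count, p=weights)
            draws = np.zeros((count, 4))
            for si, (m, c, _) in enumerate(cls.subpopulations):
                idx = np.where(choice == si)[0]
                if len(idx):
                    draws[idx] = _draw_gaussian(m, c, len(idx), rng)
        else:
            draws = _draw_gaussian(cls.mean, cls.covariance, count, rng)
        values[sel] = draws
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=values.shape)
    pixels = np.clip(np.rint(values), 0, 255).astype(np.uint8)
    mask = (class_map == spec.forest_id).astype(np.uint8)
    return MultiBandImage(pixels), GroundTruth(mask=mask, class_map=class_map)


def _draw_gaussian(mean: np.ndarray, cov: np.ndarray, count: int,
                   rng: np.random.Generator) -> np.ndarray:
    chol = np.linalg.cholesky(np.asarray(cov, dtype=np.float64))
    z = rng.standard_normal((count, 4))
    return np.asarray(mean) + z @ chol.T
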