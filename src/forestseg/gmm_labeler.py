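"""Automatic forest/no-forest pixel labeling via Gaussian-mixture clustering.

The labeling pipeline fits Gaussian mixtures with 2–10 components to the
4-band pixel distribution of an image, picks the component count by the
elbow of the AIC/BIC curve, predicts a cluster map for every image,
merges the clusters that describe forest (bright-NIR lit canopy plus the
dark shadow cluster generated by tree-height relief) into a single forest
class, cleans the resulting binary mask with a median filter and a
morphological closing, and ranks the labeled images by the Davies–Bouldin
cluster-validity index so only the most reliably clustered images become
training labels.

Information criteria, with ``k`` free parameters, ``N`` pixels and mixture
log-likelihood ``ln L``::

    AIC = 2k − 2 ln L
    BIC = k ln N − 2 ln L

Davies–Bouldin index over clusters with centers ``c_i`` and mean
within-cluster distances ``σ_i``::

    DB = (1/N) Σ_i max_{j≠i} (σ_i + σ_j) / d(c_i, c_j)

lower is better; for two clusters this reduces to (σ0+σ1)/d(c0,c1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage
from scipy.special import logsumexp
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .imagery_io import MultiBandImage

RIDGE = 1e-6  # covariance-diagonal regularization used by every fit

#: default pixel budget for mixture fitting; larger images are subsampled
MAX_FIT_PIXELS = 2_000_000


class InputError(ValueError):
    pass


class SelectionError(ValueError):
    pass


class RuleError(ValueError):
    pass


class ValidityError(ValueError):
    """A mask whose cluster structure cannot be scored (e.g. one class empty)."""


@dataclass
class GmmModel:
    """A fitted K-component 4-dimensional Gaussian mixture."""

    K: int
    weights: np.ndarray
    means: np.ndarray         # K×4
    covariances: np.ndarray   # K×4×4 (full) or K×4 (diagonal)
    covariance_type: str
    seed: int
    converged: bool
    log_likelihood_trajectory: List[float] = field(default_factory=list)
    regularized: bool = False

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights < 0):
            raise ValueError("mixture weights must be non-negative")

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def full_covariances(self) -> np.ndarray:
        """Covariances as K×d×d regardless of storage convention."""
        if self.covariance_type == "diagonal":
            return np.stack([np.diag(c) for c in self.covariances])
        return self.covariances

    def component_log_densities(self, x: np.ndarray) -> np.ndarray:
        """N×K matrix of per-component Gaussian log densities."""
        x = np.asarray(x, dtype=np.float64)
        n, d = x.shape
        out = np.empty((n, self.K))
        for k, (mu, cov) in enumerate(zip(self.means, self.full_covariances())):
            chol = np.linalg.cholesky(cov)
            diff = x - mu
            sol = np.linalg.solve(chol, diff.T)
            maha = np.sum(sol**2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            out[:, k] = -0.5 * (d * np.log(2 * np.pi) + logdet + maha)
        return out

    def log_likelihood(self, x: np.ndarray) -> float:
        """Total mixture log-likelihood Σ_n log Σ_k w_k N(x_n | μ_k, Σ_k)."""
        log_dens = self.component_log_densities(x)
        return float(np.sum(logsumexp(log_dens + np.log(self.weights), axis=1)))

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        """N×K posterior component probabilities."""
        logp = self.component_log_densities(x) + np.log(self.weights)
        logp -= logsumexp(logp, axis=1, keepdims=True)
        return np.exp(logp)


@dataclass
class CriterionScan:
    """AIC/BIC scan over candidate component counts."""

    rows: List[Tuple[int, float, int, float, float]]  # (K, logL, k, AIC, BIC)
    models: List[GmmModel] = field(default_factory=list)

    def criterion_values(self, criterion: str) -> Tuple[np.ndarray, np.ndarray]:
        ks = np.array([r[0] for r in self.rows])
        col = {"AIC": 3, "BIC": 4}[criterion.upper()]
        return ks, np.array([r[col] for r in self.rows])

    def model_for(self, K: int) -> GmmModel:
        for row, model in zip(self.rows, self.models):
            if row[0] == K:
                return model
        raise SelectionError(f"no fitted model for K={K}")

    def to_csv(self) -> str:
        lines = ["K,logL,k,AIC,BIC"]
        for K, logL, k, aic, bic in self.rows:
            lines.append(f"{K},{logL:.6f},{k},{aic:.6f},{bic:.6f}")
        return "\n".join(lines) + "\n"


@dataclass
class ClusterMap:
    labels: np.ndarray  # H×W int
    K: int

    def __post_init__(self) -> None:
        if self.labels.min() < 0 or self.labels.max() >= self.K:
            raise ValueError("cluster labels out of range")


@dataclass
class MergeRule:
    forest_components: Set[int]
    rationale: str = "auto"

    def __post_init__(self) -> None:
        if not self.forest_components:
            raise RuleError("forest component set must be non-empty")


@dataclass
class BinaryMask:
    mask: np.ndarray  # H×W uint8 in {0,1}

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        vals = np.unique(m)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask values must be 0/1")
        self.mask = m.astype(np.uint8)


@dataclass
class DbRanking:
    entries: List[Tuple[str, float]]           # ascending by index
    selected: List[str] = field(default_factory=list)
    excluded: List[Tuple[str, str]] = field(default_factory=list)

    def to_csv(self) -> str:
        chosen = set(self.selected)
        lines = ["image_id,db_index,selected"]
        for image_id, db in self.entries:
            lines.append(f"{image_id},{db:.6f},{int(image_id in chosen)}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# fitting


def _as_pixels(data) -> np.ndarray:
    if isinstance(data, MultiBandImage):
        return data.flat_pixels()
    x = np.asarray(data, dtype=np.float64)
    if x.ndim == 3:
        x = x.reshape(-1, x.shape[-1])
    if x.ndim != 2:
        raise InputError(f"expected N×d sample matrix, got shape {x.shape}")
    return x


def subsample_pixels(pixels: np.ndarray, limit: int, seed: int) -> np.ndarray:
    """Seeded subsample used to keep mixture fitting tractable on large rasters."""
    if len(pixels) <= limit:
        return pixels
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pixels), size=limit, replace=False)
    return pixels[idx]


def fit_gmm(
    pixels,
    K: int,
    seed: int = 0,
    covariance_type: str = "full",
    max_iter: int = 200,
    tol: float = 1e-3,
) -> GmmModel:
    """Fit a K-component Gaussian mixture by EM with a seeded k-means++ start.

    EM is stepped one iteration at a time so the full log-likelihood
    trajectory is recorded (it must be non-decreasing); convergence is
    declared when the per-sample log-likelihood improves by less than
    ``tol``.  Covariances carry a fixed diagonal ridge for numerical
    safety; the model records when the ridge was material (any raw
    eigenvalue at or below the ridge).
    """
    x = _as_pixels(pixels)
    n = len(x)
    if K < 1:
        raise InputError("K must be ≥ 1")
    if n < K:
        raise InputError(f"need at least K={K} samples, got {n}")
    if n < 10 * K:
        warnings.warn(f"fewer than 10·K samples (N={n}, K={K}); fit may be unstable")
    sk_cov = {"full": "full", "diagonal": "diag"}[covariance_type]
    gm = GaussianMixture(
        n_components=K,
        covariance_type=sk_cov,
        max_iter=1,
        tol=0.0,
        reg_covar=RIDGE,
        init_params="k-means++",
        random_state=seed,
        warm_start=True,
        n_init=1,
    )
    trajectory: List[float] = []
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        for _ in range(max_iter):
            gm.fit(x)
            ll = float(gm.score(x) * n)
            if trajectory:
                prev = trajectory[-1]
                if (ll - prev) / n < tol:
                    trajectory.append(ll)
                    converged = True
                    break
            trajectory.append(ll)
    if covariance_type == "diagonal":
        covs = gm.covariances_.copy()
        regularized = bool(np.any(covs <= RIDGE * 1.001))
    else:
        covs = gm.covariances_.copy()
        eigs = np.linalg.eigvalsh(covs)
        regularized = bool(np.any(eigs <= RIDGE * 1.001))
    return GmmModel(
        K=K,
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=covs,
        covariance_type=covariance_type,
        seed=seed,
        converged=converged,
        log_likelihood_trajectory=trajectory,
        regularized=regularized,
    )


def n_free_params(K: int, d: int = 4, covariance_type: str = "full") -> int:
    """Free parameters of a K-component d-dimensional Gaussian mixture."""
    if K < 1 or d < 1:
        raise InputError("K and d must be ≥ 1")
    if covariance_type == "full":
        return (K - 1) + K * d + K * d * (d + 1) // 2
    if covariance_type == "diagonal":
        return (K - 1) + K * d + K * d
    raise InputError(f"unknown covariance_type {covariance_type!r}")


def information_criteria(model: GmmModel, pixels) -> Tuple[float, int, float, float]:
    """(logL, k, AIC, BIC) of a fitted mixture on a pixel sample."""
    x = _as_pixels(pixels)
    if len(x) == 0:
        raise InputError("empty pixel set")
    if x.shape[1] != model.dim:
        raise InputError("pixel dimension does not match model")
    logL = model.log_likelihood(x)
    k = n_free_params(model.K, model.dim, model.covariance_type)
    return (logL, k, *aic_bic(logL, k, len(x)))


def aic_bic(logL: float, k: int, N: int) -> Tuple[float, float]:
    """AIC = 2k − 2 ln L and BIC = k ln N − 2 ln L."""
    aic = 2.0 * k - 2.0 * logL
    bic = k * np.log(N) - 2.0 * logL
    return float(aic), float(bic)


def regression_log_likelihood(y: np.ndarray, y_hat: np.ndarray, sigma2: float) -> float:
    """Gaussian regression log-likelihood with known variance.

    ``−(N/2)·log 2π − (N/2)·ln σ² − Σ (y_i − ŷ_i)² / (2σ²)``.  Provided as a
    standalone utility; the clustering criteria use the mixture
    log-likelihood instead, since clustering has no per-pixel targets.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    y_hat = np.asarray(y_hat, dtype=np.float64).ravel()
    if y.shape != y_hat.shape:
        raise InputError("y and y_hat must have the same length")
    n = len(y)
    return float(-n / 2.0 * np.log(2 * np.pi) - n / 2.0 * np.log(sigma2)
                 - np.sum((y - y_hat) ** 2) / (2.0 * sigma2))


def scan_k(
    image,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 0,
    covariance_type: str = "full",
    max_fit_pixels: int = MAX_FIT_PIXELS,
    max_iter: int = 200,
    tol: float = 1e-3,
) -> CriterionScan:
    """Fit one mixture per K in [k_min, k_max] and tabulate AIC/BIC.

    All fits share the same seeded pixel subsample and seed policy so the
    criterion curve varies only through K.
    """
    if k_min < 2 or k_max < k_min:
        raise SelectionError("need 2 ≤ k_min ≤ k_max")
    x = _as_pixels(image)
    x = subsample_pixels(x, max_fit_pixels, seed)
    rows, models = [], []
    for K in range(k_min, k_max + 1):
        try:
            model = fit_gmm(x, K, seed=seed, covariance_type=covariance_type,
                            max_iter=max_iter, tol=tol)
        except Exception as exc:
            raise RuntimeError(f"mixture fit failed at K={K}: {exc}") from exc
        logL, k, aic, bic = information_criteria(model, x)
        rows.append((K, logL, k, aic, bic))
        models.append(model)
    return CriterionScan(rows=rows, models=models)


def select_k_elbow(scan: CriterionScan, criterion: str = "BIC",
                   override: Optional[int] = None) -> int:
    """Pick K at the elbow of the criterion curve.

    The elbow is the interior K where the decrease of the criterion slows
    most sharply, i.e. the K maximizing the second difference
    ``C(K−1) − 2·C(K) + C(K+1)``; ties break toward smaller K.  A manual
    ``override`` bypasses the rule.
    """
    if override is not None:
        return override
    if len(scan.rows) < 3:
        raise SelectionError("elbow selection needs a scan of ≥ 3 component counts")
    ks, values = scan.criterion_values(criterion)
    curvature = values[:-2] - 2.0 * values[1:-1] + values[2:]
    best = int(np.argmax(curvature))  # argmax takes the first (smallest K) on ties
    return int(ks[1 + best])


# ---------------------------------------------------------------------------
# prediction, merging, filtering


def predict_clusters(model: GmmModel, image) -> ClusterMap:
    """Assign every pixel to its maximum-posterior component.

    Ties go to the lowest component index.  Deterministic.
    """
    if isinstance(image, MultiBandImage):
        shape = (image.height, image.width)
        x = image.flat_pixels()
    else:
        arr = np.asarray(image)
        shape = arr.shape[:2]
        x = arr.reshape(-1, arr.shape[-1]).astype(np.float64)
    if x.shape[1] != model.dim:
        raise InputError("image band count does not match model dimension")
    logp = model.component_log_densities(x) + np.log(model.weights)
    labels = np.argmax(logp, axis=1).reshape(shape)
    return ClusterMap(labels=labels, K=model.K)


def auto_merge_rule(model: GmmModel, cmap: ClusterMap,
                    adjacency_threshold: float = 0.10) -> MergeRule:
    """Formalized forest-cluster merging.

    The seed component is the one with the highest NIR mean — lit forest
    canopy.  Any other component is merged into forest when it is both
    spatially interleaved with the seed (its 4-neighbor adjacency score to
    the seed is at least the threshold) and darker than the seed in visible
    luminance — the signature of the cast-shadow cluster.  This automates a
    merge that would otherwise be done by visual inspection; rule outputs
    record that provenance.
    """
    if model.K < 2:
        raise RuleError("merging needs at least two components")
    seed = int(np.argmax(model.means[:, 3]))
    labels = cmap.labels
    if not np.any(labels == seed):
        raise RuleError(f"seed component {seed} is empty in the cluster map")
    counts = np.bincount(labels.ravel(), minlength=model.K)
    seed_lum = model.means[seed, :3].mean()
    # 4-neighborhood pair counts between each component and the seed
    pair_counts = np.zeros(model.K, dtype=np.int64)
    for a, b in (
        (labels[:-1, :], labels[1:, :]),   # vertical neighbor pairs
        (labels[:, :-1], labels[:, 1:]),   # horizontal neighbor pairs
    ):
        for this, other in ((a, b), (b, a)):
            sel = other == seed
            np.add.at(pair_counts, this[sel].ravel(), 1)
    pair_counts[seed] = 0
    merged = {seed}
    for i in range(model.K):
        if i == seed or counts[i] == 0:
            continue
        adjacency = pair_counts[i] / counts[i]
        darker = model.means[i, :3].mean() < seed_lum
        if adjacency >= adjacency_threshold and darker:
            merged.add(i)
    return MergeRule(forest_components=merged, rationale="auto")


def apply_merge(cmap: ClusterMap, rule: MergeRule) -> BinaryMask:
    """Collapse a cluster map to a forest/no-forest mask."""
    comps = sorted(rule.forest_components)
    if any(c < 0 or c >= cmap.K for c in comps):
        raise RuleError(f"components {comps} out of range [0, {cmap.K})")
    if len(comps) == cmap.K:
        warnings.warn("merge rule includes every component; mask is all forest")
    mask = np.isin(cmap.labels, comps).astype(np.uint8)
    return BinaryMask(mask=mask)


def postprocess_mask(mask: BinaryMask, median_size: int = 9,
                     closing_size: int = 9) -> BinaryMask:
    """Median filter then morphological closing of the forest mask.

    Both use square windows (default 9×9; 3 selects the compact 3×3
    reading of a "9-pixel" kernel).  The median uses edge replication; the
    closing is a dilation followed by an erosion with the same structuring
    element, which expands forest and then shrinks it back, filling
    small withered-tree voids.
    """
    for name, size in (("median_size", median_size), ("closing_size", closing_size)):
        if size < 1 or size % 2 == 0:
            raise ValueError(f"{name} must be an odd integer ≥ 1, got {size}")
    m = mask.mask.astype(np.uint8)
    if median_size > 1:
        m = ndimage.median_filter(m, size=median_size, mode="nearest")
    if closing_size > 1:
        structure = np.ones((closing_size, closing_size), dtype=bool)
        dilated = ndimage.binary_dilation(m.astype(bool), structure=structure)
        m = ndimage.binary_erosion(dilated, structure=structure,
                                   border_value=1).astype(np.uint8)
    return BinaryMask(mask=m)


# ---------------------------------------------------------------------------
# cluster-validity ranking


def davies_bouldin(pixels, mask: BinaryMask) -> float:
    """Davies–Bouldin index of the two-class pixel clustering.

    σ_i is the mean Euclidean distance of class-i pixels to the class
    center; the two-cluster index is (σ0+σ1)/d(c0,c1).  Lower is better.
    Scale-invariant and symmetric in the class labels.
    """
    x = _as_pixels(pixels)
    labels = mask.mask.ravel().astype(int)
    if len(labels) != len(x):
        raise InputError("mask size does not match pixel count")
    return _davies_bouldin_labels(x, labels)


def _davies_bouldin_labels(x: np.ndarray, labels: np.ndarray) -> float:
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValidityError("Davies–Bouldin needs both classes non-empty")
    centers, sigmas = [], []
    for cid in ids:
        pts = x[labels == cid]
        c = pts.mean(axis=0)
        centers.append(c)
        sigmas.append(np.mean(np.linalg.norm(pts - c, axis=1)))
    centers = np.asarray(centers)
    n = len(ids)
    total = 0.0
    for i in range(n):
        worst = 0.0
        for j in range(n):
            if i == j:
                continue
            d = np.linalg.norm(centers[i] - centers[j])
            worst = max(worst, (sigmas[i] + sigmas[j]) / d)
        total += worst
    return total / n


def rank_and_select(items: Sequence[Tuple[str, "MultiBandImage | np.ndarray", BinaryMask]],
                    top_n: int = 16) -> DbRanking:
    """Rank labeled images by Davies–Bouldin index and keep the best ``top_n``.

    Items are (image id, image, mask).  Images whose mask has an empty class
    are excluded with a logged reason; the ranking is ascending (lower index
    = tighter, better-separated clustering) with ties broken by image id.
    """
    entries: List[Tuple[str, float]] = []
    excluded: List[Tuple[str, str]] = []
    for image_id, image, mask in items:
        try:
            db = davies_bouldin(image, mask)
        except ValidityError as exc:
            excluded.append((image_id, str(exc)))
            continue
        if not np.isfinite(db):
            excluded.append((image_id, "non-finite index"))
            continue
        entries.append((image_id, db))
    entries.sort(key=lambda e: (e[1], e[0]))
    if len(entries) < top_n:
        raise SelectionError(
            f"only {len(entries)} valid items for top_n={top_n}; "
            f"excluded: {excluded}"
        )
    selected = [image_id for image_id, _ in entries[:top_n]]
    return DbRanking(entries=entries, selected=selected, excluded=excluded)
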