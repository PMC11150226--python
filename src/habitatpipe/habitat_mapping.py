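"""Tumor habitat mapping: voxel entropy, K-means sub-regions, consensus k.

The VOI of each patient is clustered by K-means on two voxel features —
normalized intensity and local Shannon entropy — after per-patient
z-scoring (Euclidean distance would otherwise be dominated by the 0-255
intensity channel).  The number of habitats is a single cohort-level choice
made by Monti consensus clustering on a pooled voxel sample, scanning k from
2 to 10 and applying the relative delta-area elbow rule (PAC is reported as a
diagnostic).  Cluster identities are made comparable across patients by
renumbering habitats in order of increasing centroid intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .imaging_io import CTVolume, Mask

__all__ = [
    "VoxelFeatureMatrix",
    "HabitatMap",
    "ConsensusResult",
    "entropy_map",
    "voxel_features",
    "kmeans_voxels",
    "canonicalize_labels",
    "consensus_select_k",
    "habitat_masks",
    "pool_cohort_voxels",
    "compute_habitat_map",
]


@dataclass
class VoxelFeatureMatrix:
    """Per-voxel features of one patient's VOI.

    ``features`` has one row per in-mask voxel and columns
    (normalized intensity, local entropy); ``coords`` maps rows back to
    ``(z, y, x)`` grid indices.
    """

    features: np.ndarray
    coords: np.ndarray
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.features) != len(self.coords):
            raise ValueError("features and coords row counts differ")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("voxel features contain non-finite values")


@dataclass
class HabitatMap:
    """Canonical habitat labels: 0 outside the VOI, 1..k inside, habitat index
    increasing with centroid intensity."""

    labels: np.ndarray
    k: int
    centroids: np.ndarray  # k x 2, feature space (intensity, entropy)
    ordering: str = "ascending_intensity"

    def voxel_counts(self) -> np.ndarray:
        return np.array([(self.labels == h).sum() for h in range(1, self.k + 1)])


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus_matrices: dict[int, np.ndarray]
    cdf_areas: dict[int, float]
    delta_areas: dict[int, float]
    pac_scores: dict[int, float]
    k_selected: int


def entropy_map(
    volume: CTVolume,
    mask: Mask,
    kernel_radius: int = 1,
    n_bins: int = 32,
) -> np.ndarray:
    """Local Shannon entropy of the intensity histogram in a cubic window.

    For each in-mask voxel, the *in-mask* intensities in the cubic
    neighborhood of edge ``2*kernel_radius + 1`` (clipped at the volume
    boundary) are histogrammed into ``n_bins`` equal-width bins over [0, 255]
    and ``H = -sum p_b log2 p_b`` is returned; voxels outside the mask are 0
    in the output and excluded from every histogram, so background never
    leaks texture into the VOI edge.  Bounded by ``log2(n_bins)``.
    """
    if kernel_radius < 1:
        raise ValueError("kernel_radius must be >= 1")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    data = volume.data
    m = mask.data > 0
    if not m.any():
        raise ValueError("empty mask")

    # work on the VOI bounding box padded by the kernel radius
    r = kernel_radius
    zz, yy, xx = np.where(m)
    lo = [max(0, int(c.min()) - r) for c in (zz, yy, xx)]
    hi = [min(n, int(c.max()) + r + 1) for c, n in zip((zz, yy, xx), data.shape)]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub = data[box]
    msub = m[box].astype(np.float64)

    bins = np.clip((sub / 256.0 * n_bins).astype(np.int64), 0, n_bins - 1)
    kernel = np.ones((2 * r + 1,) * 3)
    total = ndimage.correlate(msub, kernel, mode="constant", cval=0.0)
    total = np.where(total > 0, total, 1.0)
    ent = np.zeros_like(sub)
    for b in range(n_bins):
        ind = (bins == b).astype(np.float64) * msub
        if not ind.any():
            continue
        cnt = ndimage.correlate(ind, kernel, mode="constant", cval=0.0)
        p = cnt / total
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(p > 0, p * np.log2(p), 0.0)
        ent -= term
    ent = np.clip(ent, 0.0, np.log2(n_bins))

    out = np.zeros_like(data)
    out[box] = ent
    out[~m] = 0.0
    return out


def smooth_in_mask(field: np.ndarray, mask: np.ndarray, size: int = 3) -> np.ndarray:
    """Mask-aware box smoothing of a scalar field: each in-mask voxel is
    replaced by the mean of the in-mask voxels in its ``size``³ window.

    Applied to the entropy map before clustering to damp the variance of the
    plug-in entropy estimator (only ~27 samples per window at radius 1)
    without leaking background values across the VOI border.
    """
    m = (np.asarray(mask) > 0).astype(np.float64)
    num = ndimage.uniform_filter(field * m, size=size)
    den = ndimage.uniform_filter(m, size=size)
    out = np.where(m > 0, num / np.maximum(den, 1e-12), 0.0)
    return out


def voxel_features(volume: CTVolume, mask: Mask, entropy: np.ndarray) -> VoxelFeatureMatrix:
    """Assemble the (intensity, entropy) feature matrix for in-mask voxels."""
    coords = np.argwhere(mask.data > 0)
    idx = tuple(coords.T)
    feats = np.column_stack([volume.data[idx], entropy[idx]])
    return VoxelFeatureMatrix(features=feats, coords=coords, shape=volume.shape)


def _zscore(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def kmeans_voxels(
    features: np.ndarray, k: int, seed: int, standardize: bool = True
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Lloyd K-means with k-means++ init on (optionally z-scored) features.

    Returns ``(labels, centroids_in_input_space, info)``.  If the data hold
    fewer distinct rows than ``k``, k is reduced with a warning recorded in
    ``info['provenance']``.
    """
    X = np.asarray(features, dtype=np.float64)
    Xs = _zscore(X) if standardize else X
    n_distinct = len(np.unique(Xs, axis=0))
    info: dict = {"provenance": []}
    k_eff = k
    if n_distinct < k:
        k_eff = max(1, n_distinct)
        msg = f"reduced k from {k} to {k_eff}: only {n_distinct} distinct voxels"
        info["provenance"].append(msg)
        warnings.warn(msg)
    km = KMeans(n_clusters=k_eff, init="k-means++", n_init=5, random_state=seed)
    labels = km.fit_predict(Xs)
    info["inertia"] = float(km.inertia_)
    info["n_iter"] = int(km.n_iter_)
    info["converged"] = bool(km.n_iter_ < km.max_iter)
    # centroids reported in the input feature space
    cent = np.vstack([X[labels == c].mean(axis=0) for c in range(k_eff)])
    return labels, cent, info


def canonicalize_labels(
    labels: np.ndarray, centroids: np.ndarray, coords: np.ndarray, shape
) -> HabitatMap:
    """Renumber clusters so habitat index increases with centroid intensity
    (ties broken by entropy, then by cluster size); emit the label volume."""
    k = len(centroids)
    sizes = np.array([(labels == c).sum() for c in range(k)])
    order = sorted(
        range(k), key=lambda c: (centroids[c, 0], centroids[c, 1], sizes[c], c)
    )
    remap = np.empty(k, dtype=np.int16)
    for new_idx, old_idx in enumerate(order, start=1):
        remap[old_idx] = new_idx
    vol = np.zeros(shape, dtype=np.int16)
    vol[tuple(coords.T)] = remap[labels]
    return HabitatMap(labels=vol, k=k, centroids=centroids[order])


def compute_habitat_map(
    volume: CTVolume,
    mask: Mask,
    k: int,
    seed: int,
    kernel_radius: int = 1,
    n_bins: int = 32,
    entropy: np.ndarray | None = None,
    smooth_size: int = 3,
) -> HabitatMap:
    """Full per-patient habitat mapping: entropy (box-smoothed inside the
    mask) -> z-scored K-means -> canonical renumbering."""
    if entropy is None:
        entropy = entropy_map(volume, mask, kernel_radius, n_bins)
    if smooth_size and smooth_size > 1:
        entropy = smooth_in_mask(entropy, mask.data, smooth_size)
    vfm = voxel_features(volume, mask, entropy)
    labels, cent, _ = kmeans_voxels(vfm.features, k, seed)
    return canonicalize_labels(labels, cent, vfm.coords, vfm.shape)


def habitat_masks(h: HabitatMap) -> list[tuple[np.ndarray, bool]]:
    """Split a habitat map into k binary masks (pairwise disjoint, union = VOI).

    Returns ``[(mask, is_empty), ...]`` for habitats 1..k; an empty habitat is
    emitted as an all-zero mask with the flag set.
    """
    out = []
    for hab in range(1, h.k + 1):
        m = (h.labels == hab).astype(np.uint8)
        out.append((m, not bool(m.any())))
    return out


def pool_cohort_voxels(
    feature_matrices: list[VoxelFeatureMatrix],
    max_per_patient: int = 2000,
    seed: int = 0,
) -> np.ndarray:
    """Pool z-scored voxel features evenly across patients (uniform random
    subsample capped per patient) for cohort-level consensus clustering."""
    rng = np.random.default_rng(seed)
    chunks = []
    for vfm in feature_matrices:
        X = _zscore(vfm.features)
        if len(X) > max_per_patient:
            idx = rng.choice(len(X), size=max_per_patient, replace=False)
            X = X[idx]
        chunks.append(X)
    return np.vstack(chunks)


def pool_patient_summaries(
    feature_matrices: list[VoxelFeatureMatrix], n_quantiles: int = 5
) -> np.ndarray:
    """Patient-level consensus items: each patient summarized by quantiles of
    the z-scored intensity and entropy channels (alternative to pooling raw
    voxels; items = patients rather than voxels)."""
    qs = np.linspace(0.1, 0.9, n_quantiles)
    rows = []
    for vfm in feature_matrices:
        X = _zscore(vfm.features)
        rows.append(np.concatenate([np.quantile(X[:, j], qs) for j in range(X.shape[1])]))
    return np.vstack(rows)


def consensus_select_k(
    items: np.ndarray,
    k_range: range = range(2, 11),
    n_resamples: int = 50,
    item_fraction: float = 0.8,
    seed: int = 0,
    delta_threshold: float = 0.10,
    max_items: int = 1500,
) -> ConsensusResult:
    """Monti consensus clustering over a candidate k range.

    For each k, ``n_resamples`` subsamples of ``item_fraction`` of the items
    are clustered by K-means; the consensus matrix is the co-clustering count
    divided by the co-sampling count.  The empirical CDF of the off-diagonal
    consensus values yields the area A(k); the selected k is the smallest one
    after which the relative delta-area ``(A(k+1)-A(k))/A(k)`` stays below
    ``delta_threshold``.  PAC (share of consensus entries in (0.1, 0.9)) is
    reported per k as a diagnostic.
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    rng = np.random.default_rng(seed)
    X = np.asarray(items, dtype=np.float64)
    if len(X) > max_items:  # keep the N x N matrices tractable
        X = X[rng.choice(len(X), size=max_items, replace=False)]
    n = len(X)
    m = max(2, int(round(item_fraction * n)))
    iu = np.triu_indices(n, k=1)

    ks = list(k_range)
    matrices: dict[int, np.ndarray] = {}
    areas: dict[int, float] = {}
    pacs: dict[int, float] = {}
    for k in ks:
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = rng.choice(n, size=m, replace=False)
            labels, _, _ = kmeans_voxels(
                X[idx], k, int(rng.integers(2**31)), standardize=False
            )
            co_sample[np.ix_(idx, idx)] += 1.0
            for c in range(labels.max() + 1):
                members = idx[labels == c]
                co_cluster[np.ix_(members, members)] += 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            cons = np.where(co_sample > 0, co_cluster / co_sample, 0.0)
        np.fill_diagonal(cons, 1.0)
        matrices[k] = cons

        vals = np.sort(cons[iu])
        # area under the empirical CDF of consensus values
        cdf = np.arange(1, len(vals) + 1) / len(vals)
        area = float(np.sum(np.diff(vals) * cdf[:-1])) if len(vals) > 1 else 0.0
        areas[k] = area
        pacs[k] = float(np.mean((vals > 0.1) & (vals < 0.9)))

    deltas: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else 0.0

    # elbow: smallest k whose successor's relative gain is below threshold
    k_selected = ks[-1]
    for i, k in enumerate(ks[:-1]):
        if deltas[ks[i + 1]] < delta_threshold:
            k_selected = k
            break
    return ConsensusResult(
        k_range=ks,
        consensus_matrices=matrices,
        cdf_areas=areas,
        delta_areas=deltas,
        pac_scores=pacs,
        k_selected=k_selected,
    )
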