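"""First-principles IBSI-aligned radiomic feature bank.

Texture matrices (GLCM, GLRLM, GLSZM, GLDM, NGTDM), 18 first-order statistics
and 14 shape descriptors, computed on an arbitrary region mask — each habitat
sub-region or the whole tumor.  93 intensity/texture features per region, plus
shape on the whole tumor only.

Conventions (documented because IBSI leaves aggregation choices open):

* discretization: fixed bin number (default 32) with equal-width bins over the
  region's own [min, max]; a constant region collapses to a single level;
* zones and dependence neighbourhoods use 26-connectivity;
* GLCM and GLRLM are *merged* over the 13 unique 3D directions at distance 1
  (co-occurrences symmetrized), and GLRLM run percentage is normalized by
  ``n_voxels * n_directions``;
* feature names follow the ``original_<family>_<FeatureName>`` convention.

Every matrix builder is regression-tested against exhaustive brute-force
oracles on small random regions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "QuantizedRegion",
    "TextureMatrix",
    "discretize",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_table",
    "feature_sahgle",
    "texture_features",
    "first_order_features",
    "shape_features",
    "extract_region_features",
    "INTENSITY_FEATURE_NAMES",
    "SHAPE_FEATURE_NAMES",
]

# 13 unique direction offsets covering 26-connectivity at distance 1
DIRECTIONS_13 = [
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d > (0, 0, 0)
]
OFFSETS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

_EPS = np.finfo(float).eps


@dataclass
class QuantizedRegion:
    """Discretized region: integer levels 1..Ng inside the mask, 0 outside."""

    levels: np.ndarray  # int array, 0 = outside region
    Ng: int
    bin_edges: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int((self.levels > 0).sum())


@dataclass
class TextureMatrix:
    kind: str  # GLCM / GLRLM / GLSZM / GLDM / NGTDM
    matrix: np.ndarray
    meta: dict


def _bbox_crop(mask: np.ndarray, *arrays: np.ndarray, pad: int = 0):
    idx = np.where(mask)
    lo = [max(0, int(c.min()) - pad) for c in idx]
    hi = [min(n, int(c.max()) + 1 + pad) for c, n in zip(idx, mask.shape)]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    return (mask[box],) + tuple(a[box] for a in arrays)


def discretize(
    values: np.ndarray,
    mask: np.ndarray,
    n_bins: int = 32,
    bin_width: float | None = None,
) -> QuantizedRegion:
    """Discretize in-mask intensities to integer levels 1..Ng.

    Fixed-bin-number (default): ``level = min(floor(n_bins * (x - min) /
    (max - min)) + 1, n_bins)``; a constant region maps to a single level
    (Ng = 1).  Passing ``bin_width`` switches to fixed-bin-width mode:
    ``level = floor((x - min) / bin_width) + 1``.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty region")
    mask, values = _bbox_crop(mask, np.asarray(values, dtype=np.float64))
    inside = values[mask]
    lo, hi = float(inside.min()), float(inside.max())
    levels = np.zeros(mask.shape, dtype=np.int32)
    if hi <= lo:
        levels[mask] = 1
        return QuantizedRegion(levels=levels, Ng=1, bin_edges=np.array([lo, hi]))
    if bin_width is not None:
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        lv = np.floor((values - lo) / bin_width).astype(np.int32) + 1
        n_edges = int(np.ceil((hi - lo) / bin_width)) + 1
        edges = lo + bin_width * np.arange(n_edges + 1)
    else:
        lv = np.floor(n_bins * (values - lo) / (hi - lo)).astype(np.int32) + 1
        lv = np.clip(lv, 1, n_bins)
        edges = np.linspace(lo, hi, n_bins + 1)
    levels[mask] = lv[mask]
    return QuantizedRegion(levels=levels, Ng=int(levels.max()), bin_edges=edges)


def _shift(a: np.ndarray, d, fill=0) -> np.ndarray:
    """Shift array by offset d (content moves by +d), zero-filled."""
    out = np.full_like(a, fill)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    for ax, step in enumerate(d):
        n = a.shape[ax]
        if step == 0:
            continue
        if step > 0:
            src[ax] = slice(0, n - step)
            dst[ax] = slice(step, n)
        else:
            src[ax] = slice(-step, n)
            dst[ax] = slice(0, n + step)
    out[tuple(dst)] = a[tuple(src)]
    return out


# ---------------------------------------------------------------- matrices


def glcm_matrix(q: QuantizedRegion) -> TextureMatrix:
    """Gray-level co-occurrence counts merged over the 13 unique directions at
    distance 1, symmetrized (each unordered pair counted in both orders)."""
    L = q.levels
    Ng = q.Ng
    C = np.zeros((Ng, Ng), dtype=np.float64)
    for d in DIRECTIONS_13:
        Ls = _shift(L, tuple(-x for x in d))  # neighbour at +d seen from voxel
        both = (L > 0) & (Ls > 0)
        if not both.any():
            continue
        i = L[both] - 1
        j = Ls[both] - 1
        np.add.at(C, (i, j), 1.0)
    C = C + C.T  # symmetrize
    return TextureMatrix("GLCM", C, {"n_directions": len(DIRECTIONS_13), "distance": 1})


def glrlm_matrix(q: QuantizedRegion) -> TextureMatrix:
    """Gray-level run-length counts merged over the 13 unique directions.

    A run is a maximal set of consecutive same-level in-region voxels along a
    direction; out-of-region voxels break runs.
    """
    L = q.levels
    Ng = q.Ng
    max_len = max(L.shape)
    P = np.zeros((Ng, max_len), dtype=np.float64)
    for d in DIRECTIONS_13:
        prev = _shift(L, d)  # voxel at -d seen from each voxel
        starts = np.argwhere((L > 0) & (prev != L))
        if len(starts) == 0:
            continue
        levels = L[tuple(starts.T)]
        cur = starts.copy()
        length = np.ones(len(starts), dtype=np.int64)
        active = np.ones(len(starts), dtype=bool)
        while active.any():
            nxt = cur[active] + np.array(d)
            inb = np.all((nxt >= 0) & (nxt < np.array(L.shape)), axis=1)
            same = np.zeros(len(nxt), dtype=bool)
            if inb.any():
                same[inb] = L[tuple(nxt[inb].T)] == levels[active][inb]
            idx_active = np.where(active)[0]
            cont = idx_active[same]
            stop = idx_active[~same]
            length[cont] += 1
            cur[cont] += np.array(d)
            active[stop] = False
        np.add.at(P, (levels - 1, length - 1), 1.0)
    # trim trailing all-zero run-length columns
    nz = np.where(P.sum(axis=0) > 0)[0]
    if len(nz):
        P = P[:, : nz[-1] + 1]
    return TextureMatrix("GLRLM", P, {"n_directions": len(DIRECTIONS_13)})


def glszm_matrix(q: QuantizedRegion) -> TextureMatrix:
    """Gray-level size-zone matrix: P(i, j) = number of 26-connected zones of
    level i and size j; entries sum to the total zone count Nz."""
    L = q.levels
    Ng = q.Ng
    sizes_per_level: dict[int, np.ndarray] = {}
    max_size = 0
    for g in range(1, Ng + 1):
        lab, n = ndimage.label(L == g, structure=STRUCT_26)
        if n == 0:
            sizes_per_level[g] = np.array([], dtype=np.int64)
            continue
        sizes = np.bincount(lab.ravel())[1:]
        sizes_per_level[g] = sizes
        max_size = max(max_size, int(sizes.max()))
    P = np.zeros((Ng, max(max_size, 1)), dtype=np.float64)
    for g, sizes in sizes_per_level.items():
        for s in sizes:
            P[g - 1, s - 1] += 1.0
    return TextureMatrix("GLSZM", P, {"connectivity": 26})


def gldm_matrix(q: QuantizedRegion, alpha: int = 0) -> TextureMatrix:
    """Gray-level dependence matrix: D(i, j) counts voxels of level i with
    dependence j, where j = 1 + number of 26-neighbours whose level differs
    from the centre by at most ``alpha``."""
    L = q.levels
    Ng = q.Ng
    dep = np.zeros(L.shape, dtype=np.int64)
    for d in OFFSETS_26:
        Ls = _shift(L, tuple(-x for x in d))
        dep += ((Ls > 0) & (L > 0) & (np.abs(Ls - L) <= alpha)).astype(np.int64)
    inside = L > 0
    j = dep[inside] + 1
    i = L[inside]
    D = np.zeros((Ng, 27), dtype=np.float64)
    np.add.at(D, (i - 1, j - 1), 1.0)
    nz = np.where(D.sum(axis=0) > 0)[0]
    if len(nz):
        D = D[:, : nz[-1] + 1]
    return TextureMatrix("GLDM", D, {"alpha": alpha, "connectivity": 26})


def ngtdm_table(q: QuantizedRegion) -> TextureMatrix:
    """Neighbourhood gray-tone difference table: rows ``(n_i, p_i, s_i)`` per
    level, where s_i sums |level - mean level of in-region 26-neighbours| over
    voxels of level i (voxels with no in-region neighbour are excluded)."""
    L = q.levels.astype(np.float64)
    Ng = q.Ng
    nb_sum = np.zeros(L.shape)
    nb_cnt = np.zeros(L.shape)
    for d in OFFSETS_26:
        Ls = _shift(q.levels, tuple(-x for x in d))
        valid = Ls > 0
        nb_sum += np.where(valid, Ls, 0)
        nb_cnt += valid
    inside = (q.levels > 0) & (nb_cnt > 0)
    abar = np.zeros(L.shape)
    abar[inside] = nb_sum[inside] / nb_cnt[inside]
    diff = np.abs(L - abar)
    n = np.zeros(Ng)
    s = np.zeros(Ng)
    lv = q.levels[inside]
    np.add.at(n, lv - 1, 1.0)
    np.add.at(s, lv - 1, diff[inside])
    Nvp = n.sum()
    p = n / Nvp if Nvp > 0 else n
    tab = np.column_stack([n, p, s])
    return TextureMatrix("NGTDM", tab, {"connectivity": 26})


# ---------------------------------------------------------------- features


def feature_sahgle(m: TextureMatrix) -> float:
    """Small-area high-gray-level emphasis of a GLSZM:
    ``(1/Nz) * sum_ij P(i,j) * i^2 / j^2``."""
    P = m.matrix
    Nz = P.sum()
    if Nz < 1:
        return float("nan")
    i = np.arange(1, P.shape[0] + 1)[:, None]
    j = np.arange(1, P.shape[1] + 1)[None, :]
    return float((P * i**2 / j**2).sum() / Nz)


def _glcm_features(q: QuantizedRegion) -> dict[str, float]:
    C = glcm_matrix(q).matrix
    Ng = C.shape[0]
    tot = C.sum()
    if tot == 0:  # single voxel region: no pairs
        return {name: 0.0 for name in _GLCM_NAMES} | {
            "Correlation": 1.0, "MCC": 1.0, "MaximumProbability": 0.0,
        }
    p = C / tot
    i = np.arange(1, Ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((I * p).sum())  # symmetric: mu_x == mu_y
    sig2 = float(((I - mu) ** 2 * p).sum())
    sig = np.sqrt(sig2)

    k_sum = np.arange(2, 2 * Ng + 1)
    p_sum = np.zeros(len(k_sum))
    np.add.at(p_sum, (I + J).ravel() - 2, p.ravel())
    k_diff = np.arange(0, Ng)
    p_diff = np.zeros(Ng)
    np.add.at(p_diff, np.abs(I - J).ravel(), p.ravel())

    def _ent(v):
        v = v[v > 0]
        return float(-(v * np.log2(v)).sum())

    hxy = _ent(p.ravel())
    px_py = np.outer(px, px)
    with np.errstate(divide="ignore", invalid="ignore"):
        hxy1 = float(-(p * np.where(px_py > 0, np.log2(px_py + _EPS), 0.0)).sum())
        hxy2 = _ent(px_py.ravel())
    hx = _ent(px)

    feats: dict[str, float] = {}
    feats["Autocorrelation"] = float((I * J * p).sum())
    feats["JointAverage"] = mu
    feats["ClusterProminence"] = float(((I + J - 2 * mu) ** 4 * p).sum())
    feats["ClusterShade"] = float(((I + J - 2 * mu) ** 3 * p).sum())
    feats["ClusterTendency"] = float(((I + J - 2 * mu) ** 2 * p).sum())
    feats["Contrast"] = float(((I - J) ** 2 * p).sum())
    feats["Correlation"] = (
        1.0 if sig2 <= 0 else float(((I * J * p).sum() - mu * mu) / sig2)
    )
    da = float((k_diff * p_diff).sum())
    feats["DifferenceAverage"] = da
    feats["DifferenceEntropy"] = _ent(p_diff)
    feats["DifferenceVariance"] = float((((k_diff - da) ** 2) * p_diff).sum())
    feats["JointEnergy"] = float((p**2).sum())
    feats["JointEntropy"] = hxy
    denom = max(hx, _EPS)
    feats["Imc1"] = 0.0 if denom <= _EPS else float((hxy - hxy1) / denom)
    feats["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    feats["Idm"] = float((p / (1.0 + (I - J) ** 2)).sum())
    feats["Idmn"] = float((p / (1.0 + ((I - J) / Ng) ** 2)).sum())
    feats["Id"] = float((p / (1.0 + np.abs(I - J))).sum())
    feats["Idn"] = float((p / (1.0 + np.abs(I - J) / Ng)).sum())
    off = I != J
    feats["InverseVariance"] = float((p[off] / (I - J)[off] ** 2).sum()) if off.any() else 0.0
    feats["MaximumProbability"] = float(p.max())
    feats["SumAverage"] = float((k_sum * p_sum).sum())
    feats["SumEntropy"] = _ent(p_sum)
    feats["SumSquares"] = sig2
    # maximal correlation coefficient: sqrt of 2nd-largest eigenvalue of Q
    keep = px > 0
    if keep.sum() < 2:
        feats["MCC"] = 1.0
    else:
        pk = p[np.ix_(keep, keep)]
        pxk = px[keep]
        Q = (pk[:, None, :] * pk[None, :, :] / (pxk[:, None, None] * pxk[None, None, :])).sum(
            axis=2
        )
        ev = np.sort(np.abs(np.linalg.eigvals(Q)))
        feats["MCC"] = float(np.sqrt(max(0.0, ev[-2]))) if len(ev) >= 2 else 1.0
    return feats


_GLCM_NAMES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
]


def _sized_matrix_features(P: np.ndarray, Np: int, kind: str, n_dirs: int = 1
                           ) -> dict[str, float]:
    """Shared feature family for GLRLM (runs), GLSZM (zones), GLDM
    (dependencies): a counts matrix over (gray level i, size j)."""
    N = P.sum()
    if N <= 0:
        return {}
    p = P / N
    i = np.arange(1, P.shape[0] + 1)[:, None]
    j = np.arange(1, P.shape[1] + 1)[None, :]
    pg = p.sum(axis=1)  # gray-level marginal
    ps = p.sum(axis=0)  # size marginal
    mu_g = float((np.arange(1, P.shape[0] + 1) * pg).sum())
    mu_s = float((np.arange(1, P.shape[1] + 1) * ps).sum())

    f: dict[str, float] = {}
    f["small"] = float((p / j**2).sum())
    f["large"] = float((p * j**2).sum())
    f["gln"] = float((P.sum(axis=1) ** 2).sum() / N)
    f["glnn"] = float((pg**2).sum())
    f["sn"] = float((P.sum(axis=0) ** 2).sum() / N)
    f["snn"] = float((ps**2).sum())
    f["percentage"] = float(N / (Np * n_dirs))
    f["glv"] = float((((np.arange(1, P.shape[0] + 1) - mu_g) ** 2) * pg).sum())
    f["sv"] = float((((np.arange(1, P.shape[1] + 1) - mu_s) ** 2) * ps).sum())
    nz = p[p > 0]
    f["entropy"] = float(-(nz * np.log2(nz)).sum())
    f["lgl"] = float((p / i**2).sum())
    f["hgl"] = float((p * i**2).sum())
    f["slgl"] = float((p / (i**2 * j**2)).sum())
    f["shgl"] = float((p * i**2 / j**2).sum())
    f["llgl"] = float((p * j**2 / i**2).sum())
    f["lhgl"] = float((p * i**2 * j**2).sum())
    return f


def _glrlm_features(q: QuantizedRegion) -> dict[str, float]:
    m = glrlm_matrix(q)
    f = _sized_matrix_features(m.matrix, q.n_voxels, "GLRLM", m.meta["n_directions"])
    return {
        "ShortRunEmphasis": f["small"], "LongRunEmphasis": f["large"],
        "GrayLevelNonUniformity": f["gln"], "GrayLevelNonUniformityNormalized": f["glnn"],
        "RunLengthNonUniformity": f["sn"], "RunLengthNonUniformityNormalized": f["snn"],
        "RunPercentage": f["percentage"], "GrayLevelVariance": f["glv"],
        "RunVariance": f["sv"], "RunEntropy": f["entropy"],
        "LowGrayLevelRunEmphasis": f["lgl"], "HighGrayLevelRunEmphasis": f["hgl"],
        "ShortRunLowGrayLevelEmphasis": f["slgl"],
        "ShortRunHighGrayLevelEmphasis": f["shgl"],
        "LongRunLowGrayLevelEmphasis": f["llgl"],
        "LongRunHighGrayLevelEmphasis": f["lhgl"],
    }


def _glszm_features(q: QuantizedRegion) -> dict[str, float]:
    m = glszm_matrix(q)
    f = _sized_matrix_features(m.matrix, q.n_voxels, "GLSZM")
    return {
        "SmallAreaEmphasis": f["small"], "LargeAreaEmphasis": f["large"],
        "GrayLevelNonUniformity": f["gln"], "GrayLevelNonUniformityNormalized": f["glnn"],
        "SizeZoneNonUniformity": f["sn"], "SizeZoneNonUniformityNormalized": f["snn"],
        "ZonePercentage": f["percentage"], "GrayLevelVariance": f["glv"],
        "ZoneVariance": f["sv"], "ZoneEntropy": f["entropy"],
        "LowGrayLevelZoneEmphasis": f["lgl"], "HighGrayLevelZoneEmphasis": f["hgl"],
        "SmallAreaLowGrayLevelEmphasis": f["slgl"],
        "SmallAreaHighGrayLevelEmphasis": f["shgl"],
        "LargeAreaLowGrayLevelEmphasis": f["llgl"],
        "LargeAreaHighGrayLevelEmphasis": f["lhgl"],
    }


def _gldm_features(q: QuantizedRegion) -> dict[str, float]:
    m = gldm_matrix(q)
    f = _sized_matrix_features(m.matrix, q.n_voxels, "GLDM")
    return {
        "SmallDependenceEmphasis": f["small"], "LargeDependenceEmphasis": f["large"],
        "GrayLevelNonUniformity": f["gln"], "DependenceNonUniformity": f["sn"],
        "DependenceNonUniformityNormalized": f["snn"],
        "GrayLevelVariance": f["glv"], "DependenceVariance": f["sv"],
        "DependenceEntropy": f["entropy"],
        "LowGrayLevelEmphasis": f["lgl"], "HighGrayLevelEmphasis": f["hgl"],
        "SmallDependenceLowGrayLevelEmphasis": f["slgl"],
        "SmallDependenceHighGrayLevelEmphasis": f["shgl"],
        "LargeDependenceLowGrayLevelEmphasis": f["llgl"],
        "LargeDependenceHighGrayLevelEmphasis": f["lhgl"],
    }


def _ngtdm_features(q: QuantizedRegion) -> dict[str, float]:
    tab = ngtdm_table(q).matrix
    n, p, s = tab[:, 0], tab[:, 1], tab[:, 2]
    Nvp = n.sum()
    i = np.arange(1, len(n) + 1, dtype=np.float64)
    act = p > 0
    Ngp = int(act.sum())
    feats: dict[str, float] = {}
    ps_sum = float((p * s).sum())
    feats["Coarseness"] = 1e6 if ps_sum == 0 else float(1.0 / ps_sum)
    if Ngp <= 1 or Nvp == 0:
        feats["Contrast"] = 0.0
        feats["Busyness"] = 0.0
    else:
        pi, pj = np.meshgrid(p, p, indexing="ij")
        ii, jj = np.meshgrid(i, i, indexing="ij")
        feats["Contrast"] = float(
            (pi * pj * (ii - jj) ** 2).sum() / (Ngp * (Ngp - 1)) * (s.sum() / Nvp)
        )
        denom = np.abs(ii * pi - jj * pj)[np.ix_(act, act)].sum()
        feats["Busyness"] = 0.0 if denom == 0 else float(ps_sum / denom)
    if Nvp == 0:
        feats["Complexity"] = 0.0
        feats["Strength"] = 0.0
    else:
        pi, pj = np.meshgrid(p, p, indexing="ij")
        ii, jj = np.meshgrid(i, i, indexing="ij")
        si, sj = np.meshgrid(s, s, indexing="ij")
        both = (pi > 0) & (pj > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cx = np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)
        feats["Complexity"] = float(cx[both].sum() / Nvp)
        s_sum = s.sum()
        feats["Strength"] = (
            0.0 if s_sum == 0 else float(((pi + pj) * (ii - jj) ** 2)[both].sum() / s_sum)
        )
    return feats


def first_order_features(values: np.ndarray, mask: np.ndarray,
                         spacing_mm=(1.0, 1.0, 1.0), n_bins: int = 32
                         ) -> dict[str, float]:
    """18 first-order statistics of the in-mask intensities.

    Entropy and Uniformity use the same 32-bin fixed-bin-number
    discretization as the texture matrices.  Variance/skewness/kurtosis are
    population moments; kurtosis is Pearson (not excess).
    """
    x = np.asarray(values, dtype=np.float64)[np.asarray(mask) > 0]
    if x.size == 0:
        raise ValueError("empty region")
    n = x.size
    mean = float(x.mean())
    var = float(x.var())
    sd = np.sqrt(var)
    voxvol = float(np.prod(spacing_mm))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mid = x[(x >= p10) & (x <= p90)]
    q = discretize(values, mask, n_bins)
    hist = np.bincount(q.levels[q.levels > 0], minlength=q.Ng + 1)[1:]
    ph = hist / hist.sum()
    ph_nz = ph[ph > 0]
    feats = {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float(voxvol * (x**2).sum()),
        "Entropy": float(-(ph_nz * np.log2(ph_nz)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": (
            float(np.abs(mid - mid.mean()).mean()) if mid.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": 0.0 if sd == 0 else float(((x - mean) ** 3).mean() / sd**3),
        "Kurtosis": 0.0 if sd == 0 else float(((x - mean) ** 4).mean() / sd**4),
        "Variance": var,
        "Uniformity": float((ph**2).sum()),
    }
    return feats


def shape_features(mask: np.ndarray, spacing_mm=(1.0, 1.0, 1.0)) -> dict[str, float]:
    """14 shape descriptors of a binary mask.

    Surface area and mesh volume come from a marching-cubes mesh of the
    padded mask (scikit-image); maximum diameters from convex-hull vertex
    pairs; axis lengths from 4*sqrt of the PCA eigenvalues of the physical
    voxel coordinates.
    """
    from skimage import measure

    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing_mm, dtype=np.float64)
    n = int(mask.sum())
    voxel_volume = float(n * spacing.prod())

    cropped, = _bbox_crop(mask)
    padded = np.pad(cropped, 1).astype(np.float64)
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
        surface_area = float(measure.mesh_surface_area(verts, faces))
        tri = verts[faces]
        mesh_volume = float(abs(np.einsum("ij,ij->i", tri[:, 0],
                                          np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
    except (ValueError, RuntimeError):
        # single-voxel-thin masks: fall back to voxel approximations
        surface_area = float(_voxel_face_area(mask, spacing))
        mesh_volume = voxel_volume

    coords = np.argwhere(mask).astype(np.float64) * spacing
    hull_pts = coords
    if len(coords) > 4:
        try:
            hull = ConvexHull(coords)
            hull_pts = coords[hull.vertices]
        except QhullError:
            pass
    d3 = _max_pairwise(hull_pts)

    def _max2d(drop_axis: int) -> float:
        pts = np.delete(coords, drop_axis, axis=1)
        if len(pts) > 4:
            try:
                h = ConvexHull(pts)
                pts = pts[h.vertices]
            except QhullError:
                pass
        return _max_pairwise(pts)

    cov = np.cov(coords.T, bias=True) if len(coords) > 1 else np.zeros((3, 3))
    ev = np.sort(np.maximum(np.linalg.eigvalsh(np.atleast_2d(cov)), 0.0))[::-1]
    major, minor, least = (4.0 * np.sqrt(ev)).tolist()

    sph = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area if surface_area else 0.0
    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume if mesh_volume else float("inf"),
        "Sphericity": float(sph),
        "Maximum3DDiameter": d3,
        "Maximum2DDiameterSlice": _max2d(0),   # in-plane (y, x)
        "Maximum2DDiameterColumn": _max2d(1),  # (z, x)
        "Maximum2DDiameterRow": _max2d(2),     # (z, y)
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": float(np.sqrt(ev[1] / ev[0])) if ev[0] > 0 else 0.0,
        "Flatness": float(np.sqrt(ev[2] / ev[0])) if ev[0] > 0 else 0.0,
    }


def _voxel_face_area(mask: np.ndarray, spacing: np.ndarray) -> float:
    area = 0.0
    face_areas = [spacing[1] * spacing[2], spacing[0] * spacing[2], spacing[0] * spacing[1]]
    for ax, fa in enumerate(face_areas):
        d = [0, 0, 0]
        for sgn in (-1, 1):
            d[ax] = sgn
            nb = _shift(mask.astype(np.int8), tuple(d))
            area += fa * float((mask & (nb == 0)).sum())
        d[ax] = 0
    return area


def _max_pairwise(pts: np.ndarray) -> float:
    if len(pts) < 2:
        return 0.0
    if len(pts) > 2000:  # safety cap; hull vertices are far fewer in practice
        pts = pts[:: len(pts) // 2000 + 1]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


_FAMILY_FUNCS = {
    "glcm": (_glcm_features, _GLCM_NAMES),
    "glrlm": (_glrlm_features, None),
    "glszm": (_glszm_features, None),
    "gldm": (_gldm_features, None),
    "ngtdm": (_ngtdm_features, None),
}


def texture_features(q: QuantizedRegion, kind: str) -> dict[str, float]:
    """Named features of one texture family on a quantized region."""
    kind = kind.lower()
    if kind not in _FAMILY_FUNCS:
        raise ValueError(f"unknown texture family {kind!r}")
    func, _ = _FAMILY_FUNCS[kind]
    raw = func(q)
    return {f"original_{kind}_{k}": v for k, v in raw.items()}


def extract_region_features(
    values: np.ndarray,
    region_mask: np.ndarray,
    spacing_mm=(1.0, 1.0, 1.0),
    n_bins: int = 32,
    include_shape: bool = False,
) -> dict[str, float]:
    """Full feature bank on one region: 18 first-order + 75 texture features
    (93 total), optionally + 14 shape features (whole tumor only).

    An empty region returns the same keys with NaN values (downstream
    imputation policy lives in the selection cascade).
    """
    region_mask = np.asarray(region_mask) > 0
    if not region_mask.any():
        out = {f"original_firstorder_{k}": float("nan") for k in _FIRSTORDER_NAMES}
        for fam in ("glcm", "glrlm", "glszm", "gldm", "ngtdm"):
            out.update({n: float("nan") for n in _family_names(fam)})
        if include_shape:
            out.update({f"original_shape_{k}": float("nan") for k in SHAPE_FEATURE_NAMES})
        return out
    fo = first_order_features(values, region_mask, spacing_mm, n_bins)
    out = {f"original_firstorder_{k}": v for k, v in fo.items()}
    q = discretize(values, region_mask, n_bins)
    for fam in ("glcm", "glrlm", "glszm", "gldm", "ngtdm"):
        out.update(texture_features(q, fam))
    if include_shape:
        sh = shape_features(region_mask, spacing_mm)
        out.update({f"original_shape_{k}": v for k, v in sh.items()})
    return out


_FIRSTORDER_NAMES = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile", "90Percentile",
    "Maximum", "Mean", "Median", "InterquartileRange", "Range",
    "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "Skewness", "Kurtosis", "Variance", "Uniformity",
]

SHAPE_FEATURE_NAMES = [
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio", "Sphericity",
    "Maximum3DDiameter", "Maximum2DDiameterSlice", "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow", "MajorAxisLength", "MinorAxisLength", "LeastAxisLength",
    "Elongation", "Flatness",
]


def _family_names(fam: str) -> list[str]:
    # derive names from a tiny non-degenerate probe region (cached)
    global _NAME_CACHE
    if fam not in _NAME_CACHE:
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 4, size=(3, 3, 3)).astype(float)
        q = discretize(vals, np.ones((3, 3, 3)), n_bins=4)
        _NAME_CACHE[fam] = list(texture_features(q, fam))
    return _NAME_CACHE[fam]


_NAME_CACHE: dict[str, list[str]] = {}

#: canonical per-region intensity/texture feature name list (93 names)
INTENSITY_FEATURE_NAMES = [f"original_firstorder_{k}" for k in _FIRSTORDER_NAMES]


def all_intensity_feature_names() -> list[str]:
    names = list(INTENSITY_FEATURE_NAMES)
    for fam in ("glcm", "glrlm", "glszm", "gldm", "ngtdm"):
        names.extend(_family_names(fam))
    return names
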