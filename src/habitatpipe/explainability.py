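"""Kernel SHAP attribution for the fitted models.

Shapley values are estimated by the kernel method: sampled (or, for small
feature counts, fully enumerated) coalitions are scored with missing features
marginalized over a background table, and a weighted least squares with the
Shapley kernel weight ``w(|z|) = (M−1) / (C(M,|z|)·|z|·(M−|z|))`` recovers the
attributions.  The efficiency constraint ``φ0 + Σφ = f(x)`` is enforced
exactly, so local accuracy holds by construction; with full enumeration the
estimates equal exact Shapley values.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "ShapResult",
    "kernel_shap",
    "exact_shapley",
    "shap_summary",
    "summarize_background",
]


@dataclass
class ShapResult:
    phi: np.ndarray  # one attribution per model feature
    base_value: float  # φ0 = E_background[f]
    fx: float  # model output on the explained instance
    n_samples: int
    seed: int
    feature_names: list[str]

    def local_accuracy_gap(self) -> float:
        return abs(self.base_value + self.phi.sum() - self.fx)


def _coalition_value(
    predict_fn, background: np.ndarray, instance: np.ndarray, mask: np.ndarray
) -> float:
    """E over background rows of f(x_S, b_{\\S}) for coalition S = mask."""
    synth = background.copy()
    synth[:, mask] = instance[mask]
    return float(np.mean(predict_fn(synth)))


def kernel_shap(
    predict_fn,
    background: pd.DataFrame | np.ndarray,
    instance: pd.Series | np.ndarray,
    n_samples: int | None = None,
    seed: int = 0,
) -> ShapResult:
    """Kernel SHAP for one instance.

    ``predict_fn`` maps an (n, M) array to n scalar outputs.  When the number
    of proper coalitions ``2^M − 2`` fits within ``n_samples`` (or M <= 12 by
    default) the coalitions are fully enumerated and the result is exact;
    otherwise coalitions are sampled by their kernel-weight size distribution.
    Raises if ``n_samples`` is too small to identify M attributions.
    """
    if isinstance(background, pd.DataFrame):
        names = list(background.columns)
        bg = background.to_numpy(float)
    else:
        bg = np.asarray(background, float)
        names = [f"f{i}" for i in range(bg.shape[1])]
    x = (
        instance[names].to_numpy(float)
        if isinstance(instance, pd.Series)
        else np.asarray(instance, float)
    )
    if bg.shape[0] == 0:
        raise ValueError("background must be non-empty")
    M = bg.shape[1]
    if x.shape != (M,):
        raise ValueError("instance does not match the model's features")

    phi0 = float(np.mean(predict_fn(bg)))
    fx = float(np.asarray(predict_fn(x[None, :]))[0])
    if M == 1:
        # exact single-feature Shapley value
        return ShapResult(np.array([fx - phi0]), phi0, fx, 1, seed, names)

    n_proper = 2**M - 2
    if n_samples is None:
        n_samples = min(n_proper, 2048)
    if n_samples < M:
        raise ValueError(
            f"n_samples={n_samples} too small: need at least M={M} coalitions"
        )

    rng = np.random.default_rng(seed)
    if n_proper <= n_samples:
        masks = np.array(
            [[(c >> i) & 1 for i in range(M)] for c in range(1, 2**M - 1)], dtype=bool
        )
        sizes = masks.sum(axis=1)
        weights = np.array(
            [(M - 1) / (comb(M, s) * s * (M - s)) for s in sizes], dtype=float
        )
    else:
        # sample coalition sizes with probability proportional to the summed
        # kernel weight at each size, then uniform subsets of that size
        size_w = np.array([(M - 1) / (s * (M - s)) for s in range(1, M)])
        size_p = size_w / size_w.sum()
        masks = np.zeros((n_samples, M), dtype=bool)
        for r in range(n_samples):
            s = int(rng.choice(np.arange(1, M), p=size_p))
            masks[r, rng.choice(M, size=s, replace=False)] = True
        weights = np.ones(n_samples)  # size bias already in the sampler

    vals = np.array(
        [_coalition_value(predict_fn, bg, x, m) for m in masks]
    )

    # WLS with the efficiency constraint folded in:
    # phi_M = (fx - phi0) - sum_{i<M} phi_i
    Z = masks.astype(float)
    y = vals - phi0 - Z[:, -1] * (fx - phi0)
    A = Z[:, :-1] - Z[:, [-1]]
    W = np.sqrt(weights)[:, None]
    beta, *_ = np.linalg.lstsq(W * A, (W.ravel()) * y, rcond=None)
    phi = np.empty(M)
    phi[:-1] = beta
    phi[-1] = (fx - phi0) - beta.sum()
    return ShapResult(phi, phi0, fx, len(masks), seed, names)


def exact_shapley(predict_fn, background, instance) -> np.ndarray:
    """Exhaustive 2^M Shapley enumeration (independent oracle for tests)."""
    if isinstance(background, pd.DataFrame):
        bg = background.to_numpy(float)
    else:
        bg = np.asarray(background, float)
    x = np.asarray(
        instance[list(background.columns)] if isinstance(instance, pd.Series) else instance,
        float,
    )
    M = bg.shape[1]
    values = {}
    for c in range(2**M):
        mask = np.array([(c >> i) & 1 for i in range(M)], dtype=bool)
        values[c] = _coalition_value(predict_fn, bg, x, mask)
    phi = np.zeros(M)
    for i in range(M):
        for c in range(2**M):
            if (c >> i) & 1:
                continue
            s = bin(c).count("1")
            w = 1.0 / (M * comb(M - 1, s))
            phi[i] += w * (values[c | (1 << i)] - values[c])
    return phi


def summarize_background(
    background: pd.DataFrame, max_rows: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Cap the background table at ``max_rows`` medoid-like representatives
    (K-means centers snapped to their nearest actual rows), seeded."""
    if len(background) <= max_rows:
        return background
    X = background.to_numpy(float)
    km = KMeans(n_clusters=max_rows, n_init=3, random_state=seed).fit(X)
    rows = []
    for c in range(max_rows):
        members = np.where(km.labels_ == c)[0]
        if len(members) == 0:
            continue
        d = ((X[members] - km.cluster_centers_[c]) ** 2).sum(axis=1)
        rows.append(members[int(np.argmin(d))])
    return background.iloc[sorted(set(rows))]


def shap_summary(results: list[ShapResult], feature_values: pd.DataFrame | None = None
                 ) -> pd.DataFrame:
    """Rank features by mean |φ| over a cohort of explained instances.

    Returns a table with columns ``feature, mean_abs_phi, mean_phi, rank``;
    positive φ pushes the prediction toward non-response.  When
    ``feature_values`` is given, per-patient (value, φ) pairs are attached as
    a beeswarm-ready long table in ``.attrs['beeswarm']``.
    """
    if not results:
        raise ValueError("no SHAP results to summarize")
    names = results[0].feature_names
    phis = np.vstack([r.phi for r in results])
    out = pd.DataFrame(
        {
            "feature": names,
            "mean_abs_phi": np.abs(phis).mean(axis=0),
            "mean_phi": phis.mean(axis=0),
        }
    ).sort_values(["mean_abs_phi", "feature"], ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    out = out.reset_index(drop=True)
    if feature_values is not None:
        long_rows = []
        for pi, r in enumerate(results):
            for fi, name in enumerate(names):
                long_rows.append(
                    {
                        "patient": feature_values.index[pi],
                        "feature": name,
                        "value": float(feature_values.iloc[pi][name]),
                        "phi": float(r.phi[fi]),
                    }
                )
        out.attrs["beeswarm"] = pd.DataFrame(long_rows)
    return out
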