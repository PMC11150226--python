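"""Four-stage feature-selection cascade for PFS6 prediction.

Stages, in order: (1) inter-rater reliability filter by ICC(2,1) with a 0.75
floor; (2) z-score standardization fitted on the training split only;
(3) greedy Pearson redundancy pruning at |r| > 0.9, keeping from each
offending pair the feature more associated with the outcome; (4) Welch
two-sample t-test at alpha 0.05; (5) L1-penalized logistic regression (LASSO)
with the cross-validated 1-SE rule.  Survivor sets are nested across stages
and every dropped feature carries a machine-readable reason.

Missing values (empty habitats) are imputed with training-column medians
before standardization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SelectionStage",
    "SelectionReport",
    "Scaler",
    "icc_2_1",
    "icc_filter",
    "impute_median_fit",
    "zscore_fit",
    "zscore_apply",
    "pearson_prune",
    "ttest_filter",
    "lasso_select",
    "run_selection",
]


@dataclass
class SelectionStage:
    name: str
    survivors: list[str]
    dropped: dict[str, str]  # feature -> reason
    extras: dict = field(default_factory=dict)


@dataclass
class SelectionReport:
    stages: list[SelectionStage] = field(default_factory=list)
    seed: int = 0

    @property
    def selected(self) -> list[str]:
        return self.stages[-1].survivors if self.stages else []

    def counts(self) -> list[tuple[str, int]]:
        return [(s.name, len(s.survivors)) for s in self.stages]

    def to_json(self, **kwargs) -> str:
        def _clean(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        return json.dumps(asdict(self), default=_clean, sort_keys=True, **kwargs)


@dataclass
class Scaler:
    mean: pd.Series
    sd: pd.Series
    medians: pd.Series  # training medians used for imputation


def icc_2_1(r1: np.ndarray, r2: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    With n subjects and k=2 raters:
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``.
    Returns NaN for zero-variance input (undefined).
    """
    x = np.column_stack([np.asarray(r1, float), np.asarray(r2, float)])
    n, k = x.shape
    if n < 2:
        return float("nan")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return float("nan")
    return float((msr - mse) / denom)


def icc_filter(
    table_r1: pd.DataFrame, table_r2: pd.DataFrame, threshold: float = 0.75
) -> SelectionStage:
    """Keep features whose two-rater ICC(2,1) is at least ``threshold``.

    Columns present only in ``table_r1`` (e.g. rater-independent features)
    pass through untouched.  Zero-variance columns have undefined ICC and are
    dropped with a logged reason.
    """
    shared = [c for c in table_r1.columns if c in table_r2.columns]
    if shared and not table_r1.index.equals(table_r2.index):
        raise ValueError("rater tables must cover the same patients")
    survivors, dropped, iccs = [], {}, {}
    for col in table_r1.columns:
        if col not in table_r2.columns:
            survivors.append(col)
            continue
        a, b = table_r1[col].to_numpy(float), table_r2[col].to_numpy(float)
        if np.nanstd(a) == 0 and np.nanstd(b) == 0:
            dropped[col] = "zero-variance: ICC undefined"
            continue
        ok = np.isfinite(a) & np.isfinite(b)
        val = icc_2_1(a[ok], b[ok]) if ok.sum() >= 2 else float("nan")
        iccs[col] = val
        if np.isnan(val):
            dropped[col] = "ICC undefined"
        elif val >= threshold:
            survivors.append(col)
        else:
            dropped[col] = f"ICC {val:.3f} < {threshold}"
    return SelectionStage("icc", survivors, dropped, {"icc": iccs, "threshold": threshold})


def impute_median_fit(train: pd.DataFrame) -> pd.Series:
    return train.median(numeric_only=True)


def zscore_fit(train: pd.DataFrame) -> tuple[Scaler, SelectionStage]:
    """Fit imputation medians and z-score statistics on the training split;
    zero-SD columns are dropped."""
    med = impute_median_fit(train)
    filled = train.fillna(med)
    mean = filled.mean()
    sd = filled.std(ddof=0)
    survivors = [c for c in train.columns if sd[c] > 0 and np.isfinite(sd[c])]
    dropped = {c: "zero or undefined training SD" for c in train.columns if c not in survivors}
    scaler = Scaler(mean=mean[survivors], sd=sd[survivors], medians=med)
    return scaler, SelectionStage("zscore", survivors, dropped)


def zscore_apply(scaler: Scaler, table: pd.DataFrame) -> pd.DataFrame:
    """Impute with *training* medians and standardize with *training* mean/SD."""
    cols = list(scaler.mean.index)
    out = table[cols].fillna(scaler.medians[cols])
    return (out - scaler.mean) / scaler.sd


def _welch(x: np.ndarray, y: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant columns
        return stats.ttest_ind(x[y == 1], x[y == 0], equal_var=False)


def _abs_t(x: np.ndarray, y: np.ndarray) -> float:
    t, _ = _welch(x, y)
    return abs(float(t)) if np.isfinite(t) else 0.0


def pearson_prune(
    table: pd.DataFrame, labels: np.ndarray, threshold: float = 0.9
) -> SelectionStage:
    """Greedy redundancy pruning: pairs with |r| > threshold are processed in
    descending |r| (ties by name); the member with the smaller outcome |t|
    is dropped (ties keep the lexicographically smaller name).  The surviving
    table has max pairwise |r| <= threshold."""
    cols = list(table.columns)
    y = np.asarray(labels).astype(int)
    X = table.to_numpy(float)
    r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(np.nan_to_num(r, nan=0.0))
    tstats = {c: _abs_t(X[:, i], y) for i, c in enumerate(cols)}

    pairs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(r[i, j]) > threshold:
                pairs.append((abs(r[i, j]), cols[i], cols[j]))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    kept = set(cols)
    dropped: dict[str, str] = {}
    for rv, a, b in pairs:
        if a not in kept or b not in kept:
            continue
        ta, tb = tstats[a], tstats[b]
        if ta > tb:
            loser, winner = b, a
        elif tb > ta:
            loser, winner = a, b
        else:
            winner, loser = sorted((a, b))
        kept.discard(loser)
        dropped[loser] = f"|r|={rv:.3f} with {winner}"
    survivors = [c for c in cols if c in kept]
    return SelectionStage(
        "pearson", survivors, dropped, {"threshold": threshold, "n_pairs": len(pairs)}
    )


def ttest_filter(
    table: pd.DataFrame, labels: np.ndarray, alpha: float = 0.05
) -> SelectionStage:
    """Welch two-sided t-test per column; keep p < alpha."""
    y = np.asarray(labels).astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("each class needs >= 2 patients for the t-test")
    survivors, dropped, pvals = [], {}, {}
    for col in table.columns:
        x = table[col].to_numpy(float)
        if np.std(x) == 0:
            dropped[col] = "constant column"
            continue
        _, p = _welch(x, y)
        pvals[col] = float(p)
        if np.isfinite(p) and p < alpha:
            survivors.append(col)
        else:
            dropped[col] = f"p={p:.4f} >= {alpha}"
    return SelectionStage("ttest", survivors, dropped, {"p_values": pvals, "alpha": alpha})


def lasso_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 40,
    lambda_min_ratio: float = 1e-3,
    screen_table: pd.DataFrame | None = None,
    screen_alpha: float = 0.05,
) -> SelectionStage:
    """L1-penalized logistic regression over a log-spaced λ grid.

    λ is chosen by stratified ``n_folds``-fold cross-validated deviance with
    the 1-SE rule; selected features are the nonzero coefficients of the
    full-train refit at the chosen λ.

    When ``screen_table`` is given (the pre-t-test feature pool), the t-test
    screen is *repeated inside every CV fold* on the fold-training rows, so
    the deviance estimates are free of the selection bias the full-data
    screen would otherwise leak into them; on label-permuted data this drives
    the chosen λ to the all-zero end of the grid.  When the 1-SE λ selects
    nothing *and* the deviance minimum beats the intercept-only model by more
    than one SE (evidence of real signal), the rule falls back to λ_min; on
    null data the empty selection stands.  Raises with diagnostics if a
    signal-bearing fallback still selects nothing.
    """
    X = table.to_numpy(float)
    y = np.asarray(labels).astype(int)
    n, p = X.shape
    if p == 0:
        raise ValueError("no features to select from")
    n_folds = min(n_folds, int(np.bincount(y, minlength=2).min()))
    if n_folds < 2:
        raise ValueError("need >= 2 patients per class for cross-validation")
    # data-driven grid: lambda_max (with a small safety factor) kills all
    # coefficients; the KKT threshold for logistic loss is max|X'(y-ybar)|/n
    lam_max = 1.1 * np.abs(X.T @ (y - y.mean())).max() / n
    lam_max = max(lam_max, 1e-6)
    lambdas = lam_max * np.power(10.0, np.linspace(0, np.log10(lambda_min_ratio), n_lambdas))

    def _fit(Xtr, ytr, lam) -> LogisticRegression:
        C = 1.0 / (len(ytr) * lam)
        clf = LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, random_state=seed
        )
        clf.fit(Xtr, ytr)
        return clf

    pool = screen_table.to_numpy(float) if screen_table is not None else X

    def _fold_features(tr: np.ndarray) -> np.ndarray:
        """Columns of ``pool`` passing the Welch screen on fold-train rows."""
        if screen_table is None:
            return np.arange(X.shape[1])
        keep = []
        for j in range(pool.shape[1]):
            col = pool[tr, j]
            if np.std(col) == 0:
                continue
            _, pv = _welch(col, y[tr])
            if np.isfinite(pv) and pv < screen_alpha:
                keep.append(j)
        return np.array(keep, dtype=int)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    dev = np.zeros((n_folds, len(lambdas)))
    eps = 1e-12
    for f, (tr, te) in enumerate(folds):
        cols = _fold_features(tr)
        for li, lam in enumerate(lambdas):
            if len(cols) == 0:
                prob = np.full(len(te), np.clip(y[tr].mean(), eps, 1 - eps))
            else:
                clf = _fit(pool[np.ix_(tr, cols)], y[tr], lam)
                prob = np.clip(
                    clf.predict_proba(pool[np.ix_(te, cols)])[:, 1], eps, 1 - eps
                )
            dev[f, li] = -2.0 * np.mean(
                y[te] * np.log(prob) + (1 - y[te]) * np.log(1 - prob)
            )
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(mean_dev))
    within = np.where(mean_dev <= mean_dev[i_min] + se_dev[i_min])[0]
    i_1se = int(within[0])  # grid is descending in λ; first index = largest λ

    path_coefs = np.vstack(
        [_fit(X, y, lam).coef_.ravel() for lam in lambdas]
    )

    def _survivors(i: int) -> list[str]:
        nz = np.abs(path_coefs[i]) > 0
        return [c for c, keep in zip(table.columns, nz) if keep]

    chosen, rule = i_1se, "1se"
    survivors = _survivors(chosen)
    if not survivors:
        # null_deviance: the all-zero top of the grid is the intercept-only fit
        beats_null = mean_dev[i_min] < mean_dev[0] - se_dev[i_min]
        if beats_null:
            chosen, rule = i_min, "lambda_min_fallback"
            survivors = _survivors(chosen)
            if not survivors:
                raise RuntimeError(
                    "LASSO selected no features even at lambda_min despite "
                    "CV evidence of signal; "
                    f"lambda grid [{lambdas[-1]:.3g}, {lambdas[0]:.3g}], "
                    f"min CV deviance {mean_dev[i_min]:.3f} vs null {mean_dev[0]:.3f}"
                )
        else:
            rule = "1se_empty_null_data"
    dropped = {c: "zero LASSO coefficient" for c in table.columns if c not in survivors}
    extras = {
        "lambdas": lambdas.tolist(),
        "cv_mean_deviance": mean_dev.tolist(),
        "cv_se_deviance": se_dev.tolist(),
        "coefficients_path": path_coefs.tolist(),
        "lambda_chosen": float(lambdas[chosen]),
        "rule": rule,
        "seed": seed,
    }
    return SelectionStage("lasso", survivors, dropped, extras)


def run_selection(
    table_r1: pd.DataFrame,
    table_r2: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    icc_threshold: float = 0.75,
    pearson_threshold: float = 0.9,
    alpha: float = 0.05,
    n_folds: int = 5,
) -> tuple[SelectionReport, Scaler, pd.DataFrame]:
    """Full cascade ICC → z-score → Pearson → t-test → LASSO on the training
    split; returns the report, the fitted scaler, and the standardized
    training table restricted to the selected features."""
    report = SelectionReport(seed=seed)
    stage1 = icc_filter(table_r1, table_r2, icc_threshold)
    report.stages.append(stage1)
    t = table_r1[stage1.survivors]

    scaler, stage2 = zscore_fit(t)
    report.stages.append(stage2)
    tz = zscore_apply(scaler, t)

    stage3 = pearson_prune(tz, labels, pearson_threshold)
    report.stages.append(stage3)
    tz = tz[stage3.survivors]
    table_pre_ttest = tz

    stage4 = ttest_filter(tz, labels, alpha)
    report.stages.append(stage4)
    tz = tz[stage4.survivors]

    if stage4.survivors:
        try:
            # pass the pre-t-test pool so the screen is repeated within the
            # lambda-selection CV folds (keeps the CV free of screening bias)
            stage5 = lasso_select(
                tz, labels, n_folds=n_folds, seed=seed,
                screen_table=table_pre_ttest, screen_alpha=alpha,
            )
        except RuntimeError as exc:  # all-zero even at lambda_min (null data)
            stage5 = SelectionStage(
                "lasso",
                [],
                {c: "zero LASSO coefficient" for c in stage4.survivors},
                {"rule": "empty_at_lambda_min", "diagnostics": str(exc)},
            )
    else:
        stage5 = SelectionStage("lasso", [], {}, {"rule": "skipped: no t-test survivors"})
    report.stages.append(stage5)
    return report, scaler, tz[stage5.survivors]
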