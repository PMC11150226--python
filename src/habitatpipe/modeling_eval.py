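"""SVM models, the full metric panel, survival stratification and DCA.

The positive class is the *non-responder* (progression before 6 months), so
the model output reads as progression risk.  RBF-kernel SVMs are tuned by
stratified five-fold cross-validated AUC over a log grid, refitted on the
full training split with Platt-scaled probabilities.  Test-set metrics are
computed at the training-derived Youden cutoff; the same cutoff splits
patients into high/low-risk groups for Kaplan–Meier curves and log-rank
tests.  AUC confidence intervals come from a stratified bootstrap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .synthetic_cohort import OutcomeRecord

__all__ = [
    "ModelBundle",
    "MetricPanel",
    "SurvivalStrata",
    "train_svm",
    "fuse_features",
    "metric_panel",
    "youden_cutoff",
    "km_logrank",
    "decision_curve",
    "evaluate",
]

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (0.001, 0.01, 0.1, 1.0)


@dataclass
class ModelBundle:
    """A fitted classifier with its provenance: selected features, the SVM,
    hyperparameters, the training Youden cutoff and the source tag
    (habitat1..5 / whole / DL / fusions).  ``svm=None`` marks the degenerate
    no-information model (constant score = training prevalence) used when the
    selection cascade retains nothing."""

    features: list[str]
    svm: object | None  # calibrated SVC, exposing predict_proba
    params: dict
    cutoff: float
    seed: int
    source: str = ""
    cv_auc: float = float("nan")
    prevalence: float = 0.5

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        if self.svm is None:
            return np.full(len(table), self.prevalence)
        missing = [c for c in self.features if c not in table.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        return self.svm.predict_proba(table[self.features].to_numpy(float))[:, 1]


@dataclass
class MetricPanel:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    auc_ci: tuple[float, float]
    mcc: float
    plr: float
    nlr: float
    notes: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "auc": self.auc,
            "auc_ci_low": self.auc_ci[0], "auc_ci_high": self.auc_ci[1],
            "mcc": self.mcc, "plr": self.plr, "nlr": self.nlr,
        }
        return d


@dataclass
class SurvivalStrata:
    groups: np.ndarray  # "high" / "low" per patient
    curves: dict  # endpoint -> group -> dict(times, survival, at_risk)
    logrank: dict  # endpoint -> dict(chi2, p)


def train_svm(
    train_features: pd.DataFrame,
    labels: np.ndarray,
    c_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    n_folds: int = 5,
    seed: int = 0,
    source: str = "",
) -> ModelBundle:
    """RBF SVM with (C, γ) chosen by mean stratified 5-fold CV AUC, refit on
    the full training split with Platt scaling; the cutoff is the training
    Youden point.  Grid ties break toward the first (smallest C, then γ)."""
    X = train_features.to_numpy(float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are degenerate (single class)")
    counts = np.bincount(y, minlength=2)
    folds = min(n_folds, int(counts.min()))
    if folds < 2:
        raise ValueError("need >= 2 patients per class for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    best = None
    for C in c_grid:
        for gamma in gamma_grid:
            aucs = []
            for tr, te in splits:
                clf = SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)
                clf.fit(X[tr], y[tr])
                scores = clf.decision_function(X[te])
                if len(np.unique(y[te])) < 2:
                    continue
                aucs.append(roc_auc_score(y[te], scores))
            mean_auc = float(np.mean(aucs)) if aucs else 0.5
            if best is None or mean_auc > best[0] + 1e-12:
                best = (mean_auc, C, gamma)
    cv_auc, C, gamma = best
    # Platt-scaled probabilities: sigmoid calibration on cross-validated
    # decision values, final SVC refit on the full training split
    svm = CalibratedClassifierCV(
        SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed),
        method="sigmoid", cv=folds, ensemble=False,
    )
    svm.fit(X, y)
    train_scores = svm.predict_proba(X)[:, 1]
    cutoff = youden_cutoff(train_scores, y)
    return ModelBundle(
        features=list(train_features.columns),
        svm=svm,
        params={"kernel": "rbf", "C": C, "gamma": gamma, "n_folds": folds},
        cutoff=cutoff,
        seed=seed,
        source=source,
        cv_auc=cv_auc,
        prevalence=float(y.mean()),
    )


def null_model(labels: np.ndarray, source: str = "", seed: int = 0) -> ModelBundle:
    """No-information fallback when feature selection retains nothing."""
    y = np.asarray(labels).astype(int)
    return ModelBundle(
        features=[], svm=None, params={"kind": "no_information"},
        cutoff=0.5, seed=seed, source=source, prevalence=float(y.mean()),
    )


def fuse_features(tables: list[pd.DataFrame], prefixes: list[str] | None = None
                  ) -> pd.DataFrame:
    """Column-concatenate feature tables over the same patients, prefixing
    duplicate-prone sources; the selection cascade is re-run downstream on
    the fused pool."""
    if not tables:
        raise ValueError("no tables to fuse")
    index = tables[0].index
    for t in tables[1:]:
        if not t.index.equals(index):
            raise ValueError("fused tables must cover the same patients")
    parts = []
    for i, t in enumerate(tables):
        pre = prefixes[i] if prefixes else None
        parts.append(t.add_prefix(pre + "__") if pre else t)
    out = pd.concat(parts, axis=1)
    if out.columns.duplicated().any():
        raise ValueError("fused table has duplicate column names; use prefixes")
    return out


def _confusion(scores: np.ndarray, labels: np.ndarray, cutoff: float):
    pred = np.asarray(scores) >= cutoff
    y = np.asarray(labels).astype(bool)
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    return tp, fp, fn, tn


def metric_panel(
    scores: np.ndarray,
    labels: np.ndarray,
    cutoff: float,
    n_boot: int = 2000,
    seed: int = 0,
) -> MetricPanel:
    """Confusion-matrix metrics at ``cutoff`` plus trapezoidal AUC with a
    stratified-bootstrap 95% CI.  Undefined ratios surface as NaN with a
    reason in ``notes``."""
    scores = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    tp, fp, fn, tn = _confusion(scores, y, cutoff)
    n = tp + fp + fn + tn
    notes: dict = {"confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn}}

    def _ratio(num, den, name):
        if den == 0:
            notes[name] = "undefined: zero denominator"
            return float("nan")
        return num / den

    accuracy = (tp + tn) / n
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")  # sensitivity
    specificity = _ratio(tn, tn + fp, "specificity")
    f1 = (
        2 * precision * recall / (precision + recall)
        if np.isfinite(precision) and np.isfinite(recall) and (precision + recall) > 0
        else float("nan")
    )
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else float("nan")
    if np.isfinite(specificity) and specificity < 1:
        plr = recall / (1 - specificity)
    else:
        plr = float("nan")
        notes["plr"] = "undefined: specificity is 1 (no false positives)"
    if np.isfinite(specificity) and specificity > 0:
        nlr = (1 - recall) / specificity
    else:
        nlr = float("nan")
        notes["nlr"] = "undefined: specificity is 0"

    if len(np.unique(y)) < 2:
        auc, ci = float("nan"), (float("nan"), float("nan"))
        notes["auc"] = "undefined: single class"
    else:
        auc = float(roc_auc_score(y, scores))
        rng = np.random.default_rng(seed)
        pos = np.where(y == 1)[0]
        neg = np.where(y == 0)[0]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bi = np.concatenate(
                [rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
            )
            boots[b] = roc_auc_score(y[bi], scores[bi])
        ci = tuple(np.percentile(boots, [2.5, 97.5]).tolist())
    return MetricPanel(accuracy, precision, recall, f1, auc, ci, mcc, plr, nlr, notes)


def youden_cutoff(train_scores: np.ndarray, train_labels: np.ndarray) -> float:
    """Cutoff maximizing J = sensitivity + specificity − 1 on the training
    ROC, scanning the empirical score values; ties resolve to the lowest
    cutoff."""
    scores = np.asarray(train_scores, float)
    y = np.asarray(train_labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    best_j, best_c = -np.inf, None
    for c in np.unique(scores):  # ascending
        tp, fp, fn, tn = _confusion(scores, y, c)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, float(c)
    return best_c


def km_logrank(records: list[OutcomeRecord], groups: np.ndarray) -> SurvivalStrata:
    """Kaplan–Meier curves per risk group for PFS and OS, with the two-group
    log-rank test (χ², 1 df).  With a single group the test is skipped."""
    groups = np.asarray(groups)
    endpoints = {
        "pfs": (np.array([r.pfs_months for r in records]),
                np.array([r.pfs_event for r in records], dtype=bool)),
        "os": (np.array([r.os_months for r in records]),
               np.array([r.os_event for r in records], dtype=bool)),
    }
    uniq = [g for g in ("high", "low") if (groups == g).any()] or list(np.unique(groups))
    curves: dict = {}
    lr: dict = {}
    for ep, (times, events) in endpoints.items():
        if not events.any():
            pass  # KM still defined: S(t) = 1 everywhere
        curves[ep] = {}
        for g in uniq:
            sel = groups == g
            kmf = KaplanMeierFitter()
            kmf.fit(times[sel], events[sel])
            sf = kmf.survival_function_
            curves[ep][str(g)] = {
                "times": sf.index.to_numpy().tolist(),
                "survival": sf.iloc[:, 0].to_numpy().tolist(),
                "at_risk": kmf.event_table["at_risk"].to_numpy().tolist(),
            }
        if len(uniq) == 2:
            a, b = (groups == uniq[0]), (groups == uniq[1])
            res = logrank_test(times[a], times[b], events[a], events[b])
            lr[ep] = {"chi2": float(res.test_statistic), "p": float(res.p_value)}
        else:
            lr[ep] = {"chi2": float("nan"), "p": float("nan"), "note": "single group"}
    return SurvivalStrata(groups=groups, curves=curves, logrank=lr)


def decision_curve(
    scores: np.ndarray, labels: np.ndarray, thresholds: np.ndarray | None = None
) -> pd.DataFrame:
    """Decision-curve analysis: net benefit ``TP/N − FP/N · t/(1−t)`` for the
    model plus treat-all and treat-none references on a threshold grid."""
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.99, 99)
    thresholds = np.asarray(thresholds, float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    y = np.asarray(labels).astype(int)
    n = len(y)
    prev = y.mean()
    rows = []
    for t in thresholds:
        tp, fp, _, _ = _confusion(np.asarray(scores), y, t)
        odds = t / (1 - t)
        rows.append(
            {
                "threshold": t,
                "net_benefit": tp / n - fp / n * odds,
                "treat_all": prev - (1 - prev) * odds,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


def evaluate(
    bundle: ModelBundle,
    test_features: pd.DataFrame,
    test_labels: np.ndarray,
    test_records: list[OutcomeRecord] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Full test-set evaluation at the training cutoff: metric panel, ROC and
    DCA curves, and (when outcome records are given) KM strata with log-rank
    tests for PFS and OS.  Returns a JSON-serializable report."""
    scores = bundle.predict_proba(test_features)
    y = np.asarray(test_labels).astype(int)
    panel = metric_panel(scores, y, bundle.cutoff, n_boot=n_boot, seed=seed)
    fpr, tpr, thr = roc_curve(y, scores) if len(np.unique(y)) == 2 else ([], [], [])
    report: dict = {
        "source": bundle.source,
        "cutoff": bundle.cutoff,
        "params": {k: v for k, v in bundle.params.items()},
        "cv_auc": bundle.cv_auc,
        "metrics": panel.as_dict(),
        "notes": panel.notes,
        "roc": {"fpr": list(map(float, fpr)), "tpr": list(map(float, tpr))},
        "dca": decision_curve(scores, y).to_dict(orient="list"),
        "seed": seed,
    }
    if test_records is not None:
        groups = np.where(scores >= bundle.cutoff, "high", "low")
        if len(np.unique(groups)) == 2:
            strata = km_logrank(test_records, groups)
            report["survival"] = {"curves": strata.curves, "logrank": strata.logrank}
        else:
            report["survival"] = {"note": "all patients in one risk group"}
    return report
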