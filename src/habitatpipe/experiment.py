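"""End-to-end experiment: cohort → habitats → features → selection → models.

This is the in-memory backbone used by the analysis drivers, the disk
pipeline and the test bench.  Leakage rules: the consensus choice of k, every
selection stage, scalers and SVM tuning see the *training* split only; the
test split is touched exactly once per model, at evaluation.

Per-stage seeds derive from the global seed by a documented counter scheme:
``stage_seed = (seed * 10007 + stage_offset) mod 2^31``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deep_features import ExtractorConfig, build_extractor, extract_deep_features, preprocess_roi
from .feature_selection import SelectionReport, run_selection, zscore_apply
from .habitat_mapping import (
    compute_habitat_map,
    consensus_select_k,
    entropy_map,
    habitat_masks,
    pool_cohort_voxels,
    voxel_features,
)
from .imaging_io import Mask, normalize_grayscale, resample_isotropic
from .modeling_eval import ModelBundle, evaluate, null_model, train_svm
from .radiomics import extract_region_features
from .synthetic_cohort import CohortConfig, OutcomeRecord, SyntheticPatient, generate_cohort

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "process_patient",
    "default_roster",
    "stage_seed",
    "stratified_split",
    "select_k_consensus",
    "extract_feature_tables",
    "fit_and_evaluate",
]

_STAGE_OFFSETS = {
    "cohort": 1, "split": 2, "consensus": 3, "habitats": 4,
    "deep": 5, "selection": 6, "svm": 7, "evaluate": 8, "shap": 9,
}


def stage_seed(seed: int, stage: str) -> int:
    return (seed * 10007 + _STAGE_OFFSETS[stage]) % (2**31)


@dataclass
class ExperimentConfig:
    """All stage parameters of one run; defaults follow the study conditions
    (ICC 0.75, Pearson 0.9, alpha 0.05, k scanned over 2..10, 5-fold CV)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    train_fraction: float = 2 / 3
    # habitat stage
    k_habitats: int | None = None  # None -> consensus selection on train
    k_min: int = 2
    k_max: int = 10
    n_resamples: int = 20
    item_fraction: float = 0.8
    consensus_max_items: int = 1200
    entropy_radius: int = 1
    entropy_bins: int = 32
    # features
    n_bins: int = 32
    roi_shape: tuple[int, int, int] = (32, 32, 32)
    deep_init_seed: int = 17
    # selection / modeling
    icc_threshold: float = 0.75
    pearson_threshold: float = 0.9
    ttest_alpha: float = 0.05
    n_folds: int = 5
    n_boot: int = 500
    roster: list[str] | None = None  # None -> full roster for the chosen k
    seed: int = 0


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    k_selected: int
    consensus: object | None
    train_ids: list[str]
    test_ids: list[str]
    feature_tables: dict  # source -> (train_df, test_df)
    selection_reports: dict[str, SelectionReport]
    models: dict[str, ModelBundle]
    reports: dict[str, dict]  # source -> evaluation report
    habitat_ari: dict[str, float]  # patient -> ARI vs planted truth
    labels_train: np.ndarray
    labels_test: np.ndarray

    def metrics_table(self) -> pd.DataFrame:
        rows = []
        for src, rep in self.reports.items():
            row = {"model": src, **rep["metrics"]}
            surv = rep.get("survival", {})
            if "logrank" in surv:
                row["logrank_p_pfs"] = surv["logrank"]["pfs"]["p"]
                row["logrank_p_os"] = surv["logrank"]["os"]["p"]
            rows.append(row)
        return pd.DataFrame(rows)


def default_roster(k: int) -> list[str]:
    """The model roster: one model per habitat, whole tumor and deep features,
    plus each habitat fused with deep, all habitats fused with deep, and
    whole+deep (7 single-source + 7 fused at k=5)."""
    habs = [f"habitat{i}" for i in range(1, k + 1)]
    return habs + ["whole", "DL"] + [f"{h}+DL" for h in habs] + ["all_habitat+DL", "whole+DL"]


def stratified_split(labels: np.ndarray, train_fraction: float, seed: int) -> np.ndarray:
    """Boolean train mask, stratified by class, at least 2 per class per side
    where the class size allows."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_mask = np.zeros(len(labels), dtype=bool)
    for cls in np.unique(labels):
        idx = np.where(labels == cls)[0]
        rng.shuffle(idx)
        n_tr = int(round(train_fraction * len(idx)))
        if len(idx) >= 4:
            n_tr = min(max(n_tr, 2), len(idx) - 2)
        train_mask[idx[:n_tr]] = True
    return train_mask


def process_patient(
    patient: SyntheticPatient,
    k: int,
    cfg: ExperimentConfig,
    seed: int,
    with_rater2: bool = False,
    extractor=None,
):
    """Preprocess one patient and extract all per-region features.

    Returns ``(row_r1, row_r2 | None, habitat_map)``; ``row_r2`` holds the
    rater-2 radiomics columns used by the ICC filter (training split only).
    Habitat regions for rater 2 come from an independent clustering of the
    perturbed mask at the same k; canonical intensity ordering aligns the
    habitat indices across raters.  Deep features are extracted from the
    rater-1 ROI only and pass through the ICC stage untouched.
    """

    def _one_rater(mask: Mask, include_deep: bool):
        vol_r, m_r = resample_isotropic(patient.volume, mask)
        norm = normalize_grayscale(vol_r, m_r)
        ent = entropy_map(norm, m_r, cfg.entropy_radius, cfg.entropy_bins)
        hmap = compute_habitat_map(norm, m_r, k, seed, entropy=ent)  # smooths internally
        row: dict[str, float] = {}
        for hi, (hmask, empty) in enumerate(habitat_masks(hmap), start=1):
            feats = extract_region_features(norm.data, hmask, m_r.spacing_mm, cfg.n_bins)
            row.update({f"habitat{hi}__{n}": v for n, v in feats.items()})
        whole = extract_region_features(
            norm.data, m_r.data, m_r.spacing_mm, cfg.n_bins, include_shape=True
        )
        row.update({f"whole__{n}": v for n, v in whole.items()})
        if include_deep and extractor is not None:
            tensor = preprocess_roi(norm, m_r, cfg.roi_shape)
            row.update(extract_deep_features(extractor, tensor))
        return row, hmap

    row1, hmap1 = _one_rater(patient.mask_rater1, include_deep=True)
    row2 = None
    if with_rater2:
        row2, _ = _one_rater(patient.mask_rater2, include_deep=False)
    return row1, row2, hmap1


def _ari(a: np.ndarray, b: np.ndarray) -> float:
    from sklearn.metrics import adjusted_rand_score

    sel = (a > 0) & (b > 0)
    if not sel.any():
        return float("nan")
    return float(adjusted_rand_score(a[sel], b[sel]))


def select_k_consensus(patients, train_mask, cfg: ExperimentConfig):
    """Consensus choice of the habitat count on pooled training voxels."""
    vfms = []
    for i in np.where(train_mask)[0]:
        p = patients[i]
        vol_r, m_r = resample_isotropic(p.volume, p.mask_rater1)
        norm = normalize_grayscale(vol_r, m_r)
        # consensus judges cluster-number stability on the raw voxel features;
        # the per-patient mapping additionally smooths the entropy channel
        ent = entropy_map(norm, m_r, cfg.entropy_radius, cfg.entropy_bins)
        vfms.append(voxel_features(norm, m_r, ent))
    cap = max(50, cfg.consensus_max_items // max(1, len(vfms)))
    pool = pool_cohort_voxels(vfms, max_per_patient=cap,
                              seed=stage_seed(cfg.seed, "consensus"))
    return consensus_select_k(
        pool,
        k_range=range(cfg.k_min, cfg.k_max + 1),
        n_resamples=cfg.n_resamples,
        item_fraction=cfg.item_fraction,
        seed=stage_seed(cfg.seed, "consensus"),
        max_items=cfg.consensus_max_items,
    )


def extract_feature_tables(patients, k: int, cfg: ExperimentConfig, train_mask):
    """Per-patient habitat mapping + feature extraction for the whole cohort.

    Returns ``(full, full_r2, ari)``: the rater-1 table over all patients,
    the rater-2 radiomics table over training patients, and per-patient ARI
    against the planted truth.
    """
    extractor = build_extractor(
        ExtractorConfig(input_shape=cfg.roi_shape, init_seed=cfg.deep_init_seed)
    )
    rows1, rows2, ids, r2_ids, ari = [], [], [], [], {}
    hab_seed = stage_seed(cfg.seed, "habitats")
    for i, p in enumerate(patients):
        row1, row2, hmap = process_patient(
            p, k, cfg, seed=(hab_seed + i) % 2**31,
            with_rater2=bool(train_mask[i]), extractor=extractor,
        )
        rows1.append(row1)
        ids.append(p.patient_id)
        if row2 is not None:
            rows2.append(row2)
            r2_ids.append(p.patient_id)
        ari[p.patient_id] = _ari(p.truth_habitats, hmap.labels)
    full = pd.DataFrame(rows1, index=ids)
    full_r2 = pd.DataFrame(rows2, index=r2_ids)
    return full, full_r2, ari


def _source_columns(source: str, columns: list[str]) -> list[str]:
    if source == "DL":
        return [c for c in columns if c.startswith("deep_")]
    if source == "all_habitat":
        return [c for c in columns if c.startswith("habitat")]
    return [c for c in columns if c.startswith(source + "__")]


def fit_and_evaluate(
    full: pd.DataFrame,
    full_r2: pd.DataFrame,
    labels: pd.Series,
    records: dict[str, OutcomeRecord] | None,
    train_ids: list[str],
    test_ids: list[str],
    roster: list[str],
    cfg: ExperimentConfig,
):
    """Per-source selection cascade + SVM + evaluation.

    Fused sources re-run the full cascade on the concatenated column pool.
    An empty selection degrades to the no-information model so the roster
    always evaluates.
    """
    y_train = labels.loc[train_ids].to_numpy(int)
    y_test = labels.loc[test_ids].to_numpy(int)
    records_test = [records[i] for i in test_ids] if records else None

    tables, sel_reports, models, reports = {}, {}, {}, {}
    sel_seed = stage_seed(cfg.seed, "selection")
    svm_seed = stage_seed(cfg.seed, "svm")
    eval_seed = stage_seed(cfg.seed, "evaluate")
    for source in roster:
        cols: list[str] = []
        for part in source.split("+"):
            cols.extend(_source_columns(part, list(full.columns)))
        cols = list(dict.fromkeys(cols))
        if not cols:
            continue
        tr = full.loc[train_ids, cols]
        te = full.loc[test_ids, cols]
        r2_cols = [c for c in cols if c in full_r2.columns]
        tr_r2 = full_r2.loc[train_ids, r2_cols] if r2_cols else tr.iloc[:, :0]
        tables[source] = (tr, te)

        report, scaler, tr_sel = run_selection(
            tr, tr_r2, y_train, seed=sel_seed,
            icc_threshold=cfg.icc_threshold,
            pearson_threshold=cfg.pearson_threshold,
            alpha=cfg.ttest_alpha, n_folds=cfg.n_folds,
        )
        sel_reports[source] = report
        if report.selected:
            bundle = train_svm(
                tr_sel, y_train, n_folds=cfg.n_folds, seed=svm_seed, source=source
            )
            te_sel = zscore_apply(scaler, te)[report.selected]
        else:
            bundle = null_model(y_train, source=source, seed=svm_seed)
            te_sel = te.iloc[:, :0]
        bundle.params["_scaler"] = scaler
        bundle.params["_train_selected"] = tr_sel
        models[source] = bundle
        reports[source] = evaluate(
            bundle, te_sel, y_test, records_test, n_boot=cfg.n_boot, seed=eval_seed
        )
    return tables, sel_reports, models, reports


def run_experiment(
    cfg: ExperimentConfig, patients: list[SyntheticPatient] | None = None
) -> ExperimentResult:
    """Run the full analysis on a (generated or provided) cohort."""
    if patients is None:
        patients = generate_cohort(cfg.cohort, stage_seed(cfg.seed, "cohort"))
    labels_arr = np.array([0 if p.outcome.responder else 1 for p in patients])  # 1 = non-responder
    train_mask = stratified_split(labels_arr, cfg.train_fraction, stage_seed(cfg.seed, "split"))

    consensus = None
    if cfg.k_habitats is not None:
        k = cfg.k_habitats
    else:
        consensus = select_k_consensus(patients, train_mask, cfg)
        k = consensus.k_selected

    full, full_r2, ari = extract_feature_tables(patients, k, cfg, train_mask)
    ids = list(full.index)
    labels = pd.Series(labels_arr, index=ids)
    records = {p.patient_id: p.outcome for p in patients}
    train_ids = [ids[i] for i in range(len(ids)) if train_mask[i]]
    test_ids = [ids[i] for i in range(len(ids)) if not train_mask[i]]

    roster = cfg.roster or default_roster(k)
    tables, sel_reports, models, reports = fit_and_evaluate(
        full, full_r2, labels, records, train_ids, test_ids, roster, cfg
    )
    return ExperimentResult(
        config=cfg,
        k_selected=k,
        consensus=consensus,
        train_ids=train_ids,
        test_ids=test_ids,
        feature_tables=tables,
        selection_reports=sel_reports,
        models=models,
        reports=reports,
        habitat_ari=ari,
        labels_train=labels.loc[train_ids].to_numpy(int),
        labels_test=labels.loc[test_ids].to_numpy(int),
    )
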