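import numpy as np
import pandas as pd
import pytest

from habitatpipe.modeling_eval import (
    decision_curve,
    evaluate,
    fuse_features,
    km_logrank,
    metric_panel,
    train_svm,
    youden_cutoff,
)
from habitatpipe.synthetic_cohort import OutcomeRecord

from oracles import km_product_limit_oracle, net_benefit_oracle, youden_oracle


def _toy_training(rng, n=60, informative=True):
    X = rng.normal(size=(n, 4))
    y = (X[:, 0] > 0).astype(int) if informative else (rng.random(n) < 0.5).astype(int)
    return pd.DataFrame(X, columns=list("abcd")), y


class TestTrainSVM:
    def test_separable_training_auc_one(self, rng):
        t, y = _toy_training(rng)
        t["a"] = y * 10.0  # perfectly separable
        bundle = train_svm(t, y, seed=0)
        scores = bundle.predict_proba(t)
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, scores) == 1.0
        assert 0.0 < bundle.cutoff < 1.0

    def test_same_seed_same_hyperparameters(self, rng):
        t, y = _toy_training(rng)
        a = train_svm(t, y, seed=7)
        b = train_svm(t, y, seed=7)
        assert a.params["C"] == b.params["C"]
        assert a.params["gamma"] == b.params["gamma"]
        np.testing.assert_allclose(a.predict_proba(t), b.predict_proba(t))

    def test_permuted_labels_cv_auc_near_half(self, rng):
        """Tuning on permuted labels must not fabricate signal: an unbiased
        re-estimate of the chosen configuration's CV AUC (fresh folds, so the
        winner's-curse bias of the grid maximum is removed) stays near 0.5."""
        from sklearn.metrics import roc_auc_score
        from sklearn.model_selection import StratifiedKFold
        from sklearn.svm import SVC

        t, y = _toy_training(rng, n=160, informative=False)
        bundle = train_svm(t, y, seed=1)
        X = t.to_numpy()
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=99)
        aucs = []
        for tr, te in skf.split(X, y):
            clf = SVC(kernel="rbf", C=bundle.params["C"],
                      gamma=bundle.params["gamma"], random_state=0)
            clf.fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[te], clf.decision_function(X[te])))
        assert 0.35 < np.mean(aucs) < 0.65

    def test_degenerate_labels_raise(self, rng):
        t, _ = _toy_training(rng, n=10)
        with pytest.raises(ValueError, match="degenerate|class"):
            train_svm(t, np.ones(10, dtype=int), seed=0)


class TestFuseFeatures:
    def test_prefixes_and_patient_checks(self, rng):
        a = pd.DataFrame(rng.normal(size=(5, 2)), columns=["x", "y"])
        b = pd.DataFrame(rng.normal(size=(5, 2)), columns=["x", "y"])
        fused = fuse_features([a, b], prefixes=["r", "d"])
        assert list(fused.columns) == ["r__x", "r__y", "d__x", "d__y"]
        c = b.copy(); c.index = [10, 11, 12, 13, 14]
        with pytest.raises(ValueError, match="same patients"):
            fuse_features([a, c])

    def test_self_fusion_collapses_at_pearson_stage(self, rng):
        from habitatpipe.feature_selection import pearson_prune

        a = pd.DataFrame(rng.normal(size=(40, 3)), columns=["x", "y", "z"])
        fused = fuse_features([a, a], prefixes=["s1", "s2"])
        y = (rng.random(40) < 0.5).astype(int)
        stage = pearson_prune(fused, y)
        assert len(stage.survivors) == 3  # |r| = 1 duplicates collapse

    def test_default_roster_size_matches_study_design(self):
        from habitatpipe.experiment import default_roster

        roster = default_roster(5)
        assert len(roster) == 14  # 7 single-source + 7 fused
        assert "habitat4+DL" in roster and "all_habitat+DL" in roster


class TestMetricPanel:
    def test_identities_on_crafted_confusion(self):
        # TP=6, FN=2, FP=1, TN=11 at cutoff 0.5
        scores = np.array([0.9] * 6 + [0.1] * 2 + [0.8] * 1 + [0.2] * 11)
        labels = np.array([1] * 8 + [0] * 12)
        p = metric_panel(scores, labels, cutoff=0.5, n_boot=50, seed=0)
        sens, spec = 6 / 8, 11 / 12
        assert p.recall == pytest.approx(sens)
        assert p.precision == pytest.approx(6 / 7)
        assert p.f1 == pytest.approx(2 * p.precision * p.recall / (p.precision + p.recall))
        assert p.plr == pytest.approx(sens / (1 - spec))
        assert p.nlr == pytest.approx((1 - sens) / spec)
        mcc_num = 6 * 11 - 1 * 2
        mcc_den = np.sqrt(7 * 8 * 12 * 13)
        assert p.mcc == pytest.approx(mcc_num / mcc_den)

    def test_perfect_classifier(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        p = metric_panel(scores, labels, cutoff=0.5, n_boot=50, seed=0)
        assert p.auc == 1.0 and p.mcc == 1.0 and p.nlr == 0.0

    def test_undefined_ratio_flagged(self):
        scores = np.array([0.9, 0.9, 0.9])
        labels = np.array([1, 1, 0])
        p = metric_panel(scores, labels, cutoff=0.5, n_boot=50, seed=0)
        assert np.isnan(p.nlr)  # specificity 0
        assert "nlr" in p.notes

    def test_bootstrap_ci_coverage_of_true_auc(self):
        """Stratified-bootstrap 95% CI covers the true (binormal) AUC in
        roughly 88-98% of replicates at n=80 (scaled-down coverage check)."""
        from scipy.stats import norm

        mu = 1.0
        true_auc = norm.cdf(mu / np.sqrt(2))
        covered = 0
        n_rep = 100
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            scores = np.concatenate([r.normal(0, 1, 40), r.normal(mu, 1, 40)])
            labels = np.repeat([0, 1], 40)
            p = metric_panel(scores, labels, cutoff=0.5, n_boot=200, seed=rep)
            covered += p.auc_ci[0] <= true_auc <= p.auc_ci[1]
        assert 0.88 <= covered / n_rep <= 0.98

    def test_bootstrap_ci_brackets_auc(self, rng):
        scores = np.clip(rng.normal(0.5, 0.2, 200) + 0.2 * np.repeat([0, 1], 100), 0, 1)
        labels = np.repeat([0, 1], 100)
        p = metric_panel(scores, labels, cutoff=0.5, n_boot=500, seed=0)
        assert p.auc_ci[0] < p.auc < p.auc_ci[1]


class TestYouden:
    def test_separable_case(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        c = youden_cutoff(scores, labels)
        assert 0.2 < c <= 0.8

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(5):
            scores = rng.random(8)
            labels = (rng.random(8) < 0.5).astype(int)
            if len(set(labels)) < 2:
                continue
            c = youden_cutoff(scores, labels)
            j_best, c_best = youden_oracle(scores, labels)
            assert c == pytest.approx(c_best)

    def test_argmax_contract(self, rng):
        scores = rng.random(30)
        labels = (scores + rng.normal(0, 0.3, 30) > 0.5).astype(int)
        if len(set(labels)) < 2:
            labels[0] = 1 - labels[0]
        c = youden_cutoff(scores, labels)
        j_at, _ = youden_oracle(scores, labels)
        pred = scores >= c
        y = labels.astype(bool)
        j_c = (pred & y).sum() / y.sum() + (~pred & ~y).sum() / (~y).sum() - 1
        assert j_c == pytest.approx(j_at)


def _records(times, events):
    return [
        OutcomeRecord(pfs_months=t, pfs_event=e, os_months=t + 1, os_event=e,
                      responder=False)
        for t, e in zip(times, events)
    ]


class TestSurvival:
    def test_km_matches_hand_product_limit(self):
        # 6-patient set with one censored observation
        times = [2.0, 3.0, 3.0, 5.0, 8.0, 11.0]
        events = [True, True, False, True, True, True]
        strata = km_logrank(_records(times, events), np.array(["low"] * 6))
        t_or, s_or = km_product_limit_oracle(times, events)
        curve = strata.curves["pfs"]["low"]
        got = dict(zip(curve["times"], curve["survival"]))
        for t, s in zip(t_or, s_or):
            assert got[t] == pytest.approx(s)

    def test_no_events_survival_stays_one(self):
        strata = km_logrank(_records([1, 2, 3], [False] * 3), np.array(["low"] * 3))
        assert all(s == 1.0 for s in strata.curves["pfs"]["low"]["survival"])

    def test_identical_groups_logrank_p_near_one(self, rng):
        times = list(rng.exponential(10, 20))
        events = [True] * 20
        recs = _records(times + times, events + events)
        groups = np.array(["high"] * 20 + ["low"] * 20)
        strata = km_logrank(recs, groups)
        assert strata.logrank["pfs"]["p"] > 0.95

    def test_single_group_skips_logrank(self):
        strata = km_logrank(_records([1, 2], [True, True]), np.array(["low", "low"]))
        assert np.isnan(strata.logrank["pfs"]["chi2"])


class TestDecisionCurve:
    def test_treat_none_zero_and_treat_all_zero_at_prevalence(self, rng):
        labels = np.repeat([0, 1], [60, 40])  # prevalence 0.4
        scores = rng.random(100)
        dca = decision_curve(scores, labels, thresholds=np.array([0.2, 0.4, 0.6]))
        assert (dca["treat_none"] == 0).all()
        at_prev = dca.loc[dca["threshold"] == 0.4, "treat_all"].iloc[0]
        assert at_prev == pytest.approx(0.0)

    def test_matches_confusion_matrix_oracle(self, rng):
        labels = (rng.random(50) < 0.5).astype(int)
        scores = rng.random(50)
        grid = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        dca = decision_curve(scores, labels, thresholds=grid)
        for _, row in dca.iterrows():
            assert row["net_benefit"] == pytest.approx(
                net_benefit_oracle(scores, labels, row["threshold"])
            )

    def test_threshold_one_rejected(self, rng):
        with pytest.raises(ValueError, match="inside"):
            decision_curve(rng.random(10), (rng.random(10) < 0.5).astype(int),
                           thresholds=np.array([0.5, 1.0]))


class TestEvaluate:
    def test_report_schema_and_feature_mismatch(self, rng):
        t, y = _toy_training(rng, n=80)
        bundle = train_svm(t, y, seed=0)
        test_t, test_y = _toy_training(rng, n=30)
        recs = _records(list(rng.exponential(8, 30)), [True] * 30)
        rep = evaluate(bundle, test_t, test_y, recs, n_boot=50, seed=0)
        for key in ("metrics", "roc", "dca", "cutoff", "survival", "source"):
            assert key in rep
        assert set(rep["metrics"]) >= {"accuracy", "auc", "mcc", "plr", "nlr"}
        with pytest.raises(ValueError, match="missing feature"):
            bundle.predict_proba(test_t[["a", "b"]])

    def test_resubstitution_not_worse_than_cv(self, rng):
        """Training-set (resubstitution) AUC should on average beat the
        cross-validated AUC — the classic optimism direction."""
        from sklearn.metrics import roc_auc_score

        diffs = []
        for s in range(5):
            rng_l = np.random.default_rng(s)
            X = rng_l.normal(size=(60, 4))
            y = (X[:, 0] + rng_l.normal(0, 1.2, 60) > 0).astype(int)
            t = pd.DataFrame(X, columns=list("abcd"))
            bundle = train_svm(t, y, seed=s)
            resub = roc_auc_score(y, bundle.predict_proba(t))
            diffs.append(resub - bundle.cv_auc)
        assert np.mean(diffs) > 0
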