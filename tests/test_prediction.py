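"""Patient-level folds, class balancing, per-fold selection, CV metrics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import precision_recall_fscore_support

from conftest import make_observations
from sleepvoice.prediction import (BalancingRule, FoldError, aggregate,
                                   apply_fold_rule, balance_training,
                                   bootstrap_cis, fold_metrics_frame,
                                   metrics_from_predictions, plan_folds,
                                   plan_folds_unstratified, run_skcv,
                                   select_features_per_fold)
from sleepvoice.util import round_half_up


def patient_table(n_patients, rows_each=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        for _ in range(rows_each):
            rows.append(dict(participant_id=f"P{i:02d}",
                             sleepiness=int(rng.integers(1, 5)),
                             vrt_seconds=float(rng.lognormal(0.4, 0.7))))
    return pd.DataFrame(rows)


def fold_distribution(table, plan):
    dists = []
    for f in plan.folds:
        sub = table[table["participant_id"].isin(f.test_patient_ids)]
        dists.append(sub["sleepiness"].value_counts(normalize=True)
                     .reindex([1, 2, 3, 4], fill_value=0.0).to_numpy())
    return dists


def max_pairwise_l1(dists):
    worst = 0.0
    for i in range(len(dists)):
        for j in range(i + 1, len(dists)):
            worst = max(worst, np.abs(dists[i] - dists[j]).sum())
    return worst


class TestPlanFolds:
    def test_four_patients_one_per_fold(self):
        plan = plan_folds(patient_table(4), k=4, seed=0)
        for f in plan.folds:
            assert len(f.test_patient_ids) == 1
            assert len(f.train_patient_ids) == 3

    def test_sixteen_patients_partition(self):
        t = patient_table(16)
        plan = plan_folds(t, k=4, seed=1)
        test_sets = [set(f.test_patient_ids) for f in plan.folds]
        assert all(len(s) == 4 for s in test_sets)
        assert set().union(*test_sets) == set(t["participant_id"])
        for a, b in zip(test_sets, test_sets[1:]):
            assert not a & b

    def test_no_leakage_across_seeds(self):
        t = patient_table(12, seed=5)
        for seed in range(20):
            plan = plan_folds(t, k=4, seed=seed)
            for f in plan.folds:
                assert not set(f.train_patient_ids) & set(f.test_patient_ids)

    def test_stratification_beats_random_on_average(self):
        """Over 100 seeds, stratified fold planning yields (on average) no
        worse a max pairwise L1 distance between fold-level sleepiness
        distributions than unstratified planning."""
        t = patient_table(16, rows_each=12, seed=3)
        strat, rand = [], []
        for seed in range(100):
            strat.append(max_pairwise_l1(
                fold_distribution(t, plan_folds(t, 4, seed))))
            rand.append(max_pairwise_l1(
                fold_distribution(t, plan_folds_unstratified(t, 4, seed))))
        assert np.mean(strat) <= np.mean(rand)

    def test_too_few_patients_rejected(self):
        with pytest.raises(FoldError):
            plan_folds(patient_table(3), k=4, seed=0)

    def test_deterministic(self):
        t = patient_table(10)
        assert plan_folds(t, 4, 7).as_dict() == plan_folds(t, 4, 7).as_dict()


class TestBalancing:
    def class_table(self, counts):
        rows = []
        for cls, n in counts.items():
            for i in range(n):
                rows.append(dict(participant_id=f"P{i % 7}",
                                 sleepiness=cls, x=float(i)))
        return pd.DataFrame(rows)

    def test_floor_and_cap_rule(self):
        """Counts {1:100, 2:300, 3:700} with floor 180 / cap 500:
        class 1 skipped, class 2 kept, class 3 downsampled to 500."""
        t = self.class_table({1: 100, 2: 300, 3: 700})
        out, ledger = balance_training(t, BalancingRule(180, 500, seed=0))
        counts = out["sleepiness"].value_counts().to_dict()
        assert counts == {2: 300, 3: 500}
        led = ledger.set_index("class_label")
        assert led.loc[1, "action"] == "skipped"
        assert led.loc[3, "action"] == "downsampled"

    def test_within_band_is_identity(self):
        t = self.class_table({1: 200, 2: 400})
        out, _ = balance_training(t, BalancingRule(180, 500, seed=0))
        pd.testing.assert_frame_equal(out, t)

    def test_downsample_is_subset_no_synthesis(self):
        t = self.class_table({1: 900})
        for seed in range(5):
            out, _ = balance_training(t, BalancingRule(0, 500, seed=seed))
            assert len(out) == 500
            assert set(out.index) <= set(t.index)

    def test_ledger_conservation(self, rng):
        t = self.class_table({1: int(rng.integers(50, 900)),
                              2: int(rng.integers(50, 900)),
                              3: int(rng.integers(50, 900))})
        _, ledger = balance_training(t, BalancingRule(180, 500, seed=1))
        assert (ledger["original"] == ledger["kept"] + ledger["removed"]).all()
        assert ledger["original"].sum() == len(t)

    def test_all_skipped_raises(self):
        t = self.class_table({1: 10, 2: 20})
        with pytest.raises(FoldError, match="empty"):
            balance_training(t, BalancingRule(180, 500))

    def test_floor_above_cap_rejected(self):
        with pytest.raises(ValueError):
            BalancingRule(600, 500)


class TestFoldFeatureRule:
    def test_below_cutoff_everywhere_removed(self):
        retained, removed = apply_fold_rule({"x": [5, 8, 3, 1]}, cutoff=20)
        assert removed == ("x",)

    def test_above_cutoff_in_one_fold_retained(self):
        retained, removed = apply_fold_rule({"y": [5, 25, 3, 1]}, cutoff=20)
        assert retained == ("y",)

    def test_planted_strong_predictor_always_retained(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 240
            level = rng.integers(1, 5, n)
            df = pd.DataFrame({
                "participant_id": [f"P{i % 8}" for i in range(n)],
                "sleepiness": level,
                "strong": level + 0.1 * rng.standard_normal(n),
                "noise": rng.standard_normal(n)})
            train_sets = [df.iloc[i::4] for i in range(4)]
            retained, _ = select_features_per_fold(
                train_sets, candidates=("strong", "noise"), cutoff=1.0,
                n_trees=50, seed=seed)
            assert "strong" in retained


class TestMetrics:
    def test_binary_collapse_closed_form(self):
        """All-positive predictions at prevalence 0.76: accuracy=0.76,
        precision=0.76, recall=1.00, F1=2*0.76/1.76."""
        y_true = np.array([2] * 76 + [1] * 24)
        y_pred = np.full(100, 3)
        m = metrics_from_predictions(y_true, y_pred, "binary-collapse",
                                     positive_threshold=2)
        assert m["accuracy"] == pytest.approx(0.76)
        assert m["precision"] == pytest.approx(0.76)
        assert m["recall"] == pytest.approx(1.0)
        assert m["f1"] == pytest.approx(2 * 0.76 / 1.76)

    @pytest.mark.parametrize("mode", ["macro", "weighted"])
    def test_matches_sklearn_averaging(self, mode, rng):
        for _ in range(20):
            y_true = rng.integers(1, 5, 120)
            y_pred = rng.integers(1, 5, 120)
            ours = metrics_from_predictions(y_true, y_pred, mode)
            p, r, f1, _ = precision_recall_fscore_support(
                y_true, y_pred, average=mode, zero_division=0,
                labels=[1, 2, 3, 4])
            assert ours["precision"] == pytest.approx(p, abs=1e-12)
            assert ours["recall"] == pytest.approx(r, abs=1e-12)
            assert ours["f1"] == pytest.approx(f1, abs=1e-12)
            assert ours["accuracy"] == pytest.approx(
                np.mean(y_true == y_pred))

    def test_perfect_predictions_all_ones(self):
        y = np.array([1, 2, 3, 4] * 10)
        m = metrics_from_predictions(y, y, "macro")
        assert all(v == 1.0 for v in m.values())

    def test_bootstrap_ci_degenerate_at_perfect_agreement(self, rng):
        y = rng.integers(1, 5, 50)
        cis = bootstrap_cis(y, y.copy(), "macro", b=100, seed=0)
        assert cis["accuracy"] == (1.0, 1.0)
        assert cis["f1"] == (1.0, 1.0)

    def test_bootstrap_ci_covers_true_agreement_rate(self):
        """Bernoulli(p) agreement, n=200: the 95% percentile CI for
        accuracy covers p in >=90% of 500 replicates."""
        p_true = 0.7
        rng = np.random.default_rng(99)
        covered = 0
        reps = 500
        for _ in range(reps):
            agree = rng.random(200) < p_true
            y_true = np.ones(200, dtype=int)
            y_pred = np.where(agree, 1, 2)
            cis = bootstrap_cis(y_true, y_pred, "macro", b=300,
                                seed=int(rng.integers(2**31)))
            lo, hi = cis["accuracy"]
            covered += lo <= p_true <= hi
        assert covered / reps >= 0.90


class TestRunSkcv:
    def test_perfect_feature_yields_perfect_fold_metrics(self):
        t = patient_table(8, rows_each=30, seed=2)
        t["oracle"] = t["sleepiness"].astype(float)
        plan = plan_folds(t, k=4, seed=0)
        fms = run_skcv(t, plan, BalancingRule(0, 10_000),
                       features=("oracle",), bootstrap=50,
                       rf_params={"n_estimators": 50}, seed=0)
        for fm in fms:
            assert fm.accuracy == fm.precision == fm.recall == fm.f1 == 1.0
            assert fm.cis["f1"] == (1.0, 1.0)

    def test_determinism(self):
        t = patient_table(8, rows_each=20, seed=4)
        plan = plan_folds(t, k=4, seed=3)
        kw = dict(rule=BalancingRule(0, 10_000), features=("vrt_seconds",),
                  bootstrap=50, rf_params={"n_estimators": 30}, seed=9)
        a = fold_metrics_frame(run_skcv(t, plan, **kw))
        b = fold_metrics_frame(run_skcv(t, plan, **kw))
        pd.testing.assert_frame_equal(a, b)

    def test_skipped_class_rows_stay_in_test(self):
        """The floor rule removes a class from training only; its test rows
        still count (and depress recall)."""
        t = patient_table(8, rows_each=40, seed=6)
        plan = plan_folds(t, k=4, seed=0)
        fms = run_skcv(t, plan, BalancingRule(60, 10_000),
                       features=("vrt_seconds",), bootstrap=20,
                       rf_params={"n_estimators": 20}, seed=1)
        for f, fm in zip(plan.folds, fms):
            n_expected = (t["participant_id"].isin(f.test_patient_ids)).sum()
            assert fm.n_test == n_expected

    def test_plan_not_covering_table_rejected(self):
        t = patient_table(8, rows_each=5)
        plan = plan_folds(t.iloc[:20], k=4, seed=0)
        with pytest.raises(FoldError, match="cover"):
            run_skcv(t, plan, BalancingRule(0, 100),
                     features=("vrt_seconds",), bootstrap=10)


class TestAggregate:
    def test_reported_fold_table_aggregation(self):
        """The four printed fold rows aggregate to 0.64+/-0.09 accuracy,
        0.73+/-0.04 precision, 0.84+/-0.11 recall, 0.80+/-0.08 F1."""
        folds = [
            dict(accuracy=0.76, precision=0.76, recall=1.00, f1=0.90),
            dict(accuracy=0.58, precision=0.70, recall=0.80, f1=0.80),
            dict(accuracy=0.56, precision=0.76, recall=0.79, f1=0.80),
            dict(accuracy=0.65, precision=0.68, recall=0.75, f1=0.70),
        ]
        agg = aggregate(folds).as_dict()
        expected = dict(accuracy=(0.64, 0.09), precision=(0.73, 0.04),
                        recall=(0.84, 0.11), f1=(0.80, 0.08))
        for metric, (mean, sd) in expected.items():
            assert round_half_up(agg[metric]["mean"], 2) == mean
            assert round_half_up(agg[metric]["sd"], 2) == sd

    def test_identical_folds_zero_sd(self):
        folds = [dict(accuracy=0.5, precision=0.5, recall=0.5, f1=0.5)] * 3
        agg = aggregate(folds).as_dict()
        assert all(v["sd"] == 0.0 for v in agg.values())

    def test_matches_manual_mean_sd(self, rng):
        vals = rng.random((4, 4))
        folds = [dict(zip(("accuracy", "precision", "recall", "f1"), row))
                 for row in vals]
        agg = aggregate(folds).as_dict()
        for j, m in enumerate(("accuracy", "precision", "recall", "f1")):
            col = vals[:, j]
            assert agg[m]["mean"] == pytest.approx(col.sum() / 4)
            assert agg[m]["sd"] == pytest.approx(
                np.sqrt(((col - col.mean()) ** 2).sum() / 3))

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            aggregate([dict(accuracy=1, precision=1, recall=1, f1=1)])
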