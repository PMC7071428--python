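import numpy as np
import pandas as pd
import pytest

from playmotion import simulate_study
from playmotion.classify import evaluate, model_to_json, train, train_cart_suite


def brute_force_auc(y_true, scores):
    """Concordant-pair counting with half credit for ties."""
    pos = [s for s, y in zip(scores, y_true) if y]
    neg = [s for s, y in zip(scores, y_true) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _frame(vm, labels, child="c1"):
    return pd.DataFrame({"child_id": child, "vm_value": vm, "intensity": labels})


class TestTrain:
    def test_separable_classes_single_root_split(self):
        vm = [1, 2, 3, 4, 5] * 8 + [21, 22, 23, 24, 25] * 8
        labels = ["SED"] * 40 + ["LPA"] * 40
        model = train(_frame(vm, labels), "one_vs_all", "SED", min_leaf=5)
        t = model.clf.tree_
        assert t.node_count == 3
        assert 5 < t.threshold[0] < 21
        assert (model.predict(vm) == (np.array(labels) == "SED")).all()

    def test_multiclass_separated_clusters_perfect_resubstitution(self):
        rng = np.random.default_rng(5)
        vm = np.concatenate(
            [rng.lognormal(np.log(m), 0.1, 80) for m in (5, 50, 500)]
        )
        labels = ["SED"] * 80 + ["LPA"] * 80 + ["MVPA"] * 80
        model = train(_frame(vm, labels), "multiclass")
        report = evaluate(model, _frame(vm, labels), n_boot=50, seed=0)
        diag = np.diag(report.confusion.to_numpy())
        assert list(diag) == [80, 80, 80]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train(_frame([1, 2, 3], ["SED"] * 3), "multiclass")

    def test_unknown_mode_and_target_rejected(self):
        df = _frame([1, 2], ["SED", "LPA"])
        with pytest.raises(ValueError):
            train(df, "bagging")
        with pytest.raises(ValueError):
            train(df, "one_vs_all", "WALK")


class TestEvaluate:
    def test_perfect_scores_auc_one_with_degenerate_ci(self):
        vm = [1.0] * 30 + [100.0] * 30
        labels = ["SED"] * 30 + ["MVPA"] * 30
        df = _frame(vm, labels)
        model = train(df, "one_vs_all", "MVPA", min_leaf=5)
        report = evaluate(model, df, n_boot=200, seed=1)
        m = report.per_class["MVPA"]
        assert m.auc == 1.0
        assert m.auc_ci == (1.0, 1.0)
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_auc_matches_brute_force_on_small_sets(self, rng):
        for _ in range(5):
            n = int(rng.integers(20, 200))
            vm = rng.lognormal(3, 1, n)
            labels = np.where(
                rng.random(n) < 1 / (1 + np.exp(-(np.log(vm) - 3))), "MVPA", "SED"
            )
            if len(set(labels)) < 2:
                continue
            df = _frame(vm, labels)
            model = train(df, "one_vs_all", "MVPA", min_leaf=5)
            report = evaluate(model, df, n_boot=10, seed=0)
            scores = model.scores(vm)
            expect = brute_force_auc(labels == "MVPA", list(scores))
            assert report.per_class["MVPA"].auc == pytest.approx(expect, abs=1e-12)

    def test_swapped_pair_toy_set_equals_pair_count(self):
        # scores mostly ordered, one positive/negative pair swapped
        y = [True] * 4 + [False] * 4
        s = [0.9, 0.8, 0.7, 0.2, 0.3, 0.1, 0.05, 0.04]
        assert brute_force_auc(y, s) == 15 / 16

    def test_sensitivity_from_confusion_table_oracle(self):
        vm = [1.0] * 20 + [5.0] * 10 + [100.0] * 30
        labels = ["SED"] * 20 + ["MVPA"] * 10 + ["MVPA"] * 30
        df = _frame(vm, labels)
        model = train(df, "one_vs_all", "MVPA", min_leaf=10)
        report = evaluate(model, df, n_boot=10, seed=0)
        pred = model.predict(vm)
        y = np.array(labels) == "MVPA"
        tp = int((pred & y).sum()); fn = int((~pred & y).sum())
        tn = int((~pred & ~y).sum()); fp = int((pred & ~y).sum())
        assert report.per_class["MVPA"].sensitivity == pytest.approx(tp / (tp + fn))
        assert report.per_class["MVPA"].specificity == pytest.approx(tn / (tn + fp))

    def test_permuted_labels_auc_near_chance_out_of_sample(self):
        """Shuffled labels carry no signal; held-out AUC is at chance.
        (Resubstitution would overstate it: a deep tree memorizes noise.)"""
        rng = np.random.default_rng(99)
        vm = rng.lognormal(3, 1, 600)
        labels = rng.permutation(["SED"] * 200 + ["LPA"] * 200 + ["MVPA"] * 200)
        df = _frame(vm, labels)
        model = train(df.iloc[:300], "one_vs_all", "MVPA")
        report = evaluate(model, df.iloc[300:], n_boot=500, seed=7)
        m = report.per_class["MVPA"]
        lo, hi = m.auc_ci
        assert lo <= 0.5 <= hi
        assert abs(m.auc - 0.5) < 0.1

    def test_bootstrap_ci_deterministic_and_shrinks_with_n(self):
        rng = np.random.default_rng(11)

        def make(n):
            vm = np.concatenate([rng.lognormal(2, 0.6, n), rng.lognormal(4, 0.6, n)])
            labels = ["SED"] * n + ["MVPA"] * n
            return _frame(vm, labels)

        small, large = make(30), make(300)
        m_small = train(small, "one_vs_all", "MVPA", min_leaf=5)
        m_large = train(large, "one_vs_all", "MVPA", min_leaf=5)
        r1 = evaluate(m_small, small, n_boot=300, seed=5)
        r2 = evaluate(m_small, small, n_boot=300, seed=5)
        assert r1.per_class["MVPA"].auc_ci == r2.per_class["MVPA"].auc_ci
        w_small = np.diff(r1.per_class["MVPA"].auc_ci)[0]
        w_large = np.diff(
            evaluate(m_large, large, n_boot=300, seed=5).per_class["MVPA"].auc_ci
        )[0]
        assert w_large < w_small

    def test_absent_class_metrics_missing(self):
        df = _frame([1.0] * 30 + [90.0] * 30, ["SED"] * 30 + ["LPA"] * 30)
        model = train(df, "multiclass", min_leaf=5)
        report = evaluate(model, df, n_boot=10, seed=0)
        assert report.per_class["MVPA"].auc is None


class TestStudyPattern:
    def test_one_vs_all_auc_at_least_multiclass(self):
        """On the synthetic 10-child study the per-class one-vs-all trees
        match or beat the shared multiclass tree, mirroring the study's
        CART >= MCART ordering."""
        df = simulate_study(seed=4)
        suite = train_cart_suite(df)
        mcart = evaluate(suite["mcart"], df, n_boot=200, seed=0)
        for cls in ("SED", "LPA", "MVPA"):
            ova = evaluate(suite[f"cart_{cls}"], df, n_boot=200, seed=0)
            auc_ova = ova.per_class[cls].auc
            auc_m = mcart.per_class[cls].auc
            lo, hi = mcart.per_class[cls].auc_ci
            assert auc_ova >= auc_m or lo <= auc_ova <= hi


def test_model_json_export_has_thresholds(tmp_path):
    df = _frame([1.0] * 30 + [90.0] * 30, ["SED"] * 30 + ["MVPA"] * 30)
    model = train(df, "one_vs_all", "MVPA", min_leaf=5)
    text = model_to_json(model, tmp_path / "m.json")
    import json

    payload = json.loads(text)
    assert payload["nodes"][0]["threshold"] is not None
    assert (tmp_path / "m.json").exists()
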