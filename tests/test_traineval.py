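import itertools

import numpy as np
import pytest

import dopplerfall as df
from dopplerfall import (
    build_experiment2_manifest,
    clustered_bootstrap_ci,
    evaluate_predictions,
    make_splits,
    paired_permutation_test,
    train_classifier,
)


@pytest.fixture(scope="module")
def manifest10():
    return build_experiment2_manifest()


class TestMakeSplits:
    def test_lnso_n1_folds(self, manifest10):
        plans = make_splits(manifest10, "LNSO", 1)
        assert len(plans) == 10
        for p in plans:
            assert len(p.held_out) == 1
            # 9 subjects x 144 trials in each training fold
            assert len(p.train_idx) == 1296
            assert len(p.test_idx) == 144

    def test_lnso_n2_partition(self, manifest10):
        plans = make_splits(manifest10, "LNSO", 2, seed=1)
        assert len(plans) == 5
        held = sorted(s for p in plans for s in p.held_out)
        assert held == sorted(manifest10["participant_id"].unique())

    def test_lnso_n3_covers_every_subject(self, manifest10):
        plans = make_splits(manifest10, "LNSO", 3, seed=1)
        assert len(plans) == 10
        held = {s for p in plans for s in p.held_out}
        assert held == set(manifest10["participant_id"].unique())

    def test_lnlo_choose_two(self, manifest10):
        plans = make_splits(manifest10, "LNLO", 2)
        assert len(plans) == 3  # C(3, 2)
        for p in plans:
            assert len(p.held_out) == 2

    def test_no_unit_leakage(self, manifest10):
        for proto, n in (("LNSO", 1), ("LNSO", 3), ("LNLO", 1), ("LNLO", 2)):
            col = "participant_id" if proto == "LNSO" else "location"
            for p in make_splits(manifest10, proto, n, seed=2):
                train_units = set(manifest10.iloc[p.train_idx][col])
                test_units = set(manifest10.iloc[p.test_idx][col])
                assert not train_units & test_units
                assert len(p.train_idx) + len(p.test_idx) == len(manifest10)

    def test_oversized_n_rejected(self, manifest10):
        with pytest.raises(ValueError):
            make_splits(manifest10, "LNSO", 10)
        with pytest.raises(ValueError):
            make_splits(manifest10, "LNLO", 3)


class TestEvaluatePredictions:
    def test_hand_built_confusion_oracle(self):
        """Confusion {fall:[9,1,0], walk:[1,8,1], breathe:[0,1,9]} checked
        against independent per-class F1 arithmetic."""
        y_true, y_pred = [], []
        table = {
            "fall": {"fall": 9, "walk": 1, "breathe": 0},
            "walk": {"fall": 1, "walk": 8, "breathe": 1},
            "breathe": {"fall": 0, "walk": 1, "breathe": 9},
        }
        for true_cls, row in table.items():
            for pred_cls, n in row.items():
                y_true += [true_cls] * n
                y_pred += [pred_cls] * n
        res = evaluate_predictions(y_true, y_pred)
        # hand arithmetic: precision = recall = 0.9, 0.8, 0.9 per class
        f1s = [2 * p * r / (p + r) for p, r in ((0.9, 0.9), (0.8, 0.8), (0.9, 0.9))]
        assert res.macro_f1 == pytest.approx(np.mean(f1s))
        assert res.false_alarm_rate == pytest.approx(1 / 20)
        assert np.allclose(res.confusion.sum(axis=1), 1.0)
        assert res.confusion[0, 0] == pytest.approx(0.9)

    def test_perfect_predictions(self):
        y = ["fall", "walk", "breathe"] * 5
        res = evaluate_predictions(y, y)
        assert res.macro_f1 == 1.0
        assert res.false_alarm_rate == 0.0
        assert res.accuracy == 1.0

    def test_always_fall_predictor(self):
        y_true = ["fall", "walk", "breathe"] * 10
        y_pred = ["fall"] * 30
        res = evaluate_predictions(y_true, y_pred)
        assert res.false_alarm_rate == 1.0
        assert res.fall_recall == 1.0

    def test_uniform_random_macro_f1_near_one_third(self):
        rng = np.random.default_rng(0)
        y_true = np.repeat(list(df.CLASSES), 1000)
        y_pred = rng.choice(list(df.CLASSES), size=3000)
        res = evaluate_predictions(y_true, y_pred)
        assert res.macro_f1 == pytest.approx(1 / 3, abs=0.05)

    def test_missing_class_warns(self):
        with pytest.warns(UserWarning, match="present classes"):
            res = evaluate_predictions(["fall", "walk"], ["fall", "walk"])
        assert res.macro_f1 == 1.0

    def test_per_subject_scores(self):
        y_true = ["fall", "walk", "breathe"] * 4
        y_pred = list(y_true)
        y_pred[0] = "walk"  # one error for subject A
        subjects = ["A"] * 6 + ["B"] * 6
        res = evaluate_predictions(y_true, y_pred, subjects=subjects)
        assert res.per_subject_macro_f1["B"] == 1.0
        assert res.per_subject_macro_f1["A"] < 1.0


class TestClusteredBootstrap:
    def test_constant_scores_give_degenerate_ci(self):
        lo, hi = clustered_bootstrap_ci([0.8] * 6, B=500, seed=0)
        assert lo == pytest.approx(0.8, abs=1e-12)
        assert hi == pytest.approx(0.8, abs=1e-12)

    def test_ci_contains_point_estimate(self, rng):
        for _ in range(10):
            scores = rng.uniform(0.3, 0.9, size=8)
            lo, hi = clustered_bootstrap_ci(scores, B=2000, seed=1)
            assert lo <= scores.mean() <= hi

    def test_wider_spread_wider_ci(self):
        base = np.array([0.5, 0.6, 0.7, 0.8, 0.9])
        lo1, hi1 = clustered_bootstrap_ci(base, B=2000, seed=2)
        spread = 0.7 + 3 * (base - 0.7)
        lo2, hi2 = clustered_bootstrap_ci(spread, B=2000, seed=2)
        assert (hi2 - lo2) > (hi1 - lo1)

    def test_deterministic_under_seed_and_accepts_dict(self):
        scores = {"P1": 0.7, "P2": 0.9, "P3": 0.5}
        assert clustered_bootstrap_ci(scores, B=1000, seed=5) == clustered_bootstrap_ci(
            scores, B=1000, seed=5
        )

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            clustered_bootstrap_ci([0.5], B=100)

    def test_matches_exhaustive_enumeration_on_toy(self):
        """With 3 subjects all 27 equally likely resamples can be
        enumerated; the Monte-Carlo percentile interval must agree."""
        scores = np.array([0.2, 0.5, 0.8])
        means = [
            np.mean([scores[i], scores[j], scores[k]])
            for i, j, k in itertools.product(range(3), repeat=3)
        ]
        lo_exact, hi_exact = np.quantile(means, [0.025, 0.975], method="inverted_cdf")
        lo, hi = clustered_bootstrap_ci(scores, B=40000, seed=0)
        assert lo == pytest.approx(lo_exact, abs=0.02)
        assert hi == pytest.approx(hi_exact, abs=0.02)


class TestPairedPermutationTest:
    def test_identical_scores_give_p_one(self):
        s = [0.7, 0.8, 0.9, 0.6]
        assert paired_permutation_test(s, s) == 1.0

    def test_minimum_p_with_ten_subjects(self):
        a = np.full(10, 0.9)
        b = np.full(10, 0.7)
        assert paired_permutation_test(a, b) == pytest.approx(2 / 1024)

    def test_exact_matches_independent_enumeration(self, rng):
        """Full sign-flip enumeration via itertools as an independent
        oracle on a 5-subject toy."""
        a = rng.uniform(0.4, 0.9, 5)
        b = rng.uniform(0.4, 0.9, 5)
        d = a - b
        obs = abs(d.mean())
        count = sum(
            abs(np.dot(signs, d)) / 5 >= obs - 1e-12
            for signs in itertools.product([-1, 1], repeat=5)
        )
        assert paired_permutation_test(a, b) == pytest.approx(count / 32)

    def test_monte_carlo_agrees_with_exact(self, rng):
        a = rng.uniform(0.5, 1.0, 10)
        b = a - rng.uniform(-0.05, 0.15, 10)
        exact = paired_permutation_test(a, b)
        mc = paired_permutation_test(a, b, n_permutations=10**6, seed=0)
        assert mc == pytest.approx(exact, abs=0.002)

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError):
            paired_permutation_test([0.1, 0.2], [0.1, 0.2, 0.3])


class TestTrainClassifier:
    def test_missing_class_rejected(self, sim_corpus):
        _, manifest, X = sim_corpus
        mask = manifest["class"] != "breathe"
        with pytest.raises(ValueError, match="breathe"):
            train_classifier(X[mask.to_numpy()], manifest["class"][mask], df.desk_config())

    def test_single_batch_overfit(self, sim_corpus):
        """Capacity smoke test: the model drives training accuracy to 1 on
        one batch within a small step budget."""
        _, manifest, X = sim_corpus
        idx = np.concatenate(
            [np.nonzero((manifest["class"] == c).to_numpy())[0][:11] for c in df.CLASSES]
        )
        cfg = df.TrainConfig(epochs=50, seed=0)
        model = train_classifier(X[idx], manifest["class"].iloc[idx], cfg)
        acc = np.mean(model.predict(X[idx]) == manifest["class"].iloc[idx])
        assert acc == 1.0

    def test_seeded_reproducibility(self, sim_corpus):
        _, manifest, X = sim_corpus
        cls = manifest["class"].to_numpy()
        idx = np.concatenate(
            [np.nonzero(cls == c)[0][:40] for c in df.CLASSES]
        )
        cfg = df.TrainConfig(epochs=3, seed=4)
        m1 = train_classifier(X[idx], cls[idx], cfg)
        m2 = train_classifier(X[idx], cls[idx], cfg)
        assert np.array_equal(m1.predict(X[:60]), m2.predict(X[:60]))

    def test_synthetic_holdout_accuracy(self, sim_corpus, trained_model):
        """Train/test on disjoint synthetic draws: the three classes are
        spectrally distinct, so held-out synthetic accuracy is near 1."""
        model, _ = trained_model
        spec = df.RandomizationSpec(seed=99)
        manifest, X = df.generate_corpus(spec, 40)
        res = df.evaluate(model, X, manifest["class"])
        assert res.accuracy > 0.95

    def test_empty_test_set_rejected(self, trained_model, sim_corpus):
        _, manifest, X = sim_corpus
        model, _ = trained_model
        with pytest.raises(ValueError):
            df.evaluate(model, X[:0], manifest["class"][:0])


@pytest.fixture(scope="module")
def tiny_pm():
    man = df.build_experiment2_manifest(3, ("A", "B"), 4, 1)
    return df.generate_pseudo_measured(df.pseudo_measured_spec(5), man)


class TestSuites:
    def test_ablation_table_schema_and_isolation(self, tiny_pm):
        """One row per condition with every fall-specific column populated;
        the linearized condition runs end to end (it differs from the full
        simulator only in the kinematic stage)."""
        pm, Xpm = tiny_pm
        cfg = df.TrainConfig(epochs=4, seed=0)
        table = df.ablation_suite(
            df.RandomizationSpec(seed=6), Xpm, pm["class"], cfg, n_per_class=15,
            conditions=("full", "no_direction_randomization", "linearized_kinematics"),
        )
        assert list(table["condition"]) == [
            "full", "no_direction_randomization", "linearized_kinematics"
        ]
        for col in ("macro_f1", "fall_precision", "fall_recall", "fall_f1",
                    "false_alarm_rate"):
            assert table[col].between(0, 1).all()

    def test_regime_suite_rows_and_sizes(self, tiny_pm):
        """Five regimes; the size-matched regime uses the requested synthetic
        count and the full regime the full corpus size."""
        pm, Xpm = tiny_pm
        cfg = df.TrainConfig(epochs=4, seed=0)
        table = df.regime_suite(
            cfg, df.RandomizationSpec(seed=6), pm, Xpm, pm["class"],
            n_sized=30, n_full=60, n_folds=2,
        )
        assert list(table["regime"]) == [
            "real_only",
            "real_plus_augmentation",
            "simulation_size_matched",
            "simulation_full",
            "sim_pretrain_real_finetune",
        ]
        sizes = dict(zip(table["regime"], table["training_size"]))
        assert sizes["simulation_size_matched"] == 30
        assert sizes["simulation_full"] == 60
        assert table["macro_f1"].between(0, 1).all()
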