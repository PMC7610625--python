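"""Classifier training, block-wise CV, AUC oracles, intensity regression."""

import numpy as np
import pytest

import tremorloop as tl
from tremorloop.decoding import ALGORITHMS, _fold_assignment, auc_trapezoid, make_estimator
from tremorloop.features import FeatureMatrix
from tremorloop.labeling import LabelSeries, TremorTarget


def pair_count_auc(scores, labels):
    """Independent oracle: (#concordant + ½ #ties) / (n1·n0)."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return conc / (len(pos) * len(neg))


def two_gaussian_features(n=200, sep=6.0, seed=0, d=4):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    y = (np.arange(n) % 2).astype(int)
    X[y == 1, 0] += sep
    fm = FeatureMatrix(X, [f"f{i}" for i in range(d)], np.zeros(n, bool))
    labels = LabelSeries(y, source="truth", task="movement")
    blocks = np.repeat(np.arange(10), n // 10)
    return fm, labels, blocks


class TestAucOracles:
    def test_trapezoid_equals_pair_counting_on_random_scores(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(10, 200)
            scores = rng.choice(np.linspace(0, 1, 11), n)  # ties likely
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            _, _, auc = auc_trapezoid(scores, labels)
            assert abs(auc - pair_count_auc(scores, labels)) <= 1e-9

    def test_hand_computed_example(self):
        _, _, auc = auc_trapezoid([0.1, 0.35, 0.4, 0.8], [0, 1, 0, 1])
        assert auc == pytest.approx(0.75, abs=1e-12)

    def test_perfect_scores_reach_corner(self):
        fpr, tpr, auc = auc_trapezoid([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0
        assert any((f == 0 and t == 1) for f, t in zip(fpr, tpr))


class TestTrainDecoder:
    def test_separable_features_train_auc_one(self):
        fm, labels, _ = two_gaussian_features()
        model = tl.train_decoder(fm, labels, "movement", "off", "svm")
        _, _, auc = auc_trapezoid(model.predict_score(fm.values), labels.labels)
        assert auc == 1.0

    def test_same_seed_same_scores(self):
        fm, labels, _ = two_gaussian_features(sep=1.0)
        m1 = tl.train_decoder(fm, labels, "movement", "off", "svm", seed=3)
        m2 = tl.train_decoder(fm, labels, "movement", "off", "svm", seed=3)
        np.testing.assert_array_equal(m1.predict_score(fm.values), m2.predict_score(fm.values))

    def test_single_class_labels_rejected(self):
        fm, labels, _ = two_gaussian_features()
        ones = LabelSeries(np.ones(fm.n_frames, int), "truth", "movement")
        with pytest.raises(tl.TremorLoopError, match="single-class"):
            tl.train_decoder(fm, ones, "movement", "off", "svm")

    def test_stim_state_firewall(self):
        """A stim-off model must ignore stim-on frames entirely."""
        fm, labels, _ = two_gaussian_features(n=200)
        stim_on = np.zeros(200, bool)
        stim_on[100:] = True
        # corrupt the stim-on frames; the off-model must not change
        corrupted = FeatureMatrix(fm.values.copy(), fm.names, fm.warmup)
        corrupted.values[stim_on] = 1e6
        m1 = tl.train_decoder(fm, labels, "movement", "off", "svm", stim_on=stim_on)
        m2 = tl.train_decoder(corrupted, labels, "movement", "off", "svm", stim_on=stim_on)
        np.testing.assert_array_equal(
            m1.predict_score(fm.values[:100]), m2.predict_score(fm.values[:100])
        )


class TestCrossValidate:
    def test_label_permutation_gives_chance_auc(self):
        fm, labels, blocks = two_gaussian_features(n=200, sep=3.0, seed=1)
        aucs = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            perm = LabelSeries(rng.permutation(labels.labels), "truth", "movement")
            try:
                rep_cv = tl.cross_validate(fm, perm, blocks, algorithm="lda")
                aucs.append(rep_cv.auc)
            except tl.TremorLoopError:
                continue
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_too_few_blocks(self):
        fm, labels, _ = two_gaussian_features(n=40)
        blocks = np.repeat([0, 1], 20)
        with pytest.raises(tl.TremorLoopError, match="blocks"):
            tl.cross_validate(fm, labels, blocks, k=5)

    def test_fold_assignment_covers_all_blocks(self):
        blocks = np.repeat(np.arange(7), 3)
        folds = _fold_assignment(blocks, 5)
        assert set(folds) == set(range(5))
        # one fold per block
        for b in range(7):
            assert len(set(folds[blocks == b])) == 1


class TestCompareAlgorithms:
    def test_every_algorithm_beats_chance_on_separable_data(self):
        fm, labels, blocks = two_gaussian_features(n=300, sep=2.0, seed=2)
        table = tl.compare_algorithms(fm, labels, blocks, algorithms=ALGORITHMS)
        assert (table["auc"] > 0.8).all()
        assert table["best"].sum() == 1

    def test_single_algorithm_flagged_best(self):
        fm, labels, blocks = two_gaussian_features()
        table = tl.compare_algorithms(fm, labels, blocks, algorithms=("nb",))
        assert len(table) == 1 and bool(table["best"].iloc[0])

    def test_tie_breaks_by_fixed_order(self):
        fm, labels, blocks = two_gaussian_features(sep=8.0)  # everyone perfect
        table = tl.compare_algorithms(fm, labels, blocks, algorithms=("knn", "svm", "dt"))
        top = table.loc[table["best"], "algorithm"].iloc[0]
        ties = table.loc[table["auc"] == table["auc"].max(), "algorithm"].tolist()
        if "svm" in ties:
            assert top == "svm"


class TestSelectModels:
    def _cells(self):
        cells = {}
        for i, task in enumerate(("movement", "posture")):
            for j, ss in enumerate(("on", "off")):
                fm, labels, blocks = two_gaussian_features(seed=10 + 2 * i + j, sep=4.0)
                cells[(task, ss)] = {
                    "features": fm, "labels": labels, "block_ids": blocks,
                    "stim_on": np.full(fm.n_frames, ss == "on"),
                }
        return cells

    def test_full_grid_yields_four_models(self):
        bundle, table = tl.select_models(self._cells(), algorithms=("svm", "nb"), k=3)
        assert set(bundle) == {(t, s) for t in ("movement", "posture") for s in ("on", "off")}
        assert all(m.algorithm in ("svm", "nb") for m in bundle.values())

    def test_missing_cell_errors(self):
        cells = self._cells()
        del cells[("posture", "on")]
        with pytest.raises(tl.TremorLoopError, match="incomplete|missing"):
            tl.select_models(cells, algorithms=("svm",), k=3)

    def test_degenerate_cell_errors(self):
        cells = self._cells()
        c = cells[("posture", "on")]
        c["labels"] = LabelSeries(np.ones(c["features"].n_frames, int), "truth", "posture")
        with pytest.raises(tl.TremorLoopError, match="incomplete"):
            tl.select_models(cells, algorithms=("svm",), k=3)

    def test_bundle_save_load_round_trip(self, tmp_path):
        bundle, _ = tl.select_models(self._cells(), algorithms=("svm",), k=3)
        path = tmp_path / "bundle.pkl"
        bundle.save(path)
        back = tl.ModelBundle.load(path)
        fm, _, _ = two_gaussian_features()
        m1 = bundle.model("movement", "off")
        m2 = back.model("movement", "off")
        np.testing.assert_array_equal(m1.predict_score(fm.values), m2.predict_score(fm.values))


class TestIntensity:
    def test_recovers_linear_function_of_one_feature(self):
        rng = np.random.default_rng(4)
        n = 300
        X = rng.standard_normal((n, 5))
        power = np.clip(5.0 + 1.5 * X[:, 2] + 0.05 * rng.standard_normal(n), 0.01, None)
        fm = FeatureMatrix(X, [f"f{i}" for i in range(5)], np.zeros(n, bool))
        target = TremorTarget(power)
        blocks = np.repeat(np.arange(10), n // 10)
        r, _, _ = tl.crossval_intensity(fm, target, blocks)
        assert r >= 0.95

    def test_constant_target_rejected(self):
        fm, _, _ = two_gaussian_features()
        with pytest.raises(tl.TremorLoopError, match="constant|degenerate"):
            tl.fit_intensity(fm, TremorTarget(np.ones(fm.n_frames)))

    def test_generator_session_intensity_beats_block_permutation_null(self):
        """LFP features predict tremor power better than block-shuffled chance."""
        from tremorloop.decoding import block_permutation_pvalue

        cfg = tl.SimConfig(seed=12)
        cell = tl.build_training_cell(cfg, "posture", "off", n_blocks=5,
                                      task_s=20.0, rest_s=20.0)
        _, target = tl.tremor_labels(cell["session"].accel)
        r, pred, actual = tl.crossval_intensity(
            cell["features"], target, cell["block_ids"], k=5
        )
        assert r > 0
        mask = cell["features"].valid()
        blocks = cell["block_ids"][mask][: len(pred)]
        p = block_permutation_pvalue(pred, actual, blocks, n_perm=99, seed=0)
        assert p < 0.05

    def test_predictions_are_nonnegative(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 3))
        target = TremorTarget(np.abs(rng.standard_normal(100)) * 1e-3)
        fm = FeatureMatrix(X, list("abc"), np.zeros(100, bool))
        model = tl.fit_intensity(fm, target)
        assert np.all(tl.predict_intensity(model, fm)[fm.valid()] >= 0)


class TestEffectSizeRecovery:
    def test_auc_falls_to_chance_without_effects_and_rises_with_snr(self):
        """Decoding is driven by the state-dependent generator effects."""
        aucs = {}
        for snr in (0.0, 1.0):
            cfg = tl.SimConfig(seed=21, snr_scale=snr)
            cell = tl.build_training_cell(cfg, "posture", "off", n_blocks=5,
                                          task_s=15.0, rest_s=15.0)
            truth = tl.LabelSeries(
                (cell["session"].truth_states.values != 0).astype(int), "truth", "posture"
            )
            rep = tl.cross_validate(cell["features"], truth, cell["block_ids"], algorithm="lda")
            aucs[snr] = rep.auc
        assert 0.4 <= aucs[0.0] <= 0.6
        assert aucs[1.0] > aucs[0.0] + 0.2
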