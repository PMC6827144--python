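import numpy as np
import pytest

from zcmm.classify import (
    ClassifyError,
    SvmConfig,
    ZcmmClassifier,
    cross_validate,
    grid_search,
    stratified_folds,
    train_svm,
)
from zcmm.features import FeatureMatrix, FeatureMode
from zcmm.synthetic import GeneratorSpec, generate_dataset


class TestSvmConfig:
    @pytest.mark.parametrize("bad", [dict(gamma=0.0), dict(cost=-1.0)])
    def test_rejects_nonpositive_hyperparameters(self, bad):
        with pytest.raises(ClassifyError):
            SvmConfig(**bad)


class TestStratifiedFolds:
    def test_exact_divisibility_balances_folds(self):
        y = np.array([1] * 100 + [-1] * 100)
        folds = stratified_folds(y, k=10, seed=1)
        for f in range(10):
            mask = folds == f
            assert (y[mask] == 1).sum() == 10 and (y[mask] == -1).sum() == 10

    def test_deterministic_given_seed(self):
        y = np.array([1] * 37 + [-1] * 41)
        assert np.array_equal(
            stratified_folds(y, 10, seed=5), stratified_folds(y, 10, seed=5)
        )

    def test_near_proportional_when_not_divisible(self):
        y = np.array([1] * 43 + [-1] * 57)
        folds = stratified_folds(y, k=10, seed=0)
        for f in range(10):
            n_pos = (y[folds == f] == 1).sum()
            assert abs(n_pos - 4.3) < 1.0

    def test_class_smaller_than_k_errors(self):
        y = np.array([1] * 5 + [-1] * 100)
        with pytest.raises(ClassifyError):
            stratified_folds(y, k=10)


class TestTrainSvm:
    def _toy(self, sep=10.0):
        rows = np.vstack([np.full((10, 1), sep), np.full((10, 1), -sep)])
        labels = np.array([1] * 10 + [-1] * 10)
        return FeatureMatrix(rows, labels, FeatureMode.ZCMM_DISTANCE)

    def test_separable_data_fits_perfectly(self):
        fm = self._toy()
        clf = train_svm(fm)
        assert (clf.predict(fm.rows) == fm.labels).all()

    def test_repeat_training_is_deterministic(self):
        fm = self._toy(sep=1.0)
        probe = np.linspace(-2, 2, 30).reshape(-1, 1)
        s1 = train_svm(fm).decision_scores(probe)
        s2 = train_svm(fm).decision_scores(probe)
        assert np.array_equal(s1, s2)

    def test_single_class_errors(self):
        rows = np.ones((5, 2))
        fm = FeatureMatrix(rows, np.ones(5, dtype=int), FeatureMode.ZCMM_DISTANCE)
        with pytest.raises(ClassifyError):
            train_svm(fm)


@pytest.fixture(scope="module")
def sep_dataset():
    return generate_dataset(GeneratorSpec(n_per_class=60, length=60, seed=202))


class TestCrossValidate:
    def test_separated_classes_score_high(self, sep_dataset):
        pos, neg = sep_dataset
        res = cross_validate(pos, neg, k=5, seed=3)
        assert res.mean.acc >= 0.85
        assert len(res.per_fold) == 5

    def test_bit_reproducible(self, sep_dataset):
        pos, neg = sep_dataset
        r1 = cross_validate(pos, neg, k=5, seed=3)
        r2 = cross_validate(pos, neg, k=5, seed=3)
        assert r1.mean == r2.mean
        assert r1.fold_model_hashes == r2.fold_model_hashes

    def test_k_exceeding_class_size_errors(self, sep_dataset):
        pos, neg = sep_dataset
        with pytest.raises(ClassifyError):
            cross_validate(pos, neg, k=61)

    def test_length_mismatch_errors(self, sep_dataset):
        pos, _ = sep_dataset
        other, _ = generate_dataset(GeneratorSpec(n_per_class=20, length=50, seed=1))
        with pytest.raises(ClassifyError):
            cross_validate(pos, other, k=5)

    def test_no_leakage_models_ignore_held_out_fold(self, sep_dataset):
        """The model fitted on the training folds must be bit-identical
        when the held-out fold's sequences are permuted (or replaced):
        nothing about the held-out part may reach model fitting."""
        from zcmm.seqio import SequenceSet

        pos, neg = sep_dataset
        y = np.array([1] * len(pos) + [-1] * len(neg))
        folds = stratified_folds(y, k=5, seed=3)
        r1 = cross_validate(pos, neg, k=5, folds=folds)

        # permute fold-0 members within each class (labels preserved)
        rng = np.random.default_rng(0)
        seqs = list(pos) + list(neg)
        new_seqs = list(seqs)
        for lab in (1, -1):
            idx = np.flatnonzero((folds == 0) & (y == lab))
            perm = rng.permutation(idx)
            for a, b in zip(idx, perm):
                new_seqs[a] = seqs[b]
        new_pos = SequenceSet(tuple(new_seqs[: len(pos)]))
        new_neg = SequenceSet(tuple(new_seqs[len(pos):]))
        r2 = cross_validate(new_pos, new_neg, k=5, folds=folds)
        # fold 0's model was fitted without its held-out part: unchanged
        assert r1.fold_model_hashes[0] == r2.fold_model_hashes[0]

    def test_shared_models_switch_builds_once(self, sep_dataset):
        pos, neg = sep_dataset
        res = cross_validate(pos, neg, k=5, seed=3, refit_per_fold=False)
        assert len(set(res.fold_model_hashes)) == 1


class TestGridSearch:
    def test_single_point_grid_returns_it(self, sep_dataset):
        pos, neg = sep_dataset
        cfg, res, table = grid_search(
            pos, neg, gamma_grid=[0.01], cost_grid=[2.0], k=5, seed=3
        )
        assert (cfg.gamma, cfg.cost) == (0.01, 2.0)
        assert len(table) == 1

    def test_argmax_and_tie_rules(self, sep_dataset, monkeypatch):
        # stub CV so the winner is known exactly
        import zcmm.classify as mod

        def fake_cv(pos, neg, config, **kw):
            from zcmm.metrics import MetricsReport

            acc = {(0.1, 1.0): 0.7, (0.1, 2.0): 0.9, (0.2, 1.0): 0.9, (0.2, 2.0): 0.6}[
                (config.gamma, config.cost)
            ]
            rep = MetricsReport(acc, acc, acc, 0.0, auc=acc)
            return mod.CvResult([rep], rep, [], config)

        monkeypatch.setattr(mod, "cross_validate", fake_cv)
        pos, neg = sep_dataset
        cfg, _, table = mod.grid_search(
            pos, neg, gamma_grid=[0.1, 0.2], cost_grid=[1.0, 2.0], k=5
        )
        # 0.9 tie between (0.1, 2.0) and (0.2, 1.0): smaller cost wins
        assert (cfg.gamma, cfg.cost) == (0.2, 1.0)
        assert len(table) == 4

    def test_empty_grid_errors(self, sep_dataset):
        pos, neg = sep_dataset
        with pytest.raises(ClassifyError):
            grid_search(pos, neg, gamma_grid=[], cost_grid=[1.0])


class TestZcmmClassifier:
    def test_fit_predict_and_archive_round_trip(self, sep_dataset, tmp_path):
        pos, neg = sep_dataset
        clf = ZcmmClassifier().fit(pos, neg)
        preds = clf.predict(list(pos)[:10])
        assert set(preds.tolist()) <= {1, -1}
        f = tmp_path / "clf.json"
        clf.save(f)
        clf2 = ZcmmClassifier.load(f)
        probe = list(pos)[:10] + list(neg)[:10]
        assert np.array_equal(clf.decision_scores(probe), clf2.decision_scores(probe))
        assert clf2.N == 60
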