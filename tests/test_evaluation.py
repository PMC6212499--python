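import numpy as np
import pytest

import arginylome as ag
from arginylome.ensemble import TrainingSet
from conftest import brute_force_auc, brute_force_kendall_tau_b


class OracleSpec:
    """Scores equal to the true labels; for CV plumbing tests."""

    def fit(self, data, seed):
        return lambda X, peptides=None: X[:, 0]


class TestAUC:
    def test_perfect_separation(self):
        assert ag.auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_partial_separation_matches_pair_counting(self):
        assert ag.auc([0.9, 0.1, 0.8, 0.2], [1, 0, 0, 1]) == 0.75

    def test_all_ties_give_half(self):
        assert ag.auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ag.auc([0.1, 0.2], [1, 1])

    def test_agrees_with_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(5, 200))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # discretized scores force ties
            scores = np.round(rng.uniform(size=n), 2)
            assert ag.auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels)
            )


class TestStratifiedKFoldCV:
    def test_folds_are_stratified_partitions(self):
        X = np.arange(40, dtype=float).reshape(20, 2)
        y = np.array([1] * 10 + [0] * 10)
        res = ag.stratified_kfold_cv(TrainingSet(X, y), k=10, seed=0, model_spec=OracleSpec())
        for fold in range(10):
            idx = res.fold_assignment == fold
            assert idx.sum() == 2
            assert y[idx].sum() == 1

    def test_oracle_model_scores_perfectly(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100)
        X = np.column_stack([y.astype(float), rng.normal(size=100)])
        res = ag.stratified_kfold_cv(TrainingSet(X, y), k=5, seed=1, model_spec=OracleSpec())
        assert res.mean_auc == 1.0
        assert res.pooled_auc == 1.0

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(5)
        y = np.array([1] * 1000 + [0] * 1000)
        X = rng.normal(size=(2000, 1))
        res = ag.stratified_kfold_cv(TrainingSet(X, y), k=10, seed=2, model_spec=OracleSpec())
        assert abs(res.mean_auc - 0.5) <= 0.04

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        y = np.array([1] * 20 + [0] * 30)
        X = rng.normal(size=(50, 4))
        X[:, 0] += y
        data = TrainingSet(X, y)
        spec = ag.LRESpec(n_members=3)
        r1 = ag.stratified_kfold_cv(data, k=5, seed=9, model_spec=spec)
        r2 = ag.stratified_kfold_cv(data, k=5, seed=9, model_spec=spec)
        assert r1.fold_aucs == r2.fold_aucs

    def test_too_few_positives_rejected(self):
        data = TrainingSet(np.zeros((10, 2)), np.array([1] * 2 + [0] * 8))
        with pytest.raises(ValueError):
            ag.stratified_kfold_cv(data, k=5, model_spec=OracleSpec())


class TestTransfer:
    def _two_sets(self, seed_a=1, seed_b=2):
        pa, _ = ag.generate_dataset(120, 240, seed=seed_a, source=ag.Source.ARRAY2)
        pb, _ = ag.generate_dataset(60, 120, seed=seed_b, source=ag.Source.LITERATURE)
        return ag.to_training_set(pa), ag.to_training_set(pb)

    def test_transfer_between_generator_draws_beats_chance(self):
        train, test = self._two_sets()
        res = ag.transfer_auc(train, test, ag.LRESpec(n_members=10), seed=0)
        assert res.auc > 0.75
        assert not res.sequence_overlap

    def test_shuffled_test_labels_near_half(self):
        train, _ = self._two_sets(3, 4)
        pb, _ = ag.generate_dataset(300, 700, seed=4, source=ag.Source.LITERATURE)
        test = ag.to_training_set(pb)
        rng = np.random.default_rng(0)
        y = rng.permutation(test.y)
        test_shuffled = TrainingSet(test.X, y, test.sources, test.peptides)
        res = ag.transfer_auc(train, test_shuffled, ag.LRESpec(n_members=10), seed=0)
        assert abs(res.auc - 0.5) <= 0.05

    def test_shared_provenance_rejected(self):
        train, _ = self._two_sets()
        with pytest.raises(ValueError, match="provenance"):
            ag.transfer_auc(train, train, ag.LRESpec(n_members=2))

    def test_sequence_overlap_flagged(self):
        train, test = self._two_sets()
        leaky = TrainingSet(
            np.vstack([test.X, train.X[:1]]),
            np.concatenate([test.y, train.y[:1]]),
            test.sources + ["literature"],
            ag.PeptideSet(list(test.peptides) + [train.peptides[0]], allow_duplicates=True),
        )
        with pytest.warns(UserWarning, match="share"):
            res = ag.transfer_auc(train, leaky, ag.LRESpec(n_members=2), seed=0)
        assert res.sequence_overlap


class TestKendallAssociation:
    def test_feature_equal_to_label_has_tau_one(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        X = np.column_stack([y.astype(float), 1.0 - y])
        res = ag.kendall_association(X, y, correction="none")
        assert res.tau.iloc[0] == pytest.approx(1.0)
        assert res.tau.iloc[1] == pytest.approx(-1.0)

    def test_known_small_example(self):
        res = ag.kendall_association(
            np.array([[1.0], [2.0], [3.0], [4.0]]), np.array([1, 3, 2, 4]),
            correction="none",
        )
        assert res.tau.iloc[0] == pytest.approx(2 / 3)

    def test_constant_feature_not_significant(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 30)
        y[0] = 1 - y[0]
        X = np.column_stack([np.ones(30), y.astype(float)])
        res = ag.kendall_association(X, y)
        assert res.p.iloc[0] == 1.0
        assert not res.significant.iloc[0]

    def test_bonferroni_is_stricter_than_uncorrected(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        X = rng.normal(size=(80, 30))
        X[:, 0] += 0.6 * y
        raw = ag.kendall_association(X, y, correction="none")
        bon = ag.kendall_association(X, y, correction="bonferroni")
        assert bon.significant.sum() <= raw.significant.sum()

    def test_agrees_with_pair_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            x = np.round(rng.normal(size=n), 1)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            res = ag.kendall_association(x[:, None], y, correction="none")
            assert res.tau.iloc[0] == pytest.approx(
                brute_force_kendall_tau_b(x, y), abs=1e-12
            )


class TestBaselines:
    def test_pure_noise_random_labels_is_null(self):
        # literature subset emptied of signal: all rows are array-tagged noise
        rng = np.random.default_rng(0)
        n = 400
        X = rng.normal(size=(n, 10))
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        base = TrainingSet(X, y, ["array2"] * n)
        res = ag.simulate_baseline(
            "random_labels", base, n_runs=20, seed=0, model_spec=OracleSpec(), k=5
        )
        assert abs(res.mean_auc - 0.5) <= 0.03

    def test_retained_genuine_positives_beat_chance(self, campaign_base):
        res = ag.simulate_baseline(
            "random_labels", campaign_base, n_runs=5, seed=1,
            model_spec=ag.LRESpec(n_members=8), k=5,
        )
        assert res.mean_auc > 0.55

    def test_single_run_reports_zero_sd(self, campaign_base):
        res = ag.simulate_baseline(
            "random_labels", campaign_base, n_runs=1, seed=2,
            model_spec=ag.LRESpec(n_members=5), k=5,
        )
        assert res.sd_auc == 0.0
        assert len(res.run_aucs) == 1

    def test_random_initial_protocol_runs_and_stays_modest(self, campaign_base):
        res = ag.simulate_baseline(
            "random_initial", campaign_base, n_runs=2, seed=3,
            model_spec=ag.LRESpec(n_members=5), k=5,
        )
        assert 0.3 <= res.mean_auc <= 0.7

    def test_unknown_protocol_rejected(self, campaign_base):
        with pytest.raises(ValueError, match="protocol"):
            ag.simulate_baseline("bogus", campaign_base, n_runs=1)
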