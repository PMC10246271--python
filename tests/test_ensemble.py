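"""Marker-ensemble training, prediction, and the performance metrics."""

import itertools
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fcmarker as fm
from fcmarker.ensemble import auc_score
from fcmarker.errors import DataValidationError, DimensionError


def _auc_pair_oracle(labels, scores):
    """Exhaustive concordant-pair count; ties worth 1/2."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_perfect_separation(self):
        m = fm.compute_metrics(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9]))
        assert (m.accuracy, m.mcc, m.auc) == (1.0, 1.0, 1.0)

    def test_mcc_direct_formula(self):
        # TP=9, TN=8, FP=2, FN=1 -> MCC = 70 / sqrt(9900)
        labels = np.array([1] * 10 + [0] * 10)
        probs = np.array([0.9] * 9 + [0.1] + [0.9] * 2 + [0.1] * 8)
        m = fm.compute_metrics(labels, probs)
        assert (m.tp, m.tn, m.fp, m.fn) == (9, 8, 2, 1)
        assert m.mcc == pytest.approx(70 / np.sqrt(9900))

    def test_auc_hand_example(self):
        # pairs: (0.9,0.7)+, (0.8,0.7)+, (0.6,0.7)- -> 2/3
        m = fm.compute_metrics(np.array([1, 1, 0, 1]), np.array([0.9, 0.8, 0.7, 0.6]))
        assert m.auc == pytest.approx(2 / 3)

    def test_one_class_auc_undefined_other_metrics_returned(self):
        m = fm.compute_metrics(np.array([1, 1, 1]), np.array([0.9, 0.4, 0.8]))
        assert np.isnan(m.auc)
        assert np.isnan(m.specificity)
        assert m.sensitivity == pytest.approx(2 / 3)
        assert m.accuracy == pytest.approx(2 / 3)

    def test_mcc_zero_when_factor_zero(self):
        m = fm.compute_metrics(np.array([0, 0, 1, 1]), np.array([0.9, 0.9, 0.9, 0.9]))
        assert m.mcc == 0.0

    def test_threshold_is_strict(self):
        m = fm.compute_metrics(np.array([1, 0]), np.array([0.5, 0.5]))
        assert m.tp == 0 and m.tn == 1  # P exactly 0.5 counts as control

    @given(
        st.lists(st.sampled_from([0, 1]), min_size=4, max_size=30).filter(
            lambda l: 0 < sum(l) < len(l)
        ),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=60, deadline=None)
    def test_auc_matches_pair_oracle(self, labels, rnd):
        scores = [round(rnd.random(), 2) for _ in labels]  # ties likely
        assert auc_score(np.array(labels), np.array(scores)) == pytest.approx(
            _auc_pair_oracle(labels, scores)
        )

    def test_mcc_symmetries(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        probs = rng.random(40)
        m = fm.compute_metrics(labels, probs)
        swapped = fm.compute_metrics(1 - labels, 1 - probs + 1e-9)
        assert swapped.mcc == pytest.approx(m.mcc, abs=1e-9)
        inverted = fm.compute_metrics(labels, 1 - probs + 1e-9)
        assert inverted.mcc == pytest.approx(-m.mcc, abs=1e-9)


class TestTraining:
    def test_classifier_count_is_folds_times_subsamples(self, tiny_harmonized):
        ens = fm.train_ensemble(tiny_harmonized, k_folds=5, n_subsamples=3, seed=2)
        assert ens.n_classifiers == 15
        assert {c.subsample_id for c in ens.classifiers} == {0, 1, 2}
        assert {c.fold_id for c in ens.classifiers} == set(range(5))

    def test_deterministic_for_fixed_seed(self, tiny_harmonized):
        a = fm.train_ensemble(tiny_harmonized, k_folds=3, n_subsamples=2, seed=9)
        b = fm.train_ensemble(tiny_harmonized, k_folds=3, n_subsamples=2, seed=9)
        for ca, cb in zip(a.classifiers, b.classifiers):
            np.testing.assert_array_equal(ca.weights, cb.weights)
        np.testing.assert_array_equal(a.oof_probability, b.oof_probability)
        c = fm.train_ensemble(tiny_harmonized, k_folds=3, n_subsamples=2, seed=10)
        assert any(
            not np.array_equal(x.weights, y.weights)
            for x, y in zip(a.classifiers, c.classifiers)
        )

    def test_planted_effect_recovered_out_of_fold(self, tiny_ensemble, tiny_harmonized):
        m = fm.compute_metrics(tiny_ensemble.diagnosis, tiny_ensemble.oof_probability)
        assert m.auc > 0.8

    def test_sparsity(self, tiny_ensemble, tiny_harmonized):
        nnz = sorted(c.n_nonzero for c in tiny_ensemble.classifiers)
        median = nnz[len(nnz) // 2]
        assert median < tiny_harmonized.n_edges / 3

    def test_permuted_labels_give_chance_auc(self, tiny_harmonized):
        rng = np.random.default_rng(123)
        perm = tiny_harmonized.with_diagnosis(rng.permutation(tiny_harmonized.diagnosis))
        ens = fm.train_ensemble(perm, k_folds=5, n_subsamples=2, seed=3)
        m = fm.compute_metrics(ens.diagnosis, ens.oof_probability)
        assert 0.35 < m.auc < 0.65

    def test_resubstitution_optimism(self, tiny_ensemble, tiny_harmonized):
        oof = fm.compute_metrics(tiny_ensemble.diagnosis, tiny_ensemble.oof_probability).auc
        resub = fm.compute_metrics(
            tiny_harmonized.diagnosis, fm.predict(tiny_ensemble, tiny_harmonized).probability
        ).auc
        assert resub >= oof

    def test_undersampling_balances_classes(self, tiny_harmonized):
        # majority class is undersampled to 1:1, so each subsample trains on
        # 2 * n_minority subjects; verify via the stratification requirement
        with pytest.raises(DataValidationError):
            fm.train_ensemble(tiny_harmonized, k_folds=30, n_subsamples=1, seed=0)

    def test_single_class_rejected(self, tiny_harmonized):
        controls = tiny_harmonized.subset(tiny_harmonized.diagnosis == 0)
        with pytest.raises(DataValidationError):
            fm.train_ensemble(controls, seed=0)


class TestPredict:
    def test_identical_classifiers_equal_single_model(self, tiny_ensemble, tiny_harmonized):
        from fcmarker.ensemble import MarkerEnsemble

        one = tiny_ensemble.classifiers[0]
        clones = MarkerEnsemble(
            classifiers=[one] * 7,
            oof_probability=tiny_ensemble.oof_probability,
            subject_ids=tiny_ensemble.subject_ids,
            diagnosis=tiny_ensemble.diagnosis,
            n_edges=tiny_ensemble.n_edges,
        )
        np.testing.assert_allclose(
            fm.predict(clones, tiny_harmonized).probability,
            one.predict_proba(tiny_harmonized.fc),
        )

    def test_dimension_mismatch(self, tiny_ensemble):
        other = fm.simulate_fc_dataset(replace(fm.default_config(seed=1), roi_count=8, n_effect_edges=5))
        with pytest.raises(DimensionError):
            fm.predict(tiny_ensemble, other)

    def test_boundary_probability_is_control(self, tiny_ensemble, tiny_harmonized):
        res = fm.predict(tiny_ensemble, tiny_harmonized)
        assert set(np.unique(res.label)) <= {0, 1}
        assert np.all((res.probability > 0.5) == (res.label == 1))


def test_ensemble_json_round_trip(tmp_path, tiny_ensemble, tiny_harmonized):
    path = tmp_path / "marker.json"
    tiny_ensemble.to_json(path)
    back = fm.MarkerEnsemble.from_json(path)
    assert back.n_classifiers == tiny_ensemble.n_classifiers
    np.testing.assert_allclose(
        fm.predict(back, tiny_harmonized).probability,
        fm.predict(tiny_ensemble, tiny_harmonized).probability,
    )
    assert back.config == tiny_ensemble.config
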