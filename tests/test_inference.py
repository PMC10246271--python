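"""Permutation nulls, discriminative-edge identification, multiplicity control."""

import numpy as np
import pytest

import fcmarker as fm
from fcmarker.inference import permutation_pvalue


TRAIN_SMALL = {"k_folds": 5, "n_subsamples": 2}


class TestPermutationPvalue:
    def test_never_zero_and_bounded(self):
        null = np.arange(99)
        assert permutation_pvalue(1000.0, null) == pytest.approx(1 / 100)
        assert permutation_pvalue(-1.0, null) == 1.0

    def test_monotone_in_observed(self):
        null = np.random.default_rng(0).normal(size=50)
        ps = [permutation_pvalue(obs, null) for obs in np.linspace(-3, 3, 20)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestHolm:
    def test_both_rejected(self):
        out = fm.holm_bonferroni({"a": 0.01, "b": 0.04}, alpha=0.05)
        assert out["a"][0] and out["b"][0]  # 0.01 < 0.025, then 0.04 < 0.05

    def test_step_down_stops_at_first_failure(self):
        out = fm.holm_bonferroni({"a": 0.03, "b": 0.04}, alpha=0.05)
        assert not out["a"][0] and not out["b"][0]  # 0.03 > 0.025 stops

    def test_single_p_reduces_to_plain_test(self):
        out = fm.holm_bonferroni({"only": 0.049}, alpha=0.05)
        assert out["only"][0]

    def test_adjusted_p_monotone(self):
        out = fm.holm_bonferroni([0.001, 0.01, 0.02, 0.9])
        adj = [p for _, p in out]
        ordered = sorted(range(4), key=lambda i: [0.001, 0.01, 0.02, 0.9][i])
        assert all(adj[ordered[i]] <= adj[ordered[i + 1]] for i in range(3))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fm.holm_bonferroni({})


class TestPerformancePermutation:
    def test_planted_signal_yields_minimal_p(self, tiny_harmonized, tiny_ensemble, tiny_family):
        val, _ = fm.harmonize(tiny_family[1])
        res = fm.performance_permutation_test(
            tiny_harmonized,
            [val],
            ensemble=tiny_ensemble,
            B=9,
            seed=7,
            train_kwargs=TRAIN_SMALL,
        )
        disc = res[tiny_harmonized.name]
        assert disc["AUC"].p == pytest.approx(1 / 10)  # observed beats all 9 nulls
        assert disc["AUC"].n_iterations == 9
        assert res[val.name]["AUC"].p <= 0.2

    def test_weak_observed_gets_large_p(self, tiny_harmonized, tiny_ensemble):
        res = fm.performance_permutation_test(
            tiny_harmonized,
            [],
            ensemble=tiny_ensemble,
            B=9,
            seed=8,
            train_kwargs=TRAIN_SMALL,
        )
        null = res[tiny_harmonized.name]["AUC"].null_values
        # an observed value below the null median must give p > 0.5
        fake_p = permutation_pvalue(np.median(null) - 0.05, null)
        assert fake_p > 0.5

    def test_small_B_warns_when_alpha_unreachable(self, tiny_harmonized, tiny_ensemble):
        with pytest.warns(UserWarning, match="cannot reach"):
            fm.performance_permutation_test(
                tiny_harmonized,
                [],
                ensemble=tiny_ensemble,
                B=3,
                seed=1,
                train_kwargs=TRAIN_SMALL,
            )


class TestDiscriminativeFCs:
    def test_counts_and_boundary_p(self, tiny_harmonized, tiny_ensemble):
        B = 19
        null_max = np.full(B, 3)  # null maxima never reach the top count
        edge_set = fm.identify_discriminative_fcs(
            tiny_harmonized, tiny_ensemble, B=B, null_max=null_max
        )
        counts = edge_set.counts
        assert counts.max() <= tiny_ensemble.n_classifiers
        top = np.argmax(counts)
        if counts[top] > 3:
            assert edge_set.pvalues[top] == pytest.approx(1 / (B + 1))
        assert np.all(edge_set.pvalues > 0)

    def test_p_monotone_in_count(self, tiny_harmonized, tiny_ensemble):
        null_max = np.array([2, 4, 6, 8, 10])
        edge_set = fm.identify_discriminative_fcs(
            tiny_harmonized, tiny_ensemble, null_max=null_max
        )
        order = np.argsort(edge_set.counts)
        p_sorted = edge_set.pvalues[order]
        assert np.all(np.diff(p_sorted) <= 1e-12)

    def test_hyper_hypo_partition(self, tiny_harmonized, tiny_ensemble):
        edge_set = fm.identify_discriminative_fcs(
            tiny_harmonized, tiny_ensemble, null_max=np.zeros(19)
        )
        sig = set(edge_set.edges)
        assert sig == set(edge_set.hyper_edges) | set(edge_set.hypo_edges)
        assert not set(edge_set.hyper_edges) & set(edge_set.hypo_edges)
        assert np.all(edge_set.mean_weight[edge_set.hyper_edges] > 0)

    def test_edge_order_exchangeability(self, tiny_harmonized, tiny_ensemble):
        """Permuting edge order permutes counts/p-values correspondingly."""
        rng = np.random.default_rng(5)
        perm = rng.permutation(tiny_harmonized.n_edges)
        permuted_ds = fm.FCDataset(
            tiny_harmonized.participants.copy(),
            tiny_harmonized.fc[:, perm],
            tiny_harmonized.atlas,
            name="edge_permuted",
        )
        ens_perm = fm.train_ensemble(permuted_ds, k_folds=5, n_subsamples=2, seed=5)
        null_max = np.full(9, 1)
        a = fm.identify_discriminative_fcs(tiny_harmonized, tiny_ensemble, null_max=null_max)
        b = fm.identify_discriminative_fcs(permuted_ds, ens_perm, null_max=null_max)
        # training is invariant to feature order up to solver path details;
        # selection counts of the permuted run map back to the original edges
        assert set(perm[b.edges]) == set(a.edges)

    def test_real_null_distribution(self, tiny_harmonized, tiny_ensemble):
        edge_set = fm.identify_discriminative_fcs(
            tiny_harmonized,
            tiny_ensemble,
            B=5,
            seed=11,
            train_kwargs=TRAIN_SMALL,
        )
        assert len(edge_set.null_max) == 5
        assert np.all(edge_set.null_max >= 0)


def test_permuted_ensembles_use_identical_config(tiny_harmonized, tiny_ensemble):
    stream = fm.permuted_ensembles(tiny_harmonized, B=2, seed=3, train_kwargs=TRAIN_SMALL)
    reference = {k: v for k, v in tiny_ensemble.config.items() if k != "seed"}
    for perm_ens in stream:
        echoed = {k: v for k, v in perm_ens.config.items() if k != "seed"}
        assert echoed == reference  # identical training configuration
        assert sorted(perm_ens.diagnosis) == sorted(tiny_harmonized.diagnosis)


def test_permutation_analysis_single_pass(tiny_harmonized, tiny_ensemble, tiny_family):
    val, _ = fm.harmonize(tiny_family[1])
    perf, edge_set, null_sens = fm.permutation_analysis(
        tiny_harmonized,
        [val],
        tiny_ensemble,
        B=5,
        seed=13,
        train_kwargs=TRAIN_SMALL,
        foreign_patients={"foreign": val.subset(val.diagnosis == 1)},
    )
    assert set(perf) == {tiny_harmonized.name, val.name}
    assert len(edge_set.null_max) == 5
    assert null_sens["foreign"].shape == (5,)
    # shared stream: same seed reproduces the separate-run null
    separate = fm.identify_discriminative_fcs(
        tiny_harmonized, tiny_ensemble, B=5, seed=13, train_kwargs=TRAIN_SMALL
    )
    np.testing.assert_array_equal(edge_set.null_max, separate.null_max)
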