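"""Generator contracts: determinism, planted structure, truth emission."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import fcmarker as fm
from fcmarker.consistency import diagnosis_t
from fcmarker.errors import ConfigError


def _null_config(seed=0, R=35, n=250):
    """Single site, no site effects, no planted effect, no covariates."""
    return replace(
        fm.default_config(seed=seed),
        roi_count=R,
        sites=(fm.SiteSpec("only", n // 2, n // 2, additive_sd=0.0, multiplicative_range=(1.0, 1.0)),),
        n_effect_edges=0,
        covariate_fraction=0.0,
    )


def test_determinism_same_seed():
    a = fm.simulate_fc_dataset(fm.default_config(seed=4))
    b = fm.simulate_fc_dataset(fm.default_config(seed=4))
    np.testing.assert_array_equal(a.fc, b.fc)
    assert a.participants.equals(b.participants)
    c = fm.simulate_fc_dataset(fm.default_config(seed=5))
    assert not np.array_equal(a.fc, c.fc)


def test_null_t_values_follow_student_t():
    """With no planted structure, per-edge two-sample t-values match theory."""
    ds = fm.simulate_fc_dataset(_null_config(seed=1))
    ev = diagnosis_t(ds)
    res = stats.kstest(ev.t, "t", args=(ev.df,))
    assert ev.t.shape[0] >= 500
    assert res.pvalue > 0.01


def test_planted_effect_raises_t_magnitude():
    cfg = replace(
        _null_config(seed=2, R=50, n=200),
        n_effect_edges=20,
        effect_d=1.0,
    )
    ds = fm.simulate_fc_dataset(cfg)
    ev = diagnosis_t(ds)
    planted = np.asarray(ds.truth["effect_edges"])
    null_edges = np.setdiff1d(np.arange(ds.n_edges), planted)
    assert np.abs(ev.t[planted]).mean() > 2 * np.abs(ev.t[null_edges]).mean()


def test_truth_emission_and_config_errors():
    ds = fm.simulate_fc_dataset(fm.default_config(seed=0))
    assert set(ds.truth) >= {"seed", "effect_edges", "effect_size", "gamma", "delta"}
    with pytest.raises(ConfigError):
        fm.SimConfig(roi_count=5, n_effect_edges=100)  # more effects than edges
    with pytest.raises(ConfigError):
        fm.SiteSpec("bad", 1, 0)


def test_single_null_edge_auc_near_chance():
    ds = fm.simulate_fc_dataset(_null_config(seed=3, n=400))
    y = ds.diagnosis
    aucs = [fm.ensemble.auc_score(y, ds.fc[:, e]) for e in range(0, 200, 10)]
    assert abs(np.mean(aucs) - 0.5) < 0.03
    assert max(abs(a - 0.5) for a in aucs) < 0.15


def test_site_anova_detects_planted_site_effects():
    """Additive site effects at the noise scale are nearly always detected."""
    cfg = replace(
        fm.default_config(seed=6),
        roi_count=20,
        sites=tuple(
            fm.SiteSpec(f"s{k}", 25, 25, additive_sd=1.0, multiplicative_range=(1.0, 1.0))
            for k in range(3)
        ),
        n_effect_edges=0,
    )
    ds = fm.simulate_fc_dataset(cfg)
    summary = fm.site_effect_summary(ds)
    assert (summary.p < 0.05).mean() > 0.9


class TestFamily:
    def test_shared_effects_and_positive_t_correlation(self, tiny_family):
        disc, val = tiny_family
        assert disc.truth["effect_edges"] == val.truth["effect_edges"]
        edges = np.asarray(disc.truth["effect_edges"])
        r = np.corrcoef(diagnosis_t(disc).t[edges], diagnosis_t(val).t[edges])[0, 1]
        assert r > 0.5

    def test_sign_share_flips_expected_count(self):
        cfg = replace(fm.default_config(seed=9), roi_count=20, n_effect_edges=40, effect_d=1.0)
        flipped_positions = set()
        for seed in range(10):
            fam = fm.simulate_family(
                replace(cfg, seed=seed), n_validation=1, sign_share=0.5
            )
            kept = np.asarray(fam[1].truth["sign_kept"])
            assert (kept == -1).sum() == 20  # half of 40 effect edges flip
            flipped_positions.update(np.flatnonzero(kept == -1))
        assert len(flipped_positions) > 30  # flip positions vary across seeds

    def test_zero_attenuation_kills_validation_effect(self):
        cfg = replace(fm.default_config(seed=10), roi_count=20, n_effect_edges=30, effect_d=1.2)
        fam = fm.simulate_family(cfg, n_validation=1, stage_attenuation={"adult": 0.0})
        edges = np.asarray(fam[0].truth["effect_edges"])
        t_val = diagnosis_t(fam[1]).t
        assert np.abs(t_val[edges]).mean() < 1.0  # indistinguishable from noise

    def test_validation_stage_ages(self):
        fam = fm.simulate_family(
            fm.default_config(seed=1), n_validation=2, stage_attenuation={"child": 0.5, "adult": 1.0}
        )
        child = fam[1]
        assert child.truth["stage"] == "child"
        assert child.participants["age"].max() < 12


class TestDisorders:
    def test_overlap_extremes(self):
        cfg = replace(fm.default_config(seed=3), roi_count=20, n_effect_edges=20)
        full = fm.simulate_disorders(cfg, overlap=1.0)
        a = set(full["disorder_a"].truth["effect_edges"])
        b = set(full["disorder_b"].truth["effect_edges"])
        assert a == b
        none = fm.simulate_disorders(cfg, overlap=0.0)
        assert not set(none["disorder_a"].truth["effect_edges"]) & set(
            none["disorder_b"].truth["effect_edges"]
        )

    def test_half_overlap_counts(self):
        cfg = replace(fm.default_config(seed=3), roi_count=20, n_effect_edges=40)
        pair = fm.simulate_disorders(cfg, overlap=0.5)
        a = set(pair["disorder_a"].truth["effect_edges"])
        b = set(pair["disorder_b"].truth["effect_edges"])
        assert len(a & b) == 20

    def test_shared_controls_identical(self):
        cfg = replace(fm.default_config(seed=4), roi_count=15)
        pair = fm.simulate_disorders(cfg, overlap=0.3)
        a, b = pair["disorder_a"], pair["disorder_b"]
        ctrl_a = a.fc[a.diagnosis == 0]
        ctrl_b = b.fc[b.diagnosis == 0]
        np.testing.assert_array_equal(ctrl_a, ctrl_b)

    def test_infeasible_overlap_rejected(self):
        cfg = replace(fm.default_config(seed=0), roi_count=5, n_effect_edges=8)
        with pytest.raises(ConfigError):
            fm.simulate_disorders(cfg, overlap=0.0, size_b=8)  # only 10 edges total


class TestRoiTimeseries:
    def test_identity_target_recovers_uncorrelated_series(self):
        ts, truth = fm.simulate_roi_timeseries(np.eye(6), n_frames=2000, fd_spike_prob=0.0, seed=0)
        r = np.corrcoef(ts.data, rowvar=False)
        off = r[np.triu_indices(6, k=1)]
        assert np.abs(off).max() < 0.1

    def test_no_spikes_below_threshold(self):
        ts, truth = fm.simulate_roi_timeseries(np.eye(4), n_frames=300, fd_spike_prob=0.0, seed=1)
        assert (ts.fd_trace <= 0.5).all()
        assert len(truth["spike_frames"]) == 0

    def test_spike_frames_exceed_threshold(self):
        ts, truth = fm.simulate_roi_timeseries(np.eye(4), n_frames=400, fd_spike_prob=0.2, seed=2)
        assert len(truth["spike_frames"]) > 0
        assert (ts.fd_trace[truth["spike_frames"]] > 0.5).all()

    def test_deterministic(self):
        a, _ = fm.simulate_roi_timeseries(np.eye(3), n_frames=50, seed=9)
        b, _ = fm.simulate_roi_timeseries(np.eye(3), n_frames=50, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_non_psd_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalue -1
        with pytest.raises(ConfigError):
            fm.simulate_roi_timeseries(bad, n_frames=10)
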