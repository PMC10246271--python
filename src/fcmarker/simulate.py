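"""Synthetic multi-site, multi-disorder connectivity data.

The generator produces Fisher-z edge vectors with the statistical structure
the downstream analysis assumes: per-site additive and multiplicative edge
effects (the batch structure the harmonization step removes), a sparse set
of edges carrying a signed diagnosis effect, age and sex covariate effects
on a stated edge subset, and case/control imbalance per site.  Edge value
for subject j at site s on edge v:

    y = baseline_v + diagnosis * d_v * noise_sd + age * beta_age_v
        + sex * beta_sex_v + gamma_sv + delta_sv * eps,   eps ~ N(0, noise_sd^2)

with gamma_sv ~ N(0, additive_sd^2) and delta_sv ~ U(multiplicative_range)
drawn independently per site and edge.  Every simulated dataset carries its
generating parameters in ``dataset.truth`` so recovery can be tested.

Default shape: 50 ROIs (1225 edges), three discovery sites of 110 controls
and 36 patients each — the discovery cohorts this emulates pooled roughly
three controls per patient across many sites — with a 30-edge planted
effect of |d| = 0.8 and mixed signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import FCDataset
from .edges import Atlas, edge_count
from .errors import ConfigError

__all__ = [
    "EffectSpec",
    "SiteSpec",
    "SimConfig",
    "default_config",
    "simulate_fc_dataset",
    "simulate_family",
    "simulate_disorders",
    "simulate_roi_timeseries",
]


@dataclass(frozen=True)
class EffectSpec:
    """Which edges carry a diagnosis effect, and how strongly.

    effect_size is a per-edge Cohen's d on the z-scale (signed); sign_share
    is the fraction of effect edges whose sign is preserved when a derived
    (validation or second-disorder) dataset re-uses the effect set.
    """

    effect_edges: tuple[int, ...]
    effect_size: tuple[float, ...]
    sign_share: float = 1.0

    def __post_init__(self) -> None:
        if len(self.effect_edges) != len(self.effect_size):
            raise ConfigError("effect_edges and effect_size must have equal length")
        if not 0.0 <= self.sign_share <= 1.0:
            raise ConfigError("sign_share must lie in [0, 1]")
        if not all(np.isfinite(self.effect_size)):
            raise ConfigError("effect sizes must be finite")


@dataclass(frozen=True)
class SiteSpec:
    """One imaging site: group sizes and the scale of its batch effects."""

    site_id: str
    n_control: int
    n_patient: int
    additive_sd: float = 0.5
    multiplicative_range: tuple[float, float] = (0.8, 1.25)

    def __post_init__(self) -> None:
        if self.n_control + self.n_patient < 2:
            raise ConfigError(f"site {self.site_id}: needs at least 2 subjects")
        lo, hi = self.multiplicative_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ConfigError(f"site {self.site_id}: bad multiplicative range")
        if self.additive_sd < 0:
            raise ConfigError(f"site {self.site_id}: additive_sd must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Full generator configuration; reproducible from ``seed`` alone."""

    roi_count: int = 50
    sites: tuple[SiteSpec, ...] = (
        SiteSpec("siteA", 110, 36),
        SiteSpec("siteB", 110, 36),
        SiteSpec("siteC", 110, 36),
    )
    effects: EffectSpec | None = None  # None: drawn from seed (30 edges, |d|=0.8)
    n_effect_edges: int = 30
    effect_d: float = 0.8
    covariate_fraction: float = 0.1  # share of edges with age/sex effects
    age_slope: float = 0.01  # z-units per year on affected edges
    sex_effect: float = 0.15  # z-units, male vs female, on affected edges
    age_range: tuple[float, float] = (18.0, 60.0)
    baseline_sd: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_count < 2:
            raise ConfigError("roi_count must be >= 2")
        m = edge_count(self.roi_count)
        if self.effects is not None and len(self.effects.effect_edges) > m:
            raise ConfigError("more effect edges than edges in the atlas")
        if self.n_effect_edges > m:
            raise ConfigError("more effect edges than edges in the atlas")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ConfigError("scales must be >= 0")

    @property
    def n_edges(self) -> int:
        return edge_count(self.roi_count)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The desk-scale default study shape (50 ROIs, 3 imbalanced sites)."""
    return replace(SimConfig(seed=seed), **overrides) if overrides else SimConfig(seed=seed)


def _draw_effects(config: SimConfig, rng: np.random.Generator) -> EffectSpec:
    m = config.n_edges
    edges = np.sort(rng.choice(m, size=config.n_effect_edges, replace=False))
    signs = rng.choice([-1.0, 1.0], size=config.n_effect_edges)
    return EffectSpec(tuple(int(e) for e in edges), tuple(signs * config.effect_d))


def _covariate_betas(config: SimConfig, rng: np.random.Generator):
    m = config.n_edges
    k = int(round(config.covariate_fraction * m))
    beta_age = np.zeros(m)
    beta_sex = np.zeros(m)
    if k:
        beta_age[rng.choice(m, size=k, replace=False)] = config.age_slope * rng.choice(
            [-1, 1], size=k
        )
        beta_sex[rng.choice(m, size=k, replace=False)] = config.sex_effect * rng.choice(
            [-1, 1], size=k
        )
    return beta_age, beta_sex


def _simulate_with(
    config: SimConfig,
    effects: EffectSpec,
    rng: np.random.Generator,
    name: str,
    atlas: Atlas,
    shared_controls: dict | None = None,
) -> FCDataset:
    """Core generator; optionally reuses a pre-built control block per site."""
    m = config.n_edges
    baseline = rng.normal(0.0, config.baseline_sd, size=m)
    beta_age, beta_sex = _covariate_betas(config, rng)
    if shared_controls is not None:
        # patients must live on the same baseline/covariate surface as the
        # reused control block, otherwise every edge would carry a spurious
        # group difference
        baseline = shared_controls["baseline"]
        beta_age = shared_controls["beta_age"]
        beta_sex = shared_controls["beta_sex"]
    d = np.zeros(m)
    d[list(effects.effect_edges)] = np.asarray(effects.effect_size) * config.noise_sd

    rows, fc_blocks = [], []
    gamma_all, delta_all = {}, {}
    for site in config.sites:
        gamma = rng.normal(0.0, site.additive_sd, size=m)
        delta = rng.uniform(*site.multiplicative_range, size=m)
        gamma_all[site.site_id] = gamma
        delta_all[site.site_id] = delta
        if shared_controls is not None:
            gamma = shared_controls["gamma"][site.site_id]
            delta = shared_controls["delta"][site.site_id]
            gamma_all[site.site_id] = gamma
            delta_all[site.site_id] = delta
        for group, n_group in (("control", site.n_control), ("patient", site.n_patient)):
            if n_group == 0:
                continue
            diag = 0 if group == "control" else 1
            if shared_controls is not None and group == "control":
                block = shared_controls["blocks"][site.site_id]
                rows.append(block["participants"])
                fc_blocks.append(block["fc"])
                continue
            age = rng.uniform(*config.age_range, size=n_group)
            sex = rng.integers(0, 2, size=n_group)
            eps = rng.normal(0.0, config.noise_sd, size=(n_group, m))
            fc = (
                baseline
                + diag * d
                + age[:, None] * beta_age
                + sex[:, None] * beta_sex
                + gamma
                + delta * eps
            )
            part = pd.DataFrame(
                {
                    "subject_id": [f"{name}_{site.site_id}_{group[:3]}{k:03d}" for k in range(n_group)],
                    "site": site.site_id,
                    "diagnosis": diag,
                    "age": age,
                    "sex": np.where(sex == 1, "M", "F"),
                }
            )
            rows.append(part)
            fc_blocks.append(fc)
    participants = pd.concat(rows, ignore_index=True)
    fc = np.vstack(fc_blocks)
    truth = {
        "seed": config.seed,
        "effect_edges": list(effects.effect_edges),
        "effect_size": list(effects.effect_size),
        "baseline": baseline,
        "beta_age": beta_age,
        "beta_sex": beta_sex,
        "gamma": {k: v for k, v in gamma_all.items()},
        "delta": {k: v for k, v in delta_all.items()},
    }
    return FCDataset(participants, fc, atlas, name=name, truth=truth)


def simulate_fc_dataset(config: SimConfig, name: str = "discovery") -> FCDataset:
    """Generate one multi-site dataset; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    effects = config.effects if config.effects is not None else _draw_effects(config, rng)
    atlas = Atlas.synthetic(config.roi_count)
    return _simulate_with(config, effects, rng, name, atlas)


_STAGE_AGES = {"child": (6.0, 11.9), "adolescent": (12.1, 17.9), "adult": (18.0, 60.0)}


def simulate_family(
    config: SimConfig,
    n_validation: int = 2,
    stage_attenuation: dict[str, float] | None = None,
    sign_share: float | None = None,
) -> list[FCDataset]:
    """One discovery dataset plus validation datasets sharing its effect edges.

    Each validation dataset gets fresh sites (new additive/multiplicative
    effects), fresh subjects, its stage's age range, effect sizes multiplied
    by the stage's attenuation, and a fraction ``sign_share`` of effect
    edges keeping the discovery sign (the rest are flipped).  Stages are
    assigned round-robin from ``stage_attenuation`` (default: all adult at
    full strength).
    """
    if n_validation < 1:
        raise ConfigError("n_validation must be >= 1")
    if stage_attenuation is None:
        stage_attenuation = {"adult": 1.0}
    for stage in stage_attenuation:
        if stage not in _STAGE_AGES:
            raise ConfigError(f"unknown stage {stage!r}")
    rng = np.random.default_rng(config.seed)
    effects = config.effects if config.effects is not None else _draw_effects(config, rng)
    atlas = Atlas.synthetic(config.roi_count)
    discovery = _simulate_with(config, effects, rng, "discovery", atlas)
    share = effects.sign_share if sign_share is None else sign_share
    stages = list(stage_attenuation.items())
    datasets = [discovery]
    base_sizes = np.asarray(effects.effect_size)
    for v in range(n_validation):
        stage, atten = stages[v % len(stages)]
        vrng = np.random.default_rng(np.random.SeedSequence([config.seed, 7001 + v]))
        n_eff = len(effects.effect_edges)
        keep = np.ones(n_eff)
        n_flip = int(round((1.0 - share) * n_eff))
        if n_flip:
            keep[vrng.choice(n_eff, size=n_flip, replace=False)] = -1.0
        v_effects = EffectSpec(
            effects.effect_edges, tuple(base_sizes * keep * atten), sign_share=share
        )
        v_sites = tuple(
            replace(s, site_id=f"val{v}_{s.site_id}") for s in config.sites
        )
        v_config = replace(
            config, sites=v_sites, age_range=_STAGE_AGES[stage], effects=v_effects
        )
        ds = _simulate_with(v_config, v_effects, vrng, f"validation{v}_{stage}", atlas)
        ds.truth["stage"] = stage
        ds.truth["attenuation"] = atten
        ds.truth["sign_kept"] = keep.tolist()
        datasets.append(ds)
    return datasets


def simulate_disorders(
    config: SimConfig, overlap: float, size_b: int | None = None
) -> dict[str, FCDataset]:
    """Two disorders with partially overlapping effect edges and shared controls.

    Disorder B's effect set shares ``overlap`` of disorder A's edges (same
    signs there); the remainder is drawn disjointly.  The control subjects
    (and each site's batch effects) are identical across the two datasets,
    mirroring designs where the control cohort is shared between clinical
    groups.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ConfigError("overlap must lie in [0, 1]")
    rng = np.random.default_rng(config.seed)
    effects_a = config.effects if config.effects is not None else _draw_effects(config, rng)
    atlas = Atlas.synthetic(config.roi_count)
    m = config.n_edges
    n_a = len(effects_a.effect_edges)
    size_b = n_a if size_b is None else size_b
    n_shared = int(round(overlap * n_a))
    if n_shared > size_b:
        raise ConfigError("overlap infeasible: shared edges exceed disorder B's set size")
    if size_b - n_shared > m - n_a:
        raise ConfigError("overlap infeasible: not enough disjoint edges available")
    a_edges = np.asarray(effects_a.effect_edges)
    a_sizes = np.asarray(effects_a.effect_size)
    shared_pos = rng.choice(n_a, size=n_shared, replace=False)
    pool = np.setdiff1d(np.arange(m), a_edges)
    fresh = rng.choice(pool, size=size_b - n_shared, replace=False)
    b_edges = np.concatenate([a_edges[shared_pos], fresh])
    b_sizes = np.concatenate(
        [a_sizes[shared_pos], rng.choice([-1.0, 1.0], size=len(fresh)) * config.effect_d]
    )
    order = np.argsort(b_edges)
    effects_b = EffectSpec(tuple(int(e) for e in b_edges[order]), tuple(b_sizes[order]))

    ds_a = _simulate_with(config, effects_a, rng, "disorder_a", atlas)
    # capture A's control rows and site effects for reuse
    shared = {
        "gamma": ds_a.truth["gamma"],
        "delta": ds_a.truth["delta"],
        "baseline": ds_a.truth["baseline"],
        "beta_age": ds_a.truth["beta_age"],
        "beta_sex": ds_a.truth["beta_sex"],
        "blocks": {},
    }
    for site in config.sites:
        mask = (ds_a.participants["site"] == site.site_id) & (
            ds_a.participants["diagnosis"] == 0
        )
        shared["blocks"][site.site_id] = {
            "participants": ds_a.participants.loc[mask].reset_index(drop=True),
            "fc": ds_a.fc[mask.to_numpy()],
        }
    brng = np.random.default_rng(np.random.SeedSequence([config.seed, 9001]))
    ds_b = _simulate_with(config, effects_b, brng, "disorder_b", atlas, shared_controls=shared)
    ds_a.truth["overlap_edges"] = [int(e) for e in np.sort(a_edges[shared_pos])]
    ds_b.truth["overlap_edges"] = ds_a.truth["overlap_edges"]
    return {"disorder_a": ds_a, "disorder_b": ds_b}


def simulate_roi_timeseries(
    target_correlation: np.ndarray,
    n_frames: int = 500,
    fd_spike_prob: float = 0.05,
    seed: int = 0,
    tr_seconds: float = 2.0,
):
    """Stationary Gaussian ROI series with a target correlation + an FD trace.

    Returns a :class:`~fcmarker.connectivity.TimeSeries` (with the motion
    trace attached) and a truth dict recording the target matrix and which
    frames carry motion spikes above the 0.5 mm censoring threshold.
    """
    from .connectivity import TimeSeries  # deferred: avoid import cycle

    C = np.asarray(target_correlation, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-10):
        raise ConfigError("target correlation must be square and symmetric")
    vals, vecs = np.linalg.eigh(C)
    if vals.min() < -1e-8:
        raise ConfigError("target correlation must be positive semidefinite")
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_frames, C.shape[0])) @ root.T
    fd = np.abs(rng.normal(0.08, 0.06, size=n_frames))
    fd = np.minimum(fd, 0.45)  # quiescent frames stay safely below threshold
    spikes = rng.random(n_frames) < fd_spike_prob
    fd[spikes] = 0.55 + rng.exponential(0.3, size=int(spikes.sum()))
    ts = TimeSeries(data=data, tr_seconds=tr_seconds, fd_trace=fd)
    truth = {
        "target_correlation": C,
        "spike_frames": np.flatnonzero(spikes),
        "seed": seed,
    }
    return ts, truth
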