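"""End-to-end orchestration: simulate -> harmonize -> train -> infer -> map.

`run_pipeline` executes the whole analysis from a single config and writes
every artifact (datasets, marker, statistics) plus a manifest with file
hashes and the seeds in play, so a rerun with the same config reproduces
the same manifest.  Stage order: simulate (or ingest) the dataset family,
harmonize each dataset separately, train the marker on the discovery set,
apply it to each validation set, run the shared permutation stream
(performance significance with Holm correction across validation sets, and
discriminative-edge identification), mass-univariate consistency analyses,
network enrichment, and — when a second disorder is configured — the
cross-disorder projection.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .combat import harmonize
from .consistency import (
    binomial_consistency_test,
    cross_dataset_correlation,
    diagnosis_t,
    sign_consistency,
)
from .cross_disorder import cross_sensitivity, dimensional_map
from .datasets import FCDataset, write_dataset
from .ensemble import compute_metrics, predict, train_ensemble
from .errors import ConfigError
from .inference import holm_bonferroni, permutation_analysis
from .networks import enrich_edge_sets
from .simulate import SimConfig, default_config, simulate_disorders, simulate_family

log = logging.getLogger("fcmarker")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; every stochastic stage has a seed."""

    seed: int = 0
    sim: SimConfig | None = None  # default_config(seed) when omitted
    n_validation: int = 2
    stage_attenuation: dict[str, float] = field(default_factory=lambda: {"adult": 1.0})
    harmonization: bool = True
    k_folds: int = 10
    n_subsamples: int = 10
    inner_folds: int = 5
    n_lambdas: int = 30
    lambda_min_ratio: float = 1e-3
    B_performance: int = 99
    B_correlation: int = 1000
    alpha: float = 0.05
    cross_disorder_overlap: float | None = None  # enables the cross-disorder stage
    output_dir: str = "fcmarker_output"
    write_datasets: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            from .simulate import EffectSpec, SiteSpec

            sites = tuple(SiteSpec(**s) for s in sim.pop("sites", []))
            effects = sim.pop("effects", None)
            kwargs = dict(sim)
            if sites:
                kwargs["sites"] = sites
            if effects is not None:
                kwargs["effects"] = EffectSpec(
                    tuple(effects["effect_edges"]),
                    tuple(effects["effect_size"]),
                    effects.get("sign_share", 1.0),
                )
            cfg = dataclasses.replace(cfg, sim=SimConfig(**kwargs))
        return cfg

    def train_kwargs(self) -> dict:
        return {
            "k_folds": self.k_folds,
            "n_subsamples": self.n_subsamples,
            "inner_folds": self.inner_folds,
            "n_lambdas": self.n_lambdas,
            "lambda_min_ratio": self.lambda_min_ratio,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) the artifact manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_echo(config), "stages": [], "outputs": {}}
    sim = config.sim if config.sim is not None else default_config(config.seed)

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("simulate")
        datasets = simulate_family(
            sim, n_validation=config.n_validation, stage_attenuation=config.stage_attenuation
        )
        discovery, validations = datasets[0], datasets[1:]

        stage("harmonize")
        if config.harmonization:
            harmonized = []
            for ds in datasets:  # separately per dataset, never jointly
                h, model = harmonize(ds)
                harmonized.append(h)
            discovery, validations = harmonized[0], harmonized[1:]

        if config.write_datasets:
            for ds in [discovery, *validations]:
                write_dataset(ds, out / ds.name)

        stage("train")
        ensemble = train_ensemble(discovery, seed=config.seed, **config.train_kwargs())
        ensemble.to_json(out / "marker.json")

        stage("apply")
        performance = {
            discovery.name: compute_metrics(ensemble.diagnosis, ensemble.oof_probability).as_dict()
        }
        for v in validations:
            res = predict(ensemble, v)
            performance[v.name] = compute_metrics(v.diagnosis, res.probability).as_dict()

        stage("permutation")
        perf_null, edge_set, _ = permutation_analysis(
            discovery,
            validations,
            ensemble,
            B=config.B_performance,
            seed=config.seed,
            alpha=config.alpha,
            train_kwargs=config.train_kwargs(),
        )
        holm = {
            metric: holm_bonferroni(
                {v.name: perf_null[v.name][metric].p for v in validations},
                alpha=config.alpha,
            )
            for metric in ("AUC", "MCC")
        }

        stage("consistency")
        effects = [diagnosis_t(ds) for ds in [discovery, *validations]]
        correlations = {}
        for v, ev in zip(validations, effects[1:]):
            r, p = cross_dataset_correlation(
                effects[0], v, B=config.B_correlation, seed=config.seed
            )
            correlations[v.name] = {"r": r, "p": p}
        K_whole = sign_consistency(effects)
        M_whole = discovery.n_edges
        disc_edges = edge_set.edges
        x_set = sign_consistency(effects, subset=disc_edges) if len(disc_edges) else 0
        binom_p = (
            binomial_consistency_test(x_set, len(disc_edges), K_whole, M_whole)
            if len(disc_edges)
            else None
        )

        stage("enrichment")
        enrichment = enrich_edge_sets(
            {"hyper": edge_set.hyper_edges, "hypo": edge_set.hypo_edges},
            discovery.atlas,
            alpha=config.alpha,
        )
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)

        results = {
            "performance": performance,
            "performance_permutation": {
                name: {m: {"observed": pn.observed, "p": pn.p} for m, pn in mm.items()}
                for name, mm in perf_null.items()
            },
            "holm": {m: {k: list(v) for k, v in h.items()} for m, h in holm.items()},
            "discriminative_edges": {
                "n_significant": int(len(disc_edges)),
                "edges": disc_edges.tolist(),
                "n_hyper": int(len(edge_set.hyper_edges)),
                "n_hypo": int(len(edge_set.hypo_edges)),
            },
            "consistency": {
                "correlations": correlations,
                "K_whole": K_whole,
                "M_whole": M_whole,
                "x_set": x_set,
                "binomial_p": binom_p,
            },
        }

        if config.cross_disorder_overlap is not None:
            stage("cross_disorder")
            pair = simulate_disorders(sim, overlap=config.cross_disorder_overlap)
            ds_a, ds_b = pair["disorder_a"], pair["disorder_b"]
            if config.harmonization:
                ds_a, _ = harmonize(ds_a)
                ds_b, _ = harmonize(ds_b)
            marker_a = train_ensemble(ds_a, seed=config.seed, **config.train_kwargs())
            marker_b = train_ensemble(ds_b, seed=config.seed + 1, **config.train_kwargs())
            b_patients = ds_b.subset(ds_b.diagnosis == 1, name="disorder_b_patients")
            sens, sens_p = cross_sensitivity(
                marker_a,
                b_patients,
                discovery=ds_a,
                B=config.B_performance,
                seed=config.seed,
                train_kwargs=config.train_kwargs(),
            )
            cmap = dimensional_map(
                marker_a,
                marker_b,
                {
                    "controls": ds_a.subset(ds_a.diagnosis == 0, name="controls"),
                    "disorder_a": ds_a.subset(ds_a.diagnosis == 1, name="a_patients"),
                    "disorder_b": b_patients,
                },
            )
            results["cross_disorder"] = {
                "sensitivity_a_to_b": sens,
                "sensitivity_p": sens_p,
                "modal_quadrant": cmap.modal_quadrant,
                "quadrant_counts": cmap.quadrant_counts,
            }

        (out / "results.json").write_text(json.dumps(results, indent=1))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        current = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {current!r}: {exc}") from exc

    for path in sorted(out.rglob("*")):
        if path.is_file():
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _config_echo(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    return enc(config)
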