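"""Permutation significance for marker performance and edge selection.

Two permutation designs share one engine.  Labels are shuffled in the
discovery set only; a full ensemble is retrained per iteration with the
identical training configuration, and

* for performance: AUC and MCC of the permuted ensemble are recorded on
  each validation set (true labels intact) and on the permuted discovery
  set's own out-of-fold probabilities, giving a null distribution per
  dataset and metric;
* for edge selection: the per-edge count of classifiers with a nonzero
  weight is computed for the permuted ensemble and its maximum over all
  edges is recorded, giving a max-statistic null that controls the
  family-wise error of the selected edge set.

All permutation p-values use p = (1 + #{null >= observed}) / (1 + B), so
they are never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .datasets import FCDataset
from .ensemble import MarkerEnsemble, compute_metrics, predict, train_ensemble

__all__ = [
    "PermutationNull",
    "DiscriminativeFCSet",
    "permutation_pvalue",
    "permuted_ensembles",
    "performance_permutation_test",
    "identify_discriminative_fcs",
    "permutation_analysis",
    "holm_bonferroni",
]


def permutation_pvalue(observed: float, null_values: np.ndarray) -> float:
    """p = (1 + #{null >= observed}) / (1 + B); lies in (0, 1]."""
    null_values = np.asarray(null_values, dtype=float)
    return float((1 + np.sum(null_values >= observed)) / (1 + len(null_values)))


@dataclass
class PermutationNull:
    metric: str
    observed: float
    null_values: np.ndarray
    p: float

    @property
    def n_iterations(self) -> int:
        return len(self.null_values)


@dataclass
class DiscriminativeFCSet:
    """Edges surviving the max-selection-count permutation null."""

    counts: np.ndarray  # (m,) observed selection counts over the ensemble
    null_max: np.ndarray  # (B,) max count over edges per permutation
    pvalues: np.ndarray  # (m,)
    mean_weight: np.ndarray  # (m,) over all classifiers, zeros included
    alpha: float = 0.05

    @property
    def edges(self) -> np.ndarray:
        """Indices of significant edges (p < alpha)."""
        return np.flatnonzero(self.pvalues < self.alpha)

    @property
    def hyper_edges(self) -> np.ndarray:
        """Significant edges with positive mean weight (hyper-connections)."""
        e = self.edges
        return e[self.mean_weight[e] > 0]

    @property
    def hypo_edges(self) -> np.ndarray:
        """Significant edges with negative mean weight (hypo-connections)."""
        e = self.edges
        return e[self.mean_weight[e] <= 0]


def permuted_ensembles(
    discovery: FCDataset,
    B: int,
    seed: int,
    train_kwargs: dict | None = None,
) -> Iterator[MarkerEnsemble]:
    """Yield B ensembles trained on label-shuffled copies of the discovery set.

    Iteration b derives its shuffle and its training seed from
    (seed, iteration), so any prefix of the stream is reproducible.  The
    training configuration is identical to what `train_ensemble` would use
    with the same ``train_kwargs``.
    """
    train_kwargs = dict(train_kwargs or {})
    train_kwargs.pop("seed", None)
    y = discovery.diagnosis
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2, b]))
        perm = rng.permutation(y)
        permuted = discovery.with_diagnosis(perm, name=f"{discovery.name}_perm{b}")
        sub_seed = int(rng.integers(2**31 - 1))
        yield train_ensemble(permuted, seed=sub_seed, **train_kwargs)


def performance_permutation_test(
    discovery: FCDataset,
    validations: Sequence[FCDataset],
    ensemble: MarkerEnsemble | None = None,
    B: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    train_kwargs: dict | None = None,
) -> dict[str, dict[str, PermutationNull]]:
    """Label-shuffle null for AUC and MCC on discovery and validation sets."""
    if ensemble is None:
        ensemble = train_ensemble(discovery, seed=seed, **(train_kwargs or {}))
    if B >= 1 and 1.0 / (1 + B) > alpha:
        warnings.warn(
            f"B={B} cannot reach p < {alpha}: minimum attainable p is {1/(1+B):.3g}",
            stacklevel=2,
        )
    observed = {
        discovery.name: compute_metrics(ensemble.diagnosis, ensemble.oof_probability)
    }
    for v in validations:
        observed[v.name] = compute_metrics(v.diagnosis, predict(ensemble, v).probability)
    nulls = {name: {"AUC": [], "MCC": []} for name in observed}
    for perm_ens in permuted_ensembles(discovery, B, seed, train_kwargs):
        pm = compute_metrics(perm_ens.diagnosis, perm_ens.oof_probability)
        nulls[discovery.name]["AUC"].append(pm.auc)
        nulls[discovery.name]["MCC"].append(pm.mcc)
        for v in validations:
            vm = compute_metrics(v.diagnosis, predict(perm_ens, v).probability)
            nulls[v.name]["AUC"].append(vm.auc)
            nulls[v.name]["MCC"].append(vm.mcc)
    out = {}
    for name, metrics in observed.items():
        out[name] = {}
        for metric, obs in (("AUC", metrics.auc), ("MCC", metrics.mcc)):
            null = np.asarray(nulls[name][metric])
            out[name][metric] = PermutationNull(
                metric=metric,
                observed=obs,
                null_values=null,
                p=permutation_pvalue(obs, null),
            )
    return out


def identify_discriminative_fcs(
    discovery: FCDataset,
    ensemble: MarkerEnsemble,
    B: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    train_kwargs: dict | None = None,
    null_max: np.ndarray | None = None,
) -> DiscriminativeFCSet:
    """Edges selected more often than the max-count permutation null.

    The observed statistic per edge is the number of ensemble classifiers
    that gave it a nonzero weight; each permutation contributes the maximum
    such count over all edges, so a single null distribution serves every
    edge and controls the family-wise error rate.  Pass ``null_max`` to
    reuse maxima already collected from the same permutation stream.
    """
    counts = ensemble.selection_counts()
    if null_max is None:
        null_max = np.array(
            [
                perm_ens.selection_counts().max()
                for perm_ens in permuted_ensembles(discovery, B, seed, train_kwargs)
            ]
        )
    null_max = np.asarray(null_max)
    pvalues = np.array([permutation_pvalue(c, null_max) for c in counts])
    return DiscriminativeFCSet(
        counts=counts,
        null_max=null_max,
        pvalues=pvalues,
        mean_weight=ensemble.mean_weights(),
        alpha=alpha,
    )


def permutation_analysis(
    discovery: FCDataset,
    validations: Sequence[FCDataset],
    ensemble: MarkerEnsemble,
    B: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    train_kwargs: dict | None = None,
    foreign_patients: dict[str, FCDataset] | None = None,
) -> tuple[dict, DiscriminativeFCSet, dict[str, np.ndarray]]:
    """One pass over the permutation stream feeding all three nulls.

    Retraining an ensemble dominates the cost of every permutation test, so
    the performance null, the max-selection-count null, and (optionally)
    the null sensitivities of foreign-disorder patient groups are collected
    from the same permuted ensembles.

    Returns (performance results, discriminative edge set, null
    sensitivities per foreign group).
    """
    observed = {
        discovery.name: compute_metrics(ensemble.diagnosis, ensemble.oof_probability)
    }
    for v in validations:
        observed[v.name] = compute_metrics(v.diagnosis, predict(ensemble, v).probability)
    nulls = {name: {"AUC": [], "MCC": []} for name in observed}
    null_max = []
    null_sens = {name: [] for name in (foreign_patients or {})}
    for perm_ens in permuted_ensembles(discovery, B, seed, train_kwargs):
        pm = compute_metrics(perm_ens.diagnosis, perm_ens.oof_probability)
        nulls[discovery.name]["AUC"].append(pm.auc)
        nulls[discovery.name]["MCC"].append(pm.mcc)
        for v in validations:
            vm = compute_metrics(v.diagnosis, predict(perm_ens, v).probability)
            nulls[v.name]["AUC"].append(vm.auc)
            nulls[v.name]["MCC"].append(vm.mcc)
        null_max.append(perm_ens.selection_counts().max())
        for name, ds in (foreign_patients or {}).items():
            prob = predict(perm_ens, ds).probability
            null_sens[name].append(float(np.mean(prob > 0.5)))
    performance = {}
    for name, metrics in observed.items():
        performance[name] = {}
        for metric, obs in (("AUC", metrics.auc), ("MCC", metrics.mcc)):
            null = np.asarray(nulls[name][metric])
            performance[name][metric] = PermutationNull(
                metric=metric, observed=obs, null_values=null, p=permutation_pvalue(obs, null)
            )
    edge_set = identify_discriminative_fcs(
        discovery, ensemble, B=B, seed=seed, alpha=alpha, null_max=np.asarray(null_max)
    )
    return performance, edge_set, {k: np.asarray(v) for k, v in null_sens.items()}


def holm_bonferroni(pvalues: dict[str, float] | Iterable[float], alpha: float = 0.05):
    """Step-down Holm adjustment controlling the family-wise error rate.

    Accepts a mapping name -> p or a plain sequence; returns a mapping
    name -> (reject, adjusted p) or a list of such pairs, respectively.
    """
    if isinstance(pvalues, dict):
        names = list(pvalues)
        raw = [pvalues[k] for k in names]
    else:
        names = None
        raw = list(pvalues)
    if not raw:
        raise ValueError("no p-values supplied")
    reject, adjusted, *_ = multipletests(raw, alpha=alpha, method="holm")
    pairs = [(bool(r), float(a)) for r, a in zip(reject, adjusted)]
    if names is None:
        return pairs
    return dict(zip(names, pairs))
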