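"""The sparse-logistic marker ensemble and its performance metrics.

A marker is an ensemble of 100 L1-penalised logistic classifiers obtained
from 10 subsamples x 10-fold nested cross-validation.  Each subsample is a
class-balanced random undersample of the majority class; within it, a
stratified outer 10-fold split is made and, per outer fold, an inner 5-fold
cross-validation over a log-spaced penalty grid picks the penalty with the
smallest mean held-out deviance (ties prefer the sparser model).  Features
are z-scored per edge using outer-training statistics only.  The mean of
the 100 classifier outputs is the diagnostic probability; a subject is
labelled positive iff it exceeds 0.5 strictly.

Discovery-set performance is computed from out-of-fold probabilities:
within each subsample, subjects in the subsample are scored by the
classifier of the fold that held them out, and subjects left out by the
undersampling are scored by the mean of that subsample's ten fold
classifiers; probabilities are then averaged across subsamples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .datasets import FCDataset
from .errors import DataValidationError, DimensionError
from .lasso import logistic_lasso_cv

__all__ = [
    "LinearClassifier",
    "MarkerEnsemble",
    "DiagnosticResult",
    "PerformanceMetrics",
    "train_ensemble",
    "predict",
    "compute_metrics",
]


@dataclass
class LinearClassifier:
    """One sparse linear classifier with its training standardization."""

    weights: np.ndarray  # (m,) on the standardized scale; mostly zeros
    intercept: float
    lam: float
    mean_: np.ndarray  # (m,) training feature means
    sd_: np.ndarray  # (m,) training feature standard deviations
    subsample_id: int
    fold_id: int

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.weights))

    def predict_proba(self, fc: np.ndarray) -> np.ndarray:
        Z = (fc - self.mean_) / self.sd_
        return 1.0 / (1.0 + np.exp(-(self.intercept + Z @ self.weights)))


@dataclass
class DiagnosticResult:
    """Per-subject diagnostic probabilities and the strict > 0.5 labels."""

    subject_ids: list[str]
    probability: np.ndarray
    label: np.ndarray


@dataclass
class PerformanceMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    auc: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("tp", "tn", "fp", "fn", "accuracy", "sensitivity", "specificity", "mcc", "auc")}


@dataclass
class MarkerEnsemble:
    """All trained classifiers plus discovery out-of-fold probabilities."""

    classifiers: list[LinearClassifier]
    oof_probability: np.ndarray  # (n_discovery,) mean over subsamples
    subject_ids: list[str]
    diagnosis: np.ndarray  # discovery labels the marker was trained on
    n_edges: int
    config: dict = field(default_factory=dict)

    @property
    def n_classifiers(self) -> int:
        return len(self.classifiers)

    def selection_counts(self) -> np.ndarray:
        """Per edge, how many of the classifiers gave it a nonzero weight."""
        counts = np.zeros(self.n_edges, dtype=int)
        for clf in self.classifiers:
            counts += clf.weights != 0
        return counts

    def mean_weights(self) -> np.ndarray:
        """Per-edge weight averaged over all classifiers, zeros included."""
        total = np.zeros(self.n_edges)
        for clf in self.classifiers:
            total += clf.weights
        return total / self.n_classifiers

    def to_json(self, path) -> None:
        payload = {
            "config": self.config,
            "n_edges": self.n_edges,
            "subject_ids": self.subject_ids,
            "diagnosis": self.diagnosis.tolist(),
            "oof_probability": self.oof_probability.tolist(),
            "classifiers": [
                {
                    "subsample_id": c.subsample_id,
                    "fold_id": c.fold_id,
                    "lam": c.lam,
                    "intercept": c.intercept,
                    "nonzero_index": np.flatnonzero(c.weights).tolist(),
                    "nonzero_weight": c.weights[c.weights != 0].tolist(),
                    "mean": c.mean_.tolist(),
                    "sd": c.sd_.tolist(),
                }
                for c in self.classifiers
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "MarkerEnsemble":
        with open(path) as fh:
            payload = json.load(fh)
        m = payload["n_edges"]
        classifiers = []
        for c in payload["classifiers"]:
            w = np.zeros(m)
            w[np.asarray(c["nonzero_index"], dtype=int)] = c["nonzero_weight"]
            classifiers.append(
                LinearClassifier(
                    weights=w,
                    intercept=c["intercept"],
                    lam=c["lam"],
                    mean_=np.asarray(c["mean"]),
                    sd_=np.asarray(c["sd"]),
                    subsample_id=c["subsample_id"],
                    fold_id=c["fold_id"],
                )
            )
        return cls(
            classifiers=classifiers,
            oof_probability=np.asarray(payload["oof_probability"]),
            subject_ids=payload["subject_ids"],
            diagnosis=np.asarray(payload["diagnosis"], dtype=int),
            n_edges=m,
            config=payload["config"],
        )


def _derive_seed(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def train_ensemble(
    dataset: FCDataset,
    k_folds: int = 10,
    n_subsamples: int = 10,
    seed: int = 0,
    inner_folds: int = 5,
    n_lambdas: int = 30,
    lambda_min_ratio: float = 1e-3,
    patience: int = 5,
) -> MarkerEnsemble:
    """Train the k_folds x n_subsamples classifier ensemble on a dataset.

    All randomness (undersampling, fold splits) derives from ``seed``; the
    same seed and data give identical ensembles.
    """
    y = dataset.diagnosis
    X = dataset.fc
    n, m = X.shape
    n_pos, n_neg = int(y.sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataValidationError("both diagnostic classes must be present for training")
    if min(n_pos, n_neg) < k_folds:
        raise DataValidationError(
            f"minority class has {min(n_pos, n_neg)} subjects; needs >= k_folds={k_folds}"
        )
    config = {
        "k_folds": k_folds,
        "n_subsamples": n_subsamples,
        "inner_folds": inner_folds,
        "n_lambdas": n_lambdas,
        "lambda_min_ratio": lambda_min_ratio,
        "patience": patience,
        "seed": int(seed),
    }
    minority = 1 if n_pos <= n_neg else 0
    n_min = min(n_pos, n_neg)
    classifiers: list[LinearClassifier] = []
    prob_subsample = np.zeros((n_subsamples, n))
    for s in range(n_subsamples):
        rng = _derive_seed(seed, 1, s)
        keep_minority = np.flatnonzero(y == minority)
        majority_pool = np.flatnonzero(y != minority)
        keep_majority = rng.choice(majority_pool, size=n_min, replace=False)
        sub_idx = np.sort(np.concatenate([keep_minority, keep_majority]))
        excluded = np.setdiff1d(np.arange(n), sub_idx)
        Xs, ys = X[sub_idx], y[sub_idx]
        skf = StratifiedKFold(
            n_splits=k_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        prob_excluded = np.zeros((k_folds, len(excluded)))
        for f, (tr, te) in enumerate(skf.split(Xs, ys)):
            Xtr, ytr = Xs[tr], ys[tr]
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd < 1e-12] = 1.0
            Ztr = (Xtr - mu) / sd
            inner = StratifiedKFold(
                n_splits=inner_folds,
                shuffle=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            folds = list(inner.split(Ztr, ytr))
            lam, w, w0, _, _ = logistic_lasso_cv(
                Ztr,
                ytr.astype(float),
                folds,
                n_lambdas=n_lambdas,
                lambda_min_ratio=lambda_min_ratio,
                patience=patience,
            )
            clf = LinearClassifier(
                weights=w.copy(),
                intercept=w0,
                lam=lam,
                mean_=mu,
                sd_=sd,
                subsample_id=s,
                fold_id=f,
            )
            classifiers.append(clf)
            # out-of-fold scores: held-out fold subjects + undersampled-away subjects
            prob_subsample[s, sub_idx[te]] = clf.predict_proba(Xs[te])
            if len(excluded):
                prob_excluded[f] = clf.predict_proba(X[excluded])
        if len(excluded):
            prob_subsample[s, excluded] = prob_excluded.mean(axis=0)
    if all(c.n_nonzero == 0 for c in classifiers):
        warnings.warn(
            "every classifier in the ensemble is intercept-only (degenerate penalty path)",
            stacklevel=2,
        )
    return MarkerEnsemble(
        classifiers=classifiers,
        oof_probability=prob_subsample.mean(axis=0),
        subject_ids=dataset.participants["subject_id"].astype(str).tolist(),
        diagnosis=y.copy(),
        n_edges=m,
        config=config,
    )


def predict(ensemble: MarkerEnsemble, dataset: FCDataset) -> DiagnosticResult:
    """Mean diagnostic probability over all classifiers; label 1 iff > 0.5."""
    if dataset.n_edges != ensemble.n_edges:
        raise DimensionError(
            f"dataset has {dataset.n_edges} edges but the marker expects {ensemble.n_edges}"
        )
    total = np.zeros(dataset.n_subjects)
    for clf in ensemble.classifiers:
        total += clf.predict_proba(dataset.fc)
    prob = total / ensemble.n_classifiers
    return DiagnosticResult(
        subject_ids=dataset.participants["subject_id"].astype(str).tolist(),
        probability=prob,
        label=(prob > 0.5).astype(int),
    )


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC: concordant score pairs with ties counted as 1/2."""
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def compute_metrics(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> PerformanceMetrics:
    """Confusion-matrix metrics at the strict > threshold rule, plus AUC.

    With a single class present the AUC (and the rate whose denominator is
    empty) is NaN; the remaining metrics are still returned.
    """
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise DataValidationError("labels must be coded 0/1")
    pred = (np.asarray(probabilities) > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n = tp + tn + fp + fn
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return PerformanceMetrics(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        mcc=float(mcc),
        auc=auc_score(labels, probabilities),
    )
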