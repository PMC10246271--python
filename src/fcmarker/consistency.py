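"""Cross-dataset reproducibility of diagnosis effects.

The diagnosis effect of an edge in one dataset is its two-sample pooled
t-value (patient minus control).  Reproducibility across datasets is
assessed three ways: the Pearson correlation of t-vectors between datasets
with a label-permutation null, the count of edges whose t-values share one
strict sign across all datasets, and an exact binomial test asking whether
the marker's discriminative edges are sign-consistent more often than
edges are in the connectome at large.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets import FCDataset
from .errors import DataValidationError
from .inference import permutation_pvalue

__all__ = [
    "EffectVector",
    "diagnosis_t",
    "cross_dataset_correlation",
    "sign_consistency",
    "binomial_consistency_test",
]


@dataclass
class EffectVector:
    """Per-edge diagnosis t-values for one dataset."""

    t: np.ndarray
    df: int
    name: str
    zero_variance: np.ndarray | None = None  # edges flagged t := 0


def _pooled_t(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    pat = X[y == 1]
    con = X[y == 0]
    n1, n0 = len(pat), len(con)
    if n1 < 2 or n0 < 2:
        raise DataValidationError("both groups need at least 2 subjects for a t-value")
    diff = pat.mean(axis=0) - con.mean(axis=0)
    sp2 = ((n1 - 1) * pat.var(axis=0, ddof=1) + (n0 - 1) * con.var(axis=0, ddof=1)) / (
        n1 + n0 - 2
    )
    se2 = sp2 * (1.0 / n1 + 1.0 / n0)
    flagged = se2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    t[flagged] = 0.0
    return t, n1 + n0 - 2, flagged


def diagnosis_t(dataset: FCDataset, welch: bool = False) -> EffectVector:
    """Two-sample t per edge, signed patient minus control.

    Student's pooled-variance t by default; ``welch=True`` switches to the
    unequal-variance form.  Zero-variance edges get t = 0 and a flag.
    """
    y = dataset.diagnosis
    if welch:
        pat, con = dataset.fc[y == 1], dataset.fc[y == 0]
        if len(pat) < 2 or len(con) < 2:
            raise DataValidationError("both groups need at least 2 subjects for a t-value")
        res = stats.ttest_ind(pat, con, axis=0, equal_var=False)
        t = np.nan_to_num(res.statistic, nan=0.0)
        flagged = ~np.isfinite(res.statistic)
        df = len(pat) + len(con) - 2
    else:
        t, df, flagged = _pooled_t(dataset.fc, y)
    return EffectVector(t=t, df=df, name=dataset.name, zero_variance=flagged)


def cross_dataset_correlation(
    a: EffectVector,
    b_dataset: FCDataset,
    B: int = 1000,
    seed: int = 0,
    subset: np.ndarray | None = None,
) -> tuple[float, float]:
    """Pearson r of t-vectors between datasets, with a one-sided permutation p.

    The first dataset's t-vector is held fixed; the null shuffles the
    second dataset's diagnosis labels, recomputes its t-vector, and
    correlates.  p = (1 + #{null r >= observed}) / (1 + B).
    """
    idx = np.arange(len(a.t)) if subset is None else np.asarray(subset)
    tb = diagnosis_t(b_dataset).t
    if len(tb) != len(a.t):
        raise DataValidationError("datasets have different edge counts")
    ta = a.t[idx]
    if np.std(ta) == 0 or np.std(tb[idx]) == 0:
        raise DataValidationError("degenerate (constant) t-vector")
    r_obs = float(np.corrcoef(ta, tb[idx])[0, 1])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    y = b_dataset.diagnosis
    null = np.empty(B)
    for b in range(B):
        perm = rng.permutation(y)
        t_perm, _, _ = _pooled_t(b_dataset.fc, perm)
        null[b] = np.corrcoef(ta, t_perm[idx])[0, 1]
    return r_obs, permutation_pvalue(r_obs, null)


def sign_consistency(
    effects: list[EffectVector], subset: np.ndarray | None = None
) -> int:
    """Edges whose t-values share one strict sign across every vector.

    A zero t-value breaks consistency for its edge.
    """
    if len(effects) < 2:
        raise DataValidationError("need at least 2 effect vectors")
    T = np.vstack([e.t for e in effects])
    if subset is not None:
        T = T[:, np.asarray(subset)]
    all_pos = (T > 0).all(axis=0)
    all_neg = (T < 0).all(axis=0)
    return int(np.sum(all_pos | all_neg))


def binomial_consistency_test(
    x_set: int, n_set: int, K_whole: int, M_whole: int
) -> float:
    """Exact upper-tail binomial test of sign-consistency enrichment.

    Under the null, each of the ``n_set`` discriminative edges is
    sign-consistent with probability p = K_whole / M_whole, the base rate
    in the whole connectome; returns P(X >= x_set) for X ~ Bi(n_set, p).
    """
    if not 0 <= x_set <= n_set:
        raise DataValidationError("need 0 <= x_set <= n_set")
    if not 0 <= K_whole <= M_whole or M_whole <= 0:
        raise DataValidationError("need 0 <= K_whole <= M_whole with M_whole > 0")
    if K_whole == 0:
        if x_set > 0:
            warnings.warn(
                "consistent edges observed although the whole-connectome rate is zero",
                stacklevel=2,
            )
            return 0.0
        return 1.0
    p = K_whole / M_whole
    return float(stats.binom.sf(x_set - 1, n_set, p))
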