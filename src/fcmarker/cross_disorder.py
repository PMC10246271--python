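"""Cross-disorder sensitivity and dimensional mapping.

A marker trained on one disorder can be applied to patients of another;
the fraction it labels positive (mean diagnostic probability strictly
above 0.5) is its cross-disorder sensitivity, tested against the
sensitivities produced by label-permuted ensembles.  Plotting every
subject at the coordinates given by two markers' diagnostic probabilities
yields a two-dimensional map whose quadrants (split at 0.5 on each axis)
summarise where each clinical group lives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .consistency import diagnosis_t
from .datasets import FCDataset
from .ensemble import MarkerEnsemble, predict
from .errors import DataValidationError, DimensionError
from .inference import DiscriminativeFCSet, permutation_pvalue, permuted_ensembles

__all__ = [
    "CrossDisorderMap",
    "cross_sensitivity",
    "dimensional_map",
    "effect_correlation_on_marker",
    "spatial_overlap",
]

QUADRANTS = ("low-low", "high-low", "low-high", "high-high")  # (A, B) axes


@dataclass
class CrossDisorderMap:
    """Per-subject coordinates under two markers, with quadrant summaries."""

    marker_a: str
    marker_b: str
    coordinates: pd.DataFrame  # columns: group, subject_id, p_a, p_b, quadrant
    quadrant_counts: dict[str, dict[str, int]]
    modal_quadrant: dict[str, str]


def cross_sensitivity(
    marker: MarkerEnsemble,
    foreign_patients: FCDataset,
    discovery: FCDataset | None = None,
    B: int = 500,
    seed: int = 0,
    train_kwargs: dict | None = None,
    null_sensitivities: np.ndarray | None = None,
) -> tuple[float, float]:
    """Fraction of another disorder's patients the marker labels positive.

    The null distribution is the same statistic computed from ensembles
    retrained on label-shuffled discovery data.  Pass ``null_sensitivities``
    to reuse a null already collected from the shared permutation stream
    (see :func:`fcmarker.inference.permutation_analysis`); otherwise
    ``discovery`` is required and the permutations are run here.
    """
    if foreign_patients.n_subjects == 0:
        raise DataValidationError("empty foreign patient set")
    prob = predict(marker, foreign_patients).probability
    sensitivity = float(np.mean(prob > 0.5))
    if null_sensitivities is None:
        if discovery is None:
            raise DataValidationError(
                "need either a discovery dataset or precomputed null sensitivities"
            )
        null_sensitivities = np.array(
            [
                float(np.mean(predict(pe, foreign_patients).probability > 0.5))
                for pe in permuted_ensembles(discovery, B, seed, train_kwargs)
            ]
        )
    p = permutation_pvalue(sensitivity, np.asarray(null_sensitivities))
    return sensitivity, p


def _quadrant(pa: float, pb: float) -> str:
    # boundary values (exactly 0.5) fall on the low side, like the strict
    # > 0.5 labelling rule
    a = "high" if pa > 0.5 else "low"
    b = "high" if pb > 0.5 else "low"
    return f"{a}-{b}"


def dimensional_map(
    marker_a: MarkerEnsemble,
    marker_b: MarkerEnsemble,
    datasets: dict[str, FCDataset],
    name_a: str = "A",
    name_b: str = "B",
) -> CrossDisorderMap:
    """Project groups of subjects onto the plane of two markers."""
    if marker_a.n_edges != marker_b.n_edges:
        raise DimensionError("the two markers expect different edge counts")
    frames = []
    counts: dict[str, dict[str, int]] = {}
    modal: dict[str, str] = {}
    for group, ds in datasets.items():
        pa = predict(marker_a, ds).probability
        pb = predict(marker_b, ds).probability
        quad = [_quadrant(x, y) for x, y in zip(pa, pb)]
        frames.append(
            pd.DataFrame(
                {
                    "group": group,
                    "subject_id": ds.participants["subject_id"].astype(str),
                    "p_a": pa,
                    "p_b": pb,
                    "quadrant": quad,
                }
            )
        )
        c = {q: quad.count(q) for q in QUADRANTS}
        counts[group] = c
        modal[group] = max(QUADRANTS, key=lambda q: c[q])
    return CrossDisorderMap(
        marker_a=name_a,
        marker_b=name_b,
        coordinates=pd.concat(frames, ignore_index=True),
        quadrant_counts=counts,
        modal_quadrant=modal,
    )


def effect_correlation_on_marker(
    marker_edges: DiscriminativeFCSet,
    dis_a: FCDataset,
    dis_b: FCDataset,
    B: int = 500,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Similarity of two disorders' diagnosis effects on the marker's edges.

    Restricted separately to the marker's hyper- and hypo-connections,
    correlates the per-edge t-vectors of the two case/control datasets;
    the permutation null shuffles the second dataset's labels.  Classes
    with fewer than 3 edges are skipped with a warning.
    """
    from .consistency import cross_dataset_correlation

    ta = diagnosis_t(dis_a)
    out: dict[str, tuple[float, float]] = {}
    for cls, edges in (("hyper", marker_edges.hyper_edges), ("hypo", marker_edges.hypo_edges)):
        if len(edges) < 3:
            warnings.warn(f"{cls}-connection class has {len(edges)} edges; skipped", stacklevel=2)
            continue
        out[cls] = cross_dataset_correlation(ta, dis_b, B=B, seed=seed, subset=edges)
    return out


def spatial_overlap(
    set_a: DiscriminativeFCSet | np.ndarray,
    set_b: DiscriminativeFCSet | np.ndarray,
    M: int,
    include_equal: bool = False,
) -> tuple[int, float]:
    """Edge overlap of two markers and its hypergeometric tail probability.

    Uses the same tail convention as the network enrichment (strict
    P(X > x) by default) with K = |A| and n = |B| out of M edges.
    """
    a = set_a.edges if isinstance(set_a, DiscriminativeFCSet) else np.asarray(set_a)
    b = set_b.edges if isinstance(set_b, DiscriminativeFCSet) else np.asarray(set_b)
    if len(a) and a.max() >= M or len(b) and b.max() >= M:
        raise DataValidationError("edge indices exceed the stated universe size")
    x = len(np.intersect1d(a, b))
    rv = stats.hypergeom(M, len(a), len(b))
    p = rv.sf(x - 1) if include_equal else rv.sf(x)
    return x, float(p)
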