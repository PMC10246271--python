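"""Network-level characterization of discriminative edges.

Every edge belongs to exactly one category: the unordered pair of
resting-state networks of its two ROIs (a within-network category when
they coincide).  Over-representation of a marker's hyper- or
hypo-connections in a category is tested with the hypergeometric tail

    P = 1 - HypergeometricCDF(x; M, K, n) = P(X > x)

where x is the overlap between the edge set and the category, M the total
edge count, K the category size and n the edge-set size.  The strict tail
reproduces the hygecdf-based convention common in this literature; the
conventional inclusive tail P(X >= x) is available behind a flag and is
never smaller.
Bonferroni correction runs over categories x {hyper, hypo}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .edges import Atlas, edge_pairs
from .errors import DataValidationError, InvalidAtlasError

__all__ = [
    "EnrichmentResult",
    "edge_category",
    "edge_categories",
    "category_sizes",
    "enrichment_test",
    "enrich_edge_sets",
]


@dataclass
class EnrichmentResult:
    category: tuple[str, str]
    x: int  # overlap count
    M: int  # total edges
    K: int  # category edge count
    n: int  # edge-set size
    p: float
    include_equal: bool = False


def edge_category(edge: int, atlas: Atlas) -> tuple[str, str]:
    """Unordered network pair of an edge; (net, net) when within-network."""
    rows, cols = edge_pairs(atlas.roi_count)
    i, j = int(rows[edge]), int(cols[edge])
    a, b = atlas.networks[i], atlas.networks[j]
    return tuple(sorted((a, b)))


def edge_categories(atlas: Atlas) -> list[tuple[str, str]]:
    """Category of every edge, in flat edge order."""
    rows, cols = edge_pairs(atlas.roi_count)
    nets = np.asarray(atlas.networks)
    return [tuple(sorted((a, b))) for a, b in zip(nets[rows], nets[cols])]


def category_sizes(atlas: Atlas) -> dict[tuple[str, str], int]:
    """Edge count per category; values sum to the total edge count."""
    sizes: dict[tuple[str, str], int] = {}
    for cat in edge_categories(atlas):
        sizes[cat] = sizes.get(cat, 0) + 1
    return sizes


def enrichment_test(
    edge_set,
    category: tuple[str, str],
    atlas: Atlas,
    include_equal: bool = False,
) -> EnrichmentResult:
    """Hypergeometric over-representation of an edge set in one category."""
    category = tuple(sorted(category))
    cats = edge_categories(atlas)
    M = len(cats)
    K = sum(1 for c in cats if c == category)
    edge_set = np.asarray(sorted(set(int(e) for e in edge_set)))
    if len(edge_set) and (edge_set.min() < 0 or edge_set.max() >= M):
        raise DataValidationError("edge set indices outside the atlas edge range")
    n = len(edge_set)
    x = sum(1 for e in edge_set if cats[e] == category)
    if K == 0:
        p = 0.0 if not include_equal else (1.0 if x == 0 else 0.0)
        return EnrichmentResult(category, x, M, K, n, float(p), include_equal)
    rv = stats.hypergeom(M, K, n)
    p = rv.sf(x - 1) if include_equal else rv.sf(x)  # sf(x) = P(X > x)
    return EnrichmentResult(category, x, M, K, n, float(p), include_equal)


def enrich_edge_sets(
    edge_sets: dict[str, np.ndarray],
    atlas: Atlas,
    alpha: float = 0.05,
    include_equal: bool = False,
) -> pd.DataFrame:
    """Enrichment of each edge set (e.g. hyper/hypo) across all categories.

    The Bonferroni denominator is (number of categories) x (number of edge
    sets), matching a design that tests hyper- and hypo-connections
    separately.
    """
    sizes = category_sizes(atlas)
    n_tests = len(sizes) * len(edge_sets)
    rows = []
    for set_name, edges in edge_sets.items():
        for cat in sorted(sizes):
            res = enrichment_test(edges, cat, atlas, include_equal=include_equal)
            rows.append(
                {
                    "edge_set": set_name,
                    "category": "-".join(cat) if cat[0] != cat[1] else f"within-{cat[0]}",
                    "x": res.x,
                    "K": res.K,
                    "n": res.n,
                    "M": res.M,
                    "p": res.p,
                    "significant": res.p < alpha / n_tests,
                }
            )
    return pd.DataFrame(rows)
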