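"""Edge-index conventions and the ROI atlas.

A connectome on R regions of interest is stored as a flat vector of the
R(R-1)/2 unique edges, ordered row-major over the strict upper triangle of
the correlation matrix: (0,1), (0,2), ..., (0,R-1), (1,2), ...  This is the
same order as ``numpy.triu_indices(R, k=1)``, and every module in the
package addresses edges through it, so an edge index means the same ROI
pair everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EdgeIndexError, InvalidAtlasError

__all__ = ["Atlas", "edge_count", "edge_index", "edge_pair", "edge_pairs", "edge_labels"]


def edge_count(roi_count: int) -> int:
    """Number of unique unordered ROI pairs, R(R-1)/2."""
    if roi_count < 2:
        raise InvalidAtlasError(f"need at least 2 ROIs, got {roi_count}")
    return roi_count * (roi_count - 1) // 2


def edge_index(i: int, j: int, roi_count: int) -> int:
    """Flat index of the edge between ROIs i < j (row-major upper triangle)."""
    if not (0 <= i < j < roi_count):
        raise EdgeIndexError(f"invalid ROI pair ({i}, {j}) for R={roi_count}")
    # edges before row i: sum_{k<i} (R-1-k); offset within row: j - i - 1
    return i * roi_count - i * (i + 1) // 2 + (j - i - 1)


def edge_pair(index: int, roi_count: int) -> tuple[int, int]:
    """Inverse of :func:`edge_index`: the (i, j) ROI pair of a flat edge index."""
    m = edge_count(roi_count)
    if not (0 <= index < m):
        raise EdgeIndexError(f"edge index {index} out of range for R={roi_count}")
    i = 0
    row_len = roi_count - 1
    while index >= row_len:
        index -= row_len
        i += 1
        row_len -= 1
    return i, i + 1 + index


def edge_pairs(roi_count: int) -> tuple[np.ndarray, np.ndarray]:
    """Arrays (i, j) of all edges in flat order; matches numpy's triu order."""
    if roi_count < 2:
        raise InvalidAtlasError(f"need at least 2 ROIs, got {roi_count}")
    return np.triu_indices(roi_count, k=1)


def edge_labels(roi_count: int) -> list[str]:
    """Column labels 'e<i>_<j>' for the flat edge vector."""
    rows, cols = edge_pairs(roi_count)
    return [f"e{i}_{j}" for i, j in zip(rows, cols)]


@dataclass(frozen=True)
class Atlas:
    """A fixed parcellation: ROI names and their resting-state-network labels.

    The full-size atlas in this line of work has 379 regions (360 cortical
    parcels plus 19 subcortical structures) with seven cortical
    resting-state networks and an extra "subcortical" label; any size works
    as long as every ROI carries a network label.
    """

    roi_names: tuple[str, ...]
    networks: tuple[str, ...]
    name: str = field(default="atlas")

    def __post_init__(self) -> None:
        if len(self.roi_names) < 2:
            raise InvalidAtlasError("atlas needs at least 2 ROIs")
        if len(self.networks) != len(self.roi_names):
            raise InvalidAtlasError("every ROI needs a network label")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise InvalidAtlasError("ROI names must be unique")
        if any(not n for n in self.networks):
            raise InvalidAtlasError("empty network label")

    @property
    def roi_count(self) -> int:
        return len(self.roi_names)

    @property
    def n_edges(self) -> int:
        return edge_count(self.roi_count)

    @classmethod
    def from_tsv(cls, path) -> "Atlas":
        df = pd.read_csv(path, sep="\t")
        required = {"roi_index", "roi_name", "network"}
        if not required <= set(df.columns):
            raise InvalidAtlasError(f"atlas table needs columns {sorted(required)}")
        df = df.sort_values("roi_index")
        if not np.array_equal(df["roi_index"].to_numpy(), np.arange(len(df))):
            raise InvalidAtlasError("roi_index must be 0..R-1 without gaps")
        return cls(tuple(df["roi_name"]), tuple(df["network"]))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "roi_index": np.arange(self.roi_count),
                "roi_name": self.roi_names,
                "network": self.networks,
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def synthetic(cls, roi_count: int, networks: tuple[str, ...] | None = None) -> "Atlas":
        """Evenly assign ROIs to the canonical network labels (synthetic atlas)."""
        if networks is None:
            networks = (
                "visual",
                "somatomotor",
                "DAN",
                "VAN",
                "limbic",
                "FPN",
                "DMN",
                "subcortical",
            )
        labels = tuple(networks[i % len(networks)] for i in range(roi_count))
        return cls(
            tuple(f"roi{i:03d}" for i in range(roi_count)),
            labels,
            name=f"synthetic{roi_count}",
        )
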