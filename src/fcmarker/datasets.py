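"""Dataset containers and on-disk formats.

An :class:`FCDataset` joins a participant table (subject id, imaging site,
diagnosis, age, sex) to a subjects-by-edges matrix of Fisher-z connectivity
values.  Interchange formats are plain TSV (participants, connectivity with
``e<i>_<j>`` edge headers, atlas) with an optional ``.npy`` container plus a
JSON sidecar for large matrices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .edges import Atlas, edge_labels
from .errors import AlignmentError, DataValidationError

__all__ = ["FCDataset", "read_dataset", "write_dataset", "split_by_stage", "validate_participants"]

PARTICIPANT_COLUMNS = ["subject_id", "site", "diagnosis", "age", "sex"]


def validate_participants(participants: pd.DataFrame, require_min_site: bool = True) -> None:
    """Check the structural invariants of a participant table."""
    missing = set(PARTICIPANT_COLUMNS) - set(participants.columns)
    if missing:
        raise DataValidationError(f"participant table missing columns {sorted(missing)}")
    if participants["subject_id"].duplicated().any():
        dup = participants.loc[participants["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise DataValidationError(f"duplicate subject_id {dup!r}")
    diag = participants["diagnosis"]
    if not diag.isin([0, 1]).all():
        raise DataValidationError("diagnosis must be coded 0 (control) / 1 (patient)")
    age = participants["age"]
    if (age.dropna() <= 0).any():
        raise DataValidationError("ages must be positive")
    if require_min_site:
        counts = participants["site"].value_counts()
        small = counts[counts < 2]
        if len(small):
            raise DataValidationError(f"sites with fewer than 2 subjects: {list(small.index)}")


@dataclass
class FCDataset:
    """Participants joined to a subjects x edges matrix of Fisher-z values.

    Row order of ``fc`` matches the row order of ``participants``.  When the
    dataset was simulated, ``truth`` carries the generating parameters
    (planted effect edges, site effects, seed) for recovery tests.
    """

    participants: pd.DataFrame
    fc: np.ndarray
    atlas: Atlas
    name: str = "dataset"
    truth: dict[str, Any] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.participants = self.participants.reset_index(drop=True)
        self.fc = np.asarray(self.fc, dtype=np.float64)
        validate_participants(self.participants)
        if self.fc.ndim != 2:
            raise DataValidationError("fc must be a 2-D subjects x edges matrix")
        if len(self.participants) != self.fc.shape[0]:
            raise AlignmentError(
                f"{len(self.participants)} participants but {self.fc.shape[0]} fc rows"
            )
        if self.fc.shape[1] != self.atlas.n_edges:
            raise AlignmentError(
                f"fc has {self.fc.shape[1]} edges but atlas implies {self.atlas.n_edges}"
            )
        bad = ~np.isfinite(self.fc)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            sid = self.participants["subject_id"].iloc[i]
            raise DataValidationError(
                f"non-finite connectivity value for subject {sid!r} at edge {j}"
            )

    @property
    def n_subjects(self) -> int:
        return self.fc.shape[0]

    @property
    def n_edges(self) -> int:
        return self.fc.shape[1]

    @property
    def diagnosis(self) -> np.ndarray:
        return self.participants["diagnosis"].to_numpy(dtype=int)

    @property
    def sites(self) -> np.ndarray:
        return self.participants["site"].to_numpy()

    def subset(self, index: np.ndarray, name: str | None = None, *, _validate_sites: bool = True) -> "FCDataset":
        """Row subset by boolean mask or integer index, preserving order."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        sub = FCDataset.__new__(FCDataset)
        sub.participants = self.participants.iloc[index].reset_index(drop=True)
        sub.fc = self.fc[index]
        sub.atlas = self.atlas
        sub.name = name if name is not None else self.name
        sub.truth = self.truth
        return sub

    def with_diagnosis(self, labels: np.ndarray, name: str | None = None) -> "FCDataset":
        """Copy of the dataset with replaced diagnosis labels (for permutation)."""
        participants = self.participants.copy()
        participants["diagnosis"] = np.asarray(labels, dtype=int)
        out = FCDataset.__new__(FCDataset)
        out.participants = participants
        out.fc = self.fc
        out.atlas = self.atlas
        out.name = name if name is not None else self.name
        out.truth = self.truth
        return out


def split_by_stage(dataset: FCDataset) -> dict[str, FCDataset]:
    """Partition a dataset into developmental stages by age.

    child: age < 12; adolescent: 12 < age < 18; adult: age >= 18.  The
    bounds for child and adolescent are strict as printed, so subjects aged
    exactly 12 fall in neither; ages of exactly 18 go to the adult split.
    Subjects with missing age are dropped with a warning.
    """
    age = pd.to_numeric(dataset.participants["age"], errors="coerce")
    if age.isna().any():
        lost = dataset.participants.loc[age.isna(), "subject_id"].tolist()
        warnings.warn(f"excluding subjects with missing age: {lost}", stacklevel=2)
    masks = {
        "child": (age < 12).to_numpy(),
        "adolescent": ((age > 12) & (age < 18)).to_numpy(),
        "adult": (age >= 18).to_numpy(),
    }
    out = {}
    for stage, mask in masks.items():
        out[stage] = dataset.subset(mask, name=f"{dataset.name}_{stage}")
    return out


def write_dataset(dataset: FCDataset, directory, fc_format: str = "tsv") -> dict[str, Path]:
    """Write participants, connectivity, atlas (and truth, if any) to a directory.

    ``fc_format`` is "tsv" (portable, full float precision via repr) or
    "npy" (binary container with a JSON sidecar recording the edge-order
    convention and subject list).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["participants"] = directory / "participants.tsv"
    dataset.participants.to_csv(paths["participants"], sep="\t", index=False)
    paths["atlas"] = directory / "atlas.tsv"
    dataset.atlas.to_tsv(paths["atlas"])
    subjects = dataset.participants["subject_id"].astype(str).tolist()
    if fc_format == "tsv":
        paths["fc"] = directory / "fc.tsv"
        df = pd.DataFrame(dataset.fc, columns=edge_labels(dataset.atlas.roi_count))
        df.insert(0, "subject_id", subjects)
        # default float formatting is the shortest exact representation, so
        # the text round-trip is bit-stable
        df.to_csv(paths["fc"], sep="\t", index=False)
    elif fc_format == "npy":
        paths["fc"] = directory / "fc.npy"
        np.save(paths["fc"], dataset.fc)
        sidecar = {
            "roi_count": dataset.atlas.roi_count,
            "edge_order": "upper-triangle-row-major",
            "subjects": subjects,
        }
        paths["fc_sidecar"] = directory / "fc.json"
        paths["fc_sidecar"].write_text(json.dumps(sidecar))
    else:
        raise ValueError(f"unknown fc_format {fc_format!r}")
    if dataset.truth is not None:
        paths["truth"] = directory / "truth.json"
        paths["truth"].write_text(json.dumps(_jsonable(dataset.truth), indent=1))
    return paths


def read_dataset(participants_path, fc_path, atlas_path, name: str = "dataset") -> FCDataset:
    """Read a dataset from disk, verifying subject alignment by id."""
    participants = pd.read_csv(participants_path, sep="\t")
    atlas = Atlas.from_tsv(atlas_path)
    fc_path = Path(fc_path)
    if fc_path.suffix == ".npy":
        fc = np.load(fc_path)
        sidecar = json.loads(fc_path.with_suffix(".json").read_text())
        subjects = sidecar["subjects"]
    else:
        # round_trip parsing keeps the text format bit-stable
        df = pd.read_csv(fc_path, sep="\t", float_precision="round_trip")
        subjects = df["subject_id"].astype(str).tolist()
        expected = edge_labels(atlas.roi_count)
        got = [c for c in df.columns if c != "subject_id"]
        if got != expected:
            raise AlignmentError("fc edge headers do not match the atlas edge order")
        fc = df[expected].to_numpy(dtype=np.float64)
    table_ids = participants["subject_id"].astype(str).tolist()
    if table_ids != subjects:
        raise AlignmentError("subject ids in participants table and fc matrix differ")
    return FCDataset(participants, fc, atlas, name=name)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
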