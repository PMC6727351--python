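"""Validated in-memory containers for mixtures, proportions and signatures.

All matrices are stored as float64 numpy arrays with explicit row/column
identifiers, mirroring the features-by-samples layout of a GEO-style
expression or methylation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

Modality = Literal["expression", "methylation"]

_BETA_TOL = 1e-9


def _check_unique(ids: Sequence[str], kind: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {kind} identifiers: {sorted(set(dups))[:5]}")
    return ids


@dataclass
class MixtureMatrix:
    """Observed mixed signals: features x samples.

    Parameters
    ----------
    values
        P x N matrix. Expression on the linear scale, or methylation beta
        values in [0, 1].
    feature_ids, sample_ids
        Unique row / column identifiers.
    modality
        ``"expression"`` or ``"methylation"``; methylation activates the
        [0, 1] bound check on load and on the signature matrix downstream.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    modality: Modality = "expression"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        p, n = self.values.shape
        if len(self.feature_ids) != p or len(self.sample_ids) != n:
            raise ValueError("identifier lengths do not match matrix shape")
        if self.modality not in ("expression", "methylation"):
            raise ValueError(f"unknown modality {self.modality!r}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "missing or non-finite value at feature "
                f"{self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        if self.modality == "methylation":
            out = (self.values < -_BETA_TOL) | (self.values > 1 + _BETA_TOL)
            if out.any():
                i, j = np.argwhere(out)[0]
                raise ValueError(
                    f"methylation beta value {self.values[i, j]} outside [0, 1] "
                    f"at feature {self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
                )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def restrict(self, feature_ids: Sequence[str]) -> "MixtureMatrix":
        """Row subset in the given order (used on selected marker sets)."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise KeyError(f"features not present in matrix: {missing[:5]}")
        rows = [index[f] for f in feature_ids]
        return MixtureMatrix(
            self.values[rows, :], list(feature_ids), list(self.sample_ids), self.modality
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class ProportionMatrix:
    """Cell-type mixing proportions: cell types x samples.

    Every column lies on the unit simplex (entries in [0, 1], summing to 1
    within 1e-8).
    """

    values: np.ndarray
    celltype_labels: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.celltype_labels = _check_unique(self.celltype_labels, "cell-type")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        k, n = self.values.shape
        if len(self.celltype_labels) != k or len(self.sample_ids) != n:
            raise ValueError("identifier lengths do not match matrix shape")
        if not np.isfinite(self.values).all():
            raise ValueError("proportions contain non-finite values")
        if (self.values < -1e-9).any() or (self.values > 1 + 1e-9).any():
            raise ValueError("proportions must lie in [0, 1]")
        sums = self.values.sum(axis=0)
        if np.abs(sums - 1.0).max() > 1e-8:
            s = np.argmax(np.abs(sums - 1.0))
            raise ValueError(
                f"column {self.sample_ids[s]!r} sums to {sums[s]}, not 1"
            )

    @property
    def n_celltypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.celltype_labels, columns=self.sample_ids)


@dataclass
class SignatureMatrix:
    """Pure cell-type profiles over a feature subset: features x cell types.

    Entries are nonnegative; for methylation additionally bounded by 1.
    """

    values: np.ndarray
    feature_ids: list[str]
    celltype_labels: list[str]
    modality: Modality = "expression"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.celltype_labels = _check_unique(self.celltype_labels, "cell-type")
        m, k = self.values.shape
        if len(self.feature_ids) != m or len(self.celltype_labels) != k:
            raise ValueError("identifier lengths do not match matrix shape")
        if not np.isfinite(self.values).all():
            raise ValueError("signature contains non-finite values")
        if (self.values < -1e-9).any():
            raise ValueError("signature entries must be nonnegative")
        if self.modality == "methylation" and (self.values > 1 + _BETA_TOL).any():
            raise ValueError("methylation signature entries must be <= 1")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_celltypes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.celltype_labels)


@dataclass
class FeatureSet:
    """An ordered, duplicate-free list of selected feature identifiers."""

    feature_ids: list[str]
    selection_method: str = "unspecified"

    def __post_init__(self) -> None:
        self.feature_ids = _check_unique(self.feature_ids, "feature")

    @property
    def size(self) -> int:
        return len(self.feature_ids)

    def __len__(self) -> int:
        return len(self.feature_ids)

    def __iter__(self):
        return iter(self.feature_ids)

    def intersection_size(self, other: "FeatureSet") -> int:
        return len(set(self.feature_ids) & set(other.feature_ids))
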