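"""Reading and writing of matrices as TSV/CSV.

TSV is the canonical dialect (GEO-style matrix exports); CSV is accepted on
read based on the file extension. The first column holds feature IDs and the
header row holds sample IDs. Values are written at full double precision so
that a write/read round trip is bit-identical.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .containers import MixtureMatrix, Modality, ProportionMatrix, SignatureMatrix

AnyMatrix = Union[MixtureMatrix, ProportionMatrix, SignatureMatrix]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | os.PathLike, modality: Modality = "expression") -> MixtureMatrix:
    """Load a features-by-samples matrix from TSV or CSV.

    The loader rejects missing values, non-numeric cells, duplicate
    identifiers, and (for methylation) values outside [0, 1], naming the
    offending cell in each case.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    feature_ids = [str(i) for i in df.index]
    sample_ids = [str(c) for c in df.columns]
    values = np.empty(df.shape, dtype=np.float64)
    raw = df.to_numpy()
    # parse with float() for exact round trip (pandas' parser can lose the
    # last ulp); report the offending cell on failure
    for j in range(raw.shape[1]):
        for i in range(raw.shape[0]):
            cell = raw[i, j]
            try:
                v = float(cell)
            except (TypeError, ValueError):
                v = float("nan")
            if not np.isfinite(v):
                raise ValueError(
                    f"{path}: missing or non-numeric value {cell!r} at "
                    f"feature {feature_ids[i]!r}, sample {sample_ids[j]!r}"
                )
            values[i, j] = v
    return MixtureMatrix(values, feature_ids, sample_ids, modality)


def write_matrix(m: AnyMatrix, path: str | os.PathLike) -> None:
    """Write a matrix as TSV with row/column identifiers.

    Values are formatted with 17 significant digits (round-trip exact for
    float64). Empty matrices are rejected.
    """
    path = Path(path)
    frame = m.to_frame()
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError("refusing to write an empty matrix")
    frame.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def write_feature_set(features, path: str | os.PathLike) -> None:
    Path(path).write_text("\n".join(features) + "\n")


def read_feature_set(path: str | os.PathLike) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
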