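"""Benchmarking metrics for deconvolution results.

Four quantities summarize performance: per-cell-type Pearson correlation
between estimated and true proportions, the root-mean-squared bias
sqrt(sum (H - Hhat)^2 / KN), the goodness of fit r(vec(Y), vec(WH)), and the
reconstruction error RMSE = sqrt(sum (Y - WH)^2 / PN). Because
reference-free components are unlabeled, all truth comparisons first match
components to the truth by optimal assignment on the correlation matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureSet, MixtureMatrix, ProportionMatrix, SignatureMatrix
from .engine import align_components, apply_alignment


def _row_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.empty(a.shape[0])
    for i in range(a.shape[0]):
        x, y = a[i], b[i]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"zero-variance row {i} in correlation; reporting NaN", stacklevel=3
            )
            out[i] = np.nan
            continue
        xc, yc = x - x.mean(), y - y.mean()
        out[i] = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    return out


def corr_with_true(h_est: ProportionMatrix, h_true: ProportionMatrix) -> np.ndarray:
    """Per-type Pearson correlation across samples (inputs already aligned)."""
    if h_est.values.shape != h_true.values.shape:
        raise ValueError("shape mismatch between estimated and true proportions")
    return _row_pearson(h_true.values, h_est.values)


def rms_bias(h_est: ProportionMatrix, h_true: ProportionMatrix) -> float:
    """Root mean squared difference between proportion matrices."""
    if h_est.values.shape != h_true.values.shape:
        raise ValueError("shape mismatch between estimated and true proportions")
    k, n = h_true.values.shape
    return float(np.sqrt(np.sum((h_true.values - h_est.values) ** 2) / (k * n)))


def goodness_of_fit(
    y_sub: MixtureMatrix, w: SignatureMatrix, h: ProportionMatrix
) -> float:
    """Pearson correlation between vectorized observed and reconstructed data."""
    recon = w.values @ h.values
    if recon.shape != y_sub.values.shape:
        raise ValueError("reconstruction shape does not match observations")
    yv, rv = y_sub.values.ravel(), recon.ravel()
    if np.ptp(yv) == 0 or np.ptp(rv) == 0:
        warnings.warn("constant matrix in goodness-of-fit; reporting NaN", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(yv, rv)[0, 1])


def model_rmse(y_sub: MixtureMatrix, w: SignatureMatrix, h: ProportionMatrix) -> float:
    """Reconstruction RMSE sqrt(sum (Y - WH)^2 / PN) over the fitted subset."""
    recon = w.values @ h.values
    if recon.shape != y_sub.values.shape:
        raise ValueError("reconstruction shape does not match observations")
    return float(np.sqrt(np.mean((y_sub.values - recon) ** 2)))


def true_cts_markers(
    pure_means: SignatureMatrix, n: int, modality: str | None = None
) -> FeatureSet:
    """Cell-type-specific markers derivable when pure profiles are known.

    Each feature is scored per cell type by the log fold change of its mean
    in that type against the mean of the other types' means (expression), or
    by the plain difference of means on the beta scale (methylation, where
    logs near zero are unstable). The top ceil(n/K) features per type are
    pooled and the union trimmed to ``n`` by global score.
    """
    modality = modality or pure_means.modality
    means = pure_means.values
    p, k = means.shape
    if modality == "expression":
        if (means <= 0).any():
            raise ValueError(
                "nonpositive cell-type means under log scoring; add an offset "
                "or use methylation (difference) scoring"
            )
        log_means = np.log(means)
    scores = np.empty((p, k))
    for j in range(k):
        others = [i for i in range(k) if i != j]
        if modality == "expression":
            scores[:, j] = log_means[:, j] - np.log(means[:, others].mean(axis=1))
        else:
            scores[:, j] = means[:, j] - means[:, others].mean(axis=1)
    if n >= p:
        return FeatureSet(list(pure_means.feature_ids), "true_cts_markers")
    per_type = math.ceil(n / k)
    abs_scores = np.abs(scores) if modality != "expression" else scores
    chosen: dict[str, float] = {}
    for j in range(k):
        top = np.argsort(-abs_scores[:, j], kind="stable")[:per_type]
        for i in top:
            fid = pure_means.feature_ids[i]
            s = float(abs_scores[i, j])
            if fid not in chosen or s > chosen[fid]:
                chosen[fid] = s
    ranked = sorted(chosen.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    return FeatureSet([fid for fid, _ in ranked], "true_cts_markers")


def marker_overlap(a: FeatureSet, b: FeatureSet) -> int:
    """Size of the intersection of two feature sets."""
    return a.intersection_size(b)


@dataclass
class EvaluationReport:
    """Aligned comparison of an estimate against ground truth."""

    per_type_correlation: np.ndarray
    mean_correlation: float
    rms_bias: float
    goodness_of_fit: float | None
    model_rmse: float | None
    marker_overlap: int | None
    alignment: tuple[int, ...]
    celltype_labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (f"corr_{label}", value)
            for label, value in zip(self.celltype_labels, self.per_type_correlation)
        ]
        rows.append(("mean_correlation", self.mean_correlation))
        rows.append(("rms_bias", self.rms_bias))
        if self.goodness_of_fit is not None:
            rows.append(("goodness_of_fit", self.goodness_of_fit))
        if self.model_rmse is not None:
            rows.append(("model_rmse", self.model_rmse))
        if self.marker_overlap is not None:
            rows.append(("marker_overlap", self.marker_overlap))
        return pd.DataFrame(rows, columns=["metric", "value"])


def evaluate_estimate(
    h_est: ProportionMatrix,
    h_true: ProportionMatrix,
    y_sub: MixtureMatrix | None = None,
    w: SignatureMatrix | None = None,
    selected: FeatureSet | None = None,
    truth_markers: FeatureSet | None = None,
) -> EvaluationReport:
    """Align components to truth and compute the full metric suite."""
    perm = align_components(h_est, h_true)
    aligned = apply_alignment(h_est, perm)
    corr = corr_with_true(aligned, h_true)
    finite = corr[np.isfinite(corr)]
    if finite.size < corr.size:
        warnings.warn(
            f"{corr.size - finite.size} zero-variance component(s) excluded "
            "from the mean correlation",
            stacklevel=2,
        )
    gof = rmse = None
    if y_sub is not None and w is not None:
        gof = goodness_of_fit(y_sub, w, h_est)
        rmse = model_rmse(y_sub, w, h_est)
    overlap = None
    if selected is not None and truth_markers is not None:
        overlap = marker_overlap(selected, truth_markers)
    return EvaluationReport(
        per_type_correlation=corr,
        mean_correlation=float(finite.mean()) if finite.size else float("nan"),
        rms_bias=rms_bias(aligned, h_true),
        goodness_of_fit=gof,
        model_rmse=rmse,
        marker_overlap=overlap,
        alignment=perm,
        celltype_labels=list(h_true.celltype_labels),
    )
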