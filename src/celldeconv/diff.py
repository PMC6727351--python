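"""Cross-cell-type differential analysis for mixed samples.

With mixing proportions in hand (estimated or known), the expected bulk
signal of feature p is a proportion-weighted combination of its per-cell-type
means: E(Y_p) = V beta_p, where V is the N x K matrix of sample proportions
and beta_p stacks the K cell-type means mu_pk. The model is fit per feature
by ordinary least squares; the hypothesis that cell type k differs from the
average of the remaining types,

    H0: mu_pk - (1/(K-1)) * sum_{i != k} mu_pi = 0,

is tested with a Wald t statistic on df = N - K. Because some features yield
unrealistically small residual variances, a data-driven floor (the 10th
quantile of all per-feature variance estimates) stabilizes the denominators.
Negative fitted means can optionally be clamped to zero before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MixtureMatrix, ProportionMatrix

logger = logging.getLogger(__name__)


@dataclass
class DesignMatrix:
    """N x K proportion design with simplex rows."""

    values: np.ndarray
    condition_number: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        v = self.values
        if (v < -1e-9).any() or (v > 1 + 1e-9).any():
            raise ValueError("design entries must lie in [0, 1]")
        sums = v.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-8:
            s = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"design row {s} sums to {sums[s]}, not 1")


@dataclass
class CellTypeMeansFit:
    """Per-feature OLS fit of cell-type means from mixed samples."""

    beta: np.ndarray  # P x K fitted means mu_pk
    sigma2_raw: np.ndarray  # length P residual variances RSS/(N-K)
    sigma2_floored: np.ndarray
    df: int
    floor_value: float
    design: DesignMatrix
    feature_ids: list[str]
    celltype_labels: list[str]


@dataclass
class DifferentialResult:
    """One-vs-rest contrast results, one column per cell type."""

    estimate: np.ndarray  # P x K contrast estimates delta_pk
    se: np.ndarray
    t: np.ndarray
    pvalue: np.ndarray
    fit: CellTypeMeansFit

    @property
    def feature_ids(self) -> list[str]:
        return self.fit.feature_ids

    @property
    def celltype_labels(self) -> list[str]:
        return self.fit.celltype_labels

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: feature, celltype, estimate, se, t, pvalue."""
        p, k = self.estimate.shape
        return pd.DataFrame(
            {
                "feature": np.repeat(self.feature_ids, k),
                "celltype": np.tile(self.celltype_labels, p),
                "estimate": self.estimate.ravel(),
                "se": self.se.ravel(),
                "t": self.t.ravel(),
                "pvalue": self.pvalue.ravel(),
            }
        )


def variance_floor(
    sigma2_raw: np.ndarray, q: float = 0.10
) -> tuple[np.ndarray, float]:
    """Raise per-feature residual variances to their empirical q-quantile.

    The quantile uses linear interpolation between order statistics (so the
    0.1 quantile of 1..10 is 1.9). An all-zero input falls back to a tiny
    positive floor so downstream t statistics stay defined.
    """
    sigma2_raw = np.asarray(sigma2_raw, dtype=np.float64)
    if sigma2_raw.size < 1:
        raise ValueError("need at least one variance estimate")
    if (sigma2_raw < 0).any():
        raise ValueError("negative variance estimate")
    floor = float(np.quantile(sigma2_raw, q))
    if floor == 0.0:
        floor = 1e-12 * max(1.0, float(sigma2_raw.max()))
    return np.maximum(sigma2_raw, floor), floor


def fit_celltype_means(
    y: MixtureMatrix, h: ProportionMatrix, floor_q: float = 0.10
) -> CellTypeMeansFit:
    """OLS fit of per-cell-type means for every feature.

    ``h`` columns must be the samples of ``y`` in order; its transpose is the
    proportion design V. Requires N > K for at least one residual degree of
    freedom and a full-column-rank design.
    """
    if y.n_samples != h.n_samples:
        raise ValueError("sample count mismatch between mixture and proportions")
    n, k = h.n_samples, h.n_celltypes
    if n <= k:
        raise ValueError(
            f"insufficient degrees of freedom: N={n} samples, K={k} cell types"
        )
    v = h.values.T  # N x K
    cond = float(np.linalg.cond(v))
    if not np.isfinite(cond) or np.linalg.matrix_rank(v) < k:
        raise ValueError("proportion design is rank deficient; cannot fit")
    design = DesignMatrix(v, cond)

    xtx = v.T @ v
    beta = np.linalg.solve(xtx, v.T @ y.values.T).T  # P x K
    resid = y.values - beta @ v.T
    rss = (resid**2).sum(axis=1)
    df = n - k
    sigma2_raw = rss / df
    sigma2_floored, floor = variance_floor(sigma2_raw, q=floor_q)
    return CellTypeMeansFit(
        beta=beta,
        sigma2_raw=sigma2_raw,
        sigma2_floored=sigma2_floored,
        df=df,
        floor_value=floor,
        design=design,
        feature_ids=list(y.feature_ids),
        celltype_labels=list(h.celltype_labels),
    )


def bound_negative_means(fit: CellTypeMeansFit, enabled: bool = False) -> CellTypeMeansFit:
    """Optionally clamp negative fitted cell-type means to zero.

    Residual variances are not recomputed: the clamp only affects the
    contrast estimates. The fraction of clamped coefficients is logged.
    """
    if not enabled:
        return fit
    negative = fit.beta < 0
    fraction = float(negative.mean())
    logger.info("bounded %.4f of fitted cell-type means at zero", fraction)
    if not negative.any():
        return fit
    beta = fit.beta.copy()
    beta[negative] = 0.0
    return replace(fit, beta=beta)


def _contrast_vector(k: int, index: int) -> np.ndarray:
    c = np.full(k, -1.0 / (k - 1))
    c[index] = 1.0
    return c


def test_celltype_contrast(
    fit: CellTypeMeansFit, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Test cell type ``k`` (0-based index) against the mean of the others.

    Returns per-feature arrays (estimate, se, t, pvalue). The standard error
    uses the floored residual variance; p-values are two-sided from the
    Student t distribution with N - K degrees of freedom.
    """
    n_types = len(fit.celltype_labels)
    if n_types < 2:
        raise ValueError("contrast undefined with a single cell type")
    if not 0 <= k < n_types:
        raise IndexError(f"cell-type index {k} out of range 0..{n_types - 1}")
    c = _contrast_vector(n_types, k)
    v = fit.design.values
    xtx_inv = np.linalg.inv(v.T @ v)
    quad = float(c @ xtx_inv @ c)
    delta = fit.beta @ c
    se = np.sqrt(fit.sigma2_floored * quad)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, delta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=fit.df)
    return delta, se, t, p


# the name starts with "test_"; keep pytest from collecting the API function
test_celltype_contrast.__test__ = False  # type: ignore[attr-defined]


def crosscell_differential(
    y: MixtureMatrix,
    h: ProportionMatrix,
    bound_negatives: bool = False,
    floor_q: float = 0.10,
) -> DifferentialResult:
    """Fit the proportion-design model and test every one-vs-rest contrast."""
    fit = fit_celltype_means(y, h, floor_q=floor_q)
    fit = bound_negative_means(fit, enabled=bound_negatives)
    n_types = len(fit.celltype_labels)
    p = len(fit.feature_ids)
    est = np.empty((p, n_types))
    se = np.empty((p, n_types))
    t = np.empty((p, n_types))
    pv = np.empty((p, n_types))
    for k in range(n_types):
        est[:, k], se[:, k], t[:, k], pv[:, k] = test_celltype_contrast(fit, k)
    return DifferentialResult(est, se, t, pv, fit)
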