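"""Synthetic mixed-tissue datasets with full ground truth.

Three generators mirror common benchmarking designs for deconvolution:

* expression microarrays — per-subject pure panels drawn feature-by-feature
  from log-normal distributions, mixed by Dirichlet proportions with
  parameters (0.968, 4.706, 0.496, 0.347) in the four-cell-type setting,
  plus additive Gaussian measurement noise;
* DNA methylation arrays — the same construction with normal draws clipped
  to the beta-value range [0, 1], six-type Dirichlet parameters
  (0.89, 4.12, 0.47, 0.33, 0.61, 1.02);
* RNA-seq counts — negative-binomial counts with planted cell-type-specific
  differentially expressed genes, for evaluating the cross-cell-type test on
  count data.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureSet, MixtureMatrix, Modality, ProportionMatrix

logger = logging.getLogger(__name__)

#: Dirichlet parameters of the mixing proportions in the four-cell-type
#: setting; mean proportions are alpha / sum(alpha).
ALPHA_FOUR = (0.968, 4.706, 0.496, 0.347)
#: Dirichlet parameters in the six-cell-type setting.
ALPHA_SIX = (0.89, 4.12, 0.47, 0.33, 0.61, 1.02)


@dataclass
class PanelParams:
    """Per-feature, per-cell-type location/scale parameters of pure panels.

    Locations and scales are on the natural-log scale for expression and on
    the beta scale for methylation. ``marker_type[p]`` records which cell
    type feature p is a planted marker for (-1 for background features).
    """

    locations: np.ndarray  # P x K
    scales: np.ndarray  # P x K, >= 0
    modality: Modality
    feature_ids: list[str]
    celltype_labels: list[str]
    marker_type: np.ndarray  # length P ints, -1 = background
    #: P x F loadings of per-subject latent factors (co-expression /
    #: subject-effect structure of the within-type variation); zero rows
    #: for clean features. None disables the factor component.
    factor_loadings: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.scales < 0).any():
            raise ValueError("scales must be nonnegative")
        if self.modality == "methylation" and (
            (self.locations < 0).any() or (self.locations > 1).any()
        ):
            raise ValueError("methylation locations must lie in [0, 1]")

    @property
    def n_features(self) -> int:
        return self.locations.shape[0]

    @property
    def n_celltypes(self) -> int:
        return self.locations.shape[1]

    def truth_markers(self) -> FeatureSet:
        idx = np.flatnonzero(self.marker_type >= 0)
        return FeatureSet([self.feature_ids[i] for i in idx], "planted")


@dataclass
class SimulatedDataset:
    """A mixture with its generating ground truth."""

    mixture: MixtureMatrix
    h_true: ProportionMatrix
    subject_panels: np.ndarray | None  # N x P x K pure profiles
    truth_markers: FeatureSet
    alpha: tuple[float, ...]
    noise_sd: float
    seed: int


def default_panel_params(
    p: int,
    k: int = 4,
    n_markers_per_type: int = 250,
    effect_lfc: float | None = None,
    seed: int = 0,
    modality: Modality = "expression",
    n_factors: int = 2,
    factor_loading_sd: float | None = None,
) -> PanelParams:
    """Construct a synthetic pure-panel parameter set with planted markers.

    Background features share their location across cell types and carry a
    broad range of within-type scales, so high overall variance does not
    imply cell-type specificity. Planted markers are shifted by
    ``effect_lfc`` (log scale for expression, beta-difference toward the
    farther boundary for methylation; defaults 2.3 — about 10-fold, the
    strong specificity typical of marker genes in purified immune profiles
    — and 0.3 respectively) in their own cell type, and get the low
    within-type scales characteristic of good markers.

    Background features additionally load on ``n_factors`` per-subject
    latent factors (loadings Normal(0, ``factor_loading_sd``), defaults 0.1
    log-scale / 0.01 beta-scale). This emulates the correlated within-type
    variation — co-expression modules and subject effects — that makes
    high-variance non-marker features actively misleading for
    deconvolution in real data; markers carry zero loadings.
    """
    if k * n_markers_per_type > p:
        raise ValueError(
            f"{k} x {n_markers_per_type} markers do not fit in {p} features"
        )
    rng = np.random.default_rng(seed)
    feature_ids = [f"f{i + 1}" for i in range(p)]
    labels = [f"T{j + 1}" for j in range(k)]
    marker_type = np.full(p, -1, dtype=int)
    marker_idx = rng.permutation(p)[: k * n_markers_per_type]
    for j in range(k):
        marker_type[marker_idx[j * n_markers_per_type : (j + 1) * n_markers_per_type]] = j
    is_marker = marker_type >= 0

    if modality == "expression":
        if effect_lfc is None:
            effect_lfc = 2.3
        if factor_loading_sd is None:
            factor_loading_sd = 0.1
        base = rng.normal(5.0, 1.0, size=p)
        locations = np.tile(base[:, None], (1, k))
        # probe-level noise is a property of the feature, shared across types
        feat_scale = rng.uniform(0.1, 0.8, size=p)
        feat_scale[is_marker] = rng.uniform(0.05, 0.2, size=int(is_marker.sum()))
        scales = np.tile(feat_scale[:, None], (1, k))
        for j in range(k):
            locations[marker_type == j, j] += effect_lfc
    elif modality == "methylation":
        if effect_lfc is None:
            effect_lfc = 0.3
        if factor_loading_sd is None:
            factor_loading_sd = 0.01
        base = rng.uniform(0.05, 0.95, size=p)
        locations = np.tile(base[:, None], (1, k))
        feat_scale = rng.uniform(0.01, 0.1, size=p)
        feat_scale[is_marker] = rng.uniform(0.005, 0.02, size=int(is_marker.sum()))
        scales = np.tile(feat_scale[:, None], (1, k))
        for j in range(k):
            rows = marker_type == j
            direction = np.where(base[rows] <= 0.5, 1.0, -1.0)
            locations[rows, j] = np.clip(
                locations[rows, j] + direction * effect_lfc, 0.0, 1.0
            )
    else:
        raise ValueError(f"unknown modality {modality!r}")
    loadings = None
    if n_factors > 0 and factor_loading_sd > 0:
        loadings = rng.normal(0.0, factor_loading_sd, size=(p, n_factors))
        loadings[is_marker, :] = 0.0
    return PanelParams(
        locations, scales, modality, feature_ids, labels, marker_type, loadings
    )


def estimate_panel_params(
    pure: np.ndarray,
    celltype_of_replicate: list[str],
    modality: Modality = "expression",
    feature_ids: list[str] | None = None,
    expected_types: list[str] | None = None,
) -> PanelParams:
    """Estimate panel parameters from replicated pure cell-type profiles.

    ``pure`` is features x replicates; each replicate column carries a
    cell-type label. Expression values are log-transformed before taking
    per-type means and standard deviations. Types with a single replicate
    (or zero spread) fall back to the pooled average scale, logged.
    """
    pure = np.asarray(pure, dtype=np.float64)
    labels = sorted(set(celltype_of_replicate))
    if expected_types is not None:
        missing = sorted(set(expected_types) - set(labels))
        if missing:
            raise ValueError(f"no replicates for cell type(s) {missing}")
        labels = sorted(expected_types)
    p = pure.shape[0]
    if feature_ids is None:
        feature_ids = [f"f{i + 1}" for i in range(p)]
    values = pure
    if modality == "expression":
        if (pure <= 0).any():
            raise ValueError("expression profiles must be positive for log scale")
        values = np.log(pure)
    k = len(labels)
    locations = np.empty((p, k))
    scales = np.zeros((p, k))
    degenerate = []
    for j, lab in enumerate(labels):
        cols = [i for i, c in enumerate(celltype_of_replicate) if c == lab]
        if not cols:
            raise ValueError(f"no replicates for cell type {lab!r}")
        locations[:, j] = values[:, cols].mean(axis=1)
        if len(cols) > 1:
            scales[:, j] = values[:, cols].std(axis=1, ddof=1)
        if len(cols) == 1 or not scales[:, j].any():
            degenerate.append(lab)
    positive = scales[scales > 0]
    pooled = float(positive.mean()) if positive.size else 0.01
    for lab in degenerate:
        j = labels.index(lab)
        zero = scales[:, j] == 0
        scales[zero, j] = pooled
        logger.warning(
            "cell type %r lacks replicate spread; using pooled scale %.4g", lab, pooled
        )
    if modality == "methylation":
        locations = np.clip(locations, 0.0, 1.0)
    return PanelParams(
        locations, scales, modality, list(feature_ids), labels,
        np.full(p, -1, dtype=int),
    )


def _factor_component(params: PanelParams, n: int, rng: np.random.Generator):
    """Per-subject latent-factor deviations, shared across cell types."""
    if params.factor_loadings is None:
        return 0.0
    u = rng.normal(0.0, 1.0, size=(n, params.factor_loadings.shape[1]))
    return (u @ params.factor_loadings.T)[:, :, None]


def _default_noise_sd(panels: np.ndarray) -> float:
    # 0.1 x the median over features of the pure-panel standard deviation
    per_feature_sd = panels.std(axis=(0, 2))
    return 0.1 * float(np.median(per_feature_sd))


def _mix(
    params: PanelParams,
    n: int,
    alpha: tuple[float, ...],
    noise_sd: float | None,
    seed: int,
    clip_upper: float | None,
    draw,
) -> SimulatedDataset:
    if len(alpha) != params.n_celltypes:
        raise ValueError(
            f"alpha has {len(alpha)} entries but the panel has "
            f"{params.n_celltypes} cell types"
        )
    if noise_sd is not None and noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    h = rng.dirichlet(alpha, size=n).T  # K x N
    panels = draw(rng)  # N x P x K
    if noise_sd is None:
        noise_sd = _default_noise_sd(panels)
    clean = np.einsum("spk,ks->ps", panels, h)
    noise = rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else 0.0
    mixed = np.clip(clean + noise, 0.0, clip_upper)
    sample_ids = [f"s{i + 1}" for i in range(n)]
    mixture = MixtureMatrix(mixed, list(params.feature_ids), sample_ids, params.modality)
    h_true = ProportionMatrix(h, list(params.celltype_labels), sample_ids)
    return SimulatedDataset(
        mixture, h_true, panels, params.truth_markers(), tuple(alpha),
        float(noise_sd), seed,
    )


def simulate_expression_dataset(
    params: PanelParams,
    n: int,
    alpha: tuple[float, ...] = ALPHA_FOUR,
    noise_sd: float | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Log-normal pure panels mixed on the linear scale by Dirichlet draws.

    ``noise_sd=None`` uses 0.1 x the median per-feature panel standard
    deviation; negative mixed values (from noise) clip at zero.
    """
    if params.modality != "expression":
        raise ValueError("params are not expression-scale")

    def draw(rng: np.random.Generator) -> np.ndarray:
        logs = rng.normal(
            params.locations[None, :, :], params.scales[None, :, :],
            size=(n, params.n_features, params.n_celltypes),
        )
        logs += _factor_component(params, n, rng)
        return np.exp(logs)

    return _mix(params, n, alpha, noise_sd, seed, None, draw)


def simulate_methylation_dataset(
    params: PanelParams,
    n: int,
    alpha: tuple[float, ...] = ALPHA_FOUR,
    noise_sd: float | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Normal pure panels clipped to [0, 1], mixed by Dirichlet draws.

    The mixed beta values are clipped back to [0, 1] after noise.
    """
    if params.modality != "methylation":
        raise ValueError("params are not methylation-scale")

    def draw(rng: np.random.Generator) -> np.ndarray:
        vals = rng.normal(
            params.locations[None, :, :], params.scales[None, :, :],
            size=(n, params.n_features, params.n_celltypes),
        )
        vals += _factor_component(params, n, rng)
        return np.clip(vals, 0.0, 1.0)

    return _mix(params, n, alpha, noise_sd, seed, 1.0, draw)


def simulate_rnaseq_counts(
    p: int,
    n: int,
    k: int = 4,
    n_true_degs: int = 2000,
    lfc_sd: float = 1.5,
    dispersion: float = 0.1,
    alpha: tuple[float, ...] = ALPHA_FOUR,
    libsize_range: tuple[float, float] = (0.7, 1.3),
    seed: int = 0,
) -> tuple[SimulatedDataset, pd.DataFrame]:
    """Negative-binomial RNA-seq mixtures with planted cell-type DE genes.

    Baseline log2 means are drawn from a broad normal; each planted DE gene
    belongs to one cell type and carries a log2 fold change drawn from
    Normal(0, ``lfc_sd``) truncated away from zero (|lfc| >= 0.5). Per-type
    expected counts are mixed by Dirichlet proportions, scaled by a uniform
    library-size factor, and counts drawn NB(mean, ``dispersion``)
    (variance mean + dispersion * mean^2).

    Returns the dataset and a truth table (gene, is_deg, celltype, log2fc).
    """
    if n_true_degs > p:
        raise ValueError(f"cannot plant {n_true_degs} DE genes in {p} genes")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if len(alpha) != k:
        raise ValueError(f"alpha has {len(alpha)} entries for k={k}")
    rng = np.random.default_rng(seed)
    feature_ids = [f"g{i + 1}" for i in range(p)]
    labels = [f"T{j + 1}" for j in range(k)]
    base_log2 = rng.normal(5.0, 2.0, size=p)
    marker_type = np.full(p, -1, dtype=int)
    deg_idx = rng.permutation(p)[:n_true_degs]
    marker_type[deg_idx] = rng.integers(0, k, size=n_true_degs)
    lfc = np.zeros(p)
    draws = rng.normal(0.0, lfc_sd, size=n_true_degs)
    while True:  # truncate away from zero
        small = np.abs(draws) < 0.5
        if not small.any():
            break
        draws[small] = rng.normal(0.0, lfc_sd, size=int(small.sum()))
    lfc[deg_idx] = draws

    mu = np.tile(np.exp2(base_log2)[:, None], (1, k))  # P x K expected counts
    for j in range(k):
        rows = marker_type == j
        mu[rows, j] = np.exp2(base_log2[rows] + lfc[rows])
    h = rng.dirichlet(alpha, size=n).T  # K x N
    lib = rng.uniform(*libsize_range, size=n)
    mean = (mu @ h) * lib[None, :]
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mean)).astype(np.float64)

    sample_ids = [f"s{i + 1}" for i in range(n)]
    mixture = MixtureMatrix(counts, feature_ids, sample_ids, "expression")
    h_true = ProportionMatrix(h, labels, sample_ids)
    truth = pd.DataFrame(
        {
            "gene": feature_ids,
            "is_deg": marker_type >= 0,
            "celltype": [labels[t] if t >= 0 else "" for t in marker_type],
            "log2fc": lfc,
        }
    )
    markers = FeatureSet([feature_ids[i] for i in np.flatnonzero(marker_type >= 0)], "planted")
    dataset = SimulatedDataset(
        mixture, h_true, None, markers, tuple(alpha), 0.0, seed
    )
    return dataset, truth


def log_normalize_counts(counts: MixtureMatrix) -> MixtureMatrix:
    """Library-size normalize and log2(x+1)-transform a count matrix.

    Size factors are column totals divided by their median, keeping the
    transformed values on a comparable scale across samples; the result is
    the input expected by the cross-cell-type linear model.
    """
    totals = counts.values.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("a sample has zero total counts")
    sf = totals / np.median(totals)
    values = np.log2(counts.values / sf[None, :] + 1.0)
    return MixtureMatrix(
        values, list(counts.feature_ids), list(counts.sample_ids), "expression"
    )
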