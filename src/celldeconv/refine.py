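"""Iterative marker selection for reference-free deconvolution.

The algorithm starts from a conventionally chosen feature list (by default
the 1001st-2000th most variable features), deconvolves that submatrix, then
repeats: run cross-cell-type differential analysis on the *whole* matrix
using the latest proportion estimates, keep the top-ranked features (the
same number as the initial list, default 1000), and re-deconvolve on them.
The iteration chosen as the endpoint is the one with the smallest model
RMSE — reconstruction error is observable without ground truth and tracks
proportion accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureSet, MixtureMatrix
from .diff import DifferentialResult, crosscell_differential
from .engine import DeconvResult, rf_deconvolve

logger = logging.getLogger(__name__)


def initial_features(
    y: MixtureMatrix,
    method: str = "variance_window",
    window: tuple[int, int] = (1001, 2000),
    n_marker: int = 1000,
    seed: int = 0,
    k: int | None = None,
) -> FeatureSet:
    """Select the starting feature list.

    ``variance_window`` ranks features by row variance (descending) and
    returns 1-based ranks ``window[0]..window[1]`` inclusive;
    ``random`` draws ``n_marker`` features uniformly without replacement.
    Both are deterministic given the seed.
    """
    p = y.n_features
    if method == "variance_window":
        lo, hi = window
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid variance window {window}")
        if hi > p:
            raise ValueError(
                f"variance window {window} exceeds the {p} available features"
            )
        if k is not None and hi - lo + 1 < k:
            raise ValueError("window smaller than the number of cell types")
        variances = y.values.var(axis=1, ddof=1)
        order = np.argsort(-variances, kind="stable")
        idx = order[lo - 1 : hi]
        return FeatureSet([y.feature_ids[i] for i in idx], "variance_window")
    if method == "random":
        if n_marker > p:
            raise ValueError(f"cannot sample {n_marker} of {p} features")
        if k is not None and n_marker < k:
            raise ValueError("n_marker smaller than the number of cell types")
        rng = np.random.default_rng(seed)
        idx = rng.choice(p, size=n_marker, replace=False)
        return FeatureSet([y.feature_ids[i] for i in idx], "random")
    raise ValueError(f"unknown initial-feature method {method!r}")


def parse_init_spec(spec: str) -> tuple[str, tuple[int, int] | int]:
    """Parse CLI-style init specs: ``variance:1001-2000`` or ``random:1000``."""
    kind, _, arg = spec.partition(":")
    if kind == "variance":
        lo, _, hi = arg.partition("-")
        return "variance_window", (int(lo), int(hi))
    if kind == "random":
        return "random", int(arg)
    raise ValueError(f"unknown init spec {spec!r}")


def select_markers(diff: DifferentialResult, n_marker: int = 1000) -> FeatureSet:
    """Pick the top cross-cell-type features, balanced across cell types.

    Per cell type, features are ranked by ascending p-value (ties broken by
    descending |estimate|, then by feature ID); the per-type lists are then
    merged round-robin in cell-type label order, skipping features already
    taken, until ``n_marker`` unique features are collected or the features
    are exhausted.
    """
    n_types = len(diff.celltype_labels)
    if n_marker < n_types:
        raise ValueError(
            f"n_marker={n_marker} below the number of cell types {n_types}"
        )
    p = len(diff.feature_ids)
    fid_rank = np.argsort(np.argsort(np.asarray(diff.feature_ids, dtype=object)))
    orders = []
    for k in range(n_types):
        keys = np.lexsort(
            (fid_rank, -np.abs(diff.estimate[:, k]), diff.pvalue[:, k])
        )
        orders.append(keys)
    pointers = [0] * n_types
    taken: list[str] = []
    taken_set: set[int] = set()
    target = min(n_marker, p)
    while len(taken) < target:
        progressed = False
        for k in range(n_types):
            if len(taken) >= target:
                break
            while pointers[k] < p and orders[k][pointers[k]] in taken_set:
                pointers[k] += 1
            if pointers[k] < p:
                i = int(orders[k][pointers[k]])
                taken_set.add(i)
                taken.append(diff.feature_ids[i])
                pointers[k] += 1
                progressed = True
        if not progressed:
            break
    return FeatureSet(taken, "marker_selection")


@dataclass
class IterationRecord:
    iteration: int
    feature_set: FeatureSet
    result: DeconvResult
    rmse: float


@dataclass
class IterationTrace:
    """Full record of a refinement run.

    Iteration 0 is the un-iterated baseline on the initial features and is
    excluded from the endpoint choice; ``chosen_iteration`` is the argmin of
    RMSE over iterations 1..T (ties resolve to the earliest iteration).
    """

    records: list[IterationRecord] = field(default_factory=list)
    chosen_iteration: int = 0

    @property
    def baseline(self) -> IterationRecord:
        return self.records[0]

    @property
    def chosen(self) -> IterationRecord:
        return self.records[self.chosen_iteration]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": [r.iteration for r in self.records],
                "rmse": [r.rmse for r in self.records],
                "n_features": [r.feature_set.size for r in self.records],
                "chosen": [
                    1 if r.iteration == self.chosen_iteration else 0
                    for r in self.records
                ],
            }
        )


def run_refinement(
    y: MixtureMatrix,
    k: int,
    n_marker: int = 1000,
    max_iter: int = 30,
    init: str | FeatureSet = "variance:1001-2000",
    seed: int = 0,
    n_restarts: int = 3,
    tol: float = 1e-6,
    max_inner: int = 1000,
    bound_negatives: bool = False,
) -> IterationTrace:
    """Run the full iterative feature-selection / deconvolution loop.

    Each iteration re-runs the factorization from fresh random starts
    (iteration ``t`` seeds its restarts from ``seed + 1000*t``) on the newly
    selected features; the differential analysis always uses the whole
    matrix ``y``. Engine failures abort but the trace gathered so far is
    attached to the raised exception.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if isinstance(init, FeatureSet):
        fs = init
    else:
        method, arg = parse_init_spec(init)
        if method == "variance_window":
            fs = initial_features(y, method, window=arg, seed=seed, k=k)
        else:
            fs = initial_features(y, method, n_marker=arg, seed=seed, k=k)

    trace = IterationTrace()
    try:
        result = rf_deconvolve(
            y.restrict(fs.feature_ids), k, seed=seed,
            n_restarts=n_restarts, tol=tol, max_inner=max_inner,
        )
        trace.records.append(IterationRecord(0, fs, result, result.rmse))
        logger.info("iteration 0 (baseline): rmse=%.6g n_features=%d", result.rmse, fs.size)
        for t in range(1, max_iter + 1):
            diff = crosscell_differential(
                y, trace.records[-1].result.H, bound_negatives=bound_negatives
            )
            fs = select_markers(diff, n_marker=n_marker)
            result = rf_deconvolve(
                y.restrict(fs.feature_ids), k, seed=seed + 1000 * t,
                n_restarts=n_restarts, tol=tol, max_inner=max_inner,
            )
            trace.records.append(IterationRecord(t, fs, result, result.rmse))
            logger.info("iteration %d: rmse=%.6g n_features=%d", t, result.rmse, fs.size)
    except Exception as exc:
        exc.trace_so_far = trace  # type: ignore[attr-defined]
        raise
    rmses = [r.rmse for r in trace.records[1:]]
    trace.chosen_iteration = 1 + int(np.argmin(rmses))
    logger.info(
        "chosen iteration %d with rmse=%.6g",
        trace.chosen_iteration,
        trace.chosen.rmse,
    )
    return trace
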