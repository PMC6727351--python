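"""Reference-free deconvolution by alternating constrained least squares.

The factorization ``Y = WH`` is fit by alternating two exact half-steps:

* H-step: for each sample, the proportion vector solves a least-squares
  problem on the probability simplex (nonnegative, summing to one).
* W-step: for each feature, the signature row solves a bound-constrained
  least-squares problem (nonnegative; additionally bounded by 1 for
  methylation beta values).

Both half-steps are solved exactly by enumerating active-set patterns: with
K cell types there are at most 2^K - 1 supports for the simplex problem and
3^K bound patterns for the box problem, and for each pattern the
equality-constrained solution is available in closed form. The pattern
achieving the smallest objective among feasible ones is the global optimum
of the constrained problem. Because each half-step is an exact minimizer,
the Frobenius objective is non-increasing across iterations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import MixtureMatrix, Modality, ProportionMatrix, SignatureMatrix

_FEAS_TOL = 1e-9
_DEGENERATE_TOL = 1e-6


def _solve_psd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve a small symmetric system, falling back to least squares when
    the Gram matrix is singular (collinear signature columns)."""
    try:
        return np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(a, b, rcond=None)[0]


def simplex_lstsq(w: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact columnwise ``argmin ||y_s - W h||^2  s.t.  h >= 0, sum h = 1``.

    Parameters
    ----------
    w : (M, K) array
    y : (M, N) array

    Returns
    -------
    (K, N) array with every column on the unit simplex.
    """
    w = np.asarray(w, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    m, k = w.shape
    n = y.shape[1]
    gram = w.T @ w
    bty = w.T @ y  # K x N

    best_obj = np.full(n, np.inf)
    best_h = np.zeros((k, n))
    for size in range(k, 0, -1):
        for support in itertools.combinations(range(k), size):
            s = list(support)
            # KKT system for min h'Gh - 2h'b  s.t. sum h = 1 on the support
            kkt = np.zeros((size + 1, size + 1))
            kkt[:size, :size] = gram[np.ix_(s, s)]
            kkt[:size, size] = 1.0
            kkt[size, :size] = 1.0
            rhs = np.vstack([bty[s, :], np.ones((1, n))])
            sol = _solve_psd(kkt, rhs)
            h_s = sol[:size, :]
            feasible = (h_s >= -_FEAS_TOL).all(axis=0)
            if not feasible.any():
                continue
            # objective up to the constant y'y, comparable across supports
            obj = (
                np.einsum("is,ij,js->s", h_s, gram[np.ix_(s, s)], h_s)
                - 2.0 * np.einsum("is,is->s", h_s, bty[s, :])
            )
            better = feasible & (obj < best_obj - 1e-15)
            if better.any():
                best_obj[better] = obj[better]
                best_h[:, better] = 0.0
                block = h_s[:, better]
                for row, idx in enumerate(s):
                    best_h[idx, better] = block[row]
    np.clip(best_h, 0.0, None, out=best_h)
    best_h /= best_h.sum(axis=0, keepdims=True)
    return best_h


def box_lstsq(a: np.ndarray, b: np.ndarray, upper: float = np.inf) -> np.ndarray:
    """Exact columnwise ``argmin ||b_p - A x||^2  s.t.  0 <= x <= upper``.

    Parameters
    ----------
    a : (N, K) design shared by all problems
    b : (N, P) right-hand sides (one column per feature)
    upper : upper bound; ``inf`` gives plain nonnegative least squares.

    Returns
    -------
    (K, P) array of solutions.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    _, k = a.shape
    p = b.shape[1]
    gram = a.T @ a
    atb = a.T @ b  # K x P
    bounded = np.isfinite(upper)
    states = (0, 1, 2) if bounded else (0, 1)  # free, at 0, at upper

    best_obj = np.full(p, np.inf)
    best_x = np.zeros((k, p))
    for pattern in itertools.product(states, repeat=k):
        free = [i for i, st in enumerate(pattern) if st == 0]
        fixed = np.array(
            [0.0 if st == 1 else upper for st in pattern if st != 0]
        )
        fixed_idx = [i for i, st in enumerate(pattern) if st != 0]
        x = np.zeros((k, p))
        for row, idx in enumerate(fixed_idx):
            x[idx, :] = fixed[row]
        if free:
            rhs = atb[free, :]
            if fixed_idx:
                rhs = rhs - (gram[np.ix_(free, fixed_idx)] @ fixed)[:, None]
            x_free = _solve_psd(gram[np.ix_(free, free)], rhs)
            feasible = (x_free >= -_FEAS_TOL).all(axis=0)
            if bounded:
                feasible &= (x_free <= upper + _FEAS_TOL).all(axis=0)
            if not feasible.any():
                continue
            for row, idx in enumerate(free):
                x[idx, :] = x_free[row]
        else:
            feasible = np.ones(p, dtype=bool)
        obj = np.einsum("ip,ij,jp->p", x, gram, x) - 2.0 * np.einsum(
            "ip,ip->p", x, atb
        )
        better = feasible & (obj < best_obj - 1e-15)
        if better.any():
            best_obj[better] = obj[better]
            best_x[:, better] = x[:, better]
    np.clip(best_x, 0.0, upper if bounded else None, out=best_x)
    return best_x


@dataclass
class DeconvResult:
    """Outcome of one reference-free factorization."""

    W: SignatureMatrix
    H: ProportionMatrix
    rmse: float
    n_restarts_used: int
    converged: bool


def _frob_rmse(y: np.ndarray, w: np.ndarray, h: np.ndarray) -> float:
    resid = y - w @ h
    return float(np.sqrt(np.mean(resid**2)))


def update_proportions(y_sub: MixtureMatrix, w: SignatureMatrix) -> ProportionMatrix:
    """Half-step: per-sample simplex-constrained least squares given W."""
    if y_sub.n_features != w.n_features:
        raise ValueError(
            f"dimension mismatch: y has {y_sub.n_features} features, "
            f"W has {w.n_features}"
        )
    if np.linalg.matrix_rank(w.values) < w.n_celltypes:
        warnings.warn(
            "signature matrix is not of full column rank; proportions may "
            "not be uniquely determined",
            stacklevel=2,
        )
    h = simplex_lstsq(w.values, y_sub.values)
    return ProportionMatrix(h, list(w.celltype_labels), list(y_sub.sample_ids))


def update_signature(
    y_sub: MixtureMatrix, h: ProportionMatrix, modality: Modality | None = None
) -> SignatureMatrix:
    """Half-step: per-feature bounded least squares given H."""
    if y_sub.n_samples != h.n_samples:
        raise ValueError(
            f"dimension mismatch: y has {y_sub.n_samples} samples, "
            f"H has {h.n_samples}"
        )
    modality = modality or y_sub.modality
    upper = 1.0 if modality == "methylation" else np.inf
    w = box_lstsq(h.values.T, y_sub.values.T, upper=upper)
    return SignatureMatrix(
        w.T, list(y_sub.feature_ids), list(h.celltype_labels), modality
    )


def rf_deconvolve(
    y_sub: MixtureMatrix,
    k: int,
    seed: int = 0,
    n_restarts: int = 3,
    tol: float = 1e-6,
    max_inner: int = 1000,
) -> DeconvResult:
    """Reference-free factorization of a (selected-feature) mixture matrix.

    Runs ``n_restarts`` alternating-least-squares fits from random
    initializations (restart ``r`` seeded with ``seed + r``) and returns the
    solution with the lowest reconstruction RMSE. A restart whose proportion
    matrix collapses a component (a row of H with maximum below 1e-6) is
    discarded; if every restart collapses, an error advises lowering ``k``.
    """
    y = y_sub.values
    m, n = y.shape
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > min(m, n):
        raise ValueError(f"k={k} exceeds min(features={m}, samples={n})")
    labels = [f"C{i + 1}" for i in range(k)]
    if k == 1:
        # single vertex of the simplex: H is all ones, W the row means
        h = np.ones((1, n))
        w = y.mean(axis=1, keepdims=True)
        if y_sub.modality == "methylation":
            w = np.clip(w, 0.0, 1.0)
        result_w = SignatureMatrix(w, list(y_sub.feature_ids), labels, y_sub.modality)
        result_h = ProportionMatrix(h, labels, list(y_sub.sample_ids))
        return DeconvResult(result_w, result_h, _frob_rmse(y, w, h), 1, True)
    if np.ptp(y) == 0.0:
        raise ValueError("mixture matrix is constant; no separable structure to fit")

    upper = 1.0 if y_sub.modality == "methylation" else np.inf
    y_max = float(np.max(y))
    best: tuple[float, np.ndarray, np.ndarray, bool] | None = None
    used = 0
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        w = rng.uniform(0.0, max(y_max, 1e-12), size=(m, k))
        if np.isfinite(upper):
            w = np.clip(w, 0.0, upper)
        h = rng.dirichlet(np.ones(k), size=n).T
        prev_obj = np.inf
        converged = False
        for _ in range(max_inner):
            h = simplex_lstsq(w, y)
            w = box_lstsq(h.T, y.T, upper=upper).T
            obj = float(np.sum((y - w @ h) ** 2))
            # exact half-steps guarantee monotone descent up to rounding
            assert obj <= prev_obj * (1 + 1e-9) + 1e-12
            if prev_obj < np.inf and prev_obj - obj <= tol * max(prev_obj, 1e-300):
                converged = True
                break
            prev_obj = obj
        used += 1
        if h.max(axis=1).min() < _DEGENERATE_TOL:
            continue  # collapsed component; try next restart
        rmse = _frob_rmse(y, w, h)
        if best is None or rmse < best[0]:
            best = (rmse, w, h, converged)
    if best is None:
        raise RuntimeError(
            f"all {n_restarts} restarts produced a degenerate component; "
            f"consider lowering k (currently {k})"
        )
    rmse, w, h, converged = best
    result_w = SignatureMatrix(w, list(y_sub.feature_ids), labels, y_sub.modality)
    result_h = ProportionMatrix(h, labels, list(y_sub.sample_ids))
    return DeconvResult(result_w, result_h, rmse, used, converged)


def reference_based_estimate(
    y: MixtureMatrix, w_ref: SignatureMatrix
) -> ProportionMatrix:
    """Reference-based proportions by constrained least squares on a known
    signature, restricted to the reference features present in the mixture."""
    present = set(y.feature_ids)
    shared = [f for f in w_ref.feature_ids if f in present]
    k = w_ref.n_celltypes
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} reference features overlap the mixture; "
            f"need at least {k}"
        )
    y_sub = y.restrict(shared)
    row = {f: i for i, f in enumerate(w_ref.feature_ids)}
    w_sub = SignatureMatrix(
        w_ref.values[[row[f] for f in shared], :],
        shared,
        list(w_ref.celltype_labels),
        w_ref.modality,
    )
    return update_proportions(y_sub, w_sub)


def _correlation_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlations; zero-variance rows contribute 0."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a**2).sum(axis=1))
    sb = np.sqrt((b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (a @ b.T) / np.outer(sa, sb)
    corr[~np.isfinite(corr)] = 0.0
    return corr


def align_components(
    h_est: ProportionMatrix, h_true: ProportionMatrix
) -> tuple[int, ...]:
    """Match unlabeled estimated components to the truth.

    Returns the permutation ``perm`` maximizing the summed Pearson
    correlation between truth row ``i`` and estimate row ``perm[i]``. For
    K <= 8 all permutations are enumerated so ties resolve to the
    lexicographically smallest permutation; larger K uses the Hungarian
    assignment.
    """
    if h_est.n_celltypes != h_true.n_celltypes:
        raise ValueError(
            f"component count mismatch: estimate has {h_est.n_celltypes}, "
            f"truth has {h_true.n_celltypes}"
        )
    k = h_true.n_celltypes
    corr = _correlation_matrix(h_true.values, h_est.values)  # truth x est
    if k <= 8:
        best_perm = tuple(range(k))
        best_score = -np.inf
        for perm in itertools.permutations(range(k)):
            score = sum(corr[i, perm[i]] for i in range(k))
            if score > best_score + 1e-12:
                best_score = score
                best_perm = perm
        return best_perm
    rows, cols = linear_sum_assignment(-corr)
    return tuple(int(cols[i]) for i in np.argsort(rows))


def apply_alignment(h_est: ProportionMatrix, perm: tuple[int, ...]) -> ProportionMatrix:
    """Reorder estimated rows so row ``i`` matches truth row ``i``."""
    return ProportionMatrix(
        h_est.values[list(perm), :],
        [h_est.celltype_labels[i] for i in perm],
        list(h_est.sample_ids),
    )
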