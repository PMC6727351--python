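import numpy as np
import pytest

from celldeconv.containers import MixtureMatrix, ProportionMatrix, SignatureMatrix


def make_separable_instance(
    k: int = 4,
    n_markers_per_type: int = 15,
    n: int = 30,
    seed: int = 0,
    high: float = 10.0,
    low: float = 0.1,
):
    """Noiseless mixture with exclusive marker blocks: each cell type owns
    ``n_markers_per_type`` features valued ``high`` in its own type and
    ``low`` elsewhere. Returns (mixture, h_true, w_true).

    Proportions are drawn from a sparse Dirichlet(0.5) so the samples cover
    the simplex corners; with interior-only proportions the noiseless
    factorization is not unique (a small rotational ambiguity remains) and
    exact recovery is not a fair expectation."""
    rng = np.random.default_rng(seed)
    p = k * n_markers_per_type
    w = np.full((p, k), low)
    for j in range(k):
        w[j * n_markers_per_type : (j + 1) * n_markers_per_type, j] = high
    h = rng.dirichlet(np.full(k, 0.5), size=n).T
    y = w @ h
    fids = [f"f{i}" for i in range(p)]
    labels = [f"T{j}" for j in range(k)]
    sids = [f"s{i}" for i in range(n)]
    return (
        MixtureMatrix(y, fids, sids),
        ProportionMatrix(h, labels, sids),
        SignatureMatrix(w, fids, labels),
    )


@pytest.fixture
def separable():
    return make_separable_instance()


def simplex_qp_oracle(w: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent simplex-constrained least-squares solver (SLSQP)."""
    from scipy.optimize import minimize

    k = w.shape[1]
    h0 = np.full(k, 1.0 / k)
    res = minimize(
        lambda h: 0.5 * np.sum((y - w @ h) ** 2),
        h0,
        jac=lambda h: -w.T @ (y - w @ h),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda h: h.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return res.x
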