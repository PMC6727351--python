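import numpy as np
import pytest

from celldeconv.containers import MixtureMatrix, ProportionMatrix, SignatureMatrix
from celldeconv.engine import (
    align_components,
    apply_alignment,
    rf_deconvolve,
    reference_based_estimate,
    simplex_lstsq,
    box_lstsq,
    update_proportions,
    update_signature,
)
from celldeconv.metrics import corr_with_true

from conftest import make_separable_instance, simplex_qp_oracle


class TestSimplexStep:
    def test_agrees_with_qp_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            m = rng.integers(4, 21)
            k = rng.integers(2, 5)
            w = rng.uniform(0, 5, size=(m, k))
            y = rng.uniform(0, 5, size=m)
            ours = simplex_lstsq(w, y[:, None])[:, 0]
            oracle = simplex_qp_oracle(w, y)
            assert np.abs(ours - oracle).max() < 1e-6

    def test_exact_interpolation(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0, 3, size=(10, 3))
        h_star = np.array([0.2, 0.5, 0.3])
        y = w @ h_star
        h = simplex_lstsq(w, y[:, None])[:, 0]
        np.testing.assert_allclose(h, h_star, atol=1e-8)

    def test_orthonormal_closed_form(self):
        w = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([[0.3], [0.7]])
        np.testing.assert_allclose(simplex_lstsq(w, y)[:, 0], [0.3, 0.7], atol=1e-12)

    def test_columns_always_feasible(self):
        rng = np.random.default_rng(7)
        w = rng.uniform(0, 1, size=(6, 4))
        y = rng.normal(size=(6, 20))  # even negative observations
        h = simplex_lstsq(w, y)
        assert (h >= 0).all()
        np.testing.assert_allclose(h.sum(axis=0), 1.0, atol=1e-12)


class TestUpdateProportions:
    def test_dimension_mismatch(self, separable):
        y, _, w = separable
        bad = SignatureMatrix(w.values[:-1], w.feature_ids[:-1], w.celltype_labels)
        with pytest.raises(ValueError, match="mismatch"):
            update_proportions(y, bad)

    def test_duplicate_columns_warn_but_feasible(self):
        w = SignatureMatrix(
            np.array([[1.0, 1.0], [2.0, 2.0]]), ["f1", "f2"], ["A", "B"]
        )
        y = MixtureMatrix(np.array([[1.0], [2.0]]), ["f1", "f2"], ["s1"])
        with pytest.warns(UserWarning, match="rank"):
            h = update_proportions(y, w)
        assert (h.values >= 0).all()
        np.testing.assert_allclose(h.values.sum(axis=0), 1.0)


class TestSignatureStep:
    def test_recovers_true_signature_noiseless(self, separable):
        y, h, w_true = separable
        w = update_signature(y, h)
        np.testing.assert_allclose(w.values, w_true.values, atol=1e-8)

    def test_zero_row_gives_zero_signature(self):
        h = ProportionMatrix(
            np.array([[0.3, 0.6, 0.1], [0.7, 0.4, 0.9]]), ["A", "B"], ["s1", "s2", "s3"]
        )
        y = MixtureMatrix(np.zeros((1, 3)), ["f1"], ["s1", "s2", "s3"])
        w = update_signature(y, h)
        np.testing.assert_allclose(w.values, 0.0, atol=1e-12)

    def test_methylation_bounded_by_one(self):
        h = ProportionMatrix(
            np.array([[0.5, 0.9, 0.1], [0.5, 0.1, 0.9]]), ["A", "B"], list("abc")
        )
        # observations implying an unconstrained fit above 1
        y = MixtureMatrix(np.array([[1.0, 1.0, 1.0]]) * 1.0, ["f1"], list("abc"))
        y.values[:] = 1.0  # beta at ceiling everywhere
        w = update_signature(y, h, "methylation")
        assert (w.values <= 1.0 + 1e-12).all() and (w.values >= 0).all()

    def test_box_step_matches_unconstrained_when_interior(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.1, 1, size=(30, 3))
        x_true = rng.uniform(0.2, 0.8, size=(3, 5))
        b = a @ x_true
        np.testing.assert_allclose(box_lstsq(a, b, upper=1.0), x_true, atol=1e-8)


class TestRfDeconvolve:
    def test_recovers_separable_instance(self, separable):
        y, h_true, _ = separable
        res = rf_deconvolve(y, 4, seed=0)
        perm = align_components(res.H, h_true)
        corr = corr_with_true(apply_alignment(res.H, perm), h_true)
        assert (corr >= 0.99).all()

    def test_estimate_matches_qp_oracle_given_true_w(self, separable):
        y, h_true, w_true = separable
        res = rf_deconvolve(y, 4, seed=0)
        perm = align_components(res.H, h_true)
        h_est = apply_alignment(res.H, perm)
        for s in range(0, y.n_samples, 7):
            oracle = simplex_qp_oracle(w_true.values, y.values[:, s])
            # W is estimated, not the truth, so agreement is approximate
            np.testing.assert_allclose(h_est.values[:, s], oracle, atol=0.05)

    def test_objective_nonincreasing_and_rmse_consistent(self, separable):
        y, _, _ = separable
        res = rf_deconvolve(y, 4, seed=1)
        recon = res.W.values @ res.H.values
        rmse = float(np.sqrt(np.mean((y.values - recon) ** 2)))
        assert abs(rmse - res.rmse) < 1e-10

    def test_k1_analytic(self):
        y = MixtureMatrix(
            np.array([[1.0, 3.0], [2.0, 4.0]]), ["f1", "f2"], ["s1", "s2"]
        )
        res = rf_deconvolve(y, 1)
        np.testing.assert_array_equal(res.H.values, [[1.0, 1.0]])
        np.testing.assert_allclose(res.W.values[:, 0], [2.0, 3.0])

    @pytest.mark.parametrize("k", [0, 5])
    def test_invalid_k(self, k):
        y = MixtureMatrix(np.random.default_rng(0).uniform(size=(4, 4)),
                          [f"f{i}" for i in range(4)], [f"s{i}" for i in range(4)])
        with pytest.raises(ValueError):
            rf_deconvolve(y, k)

    def test_constant_matrix_rejected(self):
        y = MixtureMatrix(np.full((5, 5), 2.0), [f"f{i}" for i in range(5)],
                          [f"s{i}" for i in range(5)])
        with pytest.raises(ValueError, match="constant"):
            rf_deconvolve(y, 2)

    def test_nan_rejected_by_container(self):
        with pytest.raises(ValueError, match="non-finite"):
            MixtureMatrix(np.array([[1.0, np.nan]]), ["f1"], ["s1", "s2"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_separable_recovery_across_seeds(self, seed):
        y, h_true, _ = make_separable_instance(seed=seed + 10)
        res = rf_deconvolve(y, 4, seed=seed)
        perm = align_components(res.H, h_true)
        corr = corr_with_true(apply_alignment(res.H, perm), h_true)
        assert (corr >= 0.99).all()


class TestReferenceBased:
    def test_exact_recovery_noiseless(self, separable):
        y, h_true, w = separable
        h = reference_based_estimate(y, w)
        assert np.abs(h.values - h_true.values).max() <= 1e-8

    def test_three_type_block_mixture(self):
        w = np.array(
            [[10.0, 0.1, 0.1], [0.1, 10.0, 0.1], [0.1, 0.1, 10.0], [5.0, 5.0, 0.1]]
        )
        h_star = np.array([0.2, 0.5, 0.3])
        y = MixtureMatrix((w @ h_star)[:, None], [f"f{i}" for i in range(4)], ["s1"])
        w_ref = SignatureMatrix(w, [f"f{i}" for i in range(4)], ["A", "B", "C"])
        h = reference_based_estimate(y, w_ref)
        oracle = simplex_qp_oracle(w, y.values[:, 0])
        np.testing.assert_allclose(h.values[:, 0], oracle, atol=1e-6)
        np.testing.assert_allclose(h.values[:, 0], h_star, atol=1e-8)

    def test_insufficient_overlap(self, separable):
        y, _, w = separable
        w_small = SignatureMatrix(w.values[:2], w.feature_ids[:2], w.celltype_labels)
        y_two = y.restrict(w.feature_ids[:2])
        y_missing = MixtureMatrix(
            y_two.values, ["other1", "other2"], y_two.sample_ids
        )
        with pytest.raises(ValueError, match="overlap"):
            reference_based_estimate(y_missing, w)

    def test_simplex_output_for_arbitrary_input(self, separable):
        _, _, w = separable
        rng = np.random.default_rng(5)
        y = MixtureMatrix(
            rng.uniform(0, 20, size=(w.n_features, 8)),
            w.feature_ids,
            [f"s{i}" for i in range(8)],
        )
        h = reference_based_estimate(y, w)
        assert (h.values >= 0).all()
        np.testing.assert_allclose(h.values.sum(axis=0), 1.0, atol=1e-8)


class TestAlignComponents:
    def test_recovers_inverse_permutation(self):
        rng = np.random.default_rng(0)
        h = rng.dirichlet(np.ones(4), size=25).T
        truth = ProportionMatrix(h, list("ABCD"), [f"s{i}" for i in range(25)])
        p = [2, 0, 3, 1]
        est = ProportionMatrix(h[p], list("ABCD"), truth.sample_ids)
        perm = align_components(est, truth)
        # est row perm[i] must equal truth row i
        np.testing.assert_array_equal(est.values[list(perm)], truth.values)

    def test_k1_identity(self):
        t = ProportionMatrix(np.ones((1, 3)), ["A"], list("abc"))
        assert align_components(t, t) == (0,)

    def test_tie_resolves_lexicographically(self):
        # two identical estimated rows: both assignments score equally
        vals = np.array([[0.2, 0.6, 0.4], [0.4, 0.2, 0.3], [0.4, 0.2, 0.3]])
        vals /= vals.sum(axis=0, keepdims=True)
        est = ProportionMatrix(vals, list("XYZ"), list("abc"))
        truth_vals = np.array([[0.2, 0.6, 0.4], [0.5, 0.2, 0.3], [0.3, 0.2, 0.3]])
        truth_vals /= truth_vals.sum(axis=0, keepdims=True)
        truth = ProportionMatrix(truth_vals, list("XYZ"), list("abc"))
        assert align_components(est, truth) == (0, 1, 2)

    def test_k_mismatch(self):
        a = ProportionMatrix(np.ones((1, 2)), ["A"], ["s1", "s2"])
        b = ProportionMatrix(np.full((2, 2), 0.5), ["A", "B"], ["s1", "s2"])
        with pytest.raises(ValueError, match="mismatch"):
            align_components(a, b)
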