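"""Objective, update rules, fit loop, prediction and ranking."""

import numpy as np
import pytest

import simnmf as sn
from simnmf.errors import ConfigurationError, DimensionError, NumericError

from conftest import random_instance
from oracles import (
    brute_rank,
    naive_matmul,
    naive_objective,
    naive_update_x,
    naive_update_y,
)


class TestObjective:
    def test_zero_factors_leave_only_data_and_similarity_terms(self, small_instance):
        A, F, Sd, Se, h = small_instance
        zero = sn.LatentFactors(np.zeros_like(F.X), np.zeros_like(F.Y))
        expected = np.sum(A.values**2) + h.lam * (
            np.sum(Sd.values**2) + np.sum(Se.values**2)
        )
        assert sn.objective_value(A, zero, Sd, Se, h) == pytest.approx(expected)

    def test_exact_factorization_gives_zero(self):
        # one-hot group factors: A = X.T Y is binary, Sd = X.T X and
        # Se = Y.T Y are valid similarity matrices, so with mu = 0 every
        # residual of the objective vanishes
        X = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=float)
        Y = np.array([[1, 0, 0], [0, 1, 1]], dtype=float)
        drugs, diseases = list("abcd"), list("xyz")
        A = sn.AssociationMatrix(X.T @ Y, drugs, diseases)
        F = sn.LatentFactors(X, Y)
        Sd = sn.SimilarityMatrix(X.T @ X, drugs)
        Se = sn.SimilarityMatrix(Y.T @ Y, diseases)
        h = sn.Hyperparameters(k=2, mu=0.0, lam=0.7)
        assert sn.objective_value(A, F, Sd, Se, h) == pytest.approx(0.0, abs=1e-12)

    def test_matches_term_by_term_expansion(self, rng):
        A, F, Sd, Se, _ = random_instance(rng, n=4, m=3, k=2)
        h = sn.Hyperparameters(k=2, mu=0.1, lam=0.5)
        expected = naive_objective(
            A.values, F.X, F.Y, Sd.values, Se.values, h.mu, h.lam
        )
        assert sn.objective_value(A, F, Sd, Se, h) == pytest.approx(expected, abs=1e-10)

    def test_shape_mismatch_names_offender(self, small_instance, rng):
        A, F, Sd, Se, h = small_instance
        bad = sn.LatentFactors(rng.random((2, A.n_drugs + 1)), F.Y)
        with pytest.raises(DimensionError, match="X"):
            sn.objective_value(A, bad, Sd, Se, h)


class TestUpdates:
    def test_zero_factor_stays_zero(self, small_instance):
        A, F, Sd, Se, h = small_instance
        zero = sn.LatentFactors(np.zeros_like(F.X), np.zeros_like(F.Y))
        assert not sn.update_x(A, zero, Sd, h).any()
        assert not sn.update_y(A, zero, Se, h).any()

    def test_zero_entries_remain_zero(self, small_instance):
        A, F, Sd, Se, h = small_instance
        X = F.X.copy()
        X[0, 0] = X[1, 3] = 0.0
        F0 = sn.LatentFactors(X, F.Y)
        out = sn.update_x(A, F0, Sd, h)
        assert out[0, 0] == 0.0 and out[1, 3] == 0.0

    def test_fixed_point_when_numerator_equals_denominator(self):
        # with mu = lam = 0 and binary A = X.T Y from one-hot factors,
        # numerator Y A.T equals denominator Y Y.T X elementwise
        X = np.array([[1, 1, 0], [0, 0, 1]], dtype=float)
        Y = np.array([[1, 0, 1], [0, 1, 0]], dtype=float)
        A = sn.AssociationMatrix(X.T @ Y, list("abc"), list("xyz"))
        Sd = sn.SimilarityMatrix(np.eye(3), A.drug_ids)
        h = sn.Hyperparameters(k=2, mu=0.0, lam=0.0, eps=1e-300)
        out = sn.update_x(A, sn.LatentFactors(X, Y), Sd, h)
        np.testing.assert_allclose(out, X, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scalar_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A, F, Sd, Se, _ = random_instance(rng, n=5, m=4, k=2)
        h = sn.Hyperparameters(k=2, mu=0.1, lam=0.2)
        np.testing.assert_allclose(
            sn.update_x(A, F, Sd, h),
            naive_update_x(A.values, F.X, F.Y, Sd.values, h.mu, h.lam, h.eps),
            atol=1e-10,
        )
        np.testing.assert_allclose(
            sn.update_y(A, F, Se, h),
            naive_update_y(A.values, F.X, F.Y, Se.values, h.mu, h.lam, h.eps),
            atol=1e-10,
        )

    def test_nonfinite_input_raises(self, small_instance):
        A, F, Sd, Se, h = small_instance
        X = F.X.copy()
        X[0, 0] = np.nan
        # bypass container validation to reach the update guard
        bad = object.__new__(sn.LatentFactors)
        object.__setattr__(bad, "X", X)
        object.__setattr__(bad, "Y", F.Y)
        with pytest.raises(NumericError):
            sn.update_x(A, bad, Sd, h)


class TestFit:
    def test_max_iter_zero_returns_initialization(self, rng):
        A, _, Sd, Se, _ = random_instance(rng, n=8, m=6, k=2)
        h = sn.Hyperparameters(k=2, max_iter=0, seed=5)
        F, trace = sn.fit(A, Sd, Se, h)
        init = sn.init_factors(A, h)
        np.testing.assert_array_equal(F.X, init.X)
        np.testing.assert_array_equal(F.Y, init.Y)
        assert trace.iterations_run == 0
        assert len(trace.objective_per_iter) == 1
        assert not trace.converged

    def test_seeded_determinism_is_bitwise(self, rng):
        A, _, Sd, Se, _ = random_instance(rng, n=8, m=6, k=2)
        h = sn.Hyperparameters(k=2, max_iter=50, seed=11)
        F1, t1 = sn.fit(A, Sd, Se, h)
        F2, t2 = sn.fit(A, Sd, Se, h)
        assert np.array_equal(F1.X, F2.X) and np.array_equal(F1.Y, F2.Y)
        assert t1.objective_per_iter == t2.objective_per_iter

    def test_trace_records_every_iteration(self, rng):
        A, _, Sd, Se, _ = random_instance(rng, n=8, m=6, k=2)
        h = sn.Hyperparameters(k=2, max_iter=30, tol=0.0, seed=1)
        _, trace = sn.fit(A, Sd, Se, h)
        assert trace.iterations_run == 30
        assert len(trace.objective_per_iter) == 31

    def test_descends_and_matches_naive_update_fit(self):
        # same loop rebuilt on the scalar-loop update oracles
        bundle, _, _ = sn.generate(
            sn.SyntheticSpec(n=12, m=9, k_true=2, density=0.2, seed=4)
        )
        A, Sd, Se = bundle.A, bundle.Sd, bundle.Se
        h = sn.Hyperparameters(k=2, mu=0.1, lam=0.1, max_iter=60, tol=0.0, seed=4)
        F, trace = sn.fit(A, Sd, Se, h)
        assert trace.objective_per_iter[-1] <= trace.objective_per_iter[0]

        G = sn.init_factors(A, h)
        X, Y = G.X.copy(), G.Y.copy()
        for _ in range(h.max_iter):
            X = naive_update_x(A.values, X, Y, Sd.values, h.mu, h.lam, h.eps)
            Y = naive_update_y(A.values, X, Y, Se.values, h.mu, h.lam, h.eps)
        oracle_obj = naive_objective(A.values, X, Y, Sd.values, Se.values, h.mu, h.lam)
        assert trace.objective_per_iter[-1] == pytest.approx(oracle_obj, rel=1e-6)

    def test_k_too_large_is_configuration_error(self, rng):
        A, _, Sd, Se, _ = random_instance(rng, n=5, m=4, k=2)
        with pytest.raises(ConfigurationError):
            sn.fit(A, Sd, Se, sn.Hyperparameters(k=4))

    def test_all_zero_association_warns_but_fits(self):
        A = sn.AssociationMatrix(np.zeros((5, 4)), list("abcde"), list("wxyz"))
        Sd = sn.SimilarityMatrix(np.eye(5), A.drug_ids)
        Se = sn.SimilarityMatrix(np.eye(4), A.disease_ids)
        with pytest.warns(UserWarning, match="no known links"):
            F, _ = sn.fit(A, Sd, Se, sn.Hyperparameters(k=2, max_iter=5))
        assert F.X.min() >= 0 and F.Y.min() >= 0


class TestPredictAndRank:
    def test_exact_factorization_reproduces_a(self, rng):
        A, _, _, _, _ = random_instance(rng, n=4, m=6, k=2)
        # k = n with X = identity, Y = A's rows reproduces A exactly
        F = sn.LatentFactors(np.eye(4), A.values)
        scores = sn.predict(F, A.drug_ids, A.disease_ids)
        np.testing.assert_array_equal(scores.values, A.values)

    def test_zero_factors_give_zero_scores(self):
        F = sn.LatentFactors(np.zeros((2, 3)), np.zeros((2, 4)))
        scores = sn.predict(F, list("abc"), list("wxyz"))
        assert not scores.values.any()

    def test_matches_triple_loop_product(self, rng):
        F = sn.LatentFactors(rng.random((3, 5)), rng.random((3, 4)))
        scores = sn.predict(F, [f"d{i}" for i in range(5)], [f"s{j}" for j in range(4)])
        np.testing.assert_allclose(scores.values, naive_matmul(F.X, F.Y), atol=1e-12)

    def test_rank_excludes_known_and_truncates(self):
        A = sn.AssociationMatrix([[1, 0, 0]], ["d1"], ["s1", "s2", "s3"])
        scores = sn.ScoreMatrix([[0.9, 0.5, 0.1]], ("d1",), ("s1", "s2", "s3"))
        assert sn.rank_candidates(scores, A, "d1", 5) == [("s2", 0.5), ("s3", 0.1)]

    def test_fully_known_drug_has_empty_pool(self):
        A = sn.AssociationMatrix([[1, 1]], ["d1"], ["s1", "s2"])
        scores = sn.ScoreMatrix([[0.9, 0.5]], ("d1",), ("s1", "s2"))
        assert sn.rank_candidates(scores, A, "d1", 3) == []

    def test_matches_bruteforce_ranking(self, rng):
        A, F, _, _, _ = random_instance(rng, n=10, m=8, k=2)
        scores = sn.predict(F, A.drug_ids, A.disease_ids)
        for i, drug in enumerate(A.drug_ids):
            assert sn.rank_candidates(scores, A, drug, 4) == brute_rank(
                scores.values[i], A.values[i], A.disease_ids, 4
            )

    def test_unknown_drug_raises_lookup_error(self):
        A = sn.AssociationMatrix([[0]], ["d1"], ["s1"])
        scores = sn.ScoreMatrix([[0.5]], ("d1",), ("s1",))
        with pytest.raises(KeyError, match="nope"):
            sn.rank_candidates(scores, A, "nope", 1)

    def test_ties_break_by_disease_identifier(self):
        A = sn.AssociationMatrix([[0, 0, 0]], ["d1"], ["s3", "s1", "s2"])
        scores = sn.ScoreMatrix([[0.5, 0.5, 0.5]], ("d1",), ("s3", "s1", "s2"))
        assert [d for d, _ in sn.rank_candidates(scores, A, "d1", 3)] == ["s1", "s2", "s3"]


class TestReductionAndStationarity:
    def test_reduces_to_standard_nmf(self, rng):
        """mu = lam = 0: objective and updates are classical NMF."""
        A, F, Sd, Se, _ = random_instance(rng, n=6, m=5, k=2)
        h = sn.Hyperparameters(k=2, mu=0.0, lam=0.0, eps=1e-300)
        recon = A.values - F.X.T @ F.Y
        assert sn.objective_value(A, F, Sd, Se, h) == pytest.approx(
            float(np.sum(recon**2)), abs=1e-10
        )
        lee_seung_x = F.X * (F.Y @ A.values.T) / ((F.Y @ F.Y.T) @ F.X + h.eps)
        np.testing.assert_allclose(sn.update_x(A, F, Sd, h), lee_seung_x, atol=1e-12)

    def test_reduces_to_tikhonov_nmf(self, rng):
        """lam = 0: objective adds only the Frobenius penalty."""
        A, F, Sd, Se, _ = random_instance(rng, n=6, m=5, k=2)
        h = sn.Hyperparameters(k=2, mu=0.3, lam=0.0)
        recon = A.values - F.X.T @ F.Y
        expected = float(np.sum(recon**2)) + 0.3 * float(
            np.sum(F.X**2) + np.sum(F.Y**2)
        )
        assert sn.objective_value(A, F, Sd, Se, h) == pytest.approx(expected, abs=1e-10)

    def test_kkt_residual_small_after_deep_convergence(self):
        bundle, _, _ = sn.generate(
            sn.SyntheticSpec(n=10, m=8, k_true=2, density=0.15, seed=0)
        )
        h = sn.Hyperparameters(k=2, mu=0.1, lam=0.1, max_iter=200000, tol=1e-10, seed=0)
        F, _ = sn.fit(bundle.A, bundle.Sd, bundle.Se, h)
        gX, gY = sn.gradients(bundle.A, F, bundle.Sd, bundle.Se, h)
        assert np.abs(np.minimum(F.X, gX)).max() <= 1e-3
        assert np.abs(np.minimum(F.Y, gY)).max() <= 1e-3


def test_nonnegativity_closure_over_many_iterations():
    """Iterates stay elementwise >= 0 on randomized instances."""
    for seed in range(3):
        rng = np.random.default_rng(seed)
        A, F, Sd, Se, _ = random_instance(rng, n=7, m=6, k=2)
        h = sn.Hyperparameters(k=2, mu=0.05, lam=0.3)
        for _ in range(100):
            F = sn.LatentFactors(sn.update_x(A, F, Sd, h), F.Y)
            F = sn.LatentFactors(F.X, sn.update_y(A, F, Se, h))
            assert F.X.min() >= 0 and F.Y.min() >= 0
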