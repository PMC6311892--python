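import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kronlink.baselines import (
    heterogeneous_adjacency,
    katz,
    nbi,
    netlaprls,
    rls_avg,
    rls_kron,
    wp,
)
from kronlink.io import AssociationMatrix, RunConfig
from kronlink.kronrls import build_kernels, solve_naive
from kronlink.predictors import METHODS, make_predictor

from conftest import random_binary


def rng_kernel(rng, n):
    A = rng.random((n, n))
    K = (A + A.T) / 2
    np.fill_diagonal(K, 1.0)
    return K


class TestRlsAvg:
    def test_identity_kernels(self):
        rng = np.random.default_rng(0)
        Y = random_binary(rng, 3, 4)
        out = rls_avg(np.eye(3), np.eye(4), Y, 0.2)
        np.testing.assert_allclose(out, Y / 1.2, atol=1e-12)

    def test_zero_labels(self):
        out = rls_avg(np.eye(2), np.eye(2), np.zeros((2, 2)), 0.2)
        np.testing.assert_allclose(out, 0.0)

    def test_matches_two_solve_oracle(self):
        rng = np.random.default_rng(1)
        Kc, Kd = rng_kernel(rng, 3), rng_kernel(rng, 2)
        Y = random_binary(rng, 3, 2)
        sigma = 0.2
        a = Kc @ np.linalg.inv(Kc + sigma * np.eye(3)) @ Y
        b = (Kd @ np.linalg.inv(Kd + sigma * np.eye(2)) @ Y.T).T
        np.testing.assert_allclose(rls_avg(Kc, Kd, Y, sigma), (a + b) / 2, atol=1e-10)


class TestRlsKron:
    def test_equals_naive_oracle(self):
        rng = np.random.default_rng(2)
        Kc, Kd = rng_kernel(rng, 4), rng_kernel(rng, 3)
        Y = random_binary(rng, 4, 3)
        np.testing.assert_allclose(
            rls_kron(Kc, Kd, Y, 0.2), solve_naive(Kc, Kd, Y, 0.2), atol=1e-8
        )

    def test_equals_main_method_without_cold_start(self, toy_Y, default_config):
        Sc, Sd = build_kernels(toy_Y, default_config)
        main = make_predictor("wknn-kronrls", default_config)(toy_Y)
        base = rls_kron(Sc, Sd, toy_Y, default_config.sigma)
        np.testing.assert_array_equal(main.scores, base.scores)

    def test_differs_from_main_method_on_cold_start(self, default_config):
        Y = AssociationMatrix(
            ["c1", "c2", "c3"], ["d1", "d2"], [[1, 0], [0, 1], [0, 0]]
        )
        main = make_predictor("wknn-kronrls", default_config)(Y)
        base = make_predictor("rls-kron", default_config)(Y)
        assert np.abs(main.scores - base.scores).max() > 1e-6


class TestKatz:
    def test_length_one_is_beta_Y(self):
        rng = np.random.default_rng(3)
        Y = random_binary(rng, 3, 4)
        out = katz(Y, beta=0.3, max_length=1, augment=False)
        np.testing.assert_allclose(out, 0.3 * Y, atol=1e-12)

    def test_length_two_block_expansion(self):
        rng = np.random.default_rng(4)
        Y = random_binary(rng, 3, 4)
        Kc, Kd = rng_kernel(rng, 3), rng_kernel(rng, 4)
        beta = 0.1
        out = katz(Y, Kc, Kd, beta=beta, max_length=2)
        expected = beta * Y + beta**2 * (Kc @ Y + Y @ Kd)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_beta_zero_gives_zero(self):
        rng = np.random.default_rng(5)
        Y = random_binary(rng, 3, 3)
        np.testing.assert_allclose(katz(Y, beta=0.0, max_length=3, augment=False), 0.0)

    def test_closed_form_divergence_guard(self):
        Y = np.ones((2, 2))
        with pytest.raises(ValueError, match="diverges"):
            katz(Y, beta=1.0, max_length=None, augment=False)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_truncated_sum_converges_monotonically_to_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        Y = random_binary(rng, 4, 3)
        A = heterogeneous_adjacency(Y)
        rho = float(np.max(np.abs(np.linalg.eigvals(A))))
        beta = 0.5 / max(rho, 1e-9)
        closed = katz(Y, beta=beta, max_length=None, augment=False)
        prev_err = np.inf
        for L in (1, 3, 6, 12):
            trunc = katz(Y, beta=beta, max_length=L, augment=False)
            err = np.abs(closed - trunc).max()
            assert err <= prev_err + 1e-12  # nonnegative A: monotone approach
            prev_err = err
        assert prev_err < 1e-3


class TestNbi:
    def test_single_row_two_diseases(self):
        out = nbi(np.array([[1.0, 1.0]]))
        np.testing.assert_allclose(out, [[1.0, 1.0]], atol=1e-12)

    def test_identity_matrix_fixed_point(self):
        np.testing.assert_allclose(nbi(np.eye(3)), np.eye(3), atol=1e-12)

    def test_empty_matrix_gives_zero(self):
        np.testing.assert_allclose(nbi(np.zeros((2, 3))), 0.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_transfer_operator_conserves_resource(self, seed):
        rng = np.random.default_rng(seed)
        Y = random_binary(rng, 5, 4, p=0.6)
        kc, kd = Y.sum(axis=1), Y.sum(axis=0)
        with np.errstate(divide="ignore"):
            kc_inv = np.where(kc > 0, 1 / kc, 0.0)
            kd_inv = np.where(kd > 0, 1 / kd, 0.0)
        W = (kd_inv[:, None] * Y.T) @ (kc_inv[:, None] * Y)
        # Yhat = Y W: the source disease's unit of resource is spread over
        # target diseases, so each W row sums to <= 1, = 1 for positive degree
        sums = W.sum(axis=1)
        assert (sums <= 1 + 1e-10).all()
        for j, s in enumerate(sums):
            if kd[j] > 0:
                assert s == pytest.approx(1.0, abs=1e-10)
            else:
                assert s == 0.0


class TestWp:
    def test_identical_circrnas_share_association(self):
        Kc = np.array([[1.0, 1.0], [1.0, 1.0]])
        Kd = np.array([[1.0]])
        Y = np.array([[1.0], [0.0]])
        out = wp(Kc, Kd, Y)
        # circRNA side transfers the full label; disease side has no mass
        assert out[1, 0] == pytest.approx(0.5, abs=1e-12)
        assert 0.0 <= out.min() and out.max() <= 1.0

    def test_zero_labels(self):
        rng = np.random.default_rng(6)
        np.testing.assert_allclose(wp(rng_kernel(rng, 3), rng_kernel(rng, 2), np.zeros((3, 2))), 0.0)

    def test_symmetric_under_simultaneous_swap(self):
        Kc = np.array([[1.0, 0.5], [0.5, 1.0]])
        Kd = np.array([[1.0, 0.5], [0.5, 1.0]])
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = wp(Kc, Kd, Y)
        np.testing.assert_allclose(out, out[::-1, ::-1], atol=1e-12)


class TestNetLapRls:
    def test_zero_laplacian_weight_returns_labels(self):
        rng = np.random.default_rng(7)
        Kc, Kd = rng_kernel(rng, 4), rng_kernel(rng, 3)
        Y = random_binary(rng, 4, 3)
        out = netlaprls(Kc, Kd, Y, beta_c=0.0, beta_d=0.0)
        np.testing.assert_allclose(out, Y, atol=1e-8)

    def test_zero_labels(self):
        rng = np.random.default_rng(8)
        out = netlaprls(rng_kernel(rng, 3), rng_kernel(rng, 2), np.zeros((3, 2)))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_matches_direct_solve_oracle(self):
        rng = np.random.default_rng(9)
        Kc, Kd = rng_kernel(rng, 4), rng_kernel(rng, 3)
        Y = random_binary(rng, 4, 3)
        gamma, beta = 0.01, 0.3

        def laplacian(W):
            d = W.sum(axis=1)
            dinv = np.where(d > 0, 1 / np.sqrt(d), 0.0)
            return np.diag(d * dinv * dinv) - dinv[:, None] * W * dinv[None, :]

        Wc = (Kc + gamma * Y @ Y.T) / (1 + gamma)
        Wd = (Kd + gamma * Y.T @ Y) / (1 + gamma)
        Fc = Wc @ np.linalg.inv(Wc + beta * laplacian(Wc)) @ Y
        Fd = (Wd @ np.linalg.inv(Wd + beta * laplacian(Wd)) @ Y.T).T
        np.testing.assert_allclose(
            netlaprls(Kc, Kd, Y, gamma, gamma, beta, beta), (Fc + Fd) / 2, atol=1e-8
        )


class TestPredictorInterface:
    @pytest.mark.parametrize("method", METHODS)
    def test_deterministic_and_aligned(self, method, synth, default_config):
        Y = synth["Y"]
        pred = make_predictor(method, default_config, synth["sem"])
        a = pred(Y)
        b = pred(Y)
        assert a.row_ids == Y.row_ids and a.col_ids == Y.col_ids
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            make_predictor("bogus")
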