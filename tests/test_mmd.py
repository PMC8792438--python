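"""Kernel two-sample distance: closed forms, oracle equivalence, gradients."""

import numpy as np
import pytest

from msmra.exceptions import (
    EmptyInputError,
    InsufficientBatchError,
    InvalidConfigError,
    RepresentationCountError,
    ShapeError,
)
from msmra.mmd import KernelConfig, MMDEstimate, mmd2, mmd2_with_grad, mmd_final_domain, mmd_total


def naive_mmd2(X, Y, kernel: KernelConfig) -> float:
    """Independent O(n^2) double-loop reference implementation."""
    X, Y = np.atleast_2d(X), np.atleast_2d(Y)
    n, m = len(X), len(Y)
    if kernel.fixed_sigma is not None:
        base = kernel.fixed_sigma**2
    else:
        joint = np.vstack([X, Y])
        d2 = [
            np.sum((joint[i] - joint[j]) ** 2)
            for i in range(len(joint))
            for j in range(len(joint))
            if i != j
        ]
        base = np.median(d2) / 2.0
    k = kernel.num_kernels
    sigmas = [base * kernel.spread_factor ** (p - (k - 1) / 2.0) for p in range(k)]
    total = 0.0
    for s2 in sigmas:
        kf = lambda a, b: np.exp(-np.sum((a - b) ** 2) / (2.0 * s2))
        if kernel.unbiased:
            xx = sum(kf(X[i], X[j]) for i in range(n) for j in range(n) if i != j) / (
                n * (n - 1)
            )
            yy = sum(kf(Y[i], Y[j]) for i in range(m) for j in range(m) if i != j) / (
                m * (m - 1)
            )
        else:
            xx = sum(kf(X[i], X[j]) for i in range(n) for j in range(n)) / n**2
            yy = sum(kf(Y[i], Y[j]) for i in range(m) for j in range(m)) / m**2
        xy = sum(kf(X[i], Y[j]) for i in range(n) for j in range(m)) / (n * m)
        total += xx + yy - 2.0 * xy
    return total


class TestMMD2:
    def test_identical_batches_give_zero(self):
        X = np.random.default_rng(0).normal(size=(12, 5))
        assert abs(mmd2(X, X.copy())) < 1e-9

    def test_singleton_closed_form(self):
        x = np.array([[1.0, 2.0, -1.0]])
        y = np.array([[0.5, -0.5, 2.0]])
        sigma = 1.7
        k = KernelConfig(num_kernels=1, fixed_sigma=sigma)
        expected = 2.0 - 2.0 * np.exp(-np.sum((x - y) ** 2) / (2.0 * sigma**2))
        assert mmd2(x, y, k, strict=False) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("unbiased", [False, True])
    def test_matches_naive_double_loop(self, unbiased):
        rng = np.random.default_rng(1)
        k = KernelConfig(unbiased=unbiased)
        for _ in range(20):
            n, m, d = rng.integers(2, 33), rng.integers(2, 33), rng.integers(1, 17)
            X = rng.normal(size=(n, d))
            Y = rng.normal(size=(m, d)) + rng.normal()
            a, b = mmd2(X, Y, k), naive_mmd2(X, Y, k)
            assert abs(a - b) <= 1e-9 * max(abs(b), 1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        X, Y = rng.normal(size=(9, 4)), rng.normal(size=(7, 4)) + 0.5
        assert mmd2(X, Y) == mmd2(Y, X)

    def test_shift_response_monotone(self):
        # mean estimate over 50 seeded replicates is non-decreasing in the shift
        deltas = [0.0, 0.5, 1.0, 2.0]
        means = []
        for d in deltas:
            vals = []
            for s in range(50):
                rng = np.random.default_rng(1000 + s)
                X = rng.normal(size=(24, 6))
                Y = rng.normal(size=(24, 6)) + d
                vals.append(mmd2(X, Y))
            means.append(np.mean(vals))
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_errors(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ShapeError):
            mmd2(X, np.zeros((5, 4)))
        with pytest.raises(InsufficientBatchError):
            mmd2(X[:1], X)
        with pytest.raises(InsufficientBatchError):
            mmd2(X[:1], X, KernelConfig(unbiased=True), strict=False)

    def test_invalid_kernel_config(self):
        with pytest.raises(InvalidConfigError):
            KernelConfig(num_kernels=0)
        with pytest.raises(InvalidConfigError):
            KernelConfig(num_kernels=3, spread_factor=1.0)


class TestGradients:
    @pytest.mark.parametrize("unbiased", [False, True])
    def test_analytic_matches_finite_differences(self, unbiased):
        rng = np.random.default_rng(3)
        k = KernelConfig(num_kernels=3, fixed_sigma=1.3, unbiased=unbiased)
        X, Y = rng.normal(size=(6, 4)), rng.normal(size=(5, 4)) + 0.3
        _, gX, gY = mmd2_with_grad(X, Y, k)
        eps = 1e-6
        for A, g, is_x in ((X, gX, True), (Y, gY, False)):
            for i in range(A.shape[0]):
                for j in range(A.shape[1]):
                    ap, am = A.copy(), A.copy()
                    ap[i, j] += eps
                    am[i, j] -= eps
                    args_p = (ap, Y) if is_x else (X, ap)
                    args_m = (am, Y) if is_x else (X, am)
                    num = (mmd2(*args_p, k) - mmd2(*args_m, k)) / (2 * eps)
                    assert g[i, j] == pytest.approx(num, abs=1e-7)

    def test_value_agrees_with_mmd2(self):
        rng = np.random.default_rng(4)
        X, Y = rng.normal(size=(10, 3)), rng.normal(size=(8, 3))
        v, _, _ = mmd2_with_grad(X, Y)
        assert v == pytest.approx(mmd2(X, Y), abs=1e-12)


class TestAggregation:
    def test_single_representation_reduces_to_mmd2(self):
        rng = np.random.default_rng(5)
        X, Y = rng.normal(size=(8, 4)), rng.normal(size=(9, 4))
        assert mmd_final_domain([X], [Y]) == pytest.approx(mmd2(X, Y), abs=1e-15)

    def test_identical_representations_give_zero(self):
        rng = np.random.default_rng(6)
        reps = [rng.normal(size=(6, w)) for w in (4, 3, 2)]
        assert mmd_final_domain(reps, [r.copy() for r in reps]) < 1e-9

    def test_additivity_over_representations(self):
        rng = np.random.default_rng(7)
        srcs = [rng.normal(size=(8, w)) for w in (5, 4, 3)]
        tgts = [rng.normal(size=(7, w)) + 0.5 for w in (5, 4, 3)]
        total = mmd_final_domain(srcs, tgts)
        parts = sum(mmd2(s, t) for s, t in zip(srcs, tgts))
        assert total == pytest.approx(parts, abs=1e-12)

    def test_representation_count_mismatch(self):
        X = np.random.default_rng(8).normal(size=(6, 3))
        with pytest.raises(RepresentationCountError):
            mmd_final_domain([X, X], [X])

    def test_total_invariants(self):
        rng = np.random.default_rng(9)
        partition = []
        for _ in range(2):
            srcs = [rng.normal(size=(8, w)) for w in (5, 4, 3)]
            tgts = [rng.normal(size=(7, w)) + 0.3 for w in (5, 4, 3)]
            partition.append((srcs, tgts))
        est = mmd_total(partition)
        naive_total = sum(
            mmd2(s, t) for srcs, tgts in partition for s, t in zip(srcs, tgts)
        )
        assert est.total == pytest.approx(naive_total, abs=1e-12)
        for dom_val, reps in zip(est.per_domain, est.per_representation):
            assert dom_val == pytest.approx(sum(reps), abs=1e-12)

    def test_single_domain_total(self):
        rng = np.random.default_rng(10)
        srcs, tgts = [rng.normal(size=(6, 3))], [rng.normal(size=(6, 3))]
        est = mmd_total([(srcs, tgts)])
        assert est.total == est.per_domain[0]

    def test_empty_domain_list_rejected(self):
        with pytest.raises(EmptyInputError):
            mmd_total([])

    def test_mmd_estimate_sums(self):
        est = MMDEstimate(per_representation=[[1.0, 2.0], [0.5, 0.5]])
        assert est.per_domain == [3.0, 1.0]
        assert est.total == 4.0
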