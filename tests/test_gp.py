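"""GP core: kernel algebra, brute-force posterior oracle, interpolation,
hyperparameter recovery, and a library cross-check."""

import numpy as np
import pytest
from scipy import linalg

import neuroemu as ne
from neuroemu.emulators import (
    ConditioningError,
    GaussianProcess,
    KernelHyperparams,
    Prediction,
    TrainSet,
    Z90,
    se_kernel,
    se_kernel_matrix,
)


def test_se_kernel_closed_form_and_symmetry(rng):
    hyper = KernelHyperparams(2.5, np.array([0.7, 1.3, 0.4]))
    for _ in range(50):
        xp, xq = rng.random(3), rng.random(3)
        expected = 2.5 * np.exp(-0.5 * np.sum((xp - xq) ** 2 / np.array([0.7, 1.3, 0.4]) ** 2))
        assert se_kernel(xp, xq, hyper) == pytest.approx(expected, abs=1e-12)
        assert se_kernel(xp, xq, hyper) == se_kernel(xq, xp, hyper)


def test_se_kernel_unit_distance_value():
    hyper = KernelHyperparams(1.0, np.ones(2))
    x = np.zeros(2)
    y = np.array([1.0, 0.0])
    assert se_kernel(x, x, hyper) == pytest.approx(1.0)
    assert se_kernel(x, y, hyper) == pytest.approx(np.exp(-0.5), abs=1e-12)


def test_se_kernel_rejects_bad_lengthscale():
    with pytest.raises(ValueError):
        KernelHyperparams(1.0, np.array([1.0, -0.5]))


def test_posterior_matches_dense_brute_force_oracle(rng):
    """For n <= 10 the fitted GP posterior must agree with a direct dense
    computation from the kernel definition (constant trend profiled by GLS)."""
    n, d = 8, 2
    X = rng.random((n, d))
    y = np.sin(3 * X[:, 0]) + X[:, 1]
    train = TrainSet(X, y)
    model = GaussianProcess(train, nugget=1e-4)
    theta = np.concatenate([[np.log(1.5)], np.log([0.3, 0.5])])
    res = model._results_at(theta)

    # brute force in standardized coordinates
    hyper = res.hyper
    U, z = train.U, train.z
    K = np.array([[se_kernel(U[i], U[j], hyper) for j in range(n)] for i in range(n)])
    K += (hyper.nugget + res.jitter) * np.eye(n)
    Kinv = np.linalg.inv(K)
    ones = np.ones(n)
    beta = (ones @ Kinv @ z) / (ones @ Kinv @ ones)
    r = z - beta * ones
    Xt = rng.random((5, d))
    Ut = train.scale_X(Xt)
    pred = res.predict(Xt)
    for i in range(5):
        k = np.array([se_kernel(Ut[i], U[j], hyper) for j in range(n)])
        m = beta + k @ Kinv @ r
        v = hyper.signal_variance + hyper.nugget - k @ Kinv @ k
        mean_exp = train.y_mean + train.y_sd * m
        sd_exp = train.y_sd * np.sqrt(max(v, 0.0))
        assert pred.mean[i] == pytest.approx(mean_exp, abs=1e-8)
        assert pred.sd[i] == pytest.approx(sd_exp, abs=1e-8)


def test_zero_nugget_interpolates_training_data(rng):
    n, d = 200, 5
    X = rng.random((n, d))
    y = np.sin(2 * np.pi * X[:, 0]) + X[:, 1] ** 2 + 0.5 * X[:, 2] * X[:, 3]
    res = GaussianProcess(TrainSet(X, y), nugget=0.0).fit(seed=0, n_restarts=2)
    pred = res.predict(X)
    assert np.max(np.abs(pred.mean - y)) < 1e-6
    assert np.max(pred.sd) < 1e-3 * np.sqrt(res.hyper.signal_variance)


def test_constant_response_predicts_constant(rng):
    X = rng.random((30, 3))
    y = np.full(30, 4.2)
    res = GaussianProcess(TrainSet(X, y)).fit(seed=0, n_restarts=1, maxiter=30)
    pred = res.predict(rng.random((10, 3)))
    np.testing.assert_allclose(pred.mean, 4.2, atol=1e-6)


def test_conflicting_duplicate_rows_with_zero_nugget_error(rng):
    X = rng.random((12, 2))
    X[1] = X[0]
    y = rng.random(12)
    y[1] = y[0] + 5.0
    with pytest.raises(ConditioningError):
        GaussianProcess(TrainSet(X, y), nugget=0.0).fit(seed=0, n_restarts=1, maxiter=30)


def test_prior_reversion_far_from_data(rng):
    X = rng.random((40, 2))
    y = np.sin(4 * X[:, 0]) + X[:, 1]
    train = TrainSet(X, y)
    res = GaussianProcess(train, nugget=1e-6).fit(seed=0, n_restarts=1, maxiter=60)
    far = np.full((1, 2), 1000.0)
    pred = res.predict(far)
    trend = train.y_mean + train.y_sd * res.beta[0]
    assert pred.mean[0] == pytest.approx(trend, abs=1e-6)
    sf = train.y_sd * np.sqrt(res.hyper.signal_variance + res.hyper.nugget)
    assert pred.sd[0] == pytest.approx(sf, rel=1e-6)


def test_gaussian_quantile_identity(rng):
    X = rng.random((30, 2))
    y = X.sum(axis=1)
    res = GaussianProcess(TrainSet(X, y)).fit(seed=0, n_restarts=1, maxiter=30)
    pred = res.predict(rng.random((20, 2)))
    np.testing.assert_allclose(pred.q95 - pred.q05, 2 * Z90 * pred.sd, rtol=1e-9)
    assert Z90 == pytest.approx(1.6449, abs=1e-4)


def test_lengthscale_recovery_from_known_generator():
    """Data simulated from a GP with known hyperparameters: fitted ARD
    lengthscales within a factor 2 of truth in >= 80% of replicates."""
    true_ls = np.array([0.3, 0.8, 1.5])
    hyper = KernelHyperparams(1.0, true_ls, nugget=1e-6)
    hits = 0
    n_rep = 10
    for rep in range(n_rep):
        rng = np.random.default_rng(1000 + rep)
        X = rng.random((200, 3))
        K = se_kernel_matrix(X, X, hyper) + 1e-8 * np.eye(200)
        y = linalg.cholesky(K, lower=True) @ rng.standard_normal(200)
        res = GaussianProcess(TrainSet(X, y), nugget=1e-6).fit(
            seed=rep, n_restarts=2, maxiter=60
        )
        # TrainSet scales X by its own range (close to the unit cube here)
        ratio = res.hyper.lengthscales / true_ls
        if np.all((ratio > 0.5) & (ratio < 2.0)):
            hits += 1
    assert hits >= 0.8 * n_rep


def test_monotone_information_on_nested_designs(rng):
    """Adding training points never inflates the posterior sd at a fixed site."""
    X = rng.random((60, 2))
    y = np.sin(5 * X[:, 0]) * X[:, 1]
    site = np.array([[0.5, 0.5]])
    full = TrainSet(X, y)
    res_small = GaussianProcess(full.subset(np.arange(30)), nugget=1e-6)._results_at(
        theta=np.log([1.0, 0.4, 0.4]))
    res_big = GaussianProcess(full, nugget=1e-6)._results_at(
        theta=np.log([1.0, 0.4, 0.4]))
    assert res_big.predict(site).sd[0] <= res_small.predict(site).sd[0] + 1e-8


def test_cross_check_against_sklearn_gp(rng):
    """Independent oracle: sklearn GPR with the same kernel and fixed
    hyperparameters reproduces our posterior mean/sd."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel

    n, d = 40, 2
    X = rng.random((n, d))
    y = np.cos(3 * X[:, 0]) + 0.5 * X[:, 1]
    train = TrainSet(X, y)
    ls = np.array([0.4, 0.6])
    sf2, nug = 1.3, 1e-6
    ours = GaussianProcess(train, nugget=nug)._results_at(
        theta=np.concatenate([[np.log(sf2)], np.log(ls)]))

    sk = GaussianProcessRegressor(
        kernel=ConstantKernel(sf2, "fixed") * RBF(ls, "fixed"),
        alpha=nug, optimizer=None, normalize_y=False,
    )
    # sklearn has no trend: remove ours by centering with the GLS constant
    center = train.y_mean + train.y_sd * ours.beta[0]
    sk.fit(train.U, (train.y - center) / train.y_sd)
    Xt = rng.random((15, d))
    m_sk, sd_sk = sk.predict(train.scale_X(Xt), return_std=True)
    pred = ours.predict(Xt)
    np.testing.assert_allclose(pred.mean, center + train.y_sd * m_sk, atol=1e-6)
    np.testing.assert_allclose(
        pred.sd, train.y_sd * np.sqrt(sd_sk**2 + nug), atol=1e-5)


def test_trainset_requires_enough_rows():
    X = np.random.default_rng(0).random((5, 6))
    with pytest.raises(ValueError, match="d \\+ 2"):
        GaussianProcess(TrainSet(X, X.sum(axis=1)))


def test_summary_mentions_key_quantities(rng):
    X = rng.random((30, 2))
    res = GaussianProcess(TrainSet(X, X[:, 0])).fit(seed=0, n_restarts=1, maxiter=20)
    text = res.summary()
    assert "Signal variance" in text and "BIC" in text
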