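"""GPllm selection, local-approximate GP, treed models, baselines and the
benchmark protocol."""

import numpy as np
import pytest

from neuroemu.emulators import (
    GaussianProcess,
    LimitingLinearGP,
    LinearModel,
    LocalApproximateGP,
    NeuralNetEmulator,
    RandomForestEmulator,
    TrainSet,
    TreedEmulator,
    benchmark,
    make_emulator,
)


# ---------------------------------------------------------------- GPllm ----
def test_llm_all_linear_matches_least_squares(rng):
    X = rng.random((80, 3))
    y = 1.0 + 3.0 * X[:, 0] - 2.0 * X[:, 1] + 0.5 * X[:, 2]
    res = LimitingLinearGP(TrainSet(X, y)).fit(seed=0)
    assert all(f == "linear" for f in res.flags)
    ols = LinearModel(TrainSet(X, y)).fit()
    np.testing.assert_allclose(res.inner.beta, ols.beta, atol=1e-6)
    Xt = rng.random((20, 3))
    np.testing.assert_allclose(res.predict(Xt).mean, ols.predict(Xt).mean, atol=1e-6)


def test_llm_separates_nonlinear_from_linear_dims():
    hits = 0
    n_seeds = 6
    for seed in range(n_seeds):
        rng = np.random.default_rng(300 + seed)
        X = rng.random((300, 2))
        y = np.sin(4 * np.pi * X[:, 0]) + 2.0 * X[:, 1]
        res = LimitingLinearGP(TrainSet(X, y)).fit(seed=seed, maxiter=60)
        if res.flags == ("gp", "linear"):
            hits += 1
    assert hits >= n_seeds - 1


def test_llm_constant_response_goes_linear_with_zero_slope(rng):
    X = rng.random((40, 1))
    y = np.full(40, 2.0)
    res = LimitingLinearGP(TrainSet(X, y)).fit(seed=0)
    assert res.flags == ("linear",)
    assert abs(res.inner.beta[1]) < 1e-8


# ----------------------------------------------------------------- laGP ----
def test_lagp_with_m_equal_n_matches_full_gp(rng):
    X = rng.random((40, 2))
    y = np.sin(3 * X[:, 0]) + X[:, 1]
    train = TrainSet(X, y)
    Xt = rng.random((10, 2))
    full = GaussianProcess(train, nugget=1e-6).fit(seed=0, n_restarts=1, maxiter=60)
    local = LocalApproximateGP(train, m=40, nugget=1e-6).fit(
        seed=0, n_restarts=1, maxiter=60)
    np.testing.assert_allclose(local.predict(Xt).mean, full.predict(Xt).mean,
                               atol=5e-2)


def test_lagp_interpolates_at_training_sites(rng):
    X = rng.random((60, 2))
    y = np.cos(4 * X[:, 0]) * X[:, 1]
    res = LocalApproximateGP(TrainSet(X, y), m=20, nugget=0.0).fit(seed=0)
    pred = res.predict(X[:5])
    np.testing.assert_allclose(pred.mean, y[:5], atol=1e-3)


def test_lagp_rejects_too_few_neighbors(rng):
    X = rng.random((50, 10))
    with pytest.raises(ValueError, match="d \\+ 2"):
        LocalApproximateGP(TrainSet(X, X[:, 0]), m=5)


def test_lagp_close_to_full_gp_on_smooth_function(rng):
    n, d = 400, 2
    X = rng.random((n, d))

    def f(X):
        return np.sin(2 * np.pi * X[:, 0]) * np.exp(-X[:, 1])

    train = TrainSet(X, f(X))
    Xt = rng.random((80, d))
    yt = f(Xt)
    full = GaussianProcess(train, nugget=1e-6).fit(seed=0, n_restarts=1, maxiter=50)
    local = LocalApproximateGP(train, m=50, nugget=1e-6).fit(seed=0)
    rmse_full = full.rmse(Xt, yt)
    rmse_local = local.rmse(Xt, yt)
    assert rmse_local <= max(2 * rmse_full, 0.02 * yt.std())


# ---------------------------------------------------------------- treed ----
def test_treed_finds_the_breakpoint(rng):
    X = rng.random((300, 2))
    y = np.where(X[:, 0] > 0.6, 5.0, -5.0) + 0.01 * rng.standard_normal(300)
    res = TreedEmulator(TrainSet(X, y), leaf="linear", max_depth=1).fit(seed=0)
    splits = res.splits
    assert len(splits) == 1
    name, val = splits[0]
    assert name == "x1"
    assert abs(val - 0.6) < 0.05


def test_treed_depth_zero_equals_plain_leaf_model(rng):
    X = rng.random((100, 2))
    y = X[:, 0] ** 2 + X[:, 1]
    train = TrainSet(X, y)
    treed = TreedEmulator(train, leaf="linear", max_depth=0).fit(seed=0)
    plain = LinearModel(train).fit()
    Xt = rng.random((20, 2))
    np.testing.assert_allclose(treed.predict(Xt).mean, plain.predict(Xt).mean,
                               atol=1e-10)


def test_treed_gp_handles_bimodal_response(rng):
    """Two well-separated output regimes indexed by a threshold on x1."""
    n = 400
    X = rng.random((n, 2))
    low = -80.0 + 3.0 * X[:, 1]
    high = -25.0 + 3.0 * X[:, 1]
    y = np.where(X[:, 0] > 0.5, high, low)
    train = TrainSet(X, y)
    res = TreedEmulator(train, leaf="gp", max_depth=2, min_leaf=30).fit(
        seed=0, n_restarts=1, maxiter=30)
    Xt = rng.random((100, 2))
    yt = np.where(Xt[:, 0] > 0.5, -25.0 + 3.0 * Xt[:, 1], -80.0 + 3.0 * Xt[:, 1])
    rmse = res.rmse(Xt, yt)
    assert rmse < 0.25 * y.std()


def test_treed_infeasible_config_rejected(rng):
    X = rng.random((20, 3))
    with pytest.raises(ValueError):
        TreedEmulator(TrainSet(X, X[:, 0]), leaf="gp", min_leaf=50)


# ------------------------------------------------------------- baselines ---
def test_point_predictors_have_no_uncertainty(rng):
    X = rng.random((60, 3))
    y = X.sum(axis=1)
    train = TrainSet(X, y)
    for cls in (RandomForestEmulator, NeuralNetEmulator):
        pred = cls(train).fit(seed=0).predict(X[:5])
        assert not pred.has_uncertainty
        assert np.isnan(pred.q05).all()


# ------------------------------------------------------------- benchmark ---
class _TrainMean:
    """Null model predicting the training mean everywhere."""

    def __init__(self, train, **_):
        self.train = train

    def fit(self, seed=0, **_):
        outer = self

        class R:
            train = outer.train

            def predict(self, X):
                from neuroemu.emulators import Prediction

                return Prediction.point(
                    np.full(np.atleast_2d(X).shape[0], outer.train.y.mean()))

        return R()


def test_benchmark_null_model_rmse_equals_sd_about_train_mean(rng, monkeypatch):
    import importlib

    bench = importlib.import_module("neuroemu.emulators.benchmark")

    X = rng.random((100, 2))
    y = rng.standard_normal(100)
    train = TrainSet(X[:80], y[:80])
    Xt, yt = X[80:], y[80:]

    orig = bench.make_emulator

    def patched(method, train, **kw):
        if method == "null":
            return _TrainMean(train)
        return orig(method, train, **kw)

    monkeypatch.setattr(bench, "make_emulator", patched)
    table = bench.benchmark(["null", "lr"], train, Xt, yt, seed=0)
    row = table.set_index("method").loc["null"]
    expected = np.sqrt(np.mean((yt - y[:80].mean()) ** 2))
    assert row["rmse"] == pytest.approx(expected, rel=1e-12)
    assert row["test_sd"] == pytest.approx(yt.std(), rel=1e-12)


def test_benchmark_oracle_method_is_perfect_and_failures_isolated(rng):
    X = rng.random((80, 2))
    y = 2.0 * X[:, 0] - X[:, 1]  # exactly linear: LR is an oracle
    train = TrainSet(X[:60], y[:60])
    table = benchmark(["lr", "lagp"], train, X[60:], y[60:], seed=0,
                      method_kwargs={"lagp": {"m": 2}})  # m < d+2 -> fails
    t = table.set_index("method")
    assert t.loc["lr", "rmse"] == pytest.approx(0.0, abs=1e-10)
    assert np.isnan(t.loc["lagp", "rmse"])
    assert "ValueError" in t.loc["lagp", "error"]


def test_registry_rejects_unknown_method(rng):
    X = rng.random((30, 2))
    with pytest.raises(ValueError, match="unknown method"):
        make_emulator("krige", TrainSet(X, X[:, 0]))
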