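"""Emulator benchmark: RMSE and wall time on a held-out test set.

Mirrors the method-comparison protocol used for emulating GA generations:
fit each method on the training set, predict a disjoint test set, report
RMSE, the test-response SD as the accuracy yardstick, their ratio, and
fit+predict wall time (hardware-dependent, reported for orientation only).
Failures are recorded as failed rows without aborting the other methods.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd

from .base import TrainSet
from .baselines import NeuralNetEmulator, RandomForestEmulator
from .gp import GaussianProcess
from .lagp import LocalApproximateGP
from .llm import LimitingLinearGP, LinearModel
from .treed import TreedEmulator

__all__ = ["METHODS", "make_emulator", "benchmark"]

#: Registry of benchmarkable emulators, named after the method families of
#: the comparison tables: linear regression, neural net, random forest,
#: local-approximate GP, GP, GPllm, and the treed variants.
METHODS = ("lr", "nn", "rf", "lagp", "gp", "gpllm", "tlm", "tgp", "tgpllm")


def make_emulator(method: str, train: TrainSet, **kwargs):
    method = method.lower()
    if method == "lr":
        return LinearModel(train, **kwargs)
    if method == "nn":
        return NeuralNetEmulator(train, **kwargs)
    if method == "rf":
        return RandomForestEmulator(train, **kwargs)
    if method == "lagp":
        kwargs.setdefault("m", min(50, max(train.d + 2, train.n // 4)))
        return LocalApproximateGP(train, **kwargs)
    if method == "gp":
        return GaussianProcess(train, **kwargs)
    if method == "gpllm":
        return LimitingLinearGP(train, **kwargs)
    if method == "tlm":
        return TreedEmulator(train, leaf="linear", **kwargs)
    if method == "tgp":
        return TreedEmulator(train, leaf="gp", **kwargs)
    if method == "tgpllm":
        return TreedEmulator(train, leaf="gpllm", **kwargs)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def benchmark(
    methods,
    train: TrainSet,
    X_test,
    y_test,
    seed: int = 0,
    sort_by: str = "rmse",
    method_kwargs: dict | None = None,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Fit every method and score it on the test responses.

    Returns a DataFrame with columns ``method, rmse, test_sd, rmse_over_sd,
    seconds, error`` sorted by ``sort_by`` (failed rows last).
    """
    y_test = np.asarray(y_test, dtype=float).ravel()
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    if X_test.shape[0] != y_test.size:
        raise ValueError("test inputs and responses disagree on rows")
    test_sd = float(y_test.std())
    method_kwargs = method_kwargs or {}
    fit_kwargs = fit_kwargs or {}

    rows = []
    for name in methods:
        t0 = time.perf_counter()
        try:
            model = make_emulator(name, train, **method_kwargs.get(name, {}))
            res = model.fit(seed=seed, **fit_kwargs.get(name, {}))
            pred = res.predict(X_test)
            rmse = float(np.sqrt(np.mean((pred.mean - y_test) ** 2)))
            err = ""
        except Exception as exc:  # failed row; others unaffected
            rmse, err = np.nan, f"{type(exc).__name__}: {exc}"
        seconds = time.perf_counter() - t0
        rows.append({
            "method": name,
            "rmse": rmse,
            "test_sd": test_sd,
            "rmse_over_sd": rmse / test_sd if test_sd > 0 else np.nan,
            "seconds": seconds,
            "error": err,
        })
    table = pd.DataFrame(rows)
    return table.sort_values(sort_by, na_position="last").reset_index(drop=True)
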