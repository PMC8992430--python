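"""Shared emulator contract.

Every emulator is a statsmodels-style model: construct it from a
:class:`TrainSet`, call :meth:`fit` to obtain a results object, and call
``results.predict(Xnew)`` for a :class:`Prediction` carrying the posterior
mean, predictive SD and central 90% quantiles. Point-prediction methods
(random forest, neural net) return NaN SDs and quantiles and are excluded
from coverage analysis.

Inputs are scaled to the unit cube via the parameter bounds and responses
standardized to zero mean / unit SD before fitting; predictions are
returned on the original scale.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from ..space import ParameterSpace

__all__ = ["TrainSet", "Prediction", "Emulator", "EmulatorResults", "Z90"]

#: z-score of the 0.95 Gaussian quantile; the central 90% interval is
#: mean +/- Z90 * sd.
Z90 = float(norm.ppf(0.95))


class TrainSet:
    """Scaled training data for emulator fitting.

    Parameters
    ----------
    X, y : array-like
        Raw inputs (n x d) and responses (n,). Rows with missing responses
        must be excluded upstream — structural missingness is handled by the
        two-stage pipeline, never by the emulators.
    space : ParameterSpace, optional
        Supplies scaling bounds. If omitted, per-column data ranges are used
        (degenerate columns get unit width).
    """

    def __init__(self, X, y, space: ParameterSpace | None = None,
                 names=None, _scaler=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree on the number of rows")
        if np.isnan(y).any():
            raise ValueError("training responses contain missing values")
        if not np.all(np.isfinite(X)):
            raise ValueError("training inputs contain non-finite values")
        self.X, self.y = X, y
        if _scaler is not None:
            self.lower, self.upper, self.y_mean, self.y_sd = _scaler
        else:
            if space is not None:
                if space.dim != X.shape[1]:
                    raise ValueError("space dimension does not match X")
                self.lower, self.upper = space.lower.copy(), space.upper.copy()
            else:
                self.lower = X.min(axis=0)
                self.upper = X.max(axis=0)
                flat = self.upper - self.lower <= 0
                self.upper = np.where(flat, self.lower + 1.0, self.upper)
            self.y_mean = float(y.mean())
            sd = float(y.std())
            self.y_sd = sd if sd > 0 else 1.0
        self.names = list(names) if names is not None else (
            list(space.names) if space is not None
            else [f"x{j + 1}" for j in range(X.shape[1])]
        )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def U(self) -> np.ndarray:
        """Inputs on the unit cube."""
        return self.scale_X(self.X)

    @property
    def z(self) -> np.ndarray:
        """Standardized responses."""
        return (self.y - self.y_mean) / self.y_sd

    def scale_X(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.d:
            raise ValueError(f"expected {self.d} input columns, got {X.shape[1]}")
        return (X - self.lower) / (self.upper - self.lower)

    def destandardize(self, z_mean, z_sd=None):
        mean = self.y_mean + self.y_sd * np.asarray(z_mean)
        if z_sd is None:
            return mean
        return mean, self.y_sd * np.asarray(z_sd)

    def subset(self, idx) -> "TrainSet":
        """Row subset sharing this set's scaler state."""
        return TrainSet(
            self.X[idx], self.y[idx], names=self.names,
            _scaler=(self.lower, self.upper, self.y_mean, self.y_sd),
        )


@dataclass
class Prediction:
    """Point predictions with (where available) predictive uncertainty."""

    mean: np.ndarray
    sd: np.ndarray
    q05: np.ndarray
    q95: np.ndarray

    @classmethod
    def gaussian(cls, mean, sd) -> "Prediction":
        mean = np.asarray(mean, dtype=float)
        sd = np.asarray(sd, dtype=float)
        return cls(mean=mean, sd=sd, q05=mean - Z90 * sd, q95=mean + Z90 * sd)

    @classmethod
    def point(cls, mean) -> "Prediction":
        mean = np.asarray(mean, dtype=float)
        nan = np.full_like(mean, np.nan)
        return cls(mean=mean, sd=nan, q05=nan.copy(), q95=nan.copy())

    @property
    def has_uncertainty(self) -> bool:
        return bool(np.all(np.isfinite(self.sd)))


class Emulator:
    """Base model class; subclasses implement ``fit``."""

    def __init__(self, train: TrainSet):
        self.train = train

    @classmethod
    def from_dataframe(cls, frame, target: str, space=None, **kwargs):
        """Build from a DataFrame whose columns are inputs plus ``target``."""
        y = frame[target].to_numpy(dtype=float)
        Xcols = [c for c in frame.columns if c != target]
        keep = ~np.isnan(y)
        train = TrainSet(frame.loc[keep, Xcols].to_numpy(dtype=float), y[keep],
                         space=space, names=Xcols)
        return cls(train, **kwargs)

    def fit(self, seed: int = 0, **kwargs) -> "EmulatorResults":
        raise NotImplementedError


@dataclass
class EmulatorResults:
    """Base results object; subclasses add estimates and diagnostics."""

    model: Emulator = field(repr=False)

    @property
    def train(self) -> TrainSet:
        return self.model.train

    def predict(self, Xnew) -> Prediction:
        raise NotImplementedError

    def rmse(self, X_test, y_test) -> float:
        pred = self.predict(X_test)
        return float(np.sqrt(np.mean((pred.mean - np.asarray(y_test, dtype=float)) ** 2)))

    def _summary_rows(self) -> list[tuple[str, str]]:
        return [("Observations", str(self.train.n)),
                ("Input dim", str(self.train.d))]

    def summary(self) -> str:
        title = type(self).__name__
        rows = self._summary_rows()
        width = max(len(k) for k, _ in rows) + 2
        lines = [title, "=" * max(len(title), 30)]
        lines += [f"{k:<{width}}{v}" for k, v in rows]
        return "\n".join(lines)


def timed(fn):
    """Return (result, wall seconds) of a zero-argument callable."""
    t0 = time.perf_counter()
    out = fn()
    return out, time.perf_counter() - t0
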