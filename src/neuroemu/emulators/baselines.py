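"""Forest and neural-network baseline emulators.

Both delegate to scikit-learn behind the uniform prediction contract and
return point predictions only (NaN predictive SD), so they are excluded
from coverage analysis. Inputs are scaled to the unit cube and responses
standardized, matching the GP-family preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor

from .base import Emulator, EmulatorResults, Prediction, TrainSet

__all__ = ["RandomForestEmulator", "NeuralNetEmulator"]


class RandomForestEmulator(Emulator):
    def __init__(self, train: TrainSet, n_trees: int = 500, mtry: int | None = None):
        super().__init__(train)
        self.n_trees = int(n_trees)
        self.mtry = mtry

    def fit(self, seed: int = 0, **_) -> "SklearnResults":
        est = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=self.mtry if self.mtry is not None else 1.0 / 3.0,
            random_state=seed,
            n_jobs=1,
        )
        est.fit(self.train.U, self.train.z)
        return SklearnResults(model=self, estimator=est)


class NeuralNetEmulator(Emulator):
    """Small fixed-architecture multilayer perceptron (two 64-unit layers)."""

    def __init__(self, train: TrainSet, hidden=(64, 64), max_iter: int = 800):
        super().__init__(train)
        self.hidden = tuple(hidden)
        self.max_iter = int(max_iter)

    def fit(self, seed: int = 0, **_) -> "SklearnResults":
        est = MLPRegressor(
            hidden_layer_sizes=self.hidden,
            max_iter=self.max_iter,
            random_state=seed,
        )
        est.fit(self.train.U, self.train.z)
        return SklearnResults(model=self, estimator=est)


@dataclass
class SklearnResults(EmulatorResults):
    estimator: object = field(default=None, repr=False)

    def predict(self, Xnew) -> Prediction:
        z = self.estimator.predict(self.train.scale_X(Xnew))
        return Prediction.point(self.train.destandardize(z))

    def _summary_rows(self):
        return super()._summary_rows() + [("Estimator", type(self.estimator).__name__)]
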