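"""Local approximate GP: per-site prediction from nearby training points.

For each prediction site a GP is fit on the m nearest training points
(unit-cube Euclidean distance, ties broken by row index) — the simplest
nearest-neighbor variant of local approximate GP prediction. It trades
global accuracy for O(m^3) per-site cost, useful when n is too large for a
dense fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import Emulator, EmulatorResults, Prediction, TrainSet
from .gp import GaussianProcess

__all__ = ["LocalApproximateGP", "LocalApproximateGPResults"]


class LocalApproximateGP(Emulator):
    def __init__(self, train: TrainSet, m: int = 50, nugget="estimate"):
        super().__init__(train)
        if m > train.n:
            raise ValueError("m cannot exceed the number of training rows")
        if m < train.d + 2:
            raise ValueError(f"m must be >= d + 2 (= {train.d + 2}) for local GP fits")
        self.m = int(m)
        self.nugget = nugget

    def fit(self, seed: int = 0, n_restarts: int = 1,
            maxiter: int = 30) -> "LocalApproximateGPResults":
        """Lazy fit: local models are trained at prediction time."""
        return LocalApproximateGPResults(
            model=self, seed=seed, n_restarts=n_restarts, maxiter=maxiter
        )


@dataclass
class LocalApproximateGPResults(EmulatorResults):
    seed: int = 0
    n_restarts: int = 1
    maxiter: int = 30

    def predict(self, Xnew) -> Prediction:
        model: LocalApproximateGP = self.model
        train = self.train
        U = train.U
        Un = train.scale_X(Xnew)
        means = np.empty(Un.shape[0])
        sds = np.empty(Un.shape[0])
        cache: dict[tuple[int, ...], object] = {}
        for i, u in enumerate(Un):
            dist = np.sqrt(((U - u) ** 2).sum(axis=1))
            # stable sort -> ties broken by row index
            neigh = np.argsort(dist, kind="stable")[: model.m]
            key = tuple(np.sort(neigh))
            res = cache.get(key)
            if res is None:
                local = train.subset(np.sort(neigh))
                res = GaussianProcess(local, nugget=model.nugget).fit(
                    seed=self.seed, n_restarts=self.n_restarts, maxiter=self.maxiter
                )
                cache[key] = res
            p = res.predict(np.atleast_2d(Xnew)[i : i + 1])
            means[i], sds[i] = p.mean[0], p.sd[0]
        return Prediction.gaussian(means, sds)

    def _summary_rows(self):
        return super()._summary_rows() + [("Neighbors (m)", str(self.model.m))]
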