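"""Limiting-linear-model GP (GPllm) and the pure linear model.

A linear response in dimension j is the limit of a GP as that dimension's
length scale grows; exploiting this, GPllm makes a data-driven per-dimension
choice between a linear trend term and a kernel dimension. The search here
is a deterministic greedy coordinate pass: starting from the all-GP fit,
each dimension in index order is tentatively moved to the linear trend (its
length scale removed from the kernel, a linear basis term added), the model
refit warm-started from the incumbent hyperparameters, and the move is kept
when it improves the BIC computed from the marginal likelihood with one
parameter per length scale / slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base import Emulator, EmulatorResults, Prediction, TrainSet
from .gp import GaussianProcess, GaussianProcessResults

__all__ = ["LinearModel", "LinearModelResults", "LimitingLinearGP", "LLMResults"]


class LinearModel(Emulator):
    """Ordinary least squares on unit-cube inputs, Gaussian errors.

    Serves both as the LR baseline of the benchmark and as the all-linear
    limit of GPllm; its BIC is comparable with the GP's because both are
    Gaussian log likelihoods of the standardized response.
    """

    def fit(self, seed: int = 0, **_) -> "LinearModelResults":
        train = self.train
        H = np.column_stack([np.ones(train.n), train.U])
        z = train.z
        beta, *_ = np.linalg.lstsq(H, z, rcond=None)
        r = z - H @ beta
        n = train.n
        sigma2 = max(float(r @ r) / n, 1e-12)  # MLE error variance
        llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        HtH_inv = np.linalg.pinv(H.T @ H)
        return LinearModelResults(
            model=self, beta=beta, sigma2=sigma2, llf=float(llf), _HtH_inv=HtH_inv
        )


@dataclass
class LinearModelResults(EmulatorResults):
    beta: np.ndarray = None
    sigma2: float = None
    llf: float = None
    _HtH_inv: np.ndarray = field(default=None, repr=False)

    @property
    def k_params(self) -> int:
        return self.beta.size + 1  # slopes + intercept counted in beta; + sigma2

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.k_params * np.log(self.train.n)

    def predict(self, Xnew) -> Prediction:
        train = self.train
        Un = train.scale_X(Xnew)
        H = np.column_stack([np.ones(Un.shape[0]), Un])
        mean_z = H @ self.beta
        lever = np.einsum("ij,jk,ik->i", H, self._HtH_inv, H)
        sd_z = np.sqrt(self.sigma2 * (1.0 + np.clip(lever, 0.0, None)))
        mean, sd = train.destandardize(mean_z, sd_z)
        return Prediction.gaussian(mean, sd)

    def _summary_rows(self):
        return super()._summary_rows() + [
            ("Residual variance", f"{self.sigma2:.4g}"),
            ("BIC", f"{self.bic:.3f}"),
        ]


class LimitingLinearGP(Emulator):
    """GPllm: greedy BIC selection of linear-vs-GP per input dimension."""

    def __init__(self, train: TrainSet, nugget="estimate"):
        super().__init__(train)
        self.nugget = nugget

    def fit(self, seed: int = 0, n_restarts: int = 2, maxiter: int = 100,
            candidate_maxiter: int = 20) -> "LLMResults":
        train = self.train
        base = GaussianProcess(train, linear_dims=(), nugget=self.nugget)
        current = base.fit(seed=seed, n_restarts=n_restarts, maxiter=maxiter)
        current_bic = current.bic
        linear: list[int] = []

        for j in range(train.d):
            cand_linear = sorted(linear + [j])
            if len(cand_linear) == train.d:
                cand_res = LinearModel(train).fit(seed=seed)
            else:
                # warm start: keep incumbent hyperparameters, drop l_j
                gp_dims_now = [dd for dd in range(train.d) if dd not in linear]
                keep = [i for i, dd in enumerate(gp_dims_now) if dd != j]
                theta_now = current.theta if isinstance(current, GaussianProcessResults) else None
                x0 = None
                if theta_now is not None:
                    k_now = len(gp_dims_now)
                    parts = [theta_now[:1], theta_now[1:1 + k_now][keep]]
                    if self.nugget == "estimate":
                        parts.append(theta_now[1 + k_now:2 + k_now])
                    x0 = np.concatenate(parts)
                cand = GaussianProcess(train, linear_dims=cand_linear, nugget=self.nugget)
                cand_res = cand.fit(seed=seed, n_restarts=1,
                                    maxiter=candidate_maxiter, x0=x0)
            if cand_res.bic < current_bic:
                linear = cand_linear
                current, current_bic = cand_res, cand_res.bic

        flags = tuple("linear" if j in linear else "gp" for j in range(train.d))
        return LLMResults(model=self, inner=current, flags=flags)


@dataclass
class LLMResults(EmulatorResults):
    """Chosen model plus the per-dimension linear/GP indicator."""

    inner: EmulatorResults = None
    flags: tuple[str, ...] = ()

    @property
    def linear_dims(self) -> tuple[int, ...]:
        return tuple(j for j, f in enumerate(self.flags) if f == "linear")

    @property
    def llf(self) -> float:
        return self.inner.llf

    @property
    def bic(self) -> float:
        return self.inner.bic

    def predict(self, Xnew) -> Prediction:
        return self.inner.predict(Xnew)

    def _summary_rows(self):
        rows = super()._summary_rows()
        lin = [self.train.names[j] for j in self.linear_dims]
        rows.append(("Linear dims", ", ".join(lin) if lin else "(none)"))
        rows.append(("BIC", f"{self.bic:.3f}"))
        return rows
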