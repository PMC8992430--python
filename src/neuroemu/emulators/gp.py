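"""Gaussian-process regression emulator.

The response is modelled as a trend plus a zero-mean Gaussian process,

    f(x) = sum_i beta_i g_i(x) + Z(x),

with a constant trend by default (g_0 = 1) and optional linear trend terms
g_j(x) = x_j for dimensions whose kernel length scale has been replaced by
a linear relationship (the limiting-linear-model construction). Z has the
ARD squared-exponential covariance of :mod:`.kernels` over the remaining
dimensions, plus an optional nugget.

Hyperparameters maximize the log marginal likelihood with the trend
coefficients profiled out by generalized least squares (empirical-Bayes
conditioning); optimization is multi-start L-BFGS-B in log-hyperparameter
space with analytic gradients. With a zero nugget the fitted model
interpolates its training data. Predictive variance is the plug-in
(simple-kriging) form, so far from all training data the predictive SD
reverts to sqrt(signal variance + nugget).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .base import Emulator, EmulatorResults, Prediction, TrainSet
from .kernels import KernelHyperparams, se_kernel_matrix, sq_diffs

__all__ = ["GaussianProcess", "GaussianProcessResults", "ConditioningError"]

JITTER_LADDER = (1e-12, 1e-10, 1e-8, 1e-6)
# Hyperparameter box (log space, unit-cube inputs / standardized response).
# Length scales are capped at 50: on a unit cube a larger scale is
# statistically indistinguishable from a linear trend (that regime belongs
# to the limiting linear model) and pushes the kernel matrix into numerical
# singularity, destroying the interpolation property.
_LOG_SF2_BOUNDS = (np.log(1e-4), np.log(1e2))
_LOG_LS_BOUNDS = (np.log(1e-3), np.log(50.0))
_LOG_NUG_BOUNDS = (np.log(1e-8), np.log(1.0))


class ConditioningError(RuntimeError):
    """Kernel matrix not positive definite after jitter escalation."""


def _chol_with_jitter(K: np.ndarray, base: float = 0.0):
    """Cholesky of K, escalating additive jitter on failure.

    ``base`` is the diagonal noise already present in K (the nugget); it is
    reported only, never added again.
    """
    n = K.shape[0]
    eye = np.eye(n)
    for jitter in (0.0,) + JITTER_LADDER:
        try:
            L = linalg.cholesky(K if jitter == 0.0 else K + jitter * eye, lower=True)
            return L, jitter
        except linalg.LinAlgError:
            continue
    raise ConditioningError(
        "training covariance not positive definite after jitter escalation; "
        "check for duplicated inputs with a zero nugget"
    )


class GaussianProcess(Emulator):
    """GP regression model on a :class:`TrainSet`.

    Parameters
    ----------
    train : TrainSet
    linear_dims : sequence of int
        Dimensions acting through a linear trend term instead of the kernel.
    nugget : "estimate" | float
        Estimate the nugget by maximum likelihood (default; guards
        conditioning even for deterministic simulators) or fix it.
    """

    def __init__(self, train: TrainSet, linear_dims=(), nugget="estimate"):
        super().__init__(train)
        self.linear_dims = tuple(sorted(int(j) for j in linear_dims))
        if any(j < 0 or j >= train.d for j in self.linear_dims):
            raise ValueError("linear_dims out of range")
        self.gp_dims = tuple(j for j in range(train.d) if j not in self.linear_dims)
        if not self.gp_dims:
            raise ValueError(
                "all dimensions linear; use LimitingLinearGP / a linear model"
            )
        if nugget != "estimate" and float(nugget) < 0:
            raise ValueError("nugget must be nonnegative")
        self.nugget = nugget
        if train.n < train.d + 2:
            raise ValueError(f"GP fit needs n >= d + 2 (= {train.d + 2}) rows")
        if nugget != "estimate" and float(nugget) == 0.0:
            # a zero nugget demands an interpolable response surface
            Ug = train.U[:, self.gp_dims]
            order = np.lexsort(Ug.T)
            same = np.all(np.diff(Ug[order], axis=0) == 0.0, axis=1)
            conflict = same & (np.diff(train.z[order]) != 0.0)
            if conflict.any():
                raise ConditioningError(
                    "duplicated training inputs with conflicting responses "
                    "cannot be interpolated with a zero nugget"
                )

    # -- design pieces -----------------------------------------------------
    def _basis(self, U: np.ndarray) -> np.ndarray:
        cols = [np.ones(U.shape[0])]
        cols += [U[:, j] for j in self.linear_dims]
        return np.column_stack(cols)

    def _unpack(self, theta: np.ndarray):
        k = len(self.gp_dims)
        sf2 = np.exp(theta[0])
        ls = np.exp(theta[1 : 1 + k])
        nug = np.exp(theta[1 + k]) if self.nugget == "estimate" else float(self.nugget)
        return sf2, ls, nug

    def _nll_grad(self, theta, D2, H, z):
        n = z.size
        sf2, ls, nug = self._unpack(theta)
        expo = np.tensordot(D2, 0.5 / ls**2, axes=([2], [0]))
        Ks = sf2 * np.exp(-expo)
        K = Ks + nug * np.eye(n)
        try:
            L, jitter = _chol_with_jitter(K, base=nug)
        except ConditioningError:
            return np.inf, np.zeros_like(theta)

        A = linalg.cho_solve((L, True), H)
        G = H.T @ A
        beta = linalg.solve(G, A.T @ z, assume_a="pos")
        r = z - H @ beta
        alpha = linalg.cho_solve((L, True), r)
        ll = -0.5 * r @ alpha - np.log(np.diag(L)).sum() - 0.5 * n * np.log(2 * np.pi)

        Kinv = linalg.cho_solve((L, True), np.eye(n))
        M = np.outer(alpha, alpha) - Kinv
        E = M * Ks
        grad = np.empty_like(theta)
        grad[0] = 0.5 * E.sum()  # d/d log sf2
        k = len(self.gp_dims)
        # d/d log l_j : K_se odot D2_j / l_j^2
        gl = 0.5 * np.tensordot(E, D2, axes=([0, 1], [0, 1]))
        grad[1 : 1 + k] = gl / ls**2
        if self.nugget == "estimate":
            grad[1 + k] = 0.5 * nug * np.trace(M)
        return -ll, -grad

    def _starts(self, seed: int, n_restarts: int, x0=None):
        k = len(self.gp_dims)
        # data-adaptive initial length scales (median-heuristic style): the
        # per-dimension spread of the training inputs times sqrt(k). For
        # box-filling designs this is O(1); for concentrated GA populations
        # it shrinks with the data so the first likelihood evaluations are
        # not stuck in the flat-kernel regime.
        spread = self.train.U[:, self.gp_dims].std(axis=0)
        l0 = np.clip(spread * max(1.0, np.sqrt(k)) * 1.7,
                     np.exp(_LOG_LS_BOUNDS[0]), np.exp(_LOG_LS_BOUNDS[1]))
        l0 = np.where(l0 > 0, l0, 1.0)
        starts = []
        base = np.concatenate([[0.0], np.log(l0)])
        if self.nugget == "estimate":
            base = np.append(base, np.log(1e-4))
        if x0 is not None:
            starts.append(np.asarray(x0, dtype=float))
        starts.append(base)
        rng = np.random.default_rng(seed)
        while len(starts) < max(1, n_restarts):
            t = base.copy()
            t[0] = rng.uniform(np.log(0.1), np.log(10.0))
            t[1 : 1 + k] = np.log(l0) + rng.uniform(np.log(0.2), np.log(5.0), size=k)
            if self.nugget == "estimate":
                t[1 + k] = rng.uniform(np.log(1e-7), np.log(1e-2))
            starts.append(t)
        return starts[: max(1, n_restarts) + (1 if x0 is not None else 0)]

    def fit(self, seed: int = 0, n_restarts: int = 3, maxiter: int = 100,
            x0=None) -> "GaussianProcessResults":
        """Maximize the concentrated log marginal likelihood.

        ``x0`` optionally warm-starts the optimizer with a log-hyperparameter
        vector (used by the greedy limiting-linear-model search).
        """
        train = self.train
        U, z = train.U, train.z
        Ug = U[:, self.gp_dims]
        D2 = sq_diffs(Ug, Ug)
        H = self._basis(U)

        k = len(self.gp_dims)
        bounds = [_LOG_SF2_BOUNDS] + [_LOG_LS_BOUNDS] * k
        if self.nugget == "estimate":
            bounds.append(_LOG_NUG_BOUNDS)

        best = None
        for start in self._starts(seed, n_restarts, x0=x0):
            res = optimize.minimize(
                self._nll_grad, start, args=(D2, H, z), jac=True,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ConditioningError("hyperparameter optimization failed")
        return self._results_at(best.x, D2, H, z)

    def _results_at(self, theta, D2=None, H=None, z=None) -> "GaussianProcessResults":
        train = self.train
        U = train.U
        if D2 is None:
            Ug = U[:, self.gp_dims]
            D2 = sq_diffs(Ug, Ug)
        if H is None:
            H = self._basis(U)
        if z is None:
            z = train.z
        sf2, ls, nug = self._unpack(np.asarray(theta, dtype=float))
        hyper = KernelHyperparams(sf2, ls, nugget=nug)
        Ks = se_kernel_matrix(None, None, hyper, D2=D2)
        K = Ks + nug * np.eye(train.n)
        L, jitter = _chol_with_jitter(K, base=nug)
        A = linalg.cho_solve((L, True), H)
        G = H.T @ A
        beta = linalg.solve(G, A.T @ z, assume_a="pos")
        r = z - H @ beta
        alpha = linalg.cho_solve((L, True), r)
        # one iterative-refinement step: tightens interpolation when K is
        # ill-conditioned (smooth kernels, tiny or zero nugget)
        Keff = K if jitter == 0.0 else K + jitter * np.eye(train.n)
        alpha += linalg.cho_solve((L, True), r - Keff @ alpha)
        llf = float(
            -0.5 * r @ alpha - np.log(np.diag(L)).sum()
            - 0.5 * train.n * np.log(2 * np.pi)
        )
        return GaussianProcessResults(
            model=self, hyper=hyper, beta=beta, llf=llf,
            theta=np.asarray(theta, dtype=float), jitter=jitter,
            _L=L, _alpha=alpha,
        )


@dataclass
class GaussianProcessResults(EmulatorResults):
    """Fitted GP: hyperparameters, trend coefficients and prediction."""

    hyper: KernelHyperparams = None
    beta: np.ndarray = None
    llf: float = None
    theta: np.ndarray = None
    jitter: float = 0.0
    _L: np.ndarray = field(default=None, repr=False)
    _alpha: np.ndarray = field(default=None, repr=False)

    @property
    def k_params(self) -> int:
        """Parameter count for information criteria: signal variance, one
        length scale per kernel dimension, the (possibly estimated) nugget,
        and the trend coefficients."""
        extra = 1 if self.model.nugget == "estimate" else 0
        return 1 + self.hyper.dim + extra + self.beta.size

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.k_params * np.log(self.train.n)

    def predict(self, Xnew) -> Prediction:
        train = self.train
        Un = train.scale_X(Xnew)
        Ug_new = Un[:, self.model.gp_dims]
        Ug = train.U[:, self.model.gp_dims]
        Kx = se_kernel_matrix(Ug_new, Ug, self.hyper)
        Hn = self.model._basis(Un)
        mean_z = Hn @ self.beta + Kx @ self._alpha
        V = linalg.cho_solve((self._L, True), Kx.T)
        var_z = self.hyper.signal_variance + self.hyper.nugget - np.einsum(
            "ij,ji->i", Kx, V
        )
        var_z = np.clip(var_z, 0.0, None)
        mean, sd = train.destandardize(mean_z, np.sqrt(var_z))
        return Prediction.gaussian(mean, sd)

    def lengthscale_table(self) -> list[tuple[str, float]]:
        names = [self.train.names[j] for j in self.model.gp_dims]
        return list(zip(names, self.hyper.lengthscales))

    def _summary_rows(self):
        rows = super()._summary_rows()
        rows += [
            ("Log marginal lik.", f"{self.llf:.3f}"),
            ("BIC", f"{self.bic:.3f}"),
            ("Signal variance", f"{self.hyper.signal_variance:.4g}"),
            ("Nugget", f"{self.hyper.nugget:.3g}"),
            ("Trend coefficients", np.array2string(self.beta, precision=4)),
        ]
        ls = sorted(self.lengthscale_table(), key=lambda t: t[1])
        rows += [(f"lengthscale[{n}]", f"{v:.4g}") for n, v in ls[:8]]
        if len(ls) > 8:
            rows.append(("...", f"{len(ls) - 8} more"))
        return rows
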