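"""Squared-exponential (ARD) covariance.

k(x_p, x_q) = sigma_f^2 * exp(-1/2 * sum_j (x_pj - x_qj)^2 / l_j^2)

with one length scale per input dimension, evaluated on unit-cube
coordinates. ``sigma_f^2`` is the signal variance; a large fitted length
scale marks a dimension as nearly irrelevant (or linear) over the box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KernelHyperparams", "se_kernel", "se_kernel_matrix", "sq_diffs"]


@dataclass
class KernelHyperparams:
    """Signal variance, per-dimension length scales and nugget."""

    signal_variance: float
    lengthscales: np.ndarray
    nugget: float = 0.0

    def __post_init__(self):
        self.lengthscales = np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        if self.signal_variance <= 0:
            raise ValueError("signal variance must be positive")
        if np.any(self.lengthscales <= 0):
            raise ValueError("length scales must be positive")
        if self.nugget < 0:
            raise ValueError("nugget must be nonnegative")

    @property
    def dim(self) -> int:
        return self.lengthscales.size


def se_kernel(xp, xq, hyper: KernelHyperparams) -> float:
    """Covariance between two input vectors."""
    xp = np.asarray(xp, dtype=float).ravel()
    xq = np.asarray(xq, dtype=float).ravel()
    if xp.size != hyper.dim or xq.size != hyper.dim:
        raise ValueError("input dimension does not match the length scales")
    sq = ((xp - xq) / hyper.lengthscales) ** 2
    return float(hyper.signal_variance * np.exp(-0.5 * sq.sum()))


def sq_diffs(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Per-dimension squared differences, shape (len(A), len(B), d)."""
    return (A[:, None, :] - B[None, :, :]) ** 2


def se_kernel_matrix(A: np.ndarray, B: np.ndarray, hyper: KernelHyperparams,
                     D2: np.ndarray | None = None) -> np.ndarray:
    """Cross-covariance matrix between row sets A and B."""
    if D2 is None:
        D2 = sq_diffs(np.atleast_2d(A), np.atleast_2d(B))
    expo = np.tensordot(D2, 0.5 / hyper.lengthscales**2, axes=([2], [0]))
    return hyper.signal_variance * np.exp(-expo)
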