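"""Emulator-based inference: interval coverage and Sobol sensitivity.

*Coverage* checks the calibration of the GP-family predictive distribution:
the fraction of held-out responses falling inside the central 90% interval
[q05, q95] should match the nominal level when the model is well
calibrated. Point-prediction emulators (forest, neural net) carry no
quantiles and are rejected explicitly.

*Sensitivity* uses Saltelli paired sampling with the Jansen-form estimators
of the first-order index S_j (share of output variance explained by input j
alone) and the total index T_j (share involving j in any interaction),
applied to emulator posterior means. Two standard-normal noise factors can
be appended to the inputs as negative controls: by design they cannot
affect the output, so their estimated indices show the noise floor of the
procedure.

*Main effects* fix one input on a grid and average predictions over
Monte-Carlo draws of the remaining inputs (box-uniform by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emulators import Prediction
from .space import ParameterSpace

__all__ = [
    "CoverageReport",
    "SensitivityResult",
    "coverage",
    "add_noise_controls",
    "sobol_indices",
    "main_effects",
]


class UnsupportedEmulatorError(TypeError):
    """Raised when a point-prediction emulator is used where predictive
    quantiles are required."""


@dataclass(frozen=True)
class CoverageReport:
    """Empirical coverage of the central predictive interval."""

    nominal: float
    coverage: float
    n: int
    mean_width: float
    sd_width: float
    mean_width_sd_units: float

    def as_dict(self) -> dict:
        return {
            "nominal": self.nominal,
            "coverage": self.coverage,
            "n": self.n,
            "mean_width": self.mean_width,
            "sd_width": self.sd_width,
            "mean_width_sd_units": self.mean_width_sd_units,
        }

    def __str__(self) -> str:
        return (
            f"coverage {100 * self.coverage:.1f}% (nominal {100 * self.nominal:.0f}%), "
            f"n={self.n}, mean width {self.mean_width:.3g} "
            f"({self.mean_width_sd_units:.2f} test SDs)"
        )


def coverage(pred: Prediction, y_true, nominal: float = 0.90) -> CoverageReport:
    """Fraction of ``y_true`` inside the closed interval [q05, q95]."""
    y = np.asarray(y_true, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty test set")
    if y.size != pred.mean.size:
        raise ValueError("predictions and y_true disagree on rows")
    if not pred.has_uncertainty or np.isnan(pred.q05).any():
        raise UnsupportedEmulatorError(
            "coverage requires predictive quantiles; this emulator provides "
            "point predictions only"
        )
    inside = (y >= pred.q05) & (y <= pred.q95)
    widths = pred.q95 - pred.q05
    y_sd = float(y.std())
    return CoverageReport(
        nominal=nominal,
        coverage=float(inside.mean()),
        n=int(y.size),
        mean_width=float(widths.mean()),
        sd_width=float(widths.std()),
        mean_width_sd_units=float(widths.mean() / y_sd) if y_sd > 0 else np.nan,
    )


def add_noise_controls(X, rng: np.random.Generator, k: int = 2):
    """Append ``k`` independent standard-normal columns to ``X``.

    Returns (augmented matrix, control column names). Original columns are
    untouched.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    controls = rng.standard_normal((X.shape[0], k))
    names = [f"noise_{i + 1}" for i in range(k)]
    return np.hstack([X, controls]), names


@dataclass
class SensitivityResult:
    """First-order and total Sobol indices per input.

    ``table`` columns: S (clipped at 0), T (clipped at 0), S_raw, T_raw.
    """

    table: pd.DataFrame
    n_base: int
    seed: int | None = None
    total_variance: float = np.nan

    @property
    def S(self) -> pd.Series:
        return self.table["S"]

    @property
    def T(self) -> pd.Series:
        return self.table["T"]

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.table.sort_values("T", ascending=False).head(k)

    def plot(self, ax=None):
        """Side-by-side bar chart of first-order and total indices."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(max(6, 0.3 * len(self.table)), 4))
        idx = np.arange(len(self.table))
        ax.bar(idx - 0.2, self.table["S"], width=0.4, label="first-order $S_j$")
        ax.bar(idx + 0.2, self.table["T"], width=0.4, label="total $T_j$")
        ax.set_xticks(idx)
        ax.set_xticklabels(self.table.index, rotation=90, fontsize=7)
        ax.set_ylabel("Sobol index")
        ax.legend()
        return ax


def _predict_mean(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict"):
        out = model.predict(X)
        if isinstance(out, Prediction):
            return np.asarray(out.mean, dtype=float)
        return np.asarray(out, dtype=float).ravel()
    return np.asarray(model(X), dtype=float).ravel()


def _sample_inputs(space: ParameterSpace, n: int, rng: np.random.Generator) -> np.ndarray:
    """Box-uniform draws for box dimensions, standard normal for dimensions
    named ``noise_*`` (the appended controls)."""
    X = space.sample(n, rng)
    for j, name in enumerate(space.names):
        if name.startswith("noise_"):
            X[:, j] = rng.standard_normal(n)
    return X


def sobol_indices(
    model,
    space: ParameterSpace,
    n_base: int = 1024,
    rng: np.random.Generator | int | None = None,
    seed: int | None = None,
) -> SensitivityResult:
    """Monte-Carlo Sobol indices of the emulator mean over the input box.

    Saltelli pairing: two base matrices A, B of ``n_base`` rows each and one
    hybrid matrix AB_j per input (A with column j taken from B); Jansen
    estimators

        S_j = 1 - mean[(f(B) - f(AB_j))^2] / (2 V),
        T_j =     mean[(f(A) - f(AB_j))^2] / (2 V).

    ``model`` may be any fitted results object or a plain callable.
    """
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)
    elif isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    if n_base < 256:
        raise ValueError("n_base must be >= 256 for usable Monte-Carlo error")
    d = space.dim
    A = _sample_inputs(space, n_base, rng)
    B = _sample_inputs(space, n_base, rng)
    blocks = [A, B]
    for j in range(d):
        ABj = A.copy()
        ABj[:, j] = B[:, j]
        blocks.append(ABj)
    f = _predict_mean(model, np.vstack(blocks))
    if not np.all(np.isfinite(f)):
        raise RuntimeError("emulator returned non-finite predictions on the sample")
    fA, fB = f[:n_base], f[n_base : 2 * n_base]
    V = float(np.concatenate([fA, fB]).var())
    S_raw = np.empty(d)
    T_raw = np.empty(d)
    for j in range(d):
        fABj = f[(2 + j) * n_base : (3 + j) * n_base]
        S_raw[j] = 1.0 - np.mean((fB - fABj) ** 2) / (2.0 * V) if V > 0 else 0.0
        T_raw[j] = np.mean((fA - fABj) ** 2) / (2.0 * V) if V > 0 else 0.0
    table = pd.DataFrame(
        {
            "S": np.clip(S_raw, 0.0, None),
            "T": np.clip(T_raw, 0.0, None),
            "S_raw": S_raw,
            "T_raw": T_raw,
        },
        index=list(space.names),
    )
    return SensitivityResult(table=table, n_base=n_base, seed=seed, total_variance=V)


def main_effects(
    model,
    space: ParameterSpace,
    parameter: str,
    grid_size: int = 25,
    n_mc: int = 200,
    rng: np.random.Generator | int | None = None,
    grid=None,
) -> pd.DataFrame:
    """Averaged-prediction curve for one parameter.

    For each grid value of ``parameter``, the remaining inputs are drawn
    ``n_mc`` times from the box (noise controls standard-normal) and the
    emulator mean prediction is averaged. Returns columns ``value, effect``.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(0 if rng is None else int(rng))
    j = space.index(parameter)
    if grid is None:
        grid = np.linspace(space.lower[j], space.upper[j], grid_size)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.min() < space.lower[j] or grid.max() > space.upper[j]:
            raise ValueError(f"grid outside the bounds of {parameter!r}")
    base = _sample_inputs(space, n_mc, rng)
    effects = []
    for v in grid:
        X = base.copy()
        X[:, j] = v
        effects.append(float(_predict_mean(model, X).mean()))
    return pd.DataFrame({"value": grid, "effect": effects})
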