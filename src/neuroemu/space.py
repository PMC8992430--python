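"""Named, bounded parameter spaces.

A :class:`ParameterSpace` is the shared coordinate frame for the simulator,
the emulators (which scale inputs to the unit cube) and the genetic
algorithm (which clips offspring to the bounds). Each parameter carries a
region tag; parameters tagged ``inert`` are guaranteed to have no effect on
the simulator output and double as built-in negative controls for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ParameterSpace", "default_parameter_space", "MECHANISTIC_PARAMS"]

#: name -> (lower, upper, region) for the mechanistic dimensions of the
#: adaptive-exponential stand-in neuron. Units: ms / mV / nA throughout;
#: capacitance in nF, conductances in uS (so nA / uS = mV).
MECHANISTIC_PARAMS: dict[str, tuple[float, float, str]] = {
    "cm": (0.05, 0.5, "somatic"),          # membrane capacitance (nF)
    "g_leak": (0.003, 0.03, "somatic"),    # leak conductance (uS)
    "e_leak": (-90.0, -60.0, "somatic"),   # leak reversal (mV)
    "v_thresh": (-60.0, -40.0, "axonal"),  # exponential spike threshold (mV)
    "delta_t": (0.5, 5.0, "axonal"),       # spike slope factor (mV)
    "a_adapt": (0.0, 0.01, "somatic"),     # subthreshold adaptation coupling (uS)
    "b_adapt": (0.0, 0.2, "somatic"),      # spike-triggered adaptation (nA)
    "tau_w": (20.0, 500.0, "somatic"),     # adaptation time constant (ms)
    "v_reset": (-70.0, -45.0, "axonal"),   # post-spike reset (mV)
    "v_peak": (10.0, 30.0, "axonal"),      # spike cutoff voltage (mV)
    "t_ref": (0.0, 5.0, "axonal"),         # absolute refractory period (ms)
    "gain": (0.5, 2.0, "basal"),           # input current gain (dimensionless)
}

_REGIONS = ("somatic", "basal", "axonal", "inert")


@dataclass(frozen=True)
class ParameterSpace:
    """Named bounded inputs with per-parameter region tags."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    region: tuple[str, ...] = field(default=())

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if not self.region:
            object.__setattr__(self, "region", ("somatic",) * len(self.names))
        else:
            object.__setattr__(self, "region", tuple(self.region))
        if len(set(self.names)) != len(self.names):
            raise ValueError("parameter names must be unique")
        if not (lower.shape == upper.shape == (len(self.names),)):
            raise ValueError("bounds must match the number of names")
        if not np.all(lower < upper):
            bad = [n for n, lo, up in zip(self.names, lower, upper) if lo >= up]
            raise ValueError(f"lower >= upper for parameter(s) {bad}")
        for r in self.region:
            if r not in _REGIONS:
                raise ValueError(f"unknown region tag {r!r}")

    @property
    def dim(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def inert_names(self) -> tuple[str, ...]:
        return tuple(n for n, r in zip(self.names, self.region) if r == "inert")

    def validate(self, params: np.ndarray) -> np.ndarray:
        """Check a vector or matrix against the bounds; return as 2-d float array."""
        arr = np.atleast_2d(np.asarray(params, dtype=float))
        if arr.shape[1] != self.dim:
            raise ValueError(
                f"expected {self.dim} parameters, got {arr.shape[1]}"
            )
        low = arr < self.lower
        high = arr > self.upper
        if low.any() or high.any():
            j = int(np.argmax((low | high).any(axis=0)))
            raise ValueError(
                f"parameter {self.names[j]!r} out of bounds "
                f"[{self.lower[j]}, {self.upper[j]}]"
            )
        return arr

    def to_unit(self, X: np.ndarray) -> np.ndarray:
        """Affine map of raw coordinates onto the unit cube."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.lower) / (self.upper - self.lower)

    def from_unit(self, U: np.ndarray) -> np.ndarray:
        U = np.atleast_2d(np.asarray(U, dtype=float))
        return self.lower + U * (self.upper - self.lower)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform sample of ``n`` parameter vectors within the box."""
        return self.from_unit(rng.random((n, self.dim)))

    def clip(self, X: np.ndarray) -> np.ndarray:
        return np.clip(X, self.lower, self.upper)

    def as_frame(self, X: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(np.atleast_2d(X), columns=list(self.names))

    def subspace(self, names) -> "ParameterSpace":
        idx = [self.index(n) for n in names]
        return ParameterSpace(
            names=tuple(names),
            lower=self.lower[idx],
            upper=self.upper[idx],
            region=tuple(self.region[i] for i in idx),
        )

    def with_noise_controls(self, k: int = 2, half_width: float = 5.0) -> "ParameterSpace":
        """Append ``k`` standard-normal noise-control dimensions (tagged inert)."""
        names = self.names + tuple(f"noise_{i + 1}" for i in range(k))
        lower = np.concatenate([self.lower, np.full(k, -half_width)])
        upper = np.concatenate([self.upper, np.full(k, half_width)])
        region = self.region + ("inert",) * k
        return ParameterSpace(names, lower, upper, region)


def default_parameter_space(d: int = 31) -> ParameterSpace:
    """The default stand-in space: 12 mechanistic dimensions plus d-12 inert ones.

    ``d`` defaults to 31 so a population has the same input dimension as a
    realistic compartmental-model optimization; the surplus dimensions are
    inert by construction.
    """
    n_mech = len(MECHANISTIC_PARAMS)
    if d < n_mech:
        raise ValueError(f"d must be >= {n_mech}")
    names = list(MECHANISTIC_PARAMS)
    lower = [MECHANISTIC_PARAMS[n][0] for n in names]
    upper = [MECHANISTIC_PARAMS[n][1] for n in names]
    region = [MECHANISTIC_PARAMS[n][2] for n in names]
    for i in range(d - n_mech):
        names.append(f"inert_{i + 1:02d}")
        lower.append(0.0)
        upper.append(1.0)
        region.append("inert")
    return ParameterSpace(tuple(names), np.array(lower), np.array(upper), tuple(region))
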