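"""Synthetic GA-like populations and self-consistent target statistics.

This module produces the study conditions for everything downstream: random
generation-1 style populations over the 31-dimensional default box, their
feature tables (with structural missingness and bi-modal spiking features),
and experimental-style target statistics built from a known reference
parameter vector so the optimum of the global score is known by
construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import rng_for
from .features import FeatureConfig, FeatureTable, batch_evaluate
from .scoring import TargetStats
from .simulator import DEFAULT_PROTOCOLS
from .space import ParameterSpace, default_parameter_space

__all__ = [
    "make_population",
    "make_dataset",
    "reference_params",
    "make_targets",
    "DEFAULT_SCORED_FEATURES",
]

#: Feature subset used by default for global-score optimization: three smooth
#: subthreshold voltages plus three spiking features from the suprathreshold
#: protocol (the latter are missing for non-spiking individuals, so the
#: missing-feature penalty shapes the search).
DEFAULT_SCORED_FEATURES: tuple[str, ...] = (
    "IVf_3.steady_state_voltage_stimend",
    "IVf_3.voltage_base",
    "IVf_3.voltage_after_stimulation",
    "IDRest_7.spikecount",
    "IDRest_7.mean_ISI",
    "IDRest_7.AP_amplitude",
)


def make_population(
    n: int, d: int = 31, seed: int = 0, space: ParameterSpace | None = None
) -> tuple[pd.DataFrame, ParameterSpace]:
    """Uniform random population of ``n`` individuals over the parameter box."""
    space = space or default_parameter_space(d)
    rng = rng_for(seed, "population")
    X = space.sample(n, rng)
    return space.as_frame(X), space


def make_dataset(
    n: int,
    d: int = 31,
    seed: int = 0,
    protocols=None,
    dt: float = 0.1,
    space: ParameterSpace | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> tuple[pd.DataFrame, FeatureTable, ParameterSpace]:
    """A population plus its simulated feature table."""
    params, space = make_population(n, d=d, seed=seed, space=space)
    protocols = DEFAULT_PROTOCOLS if protocols is None else protocols
    table = batch_evaluate(params.to_numpy(), protocols, dt=dt, space=space, config=config)
    return params, table, space


def reference_params(space: ParameterSpace | None = None) -> np.ndarray:
    """A fixed in-bounds reference individual that is subthreshold under the
    weak protocol and fires a regular train under the strong one."""
    space = space or default_parameter_space()
    ref = {
        "cm": 0.15,
        "g_leak": 0.01,
        "e_leak": -70.0,
        "v_thresh": -52.0,
        "delta_t": 2.0,
        "a_adapt": 0.002,
        "b_adapt": 0.03,
        "tau_w": 150.0,
        "v_reset": -58.0,
        "v_peak": 20.0,
        "t_ref": 2.0,
        "gain": 1.0,
    }
    x = (space.lower + space.upper) / 2.0
    for name, val in ref.items():
        x[space.index(name)] = val
    return x


def make_targets(
    space: ParameterSpace | None = None,
    features=DEFAULT_SCORED_FEATURES,
    rel_sd: float = 0.1,
    sd_floor: float = 0.5,
    protocols=None,
    dt: float = 0.1,
) -> tuple[TargetStats, np.ndarray]:
    """Targets whose means are the reference individual's simulated features.

    SDs mimic experimental variability as ``max(rel_sd * |mean|, sd_floor)``.
    By construction the reference individual scores exactly 0.
    """
    space = space or default_parameter_space()
    ref = reference_params(space)
    protocols = DEFAULT_PROTOCOLS if protocols is None else protocols
    table = batch_evaluate(ref, protocols, dt=dt, space=space)
    row = table.data.iloc[0]
    missing = [f for f in features if pd.isna(row.get(f, np.nan))]
    if missing:
        raise ValueError(f"reference individual does not define feature(s) {missing}")
    mean = row[list(features)].astype(float)
    sd = np.maximum(rel_sd * mean.abs(), sd_floor)
    stats = TargetStats(pd.DataFrame({"mean": mean, "sd": sd}))
    return stats, ref
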