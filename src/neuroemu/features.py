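"""Electrophysiology feature extraction with structural missingness.

Features are extracted per trace and per protocol. A feature is *missing*
when the event that defines it never occurred in the simulation — e.g. the
minimal voltage between spikes is undefined when fewer than two spikes were
fired. Missingness is structural, never imputed; downstream code sees it as
an explicit mask (NaN in tables, a ``missing`` set on vectors).

Missingness contract:

* spike-shape features (``peak_voltage``, ``AP_amplitude``,
  ``AHP_depth_absolute``) are missing iff ``spikecount == 0``;
* inter-spike features (``time_to_second_spike``,
  ``min_voltage_between_spikes``, ``AP2_AP1_peak_difference``, ``mean_ISI``)
  are missing iff ``spikecount < 2``;
* counts and subthreshold voltages are never missing.

Window conventions (config-exposed, half-open ``[start, end)``, 0-based
sample indexing): ``voltage_base`` averages the last 100 ms before stimulus
onset; ``steady_state_voltage_stimend`` the final 10% of the stimulus
window; ``voltage_after_stimulation`` the last 100 ms of the trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulator import StimulusProtocol, VoltageTrace, simulate_batch
from .space import ParameterSpace, default_parameter_space

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "FeatureTable",
    "FEATURE_NAMES",
    "extract_features",
    "batch_evaluate",
]

FEATURE_NAMES: tuple[str, ...] = (
    "voltage_base",
    "steady_state_voltage_stimend",
    "voltage_after_stimulation",
    "spikecount",
    "peak_voltage",
    "AP_amplitude",
    "AHP_depth_absolute",
    "time_to_second_spike",
    "min_voltage_between_spikes",
    "AP2_AP1_peak_difference",
    "mean_ISI",
)

_SPIKE_SHAPE = ("peak_voltage", "AP_amplitude", "AHP_depth_absolute")
_INTERSPIKE = (
    "time_to_second_spike",
    "min_voltage_between_spikes",
    "AP2_AP1_peak_difference",
    "mean_ISI",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction windows (ms) and fractions."""

    base_window: float = 100.0       # pre-onset averaging window
    steady_state_fraction: float = 0.1  # trailing fraction of the stimulus
    after_window: float = 100.0      # trailing window of the whole trace
    ahp_window: float = 50.0         # post-spike search window for the AHP
    pre_spike: float = 1.0           # lookback for the spike take-off voltage


@dataclass
class FeatureVector:
    """Per-individual feature values plus the set of missing feature names."""

    values: dict[str, float] = field(default_factory=dict)
    missing: frozenset[str] = frozenset()

    def __post_init__(self):
        overlap = set(self.values) & set(self.missing)
        if overlap:
            raise ValueError(f"features both valued and missing: {sorted(overlap)}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values) + tuple(self.missing)

    def __getitem__(self, name: str) -> float:
        if name in self.missing:
            return float("nan")
        return self.values[name]

    def as_series(self) -> pd.Series:
        s = pd.Series(self.values, dtype=float)
        for name in self.missing:
            s[name] = np.nan
        return s


class FeatureTable:
    """A per-individual feature matrix with an explicit missingness mask.

    Thin wrapper over a float DataFrame where NaN encodes structural
    missingness ("NA" on disk).
    """

    def __init__(self, data: pd.DataFrame):
        if data.columns.duplicated().any():
            raise ValueError("duplicate feature columns")
        self.data = data.astype(float)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """True where the feature is missing."""
        return self.data.isna()

    def missing_counts(self) -> pd.Series:
        """Per-feature number of missing values."""
        return self.data.isna().sum()

    def row(self, i: int) -> FeatureVector:
        s = self.data.iloc[i]
        missing = frozenset(s.index[s.isna()])
        values = {k: float(v) for k, v in s.items() if k not in missing}
        return FeatureVector(values=values, missing=missing)

    def observed(self, column: str) -> pd.Series:
        return self.data[column].dropna()


def _window_mean(v: np.ndarray, dt: float, start: float, end: float) -> float:
    i0 = int(np.ceil(start / dt))
    i1 = int(np.ceil(end / dt))
    i1 = min(i1, v.size)
    if i1 <= i0:
        raise ValueError("empty feature window")
    return float(v[i0:i1].mean())


def extract_features(
    trace: VoltageTrace,
    protocol: StimulusProtocol,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureVector:
    """Extract the feature catalog from one trace."""
    v, dt = trace.voltage, trace.dt
    if trace.total_time + dt / 2 < protocol.total_time:
        raise ValueError(
            f"trace ({trace.total_time:g} ms) shorter than protocol "
            f"total_time ({protocol.total_time:g} ms)"
        )
    spikes = trace.spike_times
    nspk = int(spikes.size)

    values: dict[str, float] = {}
    missing: set[str] = set()

    values["voltage_base"] = _window_mean(
        v, dt, max(0.0, protocol.onset - config.base_window), protocol.onset
    )
    ss_start = protocol.offset - config.steady_state_fraction * protocol.duration
    values["steady_state_voltage_stimend"] = _window_mean(v, dt, ss_start, protocol.offset)
    values["voltage_after_stimulation"] = _window_mean(
        v, dt, trace.total_time - config.after_window, trace.total_time + dt
    )
    values["spikecount"] = float(nspk)

    idx = np.round(spikes / dt).astype(int)
    if nspk >= 1:
        peaks = v[idx]
        values["peak_voltage"] = float(peaks.max())
        look = max(1, int(round(config.pre_spike / dt)))
        takeoff = v[np.maximum(idx - look, 0)]
        values["AP_amplitude"] = float(np.mean(peaks - takeoff))
        ahp = []
        for k, i in enumerate(idx):
            j = idx[k + 1] if k + 1 < nspk else min(
                v.size, i + int(round(config.ahp_window / dt)) + 1
            )
            if j > i + 1:
                ahp.append(v[i + 1 : j].min())
        values["AHP_depth_absolute"] = float(np.mean(ahp)) if ahp else float(v[idx].min())
    else:
        missing.update(_SPIKE_SHAPE)

    if nspk >= 2:
        values["time_to_second_spike"] = float(spikes[1] - protocol.onset)
        between = [
            float(v[i + 1 : j].min())
            for i, j in zip(idx[:-1], idx[1:])
            if j > i + 1
        ]
        values["min_voltage_between_spikes"] = min(between) if between else float(v[idx[1:]].min())
        values["AP2_AP1_peak_difference"] = float(v[idx[1]] - v[idx[0]])
        values["mean_ISI"] = float(np.mean(np.diff(spikes)))
    else:
        missing.update(_INTERSPIKE)

    return FeatureVector(values=values, missing=frozenset(missing))


def batch_evaluate(
    population: np.ndarray,
    protocols=None,
    dt: float = 0.1,
    space: ParameterSpace | None = None,
    config: FeatureConfig = FeatureConfig(),
    chunk_size: int = 250,
) -> FeatureTable:
    """Simulate and featurize a population under each protocol.

    Row order is preserved; feature names are prefixed by protocol name
    (``"IVf_3.voltage_base"``). Simulation runs in chunks to bound memory.
    """
    from .simulator import DEFAULT_PROTOCOLS

    protocols = DEFAULT_PROTOCOLS if protocols is None else protocols
    P = np.atleast_2d(np.asarray(population, dtype=float))
    space = space or default_parameter_space(P.shape[1])
    space.validate(P)
    n = P.shape[0]

    frames = []
    for proto in protocols:
        rows = []
        for start in range(0, n, chunk_size):
            block = P[start : start + chunk_size]
            try:
                traces = simulate_batch(block, proto, dt=dt, space=space)
            except Exception as exc:  # annotate with the global row index
                raise RuntimeError(
                    f"simulation failed in rows {start}..{start + len(block) - 1} "
                    f"of protocol {proto.name}: {exc}"
                ) from exc
            rows.extend(extract_features(tr, proto, config).as_series() for tr in traces)
        frame = pd.DataFrame(rows).reset_index(drop=True)
        frame.columns = [f"{proto.name}.{c}" for c in frame.columns]
        frames.append(frame)
    return FeatureTable(pd.concat(frames, axis=1))
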