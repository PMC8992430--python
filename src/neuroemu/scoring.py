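"""Feature-based global score for multi-objective model fitting.

Each feature is scored as its absolute deviation from the experimental mean
in units of the experimental standard deviation,

    score_j = | f_j,sim - mu_j,exp | / sigma_j,exp ,

and the global score of an individual is the sum over scored features.
Lower is better; an individual matching every target mean scores 0. A
feature that is structurally missing from a simulation receives a fixed
penalty (default 20 SD-units, config-exposed): the experimental cell did
produce the feature, so an individual that cannot is heavily disfavoured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TargetStats", "objective_scores", "global_score", "score_table"]

DEFAULT_MISSING_PENALTY = 20.0


@dataclass
class TargetStats:
    """Per-feature experimental mean and SD (index = feature name)."""

    stats: pd.DataFrame  # columns: mean, sd

    def __post_init__(self):
        if not {"mean", "sd"}.issubset(self.stats.columns):
            raise ValueError("targets need 'mean' and 'sd' columns")
        self.stats = self.stats[["mean", "sd"]].astype(float)
        self.stats.index.name = "feature"
        bad = self.stats.index[self.stats["sd"] <= 0]
        if len(bad):
            raise ValueError(f"non-positive target SD for feature(s) {list(bad)}")

    @property
    def features(self) -> list[str]:
        return list(self.stats.index)

    def mean(self, feature: str) -> float:
        return float(self.stats.at[feature, "mean"])

    def sd(self, feature: str) -> float:
        return float(self.stats.at[feature, "sd"])


def _as_series(features) -> pd.Series:
    if hasattr(features, "as_series"):
        return features.as_series()
    return pd.Series(features, dtype=float)


def objective_scores(
    features,
    targets: TargetStats,
    missing_penalty: float = DEFAULT_MISSING_PENALTY,
) -> pd.Series:
    """Per-feature normalized deviations for one individual.

    ``features`` may be a FeatureVector, mapping or Series; NaN encodes a
    missing feature and maps to the penalty.
    """
    f = _as_series(features)
    absent = [name for name in targets.features if name not in f.index]
    if absent:
        raise KeyError(f"individual lacks scored feature(s) {absent}")
    vals = f[targets.features].to_numpy(dtype=float)
    mu = targets.stats["mean"].to_numpy()
    sigma = targets.stats["sd"].to_numpy()
    scores = np.abs(vals - mu) / sigma
    scores = np.where(np.isnan(vals), missing_penalty, scores)
    return pd.Series(scores, index=targets.features)


def global_score(
    features,
    targets: TargetStats,
    missing_penalty: float = DEFAULT_MISSING_PENALTY,
) -> float:
    """Sum of per-feature scores; nonnegative, additive over feature subsets."""
    return float(objective_scores(features, targets, missing_penalty).sum())


def score_table(
    table,
    targets: TargetStats,
    missing_penalty: float = DEFAULT_MISSING_PENALTY,
) -> np.ndarray:
    """Vectorized global score for every row of a feature table/DataFrame."""
    data = table.data if hasattr(table, "data") else table
    absent = [c for c in targets.features if c not in data.columns]
    if absent:
        raise KeyError(f"feature table lacks scored feature(s) {absent}")
    vals = data[targets.features].to_numpy(dtype=float)
    mu = targets.stats["mean"].to_numpy()
    sigma = targets.stats["sd"].to_numpy()
    scores = np.abs(vals - mu) / sigma
    scores = np.where(np.isnan(vals), missing_penalty, scores)
    return scores.sum(axis=1)
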