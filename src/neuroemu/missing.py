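"""Two-stage emulation of features with structural missingness.

Some electrical features only exist when a defining event occurs in the
simulation (e.g. a second spike). The two-stage strategy first fits a
random-forest classifier predicting whether a feature will be observed for
an individual, then fits a value emulator only on the observed rows, and
predicts values only for individuals the classifier passes — which also
guards the emulator against extrapolating outside the region where it saw
data. The decisive classifier property is high *sensitivity* (observed
individuals passed on), since discarding a valid, possibly promising,
individual is the costly error in an optimization loop; the decision
threshold is therefore exposed.

When one class is too small to learn from (fewer than ``skip_min`` rows)
the classifier is skipped and the pipeline degrades to a plain emulator
(all-observed) or an always-missing predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .emulators import EmulatorResults, TrainSet, make_emulator

__all__ = [
    "ForestConfig",
    "ConfusionMatrix",
    "ClassMetrics",
    "TwoStageEmulator",
    "fit_two_stage",
    "metrics",
    "confusion",
    "variable_importance",
    "tune_forest",
]

#: Default classifier settings: the tuned optima reported for the
#: AP-amplitude missingness classifier (1200 trees, 15 candidate features
#: per split).
DEFAULT_N_TREES = 1200
DEFAULT_MTRY = 15

#: Minority-class size below which the classifier stage is skipped.
SKIP_MIN = 10


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest settings: number of trees and features per split."""

    n_trees: int = DEFAULT_N_TREES
    mtry: int | None = DEFAULT_MTRY
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")

    def build(self, d: int, oob: bool = False) -> RandomForestClassifier:
        mtry = min(self.mtry, d) if self.mtry is not None else "sqrt"
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=mtry,
            random_state=self.seed,
            oob_score=oob,
            n_jobs=1,
        )


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts, predicted (rows) x observed (columns).

    ``pred_obs_obs`` = predicted non-missing & observed non-missing, etc.
    """

    pred_obs_obs: int
    pred_obs_mis: int
    pred_mis_obs: int
    pred_mis_mis: int

    def __post_init__(self):
        for v in self.counts().ravel():
            if v < 0:
                raise ValueError("confusion counts must be nonnegative")

    def counts(self) -> np.ndarray:
        return np.array(
            [[self.pred_obs_obs, self.pred_obs_mis],
             [self.pred_mis_obs, self.pred_mis_mis]]
        )

    @property
    def total(self) -> int:
        return int(self.counts().sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts(),
            index=pd.Index(["non-missing", "missing"], name="predicted"),
            columns=pd.Index(["non-missing", "missing"], name="observed"),
        )


@dataclass(frozen=True)
class ClassMetrics:
    """Accuracy, sensitivity and specificity; None where undefined.

    sensitivity = P(predicted non-missing | observed non-missing);
    specificity = P(predicted missing | observed missing). Rounding happens
    only at display.
    """

    accuracy: float
    sensitivity: float | None
    specificity: float | None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }

    def __str__(self) -> str:
        def pct(v):
            return "undefined" if v is None else f"{100 * v:.1f}%"

        return (f"accuracy {pct(self.accuracy)}, sensitivity {pct(self.sensitivity)}, "
                f"specificity {pct(self.specificity)}")


def metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Derive accuracy / sensitivity / specificity from the counts alone."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = (cm.pred_obs_obs + cm.pred_mis_mis) / cm.total
    obs_total = cm.pred_obs_obs + cm.pred_mis_obs
    mis_total = cm.pred_obs_mis + cm.pred_mis_mis
    sens = cm.pred_obs_obs / obs_total if obs_total > 0 else None
    spec = cm.pred_mis_mis / mis_total if mis_total > 0 else None
    return ClassMetrics(accuracy=acc, sensitivity=sens, specificity=spec)


def confusion(pred_missing: np.ndarray, obs_missing: np.ndarray) -> ConfusionMatrix:
    """Build the matrix from boolean missing indicators (True = missing)."""
    pred_missing = np.asarray(pred_missing, dtype=bool)
    obs_missing = np.asarray(obs_missing, dtype=bool)
    return ConfusionMatrix(
        pred_obs_obs=int((~pred_missing & ~obs_missing).sum()),
        pred_obs_mis=int((~pred_missing & obs_missing).sum()),
        pred_mis_obs=int((pred_missing & ~obs_missing).sum()),
        pred_mis_mis=int((pred_missing & obs_missing).sum()),
    )


def tune_forest(
    X: np.ndarray,
    missing: np.ndarray,
    n_trees_grid=(500, 800, 1100, 1200),
    mtry_grid=None,
    seed: int = 0,
) -> ForestConfig:
    """Small out-of-bag-accuracy grid over n_trees and mtry."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = X.shape[1]
    if mtry_grid is None:
        mtry_grid = sorted({int(np.ceil(np.sqrt(d))), min(15, d), min(24, d)})
    best, best_oob = None, -np.inf
    for n_trees in n_trees_grid:
        for mtry in mtry_grid:
            cfg = ForestConfig(n_trees=n_trees, mtry=mtry, seed=seed)
            clf = cfg.build(d, oob=True)
            clf.fit(X, np.asarray(missing, dtype=bool))
            if clf.oob_score_ > best_oob:
                best, best_oob = cfg, clf.oob_score_
    return best


@dataclass
class TwoStageEmulator:
    """Fitted classifier + value emulator with a decision threshold."""

    classifier: RandomForestClassifier | None
    regressor: EmulatorResults | None
    threshold: float = 0.5
    skip_mode: str | None = None  # None | "all_observed" | "all_missing"
    feature_names: list[str] = field(default_factory=list)

    def predict_missing(self, Xnew) -> np.ndarray:
        """Boolean missing prediction per row (True = predicted missing)."""
        Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
        if self.skip_mode == "all_observed":
            return np.zeros(Xnew.shape[0], dtype=bool)
        if self.skip_mode == "all_missing":
            return np.ones(Xnew.shape[0], dtype=bool)
        # column 1 of predict_proba is P(missing) because classes_ = [False, True]
        p_missing = self.classifier.predict_proba(Xnew)[:, list(self.classifier.classes_).index(True)]
        return p_missing >= self.threshold

    def predict(self, Xnew) -> np.ndarray:
        """Feature value per row; NaN is the 'missing' token. Rows predicted
        missing never reach the regressor."""
        Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
        out = np.full(Xnew.shape[0], np.nan)
        miss = self.predict_missing(Xnew)
        keep = ~miss
        if keep.any() and self.regressor is not None:
            out[keep] = self.regressor.predict(Xnew[keep]).mean
        return out

    def variable_importance(self) -> pd.Series:
        if self.classifier is None:
            raise ValueError("no classifier was fitted (skip mode)")
        return variable_importance(self.classifier, self.feature_names)


def variable_importance(classifier, names=None) -> pd.Series:
    """Mean-decrease-in-Gini importances, descending; nonnegative."""
    imp = np.asarray(classifier.feature_importances_, dtype=float)
    if names is None:
        names = [f"x{j + 1}" for j in range(imp.size)]
    s = pd.Series(imp, index=list(names)).sort_values(ascending=False)
    if (s < 0).any() or not np.isfinite(s.sum()):
        raise AssertionError("importances must be finite and nonnegative")
    return s


def fit_two_stage(
    X,
    y,
    clf: ForestConfig = ForestConfig(),
    reg_method: str = "gp",
    threshold: float = 0.5,
    space=None,
    names=None,
    tune: bool = False,
    seed: int = 0,
    reg_kwargs: dict | None = None,
    fit_kwargs: dict | None = None,
) -> TwoStageEmulator:
    """Fit the classifier on the missingness indicator of ``y`` (NaN =
    missing) over all rows, and the value emulator on observed rows only."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on rows")
    missing = np.isnan(y)
    n_mis, n_obs = int(missing.sum()), int((~missing).sum())

    skip_mode = None
    classifier = None
    if n_mis < SKIP_MIN:
        skip_mode = "all_observed"
    elif n_obs < SKIP_MIN:
        skip_mode = "all_missing"
    else:
        if tune:
            clf = tune_forest(X, missing, seed=seed)
        cfg = ForestConfig(n_trees=clf.n_trees, mtry=clf.mtry, seed=seed)
        classifier = cfg.build(X.shape[1])
        classifier.fit(X, missing)

    regressor = None
    if n_obs >= SKIP_MIN or (skip_mode == "all_observed" and n_obs > 0):
        obs = ~missing
        train = TrainSet(X[obs], y[obs], space=space, names=names)
        model = make_emulator(reg_method, train, **(reg_kwargs or {}))
        regressor = model.fit(seed=seed, **(fit_kwargs or {}))

    return TwoStageEmulator(
        classifier=classifier,
        regressor=regressor,
        threshold=threshold,
        skip_mode=skip_mode,
        feature_names=list(names) if names is not None
        else (list(space.names) if space is not None
              else [f"x{j + 1}" for j in range(X.shape[1])]),
    )
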