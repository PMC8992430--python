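"""Surrogate-assisted genetic optimization of the global score.

Four execution strategies for evaluating a generation:

* ``full_sim`` — every individual is simulated (the reference workflow);
* ``split`` — a seeded train fraction (default 80%) is simulated, per-
  feature emulators are fitted on it, and the remaining individuals'
  features are predicted, saving the corresponding fraction of simulator
  time each generation;
* ``emulate_gens`` — refresh generations are fully simulated and used to
  (re)fit emulators; intermediate generations are fully emulated except a
  small drift-check sample that is simulated and compared (feature RMSE in
  SD units); drift above threshold triggers a fallback full simulation and
  refit;
* ``screen`` — the incumbent emulators score all offspring and only the
  best keep-fraction is simulated; the rest are discarded unsimulated.

GA operators are standard real-coded choices: tournament selection
(minimizing the score), blend (BLX-alpha) crossover, per-gene Gaussian
mutation with bound clipping, and elitism. Individuals carry provenance
(simulator vs emulator); emulator-evaluated rows are never used to train
subsequent emulators, which prevents self-training feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import derive_seed
from .features import FeatureConfig, batch_evaluate
from .missing import ForestConfig, fit_two_stage
from .scoring import DEFAULT_MISSING_PENALTY, TargetStats, score_table
from .space import ParameterSpace

__all__ = ["GAConfig", "StrategyConfig", "ga_step", "run_moo", "drift_check", "MOOHistory"]


@dataclass(frozen=True)
class GAConfig:
    """Real-coded GA settings.

    The mutation scale (SD of the per-gene Gaussian, as a fraction of each
    parameter's range) anneals geometrically from ``mutation_scale`` to
    ``mutation_scale_final`` across the run — wide early exploration,
    fine late refinement. Set ``mutation_scale_final=None`` for a constant
    scale.
    """

    population: int = 1000
    generations: int = 20
    tournament: int = 4
    crossover_rate: float = 0.9
    crossover_alpha: float = 0.5
    mutation_rate: float | None = None  # default 1/d per gene
    mutation_scale: float = 0.1
    mutation_scale_final: float | None = 0.01
    elitism: int = 2
    seed: int = 0

    def scale_at(self, gen: int) -> float:
        """Mutation scale for the step producing generation ``gen + 1``."""
        if self.mutation_scale_final is None or self.generations <= 2:
            return self.mutation_scale
        frac = gen / (self.generations - 2)
        return float(self.mutation_scale
                     * (self.mutation_scale_final / self.mutation_scale) ** min(frac, 1.0))

    def __post_init__(self):
        if self.population < 2 * max(self.elitism, 1):
            raise ValueError("population must be >= 2 * elitism")
        for r in (self.crossover_rate,):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class StrategyConfig:
    mode: str = "full_sim"  # full_sim | split | emulate_gens | screen
    train_fraction: float = 0.8
    refresh_period: int = 5
    drift_sample: int = 20
    drift_threshold: float = 0.5  # feature RMSE in SD units
    keep_fraction: float = 0.3
    emulator: str = "gp"
    emulator_kwargs: dict = field(default_factory=dict)
    fit_kwargs: dict = field(default_factory=lambda: {"n_restarts": 1, "maxiter": 40})
    clf: ForestConfig = field(default_factory=lambda: ForestConfig(n_trees=300, mtry=None))

    def __post_init__(self):
        if self.mode not in ("full_sim", "split", "emulate_gens", "screen"):
            raise ValueError(f"unknown strategy mode {self.mode!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.refresh_period < 1:
            raise ValueError("refresh_period must be >= 1")


def ga_step(
    params: np.ndarray,
    scores: np.ndarray,
    config: GAConfig,
    space: ParameterSpace,
    rng: np.random.Generator,
    elite_mask: np.ndarray | None = None,
) -> np.ndarray:
    """One generation of selection / crossover / mutation; lower score wins.

    ``elite_mask`` restricts which rows may be copied unchanged by elitism
    (the surrogate-assisted strategies pass the simulator-evaluated rows:
    an emulator prediction is systematically optimistic — its conditional
    mean shrinks |f - mu| — so emulator-scored rows must not displace
    verified elites).
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size != params.shape[0]:
        raise ValueError("scores and population disagree on rows")
    if np.isnan(scores).any():
        raise ValueError("unscored individual in the population")
    n, d = params.shape
    p_mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / d
    ranges = space.upper - space.lower

    eligible = (np.arange(n) if elite_mask is None
                else np.flatnonzero(np.asarray(elite_mask, dtype=bool)))
    order = eligible[np.argsort(scores[eligible], kind="stable")]
    children = [params[order[i]].copy()
                for i in range(min(config.elitism, order.size))]

    def pick() -> np.ndarray:
        contenders = rng.integers(0, n, size=config.tournament)
        return params[contenders[np.argmin(scores[contenders])]]

    while len(children) < config.population:
        p1, p2 = pick(), pick()
        if rng.random() < config.crossover_rate:
            a = config.crossover_alpha
            gamma = rng.uniform(-a, 1.0 + a, size=d)
            c1 = gamma * p1 + (1.0 - gamma) * p2
            c2 = gamma * p2 + (1.0 - gamma) * p1
        else:
            c1, c2 = p1.copy(), p2.copy()
        for c in (c1, c2):
            mask = rng.random(d) < p_mut
            noise = rng.normal(0.0, config.mutation_scale * ranges)
            c = np.where(mask, c + noise, c)
            children.append(space.clip(c))
            if len(children) >= config.population:
                break
    return np.vstack(children[: config.population])


@dataclass
class MOOHistory:
    """Per-generation optimization log."""

    records: list[dict] = field(default_factory=list)

    def append(self, **kw):
        self.records.append(kw)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    @property
    def best_score(self) -> float:
        return float(min(r["best_score"] for r in self.records))

    @property
    def sim_calls(self) -> int:
        return int(sum(r["sim_calls"] for r in self.records))

    @property
    def emu_calls(self) -> int:
        return int(sum(r["emu_calls"] for r in self.records))


class _FeatureEmulators:
    """Per-feature emulators (independent across features), trained on
    simulator-evaluated rows only; two-stage where missingness is learnable."""

    def __init__(self, strategy: StrategyConfig, space: ParameterSpace, features):
        self.strategy = strategy
        self.space = space
        self.features = list(features)
        self.fitted: dict[str, object] = {}

    def fit(self, X: np.ndarray, table: pd.DataFrame, seed: int):
        st = self.strategy
        for feat in self.features:
            y = table[feat].to_numpy(dtype=float)
            self.fitted[feat] = fit_two_stage(
                X, y,
                clf=st.clf,
                reg_method=st.emulator,
                space=self.space,
                names=list(self.space.names),
                seed=derive_seed(seed, "emu", feat),
                reg_kwargs=st.emulator_kwargs,
                fit_kwargs=st.fit_kwargs,
            )

    @property
    def ready(self) -> bool:
        return len(self.fitted) == len(self.features)

    def predict_table(self, X: np.ndarray) -> pd.DataFrame:
        cols = {feat: self.fitted[feat].predict(X) for feat in self.features}
        return pd.DataFrame(cols)


def drift_check(
    emulated: pd.DataFrame,
    simulated: pd.DataFrame,
    threshold: float,
) -> tuple[pd.Series, bool]:
    """Per-feature RMSE between emulated and simulated sample values, in
    units of the simulated sample's SD; refit when any ratio exceeds the
    threshold. Features entirely missing in the sample are skipped."""
    if len(simulated) < 1:
        raise ValueError("empty drift-check sample")
    ratios = {}
    for feat in simulated.columns:
        sim = simulated[feat].to_numpy(dtype=float)
        emu = emulated[feat].to_numpy(dtype=float)
        both = ~(np.isnan(sim) | np.isnan(emu))
        if not both.any():
            continue  # all-missing feature in the sample; skipped
        rmse = float(np.sqrt(np.mean((sim[both] - emu[both]) ** 2)))
        sd = float(sim[both].std())
        ratios[feat] = rmse / sd if sd > 0 else (0.0 if rmse == 0 else np.inf)
    series = pd.Series(ratios, dtype=float)
    refit = bool((series > threshold).any()) if len(series) else False
    return series, refit


def run_moo(
    targets: TargetStats,
    ga: GAConfig,
    strategy: StrategyConfig = StrategyConfig(),
    space: ParameterSpace | None = None,
    protocols=None,
    dt: float = 0.1,
    feature_config: FeatureConfig = FeatureConfig(),
    missing_penalty: float = DEFAULT_MISSING_PENALTY,
) -> MOOHistory:
    """Run the GA under the chosen evaluation strategy.

    Simulator and emulator call counts are logged exactly per generation.
    """
    from .space import default_parameter_space

    space = space or default_parameter_space()
    features = targets.features
    rng = np.random.default_rng(derive_seed(ga.seed, "ga"))

    def simulate_features(X: np.ndarray) -> pd.DataFrame:
        table = batch_evaluate(X, protocols, dt=dt, space=space, config=feature_config)
        return table.data[features]

    emus = _FeatureEmulators(strategy, space, features)
    history = MOOHistory()
    pop = space.sample(ga.population, rng)

    for gen in range(ga.generations):
        sim_calls = emu_calls = 0
        drift_rmse = np.nan
        note = ""
        n = pop.shape[0]

        sim_mask = np.ones(n, dtype=bool)  # provenance: simulator-verified rows
        if strategy.mode == "full_sim":
            table = simulate_features(pop)
            sim_calls = n
        elif strategy.mode == "split":
            n_train = int(round(strategy.train_fraction * n))
            # elites (rows 0..elitism-1 after ga_step) are always simulated so
            # the best-so-far score is never replaced by an emulator guess
            elite = np.arange(min(ga.elitism, n_train))
            # subset drawn from its own derived stream so the main GA stream
            # stays aligned across strategies (paired-run comparability)
            sub_rng = np.random.default_rng(derive_seed(ga.seed, "subset", gen))
            rest = sub_rng.permutation(np.setdiff1d(np.arange(n), elite))
            tr = np.concatenate([elite, rest[: n_train - elite.size]])
            te = rest[n_train - elite.size :]
            table_tr = simulate_features(pop[tr])
            sim_calls = len(tr)
            try:
                emus.fit(pop[tr], table_tr, seed=derive_seed(ga.seed, "fit", gen))
                table_te = emus.predict_table(pop[te])
                emu_calls = len(te)
                sim_mask = np.zeros(n, dtype=bool)
                sim_mask[tr] = True
            except Exception as exc:  # fall back to full simulation
                note = f"emulator fit failed ({type(exc).__name__}); simulated"
                table_te = simulate_features(pop[te])
                sim_calls += len(te)
            table = pd.concat(
                [table_tr.set_index(tr), table_te.set_index(te)]
            ).sort_index().reset_index(drop=True)
        elif strategy.mode == "emulate_gens":
            refresh = (gen % strategy.refresh_period == 0) or not emus.ready
            if refresh:
                table = simulate_features(pop)
                sim_calls = n
                emus.fit(pop, table, seed=derive_seed(ga.seed, "fit", gen))
            else:
                table = emus.predict_table(pop)
                emu_calls = n
                k = min(strategy.drift_sample, n)
                sample = np.random.default_rng(
                    derive_seed(ga.seed, "drift", gen)).choice(n, size=k, replace=False)
                sim_sample = simulate_features(pop[sample])
                sim_calls += k
                ratios, refit = drift_check(
                    table.iloc[sample].reset_index(drop=True),
                    sim_sample,
                    strategy.drift_threshold,
                )
                drift_rmse = float(ratios.max()) if len(ratios) else np.nan
                if refit:
                    note = "drift above threshold; refit from full simulation"
                    table = simulate_features(pop)
                    sim_calls += n
                    emu_calls = 0
                    emus.fit(pop, table, seed=derive_seed(ga.seed, "refit", gen))
                else:
                    # the drift sample is already simulated: keep its exact
                    # features and let it carry simulator provenance
                    table.iloc[sample] = sim_sample.to_numpy()
                    sim_mask = np.zeros(n, dtype=bool)
                    sim_mask[sample] = True
        else:  # screen
            if not emus.ready:
                table = simulate_features(pop)
                sim_calls = n
                emus.fit(pop, table, seed=derive_seed(ga.seed, "fit", gen))
            else:
                emu_table = emus.predict_table(pop)
                emu_calls = n
                emu_scores = score_table(emu_table, targets, missing_penalty)
                keep = max(2, int(round(strategy.keep_fraction * n)))
                survivors = np.argsort(emu_scores, kind="stable")[:keep]
                pop = pop[np.sort(survivors)]
                table = simulate_features(pop)
                sim_calls = pop.shape[0]
                sim_mask = np.ones(pop.shape[0], dtype=bool)
                try:  # refit on the kept simulated rows; keep old on failure
                    emus.fit(pop, table, seed=derive_seed(ga.seed, "fit", gen))
                except Exception as exc:
                    note = f"emulator refit failed ({type(exc).__name__}); kept previous"

        scores = score_table(table, targets, missing_penalty)
        history.append(
            generation=gen,
            best_score=float(scores.min()),
            # best over simulator-verified rows only: emulator-scored rows
            # carry optimistic bias and must not be reported as the optimum
            best_verified=float(scores[sim_mask].min()) if sim_mask.any()
            else float(scores.min()),
            median_score=float(np.median(scores)),
            sim_calls=sim_calls,
            emu_calls=emu_calls,
            drift_rmse=drift_rmse,
            note=note,
        )
        if gen < ga.generations - 1:
            cfg = replace(ga, mutation_scale=ga.scale_at(gen),
                          mutation_scale_final=None)
            pop = ga_step(pop, scores, cfg, space, rng, elite_mask=sim_mask)
    return history
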