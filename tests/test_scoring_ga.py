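"""Global score, GA operators, strategy call accounting and drift checks."""

import numpy as np
import pandas as pd
import pytest

import neuroemu as ne
from neuroemu.ga import drift_check, ga_step
from neuroemu.scoring import TargetStats, global_score, objective_scores, score_table


def _targets(**feats):
    frame = pd.DataFrame(
        {"mean": {k: v[0] for k, v in feats.items()},
         "sd": {k: v[1] for k, v in feats.items()}}
    )
    return TargetStats(frame)


def test_objective_score_formula():
    t = _targets(a=(1.0, 0.5))
    s = objective_scores({"a": 2.0}, t)
    assert s["a"] == pytest.approx(2.0)


def test_perfect_match_scores_zero():
    t = _targets(a=(1.0, 0.5), b=(-70.0, 3.0))
    assert global_score({"a": 1.0, "b": -70.0}, t) == 0.0


def test_missing_feature_gets_the_penalty():
    t = _targets(a=(1.0, 0.5))
    assert global_score({"a": np.nan}, t, missing_penalty=20.0) == 20.0


def test_global_score_is_additive_over_features():
    ta = _targets(a=(1.0, 0.5))
    tb = _targets(b=(0.0, 1.0))
    tab = _targets(a=(1.0, 0.5), b=(0.0, 1.0))
    f = {"a": 2.0, "b": 1.0}
    assert global_score(f, tab) == pytest.approx(
        global_score(f, ta) + global_score(f, tb))
    assert global_score(f, tab) == pytest.approx(3.0)


def test_nonpositive_target_sd_rejected():
    with pytest.raises(ValueError, match="SD"):
        _targets(a=(1.0, 0.0))


def test_score_table_matches_per_row_scoring():
    t = _targets(a=(1.0, 0.5), b=(0.0, 2.0))
    frame = pd.DataFrame({"a": [1.0, 2.0, np.nan], "b": [0.0, 4.0, 0.0]})
    vec = score_table(frame, t)
    for i in range(3):
        assert vec[i] == pytest.approx(global_score(frame.iloc[i], t), abs=1e-12)


# ------------------------------------------------------------------- GA ----
def test_ga_step_deterministic_given_seed(space31):
    pop = space31.sample(30, np.random.default_rng(0))
    scores = np.linspace(1, 30, 30)
    cfg = ne.GAConfig(population=30, seed=0)
    a = ga_step(pop, scores, cfg, space31, np.random.default_rng(5))
    b = ga_step(pop, scores, cfg, space31, np.random.default_rng(5))
    np.testing.assert_array_equal(a, b)


def test_ga_step_elitism_copies_best_unchanged(space31):
    pop = space31.sample(20, np.random.default_rng(1))
    scores = np.arange(20.0)[::-1]  # last row is best
    cfg = ne.GAConfig(population=20, elitism=2, seed=0)
    child = ga_step(pop, scores, cfg, space31, np.random.default_rng(2))
    np.testing.assert_array_equal(child[0], pop[19])
    np.testing.assert_array_equal(child[1], pop[18])


def test_ga_step_no_variation_copies_parents(space31):
    pop = space31.sample(16, np.random.default_rng(3))
    scores = np.arange(16.0)
    cfg = ne.GAConfig(population=16, crossover_rate=0.0, mutation_rate=0.0, seed=0)
    child = ga_step(pop, scores, cfg, space31, np.random.default_rng(4))
    pop_rows = {tuple(r) for r in pop}
    assert all(tuple(r) in pop_rows for r in child)


def test_ga_step_respects_bounds(space31):
    pop = space31.sample(40, np.random.default_rng(6))
    cfg = ne.GAConfig(population=40, mutation_rate=1.0, mutation_scale=2.0, seed=0)
    child = ga_step(pop, np.arange(40.0), cfg, space31, np.random.default_rng(7))
    assert np.all(child >= space31.lower) and np.all(child <= space31.upper)


def test_ga_step_requires_scores(space31):
    pop = space31.sample(10, np.random.default_rng(8))
    scores = np.arange(10.0)
    scores[3] = np.nan
    with pytest.raises(ValueError, match="unscored"):
        ga_step(pop, scores, ne.GAConfig(population=10), space31,
                np.random.default_rng(9))


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        ne.GAConfig(population=1, elitism=1)
    with pytest.raises(ValueError):
        ne.StrategyConfig(mode="turbo")
    with pytest.raises(ValueError):
        ne.StrategyConfig(train_fraction=1.5)


# ------------------------------------------------------- call accounting ---
@pytest.fixture(scope="module")
def tiny_targets():
    targets, _ = ne.make_targets(dt=0.4)
    return targets


def test_full_sim_call_accounting(tiny_targets):
    ga = ne.GAConfig(population=20, generations=3, seed=0)
    h = ne.run_moo(tiny_targets, ga, ne.StrategyConfig(mode="full_sim"), dt=0.4)
    f = h.as_frame()
    assert (f.sim_calls == 20).all() and (f.emu_calls == 0).all()
    assert h.sim_calls + h.emu_calls == 20 * 3


def test_split_call_accounting_80_20(tiny_targets):
    """80/20 split: exactly 80% simulated, 20% emulated, every generation."""
    ga = ne.GAConfig(population=50, generations=3, seed=1)
    strat = ne.StrategyConfig(mode="split", train_fraction=0.8, emulator="rf")
    h = ne.run_moo(tiny_targets, ga, strat, dt=0.4)
    f = h.as_frame()
    assert (f.sim_calls == 40).all()
    assert (f.emu_calls == 10).all()
    assert h.sim_calls + h.emu_calls == 50 * 3


def test_screen_mode_call_accounting(tiny_targets):
    ga = ne.GAConfig(population=40, generations=3, seed=2)
    strat = ne.StrategyConfig(mode="screen", keep_fraction=0.3, emulator="rf")
    h = ne.run_moo(tiny_targets, ga, strat, dt=0.4)
    f = h.as_frame()
    assert f.sim_calls[0] == 40 and f.emu_calls[0] == 0
    assert (f.sim_calls[1:] == 12).all()
    assert (f.emu_calls[1:] == 40).all()


def test_emulate_gens_refresh_schedule(tiny_targets):
    ga = ne.GAConfig(population=40, generations=4, seed=3)
    strat = ne.StrategyConfig(mode="emulate_gens", refresh_period=2,
                              drift_sample=5, drift_threshold=np.inf,
                              emulator="rf")
    h = ne.run_moo(tiny_targets, ga, strat, dt=0.4)
    f = h.as_frame()
    # refresh at generations 0 and 2; emulated (plus drift sample) otherwise
    assert list(f.sim_calls) == [40, 5, 40, 5]
    assert list(f.emu_calls) == [0, 40, 0, 40]


def test_screening_with_perfect_emulator_keeps_true_best(tiny_targets, monkeypatch):
    """With an emulator that reproduces the simulator exactly, the screened
    survivor set always contains the true best offspring, so the generation
    best equals the best of the full (pre-screen) offspring pool."""
    import neuroemu.ga as ga_mod
    from neuroemu.features import batch_evaluate
    from neuroemu.scoring import score_table

    true_best = []

    def perfect_predict(self, X):
        table = batch_evaluate(X, space=self.space, dt=0.4).data[self.features]
        true_best.append(float(score_table(table, tiny_targets).min()))
        return table.reset_index(drop=True)

    monkeypatch.setattr(ga_mod._FeatureEmulators, "predict_table", perfect_predict)
    monkeypatch.setattr(
        ga_mod._FeatureEmulators, "fit",
        lambda self, X, table, seed: self.fitted.update(
            dict.fromkeys(self.features, object())),
    )
    ga = ne.GAConfig(population=30, generations=3, seed=4)
    h = ne.run_moo(tiny_targets, ga,
                   ne.StrategyConfig(mode="screen", keep_fraction=0.3), dt=0.4)
    f = h.as_frame()
    assert len(true_best) == 2  # generations 1 and 2 are screened
    for gen, best in zip((1, 2), true_best):
        assert f.best_verified[gen] == pytest.approx(best, abs=1e-9)


# ------------------------------------------------------------ drift check --
def test_drift_zero_for_perfect_emulator(rng):
    sim = pd.DataFrame({"f": rng.standard_normal(20)})
    ratios, refit = drift_check(sim.copy(), sim, threshold=0.5)
    assert ratios["f"] == 0.0 and not refit


def test_drift_constant_emulator_triggers_refit(rng):
    sim = pd.DataFrame({"f": rng.standard_normal(50)})
    emu = pd.DataFrame({"f": np.zeros(50)})
    ratios, refit = drift_check(emu, sim, threshold=0.5)
    assert ratios["f"] == pytest.approx(1.0, rel=0.15)
    assert refit


def test_drift_infinite_threshold_never_refits(rng):
    sim = pd.DataFrame({"f": rng.standard_normal(30)})
    emu = pd.DataFrame({"f": rng.standard_normal(30)})
    _, refit = drift_check(emu, sim, threshold=np.inf)
    assert not refit


def test_drift_all_missing_feature_skipped(rng):
    sim = pd.DataFrame({"f": [np.nan] * 10, "g": rng.standard_normal(10)})
    ratios, _ = drift_check(sim.copy(), sim, threshold=0.5)
    assert "f" not in ratios.index and "g" in ratios.index
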