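# neuroemu

Statistical emulation of expensive neural simulators: Gaussian-process-family
surrogate models of a spiking neuron's electrical features, a two-stage
classifier + regressor pipeline for features that are structurally missing in
some simulations, a surrogate-assisted genetic algorithm for feature-based
multi-objective model fitting, and emulator-based inference — predictive-
interval coverage and Sobol sensitivity analysis with noise-factor negative
controls.

## Who this is for

Fitting a conductance-based neuron model to electrophysiology data means
searching a high-dimensional parameter space with a simulator that can take
an hour per generation of candidates. An *emulator* — a statistical model
f̂(**x**) trained on simulator input/output pairs — can predict a candidate's
electrical features in microseconds, so it can replace part of each
generation's simulations, screen unpromising offspring before they are
simulated, and answer inference questions (which channel densities drive a
feature; how uncertain is a prediction) that raw simulation cannot.

`neuroemu` packages that workflow against a built-in deterministic
adaptive-exponential integrate-and-fire stand-in neuron (31 bounded
parameters, 12 of them mechanistic, the rest provably inert), so the whole
loop runs in minutes on a laptop and every claim is testable.

## The core quantities

Each candidate parameter vector ("individual") is scored against
experimental target statistics per feature *j*:

    score_j = | f_j,sim − μ_j,exp | / σ_j,exp        (units of experimental SD)
    global score = Σ_j score_j                        (lower is better)

Emulators model each feature separately. The reference emulator is GP
regression, f(**x**) = Σ β_i g_i(**x**) + Z(**x**), with the ARD
squared-exponential kernel

    k(x, x′) = σ_f² · exp( −½ Σ_j (x_j − x′_j)² / l_j² )

fitted by maximizing the marginal likelihood; variants include GPllm (a
data-driven per-dimension choice between linear-trend and kernel terms),
local-approximate GP, greedy treed models with GP or linear leaves, and
random-forest / neural-net / linear baselines, all behind one
`Model.fit() → Results.predict()` contract.

## A worked example

```python
import numpy as np
import neuroemu as ne

# 1000 synthetic individuals; extract features under the 0.04 nA protocol
params, table, space = ne.make_dataset(1000, d=31, seed=11,
                                       protocols=[ne.IVF_3])
y = table.data["IVf_3.steady_state_voltage_stimend"].to_numpy()
X = params.to_numpy()

# fit a GP emulator on 800, test on 200
rng = np.random.default_rng(3)
perm = rng.permutation(1000)
train = ne.TrainSet(X[perm[:800]], y[perm[:800]], space=space)
res = ne.GaussianProcess(train).fit(seed=0, n_restarts=2)
rmse = res.rmse(X[perm[800:]], y[perm[800:]])
sd = y[perm[800:]].std()
print(f"rmse {rmse:.3f} mV, test sd {sd:.3f} mV, ratio {rmse/sd:.3f}")
```

prints

```
rmse 2.373 mV, test sd 9.759 mV, ratio 0.243
```

— the emulator's error is a quarter of the feature's spread, i.e. it
explains 94.1% of the held-out variance (an RMSE below half the SD means
more than 75% explained). The fitted object also carries calibrated
uncertainty:

```python
pred = res.predict(X[perm[800:]])
rep = ne.coverage(pred, y[perm[800:]])   # fraction inside [q05, q95]
print(rep)
```

```
coverage 89.0% (nominal 90%), n=200, mean width 2.09 (0.21 test SDs)
```

Surrogate-assisted optimization with exact call accounting:

```python
targets, ref = ne.make_targets()            # targets from a known individual
ga = ne.GAConfig(population=200, generations=30, seed=1)
hist = ne.run_moo(targets, ga, ne.StrategyConfig(mode="split"))
print(hist.as_frame()[["generation", "best_score", "sim_calls", "emu_calls"]])
```

In `split` mode each generation simulates exactly 80% of individuals (160
here) and predicts the remaining 20% (40) with per-feature emulators — the
fraction of simulator time saved is exactly the emulated fraction.

A command-line layer mirrors the library:

```
neuroemu make-synthetic --n 1000 --d 31 --seed 7 --out-prefix gen1
neuroemu benchmark --methods lr,rf,gp,gpllm --train-csv train.csv \
    --test-csv test.csv --target-col IVf_3.voltage_base --seed 1
neuroemu two-stage --train-csv train.csv --test-csv test.csv \
    --feature IDRest_7.AP_amplitude --seed 1
neuroemu run-moo --mode split --pop 1000 --gens 20 --seed 1
```

Every command writes a JSON run manifest (config, seeds, call counts) next
to its outputs.

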