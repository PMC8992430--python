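# Methods

This note documents the models, numerical choices and limitations behind
`neuroemu`. It is the place to look when a default needs justifying.

## The problem

Fitting a biophysical neuron model to experimental electrophysiology is
usually posed as feature-based multi-objective optimization: a simulator
maps a parameter vector **x** (ion-channel densities, passive properties)
to a set of electrical features f_j(**x**) (resting voltage, spike count,
spike shape, inter-spike statistics), and a genetic algorithm searches for
parameter vectors whose features match experimental target statistics.
Each simulator call is expensive — a full compartmental model takes on the
order of an hour per 1000-individual generation on a cluster — so a cheap
statistical *emulator* f̂(**x**) trained on simulator input–output pairs can
replace or screen simulator calls inside the loop, and doubles as an
inference engine (which inputs matter, how certain are predictions).

`neuroemu` implements that whole loop against a deterministic,
millisecond-cost stand-in neuron, so every strategy can be exercised,
measured and tested end to end on one workstation.

## The stand-in simulator

An adaptive-exponential integrate-and-fire (AdEx) neuron:

    C dV/dt  = −g_L (V − E_L) + g_L Δ_T exp((V − V_T)/Δ_T) − w + gain·I(t)
    τ_w dw/dt = a (V − E_L) − w

with spike cutoff V_peak (voltage recorded at V_peak for one sample, then
reset to V_reset, w ← w + b, absolute refractory t_ref). Integration is
fixed-step explicit Euler, default dt = 0.1 ms, units ms / mV / nA / nF /
µS throughout, 0-based sample indexing, windows half-open [start, end).
The exponential argument is capped at 30 to avoid overflow in the
half-step before cutoff.

Why AdEx: it is the simplest model that produces *genuine* values for
spike-shape and inter-spike features (peak, AHP depth, ISI statistics) and
*natural structural missingness* — a sub-threshold individual simply has no
AP amplitude — which is the phenomenon half of this package exists to
handle. The default parameter space has 31 dimensions: 12 mechanistic AdEx
parameters with physiologically plausible bounds, and 19 inert dimensions
that the integrator provably never reads. The inert block mimics the
realistic situation where many tuned parameters barely matter, and doubles
as a built-in negative control for sensitivity analysis and variable
importance.

Two stimulus protocols mirror a weak/strong pair: `IVf_3` (0.04 nA,
1000 ms — sub-threshold for most of the box) and `IDRest_7` (0.27 nA,
2000 ms — supra-threshold for roughly half of a random population, giving
a realistic mixed missingness profile and bi-modal spiking features).

Feature windows (config-exposed in `FeatureConfig`): `voltage_base` = mean
of the last 100 ms before onset; `steady_state_voltage_stimend` = mean of
the final 10% of the stimulus; `voltage_after_stimulation` = mean of the
last 100 ms of the trace; AHP search window 50 ms post-spike; spike
take-off lookback 1 ms. These follow common electrophysiology practice;
they are analogs of, not reproductions of, any particular feature library.

Missingness contract: spike-shape features are missing iff spikecount = 0;
inter-spike features iff spikecount < 2; counts and sub-threshold voltages
are never missing. Missingness is structural and never imputed.

## Emulators

All emulators share one contract: inputs scaled to the unit cube via the
parameter bounds, responses standardized to zero mean / unit SD, models
built from a `TrainSet` and fitted into a results object whose
`predict()` returns mean, predictive SD and central-90% quantiles
(point-prediction methods return NaN uncertainty).

**GP regression.** Response = trend + zero-mean GP with the ARD
squared-exponential kernel k(x, x′) = σ_f² exp(−½ Σ_j (x_j − x′_j)²/l_j²)
plus nugget σ_n². The trend is a constant by default; trend coefficients
are profiled out by generalized least squares and the remaining
hyperparameters maximize the concentrated log marginal likelihood
(empirical Bayes), by multi-start L-BFGS-B in log space with analytic
gradients. Defaults: 3 starts (first deterministic, rest seeded), bounds
σ_f² ∈ [1e−4, 1e2], l_j ∈ [1e−3, 50], σ_n² ∈ [1e−8, 1], nugget estimated
by default even though the stand-in is deterministic (it guards
conditioning). The length-scale cap at 50 is deliberate: on a unit cube a
larger scale is statistically indistinguishable from a linear trend, and
letting σ_f² and l grow together pushes the kernel matrix onto a
numerically singular ridge where the interpolation property is lost in
double precision. Near-linear dimensions belong to the limiting linear
model instead.

Numerics: Cholesky with a jitter ladder (plain attempt, then 1e−12 …
1e−6, then a conditioning error); one iterative-refinement step on the
dual weights; a zero-nugget fit with duplicated inputs and conflicting
responses is rejected up front. Predictive variance is the plug-in
(simple-kriging) form, so far from all data the SD reverts to
√(σ_f² + σ_n²); the trend-estimation variance is not added. Predictive
quantiles are Gaussian: q05/q95 = mean ∓ 1.6449·sd.

**GPllm.** Per-dimension linear-vs-GP choice by a greedy deterministic
pass in index order: move dimension j to a linear trend term, refit
warm-started from the incumbent hyperparameters with a capped iteration
budget, keep the move if BIC (−2·loglik + one parameter per length scale /
slope / variance term) improves. The all-linear limit is exactly ordinary
least squares. This is a deliberate, reproducible stand-in for MCMC model
averaging over the linear/GP indicators.

**laGP.** Per-site GP on the m (default 50) nearest training points,
unit-cube Euclidean distance, ties broken by row index — the simplest
nearest-neighbor variant of local approximate GP prediction.

**Treed models.** Greedy CART-style axis-aligned splits maximizing
residual-variance reduction, each leaf fitted with linear / GP / GPllm
models (`tlm`, `tgp`, `tgpllm`). This is a deliberate greedy simplification
of fully Bayesian treed-GP posteriors: no tree-space posterior, one tree,
deterministic given a seed. `max_depth=0` reduces to the plain leaf model.

**Baselines.** Linear regression (with OLS predictive intervals), random
forest (500 trees) and a small fixed multilayer perceptron (two 64-unit
layers), the latter two via scikit-learn behind the same contract, point
predictions only, excluded from coverage analysis.

`benchmark()` fits any subset of the registry on a train split, reports
RMSE on a disjoint test split, the test-response SD as the accuracy
yardstick (RMSE below half the SD ⇔ more than 75% of test variance
explained), and fit+predict wall time. Timing is hardware-dependent and is
never asserted on.

## Two-stage emulation of sometimes-missing features

A random-forest classifier (defaults: 1200 trees, 15 candidate features
per split — tunable by a small out-of-bag grid in `tune_forest`, off by
default) predicts whether a feature will be observed; a value emulator is
trained on observed rows only and consulted only for rows the classifier
passes, which also keeps the regressor from extrapolating outside the
region where it saw data. The decision threshold on the forest's missing
vote defaults to 0.5 and is exposed because the operationally important
property is *sensitivity* — discarding an individual that would have
produced a valid, possibly promising value is the costly error inside an
optimization loop. When a class has fewer than 10 training rows the
classifier stage is skipped (all-observed or all-missing mode). Confusion
matrices are reported predicted × observed with accuracy, sensitivity
(= P(pred non-missing | obs non-missing)) and specificity
(= P(pred missing | obs missing)); rounding only at display.

## Global score and the genetic algorithm

Per-feature objective: |f_j,sim − μ_j,exp| / σ_j,exp; global score = sum
over scored features; lower is better. A structurally missing feature
scores a fixed penalty, default 20 SD-units, config-exposed and worth
flagging: it is a modelling choice, not a measurement, and it shapes the
search strongly early on (it is what pushes a random population toward
spiking regimes when spiking features are scored).

GA operators (all config-exposed): tournament selection of size 4
minimizing the score, blend (BLX-α) crossover with α = 0.5 at rate 0.9,
per-gene Gaussian mutation with probability 1/d and an SD that anneals
geometrically from 10% to 1% of each parameter's range across the run,
elitism 2, bound clipping. The annealed mutation and moderately strong
selection were chosen after measuring convergence on the stand-in: with
tournament 2, constant 10% mutation and elitism 1 the 30-generation
best-score reduction stalled near ×5–12; the defaults here reach ×10 in
most seeds while remaining entirely standard real-coded choices.

Execution strategies (`StrategyConfig.mode`):

* `full_sim` — simulate everything.
* `split` — simulate a seeded 80% (including, deliberately, the elite
  rows, so the best-so-far score is never overwritten by an emulator
  guess), fit per-feature emulators on the simulated subset, predict the
  rest. Exactly 0.8·N simulator calls and 0.2·N emulator predictions per
  generation.

  Emulator predictions are systematically *optimistic* for this score: the
  emulator predicts a conditional mean, and |E[f] − μ| ≤ E|f − μ|, so an
  emulator-scored individual tends to look better than it is (instrumented
  runs showed biases of −2 to −20 score units). Two safeguards follow:
  elitism only ever copies simulator-verified individuals (emulator-scored
  rows still compete in tournaments, where selection noise is tolerable,
  but cannot claim elite status), and the history records `best_verified`
  — the best simulator-evaluated score — alongside the raw `best_score`,
  which for surrogate generations may be an emulator guess.
* `emulate_gens` — fully simulate refresh generations (default every 5th)
  and refit; fully emulate the others apart from a small simulated
  drift-check sample (default 20) whose per-feature RMSE in units of the
  sample SD triggers a fallback full simulation and refit above the
  threshold (default 0.5 — half an SD, the same bar used to call an
  emulator accurate).
* `screen` — the incumbent emulators score all offspring; only the best
  keep-fraction (default 0.3) is simulated, the rest discarded unsimulated.

Per-feature emulators inside the GA are independent across features,
trained only on simulator-evaluated rows (emulator-evaluated individuals
carry provenance and are excluded, preventing self-training feedback), and
use the two-stage pipeline automatically when a feature has at least 10
missing and 10 observed training rows. Simulator and emulator call counts
are logged exactly per generation.

## Inference

**Coverage.** Fraction of held-out responses inside the closed central-90%
interval [q05, q95]; widths reported absolutely and in units of the test
SD. Only GP-family emulators support it. Calibration is verified under the
model's own assumptions (test responses drawn from the fitted predictive
distribution); real-data coverage can of course be worse when the model is
misspecified.

**Sobol sensitivity.** Saltelli paired sampling (A, B, and one hybrid
matrix per input) over the box-uniform input distribution, with the
Jansen-form estimators of the first-order index S_j and total index T_j,
applied to emulator posterior means. The base sample defaults to a power
of two (1024). Two standard-normal noise-control columns can be appended
to the inputs; they cannot affect the output by construction, so their
estimated indices display the Monte-Carlo noise floor next to the real
factors. Indices are reported clipped at zero with raw values retained.
The input distribution is pluggable in principle (a posterior would be the
natural choice after an optimization run); box-uniform is the default
because nothing better is available a priori.

**Main effects.** Fix one input on a grid, average emulator predictions
over Monte-Carlo draws of the others.

## What the synthetic conditions do and do not show

The stand-in reproduces the *structure* of the real problem: 31 bounded
inputs with a minority of influential ones, ~20 output features per
individual across weak/strong protocols, structural missingness tied to
spike events, bi-modal inter-spike features, deterministic outputs, and
GA populations that concentrate over generations. It does not reproduce
multi-compartment morphology, ion-channel kinetics, or the real feature
covariances, so passing tests demonstrate the correctness and internal
calibration of the machinery — not that any particular accuracy number
carries over to a specific compartmental model.

One empirical property of desk-scale runs deserves emphasis: the final
best score of a 30-generation run is a heavy-tailed random variable — runs
differing only in seed span a ~4–6× range of final bests, in every
evaluation mode and at population 200 and 300 alike. Surrogate-assisted
modes match full simulation *in distribution* (split-mode medians agree
with full-simulation medians within a few percent), but any two individual
runs, however paired by seed, can differ by a factor of two or more: the
GA is chaotic, and near the missingness boundary a single classifier error
worth ±20 score units flips a tournament and the trajectories part ways.
Comparisons between evaluation strategies should therefore be made on
aggregates over seeds, never on single paired runs.

Desk-scale defaults used by the test suite and the acceptance script:
GA property checks run at population 200 for 30 generations with dt =
0.2 ms (the grid-refinement invariant shows <1% feature change vs halved
dt); emulation accuracy runs at 1000 individuals (800/200 split), d = 31.

## Known limitations

* The treed models are greedy single-tree approximations; they understate
  predictive uncertainty at partition boundaries.
* GPllm's greedy pass can miss jointly-optimal flag sets; it is order-
  dependent by construction (index order, documented).
* The missing-feature penalty makes the global score discontinuous at the
  missingness boundary; gradient-based refinement of GA output would need
  a smoothed score.
* laGP refits per prediction site; it is meant for large-n regimes and is
  slower than the dense GP below n ≈ 2000.
* Coverage and quantiles assume a Gaussian predictive law; no conformal
  or distribution-free intervals are provided.
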