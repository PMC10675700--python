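# Methods

## The inversion problem

Surface temperature measured by infrared thermography tracks core body
temperature only loosely: convective and evaporative heat loss couple the
skin reading to ambient temperature, humidity and (through its correlation
with activity and lighting regime) illuminance. `sowtherm` implements a
*temperature inversion model*: a regressor mapping the tuple
(AT, RH, AI, T_vulva) — ambient temperature in °C, relative humidity in %,
illuminance in lux, and the vulva-region surface temperature in °C — to the
rectal (core) temperature in °C. The vulva is used as the thermal window
because it is exposed, well perfused and visible from behind a gestation
crate.

The regressor is a random forest whose hyperparameters are tuned by a
genetic algorithm with *fitness-adaptive* crossover and mutation rates
(AGA-RF). The forest contributes robustness to the contaminated IR
readings (sensor glitches, animal movement); the adaptive GA replaces
manual hyperparameter selection.

## Random forest

Trees are CART regression trees grown greedily on bootstrap resamples of
size n drawn with replacement. At each node a feature subset of size
`ceil(max_features · p)` is redrawn, every midpoint between consecutive
distinct sorted values of each candidate feature is scored by
sum-of-squared-error reduction, and the best split wins; ties break toward
the lowest feature index, then the lowest threshold, which makes tree
growth fully deterministic given its seed. Recursion stops at `max_depth`,
when a child would drop below `min_samples_leaf`, or at zero target
variance; a candidate split must improve SSE by more than 1e-12 to be
accepted (guards against vacuous splits on numerically constant targets).
Leaves predict their training-target mean, and the forest averages over
trees, so predictions can never leave the training-target range.

The builder runs under numba with an explicit node stack; the randomness
contract is a single root seed from which a bootstrap stream and per-tree
split-subsampling seeds are derived — no global random state.

## Adaptive genetic algorithm

Genomes are tuples over a finite grid (`SearchSpace`), one gene per forest
hyperparameter. Fitness of a genome is `1/(1 + MSE_cv)` with MSE_cv the
k-fold cross-validated MSE of a forest built from the genome (folds depend
only on the run seed, so all genomes see the same folds; forest seeds mix
in a genome digest). This maps model quality to (0, 1], which roulette
selection and the adaptive ratios below both require; the choice of
fitness functional form is this package's, as is the whole evaluation
plumbing — only the adaptive-rate equations are fixed by the method.

With `f_max` the population maximum fitness, `f̄` the mean, `f′` the
fitter parent of a crossover pair and `f` the fitness of the individual
being mutated:

    Pc = k1 (f_max − f′)/(f_max − f̄)   if f′ ≥ f̄,   else k2
    Pm = k3 (f_max − f) /(f_max − f̄)   if f  ≥ f̄,   else k4

Notes on the corner cases, all exercised by tests:

* The boundary `f′ = f̄` (or `f = f̄`) belongs to the *adaptive* branch,
  where the ratio equals 1 and the rate equals `k1` (resp. `k3`). The
  piecewise form is discontinuous there (`k1` vs `k2`); it is implemented
  as printed, not smoothed.
* A degenerate uniform population (`f_max − f̄ < eps`, default 1e-12)
  makes the ratio 0/0; the implementation returns the exploratory
  constants `k2`/`k4`, since exploration is the safe resolution when the
  population carries no gradient information.
* A fresh crossover offspring has no fitness of its own yet when its
  mutation rate is needed; it inherits `f′` (the fitter parent) as its
  reference fitness, while uncrossed copies keep their own. This is a
  design choice; the equations do not specify it.
* Under these equations high-fitness individuals receive *low* crossover
  and mutation rates — their genes are preserved; below-average
  individuals are churned. Defaults k1 = k2 = 0.9, k3 = k4 = 0.1.

One generation: copy the `elitism_count` best unchanged; fill the rest by
roulette selection of pairs, single-point crossover with probability Pc,
and per-gene uniform resampling with probability Pm; population size is
constant, and with elitism ≥ 1 the best-so-far fitness is non-decreasing.
The search returns the best genome ever evaluated, and `fit_aga_rf`
refits it on the full training data.

Two search grids ship with the package: the broad default
(n_trees 50–500 step 50, depth 3–20, leaf 1–10, features {0.3, 0.5, 0.7,
1.0}; 7200 genomes) and a compact grid for desk-scale experiments
(n_trees {25, 50, 100}, depth {4, 8, 12, 16}, leaf {1, 2, 4, 8},
features {0.5, 0.75, 1.0}; 144 genomes). The acceptance experiments use
the compact grid with population 10, 5 generations and 3-fold CV —
problem sizes chosen so the whole study runs on one CPU in minutes while
still leaving the GA a nontrivial landscape (the grid's best and worst
genomes differ severalfold in CV error).

## CBAM forward computation

The attention module that sharpens vulva localisation in the upstream
segmentation networks is provided as pure array math on supplied weights
(no training, no framework). Channel attention pools a C×H×W map globally
(average and max per channel), pushes both vectors through a shared
bottleneck MLP (ReLU hidden activation — the canonical choice, as the
source formulation is silent), and combines through the sigmoid σ in one
of two variants: `as_printed` sums two sigmoids (range (0, 2));
`standard` applies σ to the summed MLP outputs (range (0, 1), the
canonical form). Which variant the original trained networks used is
unknowable from the text, so both are first-class and `as_printed` is the
default for fidelity. Spatial attention stacks the channel-wise average
and max maps and cross-correlates them with a single 7×7 kernel under
zero padding 3, stride 1 (the only setting that preserves H×W), then σ.
Refinement is multiplicative: F′ = mc ⊙ F, output = ms ⊙ F′, so the
element-wise output magnitude is bounded by 2|F| (`as_printed`) or |F|
(`standard`).

## Synthetic data generator

The farm dataset (environment loggers + IR camera + rectal thermometer)
is not deposited, so the generator emulates its structure:

* Rectal temperature: truncated normal, mean 38.6 °C, SD 0.4 °C, clipped
  to the physiological range [37, 41] °C.
* Environment: uniform AT 5–30 °C, RH 40–90 %, AI 50–500 lux. These
  ranges are plausible for an enclosed house over an autumn–winter trial,
  but are *placeholders*, not measured facts.
* Surface coupling (declared plumbing — the true relationship is unknown):

      t_vulva = t_rectal − b_core − b_at·max(0, t_rectal − at)
                − b_rh·(rh/100) + b_ai·log1p(ai) + ε

  with defaults b_core = 2 °C (core-to-surface offset), b_at = 0.1
  (heat-loss slope per °C of core–ambient gradient; deliberately weak so
  the surface reading remains an informative proxy), b_rh = 0.5,
  b_ai = 0.05, and ε Gaussian IR noise.
* Sensor noise defaults follow the instrument accuracies of the
  acquisition hardware: σ = 0.3 °C ambient, σ = 3 % RH, and the IR
  camera's ±2 °C read as a ~2σ envelope, i.e. σ = 1 °C (configurable;
  the noise-floor experiment uses σ = 0.2 °C).
* Outliers: a seeded `round(n · outlier_fraction)` subset gets its vulva
  reading shifted by ±3 °C (sign seeded) and flagged, mimicking
  equipment glitches and posture changes that corrupt the IR reading but
  not the rectal reference.

What the generator does **not** emulate: sow-level autocorrelation and
circadian rhythm, heteroscedastic noise, occlusion by crate bars,
non-uniform environment joint distributions, or any illness dynamics.
Passing tests therefore demonstrate the correctness and statistical
behaviour of the machinery under the assumed structure — not field
accuracy on real animals.

Thermal scenes are an elliptical warm plateau on a cool background plus
Gaussian noise. A pixel (i, j) is inside the ROI iff
`((j−cx)/ax)² + ((i−cy)/ay)² ≤ 1` in pixel-center coordinates (0-based,
row-major, boundary inclusive).

## ROI temperature extraction

The mask is resampled to the matrix grid by nearest-neighbour with
pixel-center alignment (output pixel i′ reads input `floor((i′+0.5)·H/H′)`;
equidistant ties go to the larger index), then the masked pixels are
reduced to one statistic. The default is **max** — conventional for
thermal windows and robust to partial occlusion — with mean and arbitrary
percentiles exposed, because which statistic the original pipeline used is
unstated. Missing pixels (`nan`) are excluded; a mask whose finite
selection is empty is an error, never a silent fallback.

## Dataset split

Seeded shuffle, then `floor(n·r_train)` / `floor(n·r_val)` / remainder —
deterministic and exhaustive; 8:1:1 by default.

## Metrics

IoU by pixel counting (two empty masks score 1.0 by vacuous agreement —
a case the evaluation data never produces but the code must define); MSE,
MAE, R² in their standard forms. MSE is reported as °C² (`mse_c2` keys)
even though field reports often label it °C. Two typographic artifacts of
the printed formulas are deliberately not reproduced: an MAE printed
without absolute-value bars (which would be mean signed error) and a
garbled R² numerator symbol; the standard forms are implemented.

## Pipeline and determinism

`run_pipeline` chains simulate → ROI extraction → split → fit/tune →
predict → evaluate. Every artifact embeds a SHA-256 hash (truncated) of
the canonical config; all randomness derives from the single config seed;
timestamps in generated records follow a fixed 10-minute cadence from a
nominal trial start rather than the wall clock. Consequently two runs of
the same config produce byte-identical models, predictions and metrics;
wall-time appears only in the run report. Feature order is fixed as
(at_c, rh_pct, ai_lux, t_vulva_c), and features are min-max normalised on
the training split only (a documented convention — trees are
scale-invariant, but the stored normaliser keeps the model file
self-contained if another regressor is swapped in).

## Known limitations

* The generator's coupling is a stand-in; conclusions about real sows
  require the real acquisition chain.
* The GA evaluates fitness sequentially; no parallel evaluation.
* The forest has no out-of-bag machinery, classification mode or feature
  importances — none are needed by the inversion method.
* CBAM is forward-only; the segmentation networks it belongs to are out
  of scope, so IoU here scores synthetic threshold segmentations, not a
  learned segmenter.
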