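# Methods

## Statistical model of the data

A trial record is one yield observation (bushels/acre) of genotype *g*
at location *l* in year *t*, together with the environment's daily
weather block: 7 variables × 214 days (April 1 – October 31).  Records
sharing (location, year) share one weather block.  The package treats
yield as

y = μ + year + location + genotype + f(weather) + G×E + ε,

where f is learned by the networks and G×E denotes
genotype-by-environment interaction.  Nothing in the pipeline assumes
this additive form — it is what the synthetic generator produces and
what the recovery tests exploit.

## Preprocessing

* **4-day aggregation.** Each 214-day series becomes 53 period means.
  214 = 52·4 + 6, so periods 1–52 average consecutive 4-day windows
  and period 53 averages the remaining 6 days (209–214).  Folding the
  2 leftover days into the last period keeps all data while producing
  the canonical 53-period layout; a mean-conservation identity
  (weights 4,…,4,6 over 214) is tested.
* **z-scoring.** Per-column mean and *population* (divisor-n) standard
  deviation, fitted by default on training rows only so that
  validation/test information cannot leak into the scaling; a global
  fit is available (`norm_scope="all"`).  Zero-variance columns are
  flagged and map to 0.
* **One-hot encoding.** Year, location and genotype blocks in a fixed
  registry order.  Unseen categories encode as all-zeros in their
  block — the contract for scoring genotypes or environments absent
  from the registry.  Maturity group is parsed and carried but never
  featurized; the selection task deliberately ignores it because
  maturity classes differ by region.
* **Combination split.** Unique (genotype, location) combinations are
  shuffled under a seed and cut 60 / 20 / 20 (the 40% remainder is
  halved into validation and test).  Any genotype then missing from
  training is repaired by moving the combination holding its first
  occurrence (dataset row order, validation searched before test)
  wholesale into training.  Masks therefore partition rows, no
  combination spans two splits, and every genotype trains; repair only
  ever grows the training set.

## Network architectures

Both regressors read three streams: the standardized (7 × 53) weather
block, the concatenated one-hot vector ("other"), and optionally a
standardized 66-column soil block.

* Seven parallel 1-D convolution branches (shared layout, separate
  weights), valid padding, ReLU.  Default stack per branch:
  (8 filters, kernel 9, stride 1) → (12, 3, 2) → (16, 3, 2), reducing
  53 periods to a 16×10 feature map.  These numerals are package
  defaults chosen to compress the 53-period series into a compact map;
  they are fully overridable in `ArchitectureSpec`.
* **CNN variant:** branch outputs are flattened, concatenated and
  passed through a dense layer (default 1,024 units, ReLU; also a
  declared default).  The one-hot stream passes one dense layer of
  2,048 units with Leaky ReLU (slope 0.3, configurable).  Streams
  concatenate into a 3,200-unit dense layer and a scalar head.
  Dropout 0.5 / 0.7 / 0.2 after the post-conv dense layer, after the
  "other" dense layer, and before the output layer.
* **CNN-LSTM variant:** branch feature maps are concatenated along
  channels and transposed time-major — a sequence of 10 steps × 112
  channels — into a 128-unit LSTM whose last hidden state summarizes
  the season.  The "other" dense layer has 1,596 units, the combined
  dense 1,280.  Dropout 0.5 / 0.5 / 0.7 / 0.2 on the conv output, the
  LSTM state, the "other" stream and before the output.
* **Soil branch:** dense 512 units, Leaky ReLU, dropout 0.5,
  concatenated with the other streams.  State-level soil (11
  properties × 6 depths) is constant within a state, so its resolution
  is coarse by construction.

The layers (Conv1D, LSTM, Dense, Dropout, rectifiers) and the Adam
optimizer are implemented directly in numpy with hand-derived
backward passes; every gradient is verified against central finite
differences in the test suite (skipping evaluations whose ± steps
cross a rectifier kink, where the difference quotient is undefined).
Weights use He/variance-scaling initialization under the run seed;
inference disables dropout and is deterministic.

## Training protocol

Adam, initial learning rate 4·10⁻⁴ with a staircase decay of ×0.96
every 2,500 steps, batch size 48, MSE loss, minibatches sampled with
replacement from the training rows under the config seed.  The
full-scale protocol is 100,000 iterations; desk-scale runs in the
tests and the acceptance script use 1,200–2,500 iterations with the
compact architecture (conv filters 4/6/8, 16 LSTM units, dense widths
32–64), which trains in tens of seconds on one CPU while still
recovering genotype rankings (Spearman ≈ 0.99 against generator truth)
and causal weather windows.  A non-finite loss aborts with a
diagnostic rather than continuing.

## GEM ensemble

Simplex-constrained least squares over base-model validation
predictions: minimize mean squared error subject to w ≥ 0, Σw = 1.
Solved by SLSQP from the uniform start with an analytic gradient
(ftol 10⁻¹²), then guarded by the convex-program guarantee: if the
returned point is ever worse than the best vertex, the best vertex
(lowest model index on ties) is returned, so the fitted ensemble MSE
never exceeds the best base model's MSE on the fitting set.  An
exhaustive simplex-grid oracle (k ≤ 3) exists purely for verification;
solver-vs-oracle agreement within 10⁻⁴ is part of the acceptance
checks.  Weights are fitted on validation predictions only and applied
unchanged elsewhere.

## Permutation importance

Baseline RMSE r₀ is computed once on the test split against the GEM
ensemble.  For each group, one random row-permutation is applied
jointly to all of the group's columns (keeping one-hot blocks valid
and weather periods coherent) and the RMSE change is averaged over
repetitions (default 10; single-shot available).  Per-group RNGs are
keyed by group name so results are independent of evaluation order.
Groups: year / location / genotype / seven weather variables (/ soil),
or 53 single-period groups per weather variable for localization.

## Synthetic generator

The generator emulates the structure the method assumes:

* Unbalanced availability: each (location, year) cell is observed with
  probability `availability_fraction`; `genotypes_per_env` genotypes
  are sampled per observed environment without replacement, with full
  genotype coverage enforced (redraw, then a deterministic repair that
  swaps over-represented entries; infeasible slot budgets raise).
* Additive Gaussian effects with configurable sds — defaults genotype
  4, location 8, year 4, G×L interaction 2, residual 5 bu/ac around a
  base yield of 50.66 bu/ac, giving overall yield variability of the
  order seen in large soybean MET datasets (sd ≈ 11–16 bu/ac).
* Weather: a per-variable sinusoidal seasonal curve peaking mid-season
  with hand-set plausible means/amplitudes, plus three scaled noise
  components per environment — a season-constant offset, a smooth
  within-season anomaly interpolated from 8-day knots, and day-level
  noise.  The knot anomaly is what lets distant 4-day periods
  decorrelate across environments; with a season-constant offset
  alone, all 53 periods of a variable move in lockstep and a
  period-localized causal window would be unidentifiable in principle.
* Window effects: yield responds linearly (β bu/ac per standardized
  unit) to the mean of a variable's standardized 4-day period means
  over a named period range — the same granularity the models consume,
  so importance recovery aligns with preprocessing.  Defaults place an
  irradiance (MDNI) window at periods 24–26 (around flowering) and a
  precipitation (AP) window at periods 18–20 (vegetative growth).
* The stored truth records every effect, the observed environment
  list and the window standardization constants, so oracle predictors
  can reproduce the noise-free yield of any record (including novel
  genotype-environment combinations).

What the generator does **not** emulate: spatial weather correlation
between locations, climate cycles, maturity-group-dependent phenology,
non-Gaussian yield tails, and measurement artifacts.  Passing recovery
tests therefore demonstrates that the pipeline's machinery is correct
and sensitive under its own assumptions — not that the trained desk
models match field-scale accuracy on real trial data.  Simulated
yields are not truncated at 0 by default (configurable), since the
default effect scales make negative yields vanishingly rare.

## Selection

The candidate pool is the full genotype registry (not just genotypes
historically planted at a location), matching exhaustive per-record
prediction; a planted-only restriction can be applied by passing a
reduced registry.  Ties in the ranking break by genotype identifier.
Gap reports are offered per environment and aggregated per state-year
(both groupings, since the natural aggregation is a judgment call);
gaps are signed and never clipped.

## Numerical and design choices

* Population-sd convention in the z-score (immaterial at n in the
  tens of thousands; fixed for determinism).
* Pearson r raises on constant inputs instead of returning 0 — silent
  zeros would corrupt report tables.
* Float64 throughout the networks; exactness matters more than speed
  at desk scale and makes gradient checks sharp.
* All randomness flows through seeded `numpy.random.Generator`
  instances recorded in artifacts; repeated runs are bit-identical on
  one device.

## Known limitations

* Desk-scale training budgets under-fit relative to the 100,000-step
  protocol; reported desk metrics characterize the pipeline, not the
  attainable accuracy ceiling.
* The LSTM backward pass is a straightforward BPTT loop — adequate for
  10-step sequences, not tuned for long ones.
* State-level soil adds little signal by construction (constant within
  state), mirroring the coarse resolution of state-keyed soil tables.
* The CLI holds the full feature matrix in memory; at the full trial
  scale (≈93k × 6,381) this is a few GiB in float64.
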