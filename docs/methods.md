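# Methods

## The model

`basisimpute` fills missing entries of a multi-station series (rows = time
steps at a uniform cadence, columns = monitoring locations, typically
particulate-matter concentrations in µg/m³) one fixed-length window at a
time. A window is a `T × N` matrix `X` with an aligned binary mask `M`
(1 = observed). The model eliminates four components in sequence, and the
sum of the eliminated parts is the imputation:

1. **Bias.** `h_bias[j] = Σ_t X[t,j]·M[t,j] / Σ_t M[t,j]` — the masked
   per-station mean, computed in closed form. Missing entries are filled
   with this bias before the first subtraction, so the subsequent blocks
   see exactly 0 at unobserved positions and never need the mask.
2. **Slope.** A scalar coefficient `θ⁽²⁾`, produced by a five-layer
   fully connected encoder (hidden width 64, leaky-rectifier slope 0.2)
   reading the flattened previous output, multiplies the centred window
   grid `v = [−T/2, …, T/2−1]/T`: `h_slope = θ⁽²⁾ v`.
3. **Seasonality.** An 8-vector `θ⁽³⁾` from a second encoder weights four
   sine/cosine harmonic pairs: `h_season = Σᵢ₌₁⁴ a_i sin(2πi v) + b_i
   cos(2πi v)`, with `(a_i, b_i)` consecutive entries of `θ⁽³⁾`. The
   harmonics have fixed periods `T, T/2, T/3, T/4`.
4. **Residual.** A 256-vector `θ⁽⁴⁾` from a third encoder passes through
   the leaky rectifier and an affine head onto a free `T × N` matrix.

Slope and seasonality are shared across stations (broadcast); only the bias
and the residual are station-specific. After each block, `X⁽ˡ⁾ = X⁽ˡ⁻¹⁾ −
h⁽ˡ⁾`; training drives the final remainder toward zero and `Ŷ = Σ h⁽ˡ⁾` is
the imputation. Every component is exposed, so an analyst can read off how
much of an imputed value is level, trend, diurnal-style periodicity, or
unexplained structure.

### Grid normalisation

On the raw integer grid, `sin(2πiv)` vanishes identically and `cos(2πiv)`
is 1, so the Fourier block would be degenerate. The bases are therefore
evaluated on the normalised grid `v/T` (periods `T/i` in raw steps), which
is the convention of interpretable basis-expansion forecasting models.
`integer_grid=True` restores the literal grid for comparison.

### θ⁽³⁾ indexing

With an 8-vector, pair indices `2i`/`2i+1` for `i = 1..4` would address
nine slots; the implementation pairs consecutive entries
`(a_i, b_i) = (θ_{2i−1}, θ_{2i})`.

## Training

Training is self-supervised masked reconstruction: per iteration, each
window in the batch is (a) jointly shift/scale augmented — with probability
0.25 add `s ~ U(0,10)` to input and target, independently with probability
0.25 multiply both by `f ~ U(0,3)` — and (b) stripped of a further 20% of
its *observed* entries (exact count, uniform). The loss is the mean
absolute error between `Ŷ` and the original values over **all originally
observed** positions — dropped ones included, which is what makes
restoration learnable; originally missing positions never contribute
(perturbing them leaves the loss bit-identical). Optimisation is Adam
(`lr = 1e−5`, `β₁ = 0.9`, `β₂ = 0.999`), batch size 512, master seed 42;
the whole trajectory is reproducible from the seed.

Early stopping watches a fixed validation set of held-out windows whose
extra 20% injection is drawn once from the seed; the metric is the masked
MAE of the *restored injected* entries, and training stops after 5 epochs
without improvement (best-validation weights are returned).

The forward pass, the loss gradient and Adam are implemented directly on
numpy arrays; the hand-derived backward pass is verified against central
differences in the test suite.

### What counts as an epoch

With production-sized archives an epoch (one pass at batch 512) is hundreds
to thousands of optimiser steps, and "patience 5" spans a meaningful
stretch of optimisation. The desk-scale studies here have ~100 windows, so
a literal pass is a *single* step and patience would fire after 5 steps —
long before the small, fixed learning rate can converge. `TrainConfig.
steps_per_epoch` therefore sets how many steps form an epoch (default
`None` = one literal pass); the shipped studies use 250 steps per epoch so
the patience rule keeps its intended meaning. Because every iteration
re-draws augmentation and injected missingness, the training stream is
effectively unbounded and the epoch is purely the validation interval.

### Initialisation

Hidden layers use He-style initialisation scaled for the leaky rectifier.
The final layer of each encoder starts at zero, so every coefficient — and
hence every learned component — is exactly zero at initialisation and the
fresh model is precisely the per-station masked-mean imputer. The residual
*head* must **not** also start at zero: with both the encoder output
`θ⁽⁴⁾ = 0` and a zero head, the head gradient (`∝ leaky(θ⁽⁴⁾) = 0`) and
the gradient reaching the encoder (`∝ W_head = 0`) vanish simultaneously
and the block is permanently frozen at a constant. The head is therefore
He-initialised; `h_resid` is still exactly zero at the start.

### Degenerate inputs

A window with no observed entry at all is an error. A single station with
no observed entry in a window gets bias 0, i.e. a neutral all-zero
post-bias representation. Ties in the masked-MAE subgradient use
`sign(0) = 0`.

## Synthetic scenarios

The monitoring datasets the model targets are access-restricted, so the
package ships a generator whose ground truth is exact:
`x[t,j] = bias_j + slope·g(t) + Σᵢ aᵢ sin(2πi g(t)) + bᵢ cos(2πi g(t)) +
ε[t,j]`, where `g` maps each position onto the model's normalised window
grid, and `ε` is zero-mean Gaussian with standard deviation `noise_sd` and
equicorrelation `ρ` across stations (the simplest structure with tunable
spatial dependence for the spatial-average baseline to exploit).
Missingness is exact-count MCAR, so scored-entry counts are deterministic.

Presets: `constant`, `linear`, `seasonal`, `combined` (N = 10, 6000
minutes, station biases 30–50 µg/m³, slope 6 per window, harmonic
amplitudes 6/4/3/2/2/1/1/1, noise sd 2, ρ = 0.6, 12% natural missingness —
a realistic archive rate), `combined-noisefree`, and
`period-mismatch` (seasonality of period 90 ≠ 60/i steps, deliberately
outside the model's fixed basis). Values stay strictly positive, as
concentrations must.

What the generator does *not* emulate: heavy-tailed pollution spikes,
nonstationary daily/annual cycles, station dropout in contiguous blocks,
and sensor-specific calibration drift. Tests passing on these scenarios
show the machinery is correct and the protocol behaves as designed — not
that the model handles every property of real monitoring data.

## Evaluation

True values behind natural missingness are unknowable, so accuracy is
measured by removing an extra exact-count 20% of the *observed* test
entries completely at random, imputing from the doubly-masked series, and
scoring only the removed entries:

- `MAE = (1/B) Σ |ŷ − y|` (µg/m³),
- `sMAPE = (1/B) Σ |ŷ − y| / ((ŷ + y)/2) · 100%`, with a `0/0` term
  defined as 0; for nonnegative data it lies in [0, 200] and is invariant
  under joint rescaling.

Baselines: **Mean** (global observed-training mean) and **SA** (spatial
average: same-timestamp mean of the observed stations, falling back to the
training mean for an all-missing row). The SA definition follows its prose
description — mean of the *observed* entries — rather than a literal
`(1/N) Σ x_{ij}(1−m_{ij})`, which divides by the wrong count and selects
the complement. A slot for any external chained-equations imputer with the
same `transform` contract can be passed to `evaluate_protocol`; none is
bundled.

### Readout condition

Encoder outputs scale with the observed fraction of their input (a window
with fewer zeros produces proportionally larger sums), so coefficients are
read out under the same input condition the model is trained and evaluated
in — natural missingness plus the 20% artificial drop. On inputs with less
missingness than the training condition the coefficients run
systematically high, roughly in proportion to the extra observed
fraction; this is a property of the method worth knowing when
interpreting decompositions of lightly masked data.

## Study protocol and problem sizes

`studies.run_study` chains the pipeline end to end: generate a scenario,
apply natural MCAR, split chronologically (leading 80% of rows for
self-supervised fitting with an internal window-level validation split,
trailing 20% as the test period), fit, then run the artificial-masking
evaluation against the baselines. The shipped studies use the scenario
sizes above with 250 optimiser steps per epoch and an epoch cap of 60
(the reference hyperparameters `lr`, batch, patience, β, seed are never
altered); study runs use float32 parameters, which roughly halve the cost
of an optimiser step.

### Attribution is only weakly identified

The linear grid `v` is strongly collinear with the sine harmonics on a
centred window (the Fourier expansion of the identity is a pure sine
series), and the residual head's offset can carry any fixed per-window
pattern. Nothing in the objective penalises shifting trend between the
slope, seasonality and residual blocks, so the *attribution* — unlike the
sum — is only weakly identified: with very long optimisation the slope
coefficient slowly drains into the other blocks. The shipped studies use
a fixed budget (60 epochs × 250 steps) at which the slope readout tracks
the generating trend; decompositions from much longer runs should be read
with this caveat in mind.

## Known limitations

- Fixed-period harmonics cannot represent seasonality at other periods;
  on the `period-mismatch` scenario the seasonality block fits poorly and
  the residual block must compensate. This is inherent to the fixed basis.
- One slope and one seasonal curve are shared by all stations; per-station
  trends end up in the residual.
- Windows are processed independently; no information crosses window
  boundaries, and a trailing partial window reuses the last full `T` rows
  (only its novel tail is written back).
- Observed values pass through unchanged at inference by default; the
  literal use-`Ŷ`-everywhere behaviour is available via
  `overwrite_observed=True`.
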