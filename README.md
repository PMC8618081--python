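# basisimpute

Interpretable missing-value imputation for multi-station environmental
time series.

Continuous monitoring networks — for example particulate-matter
(PM2.5/PM10) sensors reporting every minute from dozens of locations —
routinely lose observations to sensor faults and transmission errors, and
the gaps appear across many stations at once. Black-box imputers can fill
the gaps but give an analyst no way to see *why* a value was filled in.
`basisimpute` implements a deep-but-interpretable alternative: a network
that decomposes each one-hour window of the multi-station series into four
additive, human-readable components and imputes with their sum.

## The model

For a window `X ∈ R^{T×N}` (T time steps, N stations) with observation
mask `M`, four blocks sequentially *eliminate* structure, each block
subtracting its component from what the previous block left behind
(`X⁽ˡ⁾ = X⁽ˡ⁻¹⁾ − h⁽ˡ⁾`):

| block | component | form |
|---|---|---|
| bias | `h_bias ∈ R^N` | masked per-station mean `Σ_t x_{tj} m_{tj} / Σ_t m_{tj}` |
| slope | `h_slope = θ⁽²⁾ v` | shared linear trend on the centred grid `v = [−T/2..T/2−1]/T` |
| seasonality | `h_season = Σᵢ₌₁⁴ aᵢ sin(2πi v) + bᵢ cos(2πi v)` | shared fixed-period Fourier curve |
| residual | `h_resid ∈ R^{T×N}` | free-form remainder |

Each learned coefficient (`θ⁽²⁾` scalar, `θ⁽³⁾ ∈ R⁸`, `θ⁽⁴⁾ ∈ R²⁵⁶`) is
produced by its own five-layer fully connected encoder (hidden width 64,
LeakyReLU 0.2) reading the flattened output of the previous block. The
imputation is `Ŷ = h_bias + h_slope + h_season + h_resid`.

Training is self-supervised: an extra 20% of each window's observed
entries is dropped every iteration and the model minimises the masked MAE
of reconstructing all originally observed values (Adam, lr 1e-5, batch
512, early stopping on a held-out window set). Because the real
monitoring archives this model was designed around are access-restricted,
the package ships a synthetic generator with known
bias/trend/seasonality/noise structure and MCAR missingness for all
studies and tests.

## Worked example

```python
import numpy as np
from basisimpute import (
    BasisDecompositionImputer, MeanImputer, SpatialAverageImputer,
    apply_mcar, generate_series, get_preset, evaluate_protocol,
)

# ten stations, 6000 minutes, shared trend + seasonality, correlated
# noise, 12% of entries missing completely at random
spec = get_preset("combined")
series = generate_series(spec)
masked, _ = apply_mcar(series.values, spec.missing_rate, seed=8)

train, test = masked[:4800], masked[4800:]
model = BasisDecompositionImputer(max_epochs=60, steps_per_epoch=250,
                                  dtype="float32").fit(train)

report = evaluate_protocol(
    test,
    {"model": lambda X: model.transform(X),
     "spatial_average": SpatialAverageImputer().fit(train),
     "mean": MeanImputer().fit(train)},
    extra_rate=0.2, seed=9,
)
print(report)
```

Output from this exact run:

```
artificial-masking protocol: rate=0.2, seed=9, n_scored=2118
         method   mae  smape error
          model 1.781  4.720
spatial_average 6.391 16.564
           mean 8.031 20.472
```

2118 observed test entries were removed at random and re-predicted. The
decomposition model reconstructs them to 1.78 µg/m³ mean absolute error
(4.7% symmetric percentage error) — close to the scenario's irreducible
noise level —
while the spatial-average baseline pays for between-station offsets (6.39)
and the global-mean baseline ignores all temporal structure (8.03). The
same `Ours < SA < Mean` ordering holds for both metrics.

`model.decompose(X)` returns a long-format table
(`window_id, t, station, component, value`) with the per-window bias /
slope / seasonality / residual curves, their sum, the masked input and the
mask — everything needed to plot cumulative component fits.

## Command line

```bash
basisimpute simulate --scenario combined --out data/
basisimpute train    --data data/data.csv --out model.npz -v
basisimpute impute   --data data/data.csv --ckpt model.npz --out filled.csv \
                     --export-decomposition decomp.csv
basisimpute evaluate --data data/data.csv --ckpt model.npz --rate 0.2 \
                     --seed 3 --out report.csv
basisimpute decompose --data data/data.csv --ckpt model.npz --out decomp.csv
```

Scenario presets: `constant`, `linear`, `seasonal`, `combined`,
`combined-noisefree`, `period-mismatch` (seasonality the fixed basis
cannot represent — the model's documented limitation).

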