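# phenoyield

Plot-level maize grain-yield modelling from multi-modal UAV remote sensing
— hyperspectral reflectance, LiDAR canopy structure and weather time series
— with genotype-stratified cross-validation, attention-based growth-stage
interpretation, and a synthetic trial generator with planted ground truth.

## Who this is for

Plant-phenomics and breeding-analytics groups who fly UAVs over trial
fields through the season and want to (a) predict end-of-season grain yield
per plot from the resulting time series and (b) understand *when* in the
season each sensing modality actually informs the prediction. Breeding
trials replicate each hybrid only a handful of times, so the pipeline
stratifies its cross-validation by genetic cluster and excludes the
replicated check hybrids from training and testing.

## The model

Per plot and acquisition date the inputs are reduced to fixed feature
vectors: 9 hyperspectral features — band-range integrals
∫S(λ)dλ over 670–780 nm and 910–1000 nm, the integral of dS/dλ over the
NIR, and the indices VOG3, NDRE, MCARI2, DATT3, PSRI, RDVI — plus 7 LiDAR
canopy metrics (P75, P90, quadratic mean height Q = √(Σxᵢ²/n), 8 cm column
voxel volume, canopy cover above the 20th/50th/75th percentile heights) and
3 cumulative weather variables (GDD, precipitation, radiation).

Three stacked-LSTM architectures consume the resulting
plots × dates × features tensors:

| model | fusion | interpretation |
|---|---|---|
| `VanillaLSTMModel` | early (per-date concatenation) | — |
| `AttentionLSTMModel` | early | per-(date, feature) additive attention, softmax-normalized per plot |
| `MultimodalFusionModel` | late (sigmoid fusion of per-modality attention branches) | per-branch attention maps |

Training: Adam (lr 0.001), MSE on min-max-scaled yields, dropout 0.2,
early stopping on validation MSE. Accuracy is reported as R²_ref
(1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)², i.e. against the 1:1 reference line) and RMSE,
per cross-validation fold on the independent test split and on the complete
dataset. Averaging each plot's attention over features per time-step gives
a temporal importance profile per modality — the growth-stage
interpretation.

The networks run on a small numpy reverse-mode autodiff engine bundled as
`phenoyield.nn`; there is no deep-learning-framework dependency.

## Worked example

Generate a 300-plot synthetic trial whose yield signal spans the season
(LiDAR structure early, chlorophyll dynamics later), train the attention
model, and read off accuracy and temporal importance:

```python
import numpy as np
from phenoyield.experiments import prepare_trial
from phenoyield.models import AttentionLSTMModel, ModelConfig
from phenoyield.evaluate import r2_ref, rmse, temporal_importance
from phenoyield.simulate import full_season_profiles

ds, y, tensors, train, val, test = prepare_trial(
    seed=7, n_plots=300, importance_profile=full_season_profiles(7))
model = AttentionLSTMModel(
    y, tensors, ModelConfig(seed=7, max_epochs=400, patience=80, batch_size=32))
res = model.fit(train, val)
print(res.summary())
pred = res.predict(plot_idx=test)
print(f"test R2_ref: {r2_ref(y[test], pred):.3f}")
print(f"test RMSE:   {rmse(y[test], pred):.2f}")
print("temporal importance:", np.round(temporal_importance(res.attention()).values, 3))
```

Output (about half a minute on one CPU):

```
AttentionLSTMModel results
========================================
architecture:      attention
parameters:        16561
epochs run:        158
best epoch:        77
best val MSE:      0.004755 (scaled units)
train plots:       200
validation plots:  28
test R2_ref: 0.845
test RMSE:   4.31
temporal importance: [0.19  0.213 0.151 0.17  0.116 0.097 0.064]
```

The model explains 84.5% of held-out yield variance (the trial's noise
level caps the attainable R² at 0.9) with a 4.3-unit RMSE on yields of mean
150, and the attention mass sits on the early-to-mid season dates where the
planted signal lives. `res.attention()` returns the full per-plot
(date × feature) weight maps; `phenoyield.evaluate.cross_validate` runs the
5-fold genotype-stratified protocol and `render_report` writes the
mean ± sd tables and profile figures.

A thin CLI wraps the library for quick runs:

```bash
phenoyield simulate --out trial/ --plots 500 --seed 1
phenoyield run --arch multimodal --scenario 1 --plots 300 --seed 1
```

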