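# droughtfire

Drought-characteristic-driven modelling of gridded forest-fire occurrence
probability, with spatially varying coefficients.

Forest-fire regimes respond to drought differently from place to place: in
humid, fuel-rich regions drought dries fuels and promotes fire, while in arid,
fuel-limited regions drought suppresses the vegetation that carries fire.  A
single global regression hides this.  `droughtfire` implements the full chain
needed to study the question on a lon/lat grid of cells:

1. **SPEI** — the Standardized Precipitation Evapotranspiration Index at 1-,
   3-, 6- and 12-month scales.  The climatic water balance `D = P − PET`
   (Thornthwaite PET from monthly mean temperature) is accumulated over `k`
   months and mapped to a standard-normal deviate through a per-calendar-month
   three-parameter log-logistic distribution fitted by unbiased
   probability-weighted moments.
2. **Run-theory drought events** — maximal runs of `SPEI ≤ −0.5` (light) or
   `≤ −1.0` (mid drought) lasting ≥ 3 months, each with duration
   `DD = DTT − DIT`, severity `DS = Σ SPEIᵢ` and intensity `DI = DS/DD`, and
   per-period aggregates `MDN = n/y`, `MDD`, `MDS`, `MDI`.
3. **Covariates** — terrain roughness `R = Z_max − Z_min`, network density
   `δ = L/F`, min–max normalization to `[0, 1]`, VIF collinearity diagnosis,
   and PCA of the four (nearly collinear) drought characteristics retaining
   components to ≥ 90 % cumulative variance, with stored loadings reused for
   future periods.
4. **GLR / GWLR** — the per-cell fire probability `FP` (fraction of years with
   at least one fire) is modelled as binomial with logit link,
   `logit(P) = β₀(u,v) + Σ βₖ(u,v) xₖ`.  The geographically weighted model
   refits the likelihood at every location with an adaptive bi-square kernel
   `w = (1 − (d/b)²)²`, bandwidth chosen by minimizing
   `AICc = AIC + 2k(k+1)/(m−k−1)`.
5. **Evaluation** — held-out AUC (Mann–Whitney, midrank ties), Brier score,
   AICc.
6. **Projection** — future drought characteristics per SSP scenario and
   period, pushed through the *stored* PCA/normalization into the fitted local
   coefficients; forest-masked regional mean probability changes.

A seeded synthetic-data module generates a full gridded world (seasonal
climate with an AR(1) wetness anomaly, smooth static covariates, spatially
sign-flipping true coefficient surfaces, Bernoulli fire records) so every
stage is testable without any data download.

## Worked example

```python
from droughtfire.config import RunConfig, ScenarioSpec
from droughtfire.pipeline import run_pipeline

cfg = RunConfig(seed=1, n_lon=10, n_lat=10, scales=[1, 3], model_scale=3,
                scenarios=[ScenarioSpec(name="SSP126", trend=-0.3),
                           ScenarioSpec(name="SSP585", trend=1.5)],
                n_ensemble_members=2)
res = run_pipeline(cfg)
print("bandwidth", res.model.bandwidth)
print(res.report)
print(res.projections[("SSP585", "near")].regional)
```

prints (seed 1):

```
bandwidth 64
EvalReport(auc=0.8433441558441559, p_value=4.327817545603444e-09,
           brier=0.18061493437162146, aicc=443.0198181903349,
           train_period=(2000, 2019), test_period=(2020, 2021), note='')
  region  n_cells  mean_delta_pp
0      C        7       5.106753
1      E       13       3.404427
2      N        3      -0.563910
3     NE       10      -0.589081
4     NW       12       1.492412
5      S        9       3.930191
6     SW        8       6.039324
```

The AICc-selected adaptive bandwidth is 64 nearest neighbours; the fitted
model separates held-out fire and no-fire cells with AUC 0.84 (well above the
0.75 bar for a useful probability model); and under the strongly drying
SSP585 scenario the near-term regional mean fire-probability changes range
from −0.6 to +6.0 percentage points relative to the modelled historical
probability, varying by region block as the planted south-promoting /
north-inhibiting coefficient structure dictates.

The same run is available from the shell:

```bash
droughtfire all --config run.yaml      # stages: simulate spei drought
                                       # features fit evaluate project
```

Each stage writes CSV/JSON artifacts plus a manifest carrying the config
hash; rerunning with the same config reproduces every output byte-for-byte.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole analysis from scratch at the default configuration —
synthetic world, SPEI at all four scales, both drought thresholds,
AICc-selected GWLR, held-out evaluation, and four-scenario ensemble
projections — and logs the bandwidth, AUC/Brier/AICc and regional
probability-change ranges to stderr.
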