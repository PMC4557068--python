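# sedfire

Regional reconstruction of Holocene biomass burning from networks of
sedimentary charcoal records, and millennial-scale attribution of the
burning history to climate, vegetation and human drivers.

`sedfire` is written for paleoecologists and paleofire scientists who
work with lake-sediment charcoal series, fossil pollen and gridded
paleoclimate/population products. It implements a complete, tested
pipeline of the kind used to study eastern North American fire history
over the last 7000 years across four vegetation zones (open coniferous
forest/tundra, closed boreal coniferous forest, boreal mixedwood
forest, temperate forest), together with a synthetic-data module that
generates inputs with known embedded effects so that every stage of the
pipeline has a parameter-recovery test.

## What it computes

**Charcoal compositing.** Each record's concentrations (particles
cm⁻³) are converted to charcoal accumulation rates using its age-depth
model, CHARᵢ = cᵢ·Δdᵢ/Δtᵢ (particles cm⁻² yr⁻¹), then standardised
within record by minmax rescaling to [0, 1], a Box-Cox transform
y = ((x+ε)^λ − 1)/λ with λ fitted per record by grid maximum
likelihood over [−2, 2], and a Z-score. Standardised records are
averaged in non-overlapping 10-yr bins and the *sites* are bootstrap
resampled 999 times; each pooled draw is smoothed with a
fixed-bandwidth tricube local-linear smoother (half-widths 500 and
200 yr), giving a composite mean and a percentile confidence band
(90% by default, 95% supported).

**Pollen → biomass (MAT).** Per tree genus (Abies, Acer, Betula,
Picea, Pinus, Populus), modern pollen spectra are paired with the mean
remote-sensed biomass within a source-area radius of each surface
sample; the radius is chosen per genus by maximising leave-one-out
predictive R² over a 1–150 km candidate sweep, and the number of
analogues k by bootstrap train/test RMSEP. Fossil assemblages within
100 km of a charcoal site are then predicted as the mean biomass of
their k nearest modern analogues under squared-chord dissimilarity,
and the conifer/broadleaf biomass ratio is tracked against its
long-term (7000-yr) mean.

**Drivers.** Seasonal (MAM/JJA) temperature and precipitation
anomalies against the pre-industrial state, extracted as 100-km-buffer
means around sites for two GCM variants; human population density as
the summed HYDE-like pixel counts within 100 km divided by
πr² ≈ 3.14 × 10⁴ km².

**Attribution.** All series are downsampled to millennial resolution
and stacked into a region × millennium panel (4 × 8 = 32 rows),
centred to zero mean by region. Each driver's unique contribution to
biomass burning is the semipartial Spearman rank correlation
sr(y, x·Z): rank(x) is residualised on the ranks of the remaining
drivers Z and correlated with rank(y); significance uses the t-test of
the unique contribution with n − 2 − g degrees of freedom. One-component
PLS regression exposes the functional form of significant
relationships.

## Worked example

Run the full synthetic study — charcoal records, modern/fossil pollen,
biomass grid, climate and population grids are generated with a known
negative summer-precipitation effect on log fire intensity — and
attribute the resulting composite burning curves:

```python
from sedfire import synth, TransformParams
from sedfire.pipeline import run_study

cfg = synth.SynthConfig(seed=1)          # 15 sites/zone, effect P_summer = -1.0
study = run_study(cfg, TransformParams(n_boot=999))
print(study["attribution"]["hadcm3like"].to_string(index=False))
```

```
               variable      model     sr  p_value  n  significant
conifer_broadleaf_ratio hadcm3like -0.107    0.257 32        False
           tree_biomass hadcm3like  0.091    0.334 32        False
            pop_density hadcm3like  0.159    0.097 32        False
               T_spring hadcm3like -0.159    0.097 32        False
               T_summer hadcm3like -0.182    0.060 32        False
               P_spring hadcm3like -0.207    0.034 32         True
               P_summer hadcm3like -0.723    0.000 32         True
```

The injected driver (summer precipitation, true effect negative) is
recovered with a strong negative sr and p < 0.001, while the null
drivers hover near zero; `study["composites"]` holds the per-zone
burning curves with their confidence bands (for seed 1 the boreal
mixedwood composite spans 801 10-yr bins with a mean 90%-CI width of
0.136 Z-score units).

The same pipeline is scriptable from the shell:

```bash
sedfire synth generate --seed 9 --out bundle/
sedfire validate bundle/
sedfire composite run --bundle bundle/ --zone temperate --seed 3 --out comp.csv
sedfire mat calibrate --bundle bundle/ --seed 3 --out-dir mat/
sedfire drivers build --bundle bundle/ --out drivers.csv
```

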