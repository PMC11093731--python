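# defolicarbon

Quantify insect-defoliation impacts on forest productivity and carbon
uptake from satellite surface-reflectance time series — the computational
chain behind studies of the 2021 spongy-moth (*Lymantria dispar*) outbreak
in the Canadian Great Lakes region, packaged as a tested, reusable
pipeline that runs end-to-end on synthetic scenes with no data download.

It is aimed at ecosystem remote-sensing and carbon-cycle researchers who
want each stage as a composable, unit-tested operation:

1. **Radiative transfer** (`defolicarbon.radiative_transfer`): a
   generalized plate leaf model coupled to a four-stream canopy model
   produces top-of-canopy reflectance on the 400–2500 nm grid; sensor bands
   are the response-weighted means Σρψ/Σψ (Sentinel-2-like blue/red/NIR/SWIR
   by default).
2. **LAI retrieval** (`lai_retrieval`): lookup-table inversion of band
   reflectance to leaf area index over [0, 8] with an RMS-residual cost,
   plus growing-season statistics.
3. **Productivity** (`vegetation_productivity`): a light-use-efficiency
   model, GPP = PAR · fPARchl · ε₀ · T_scalar · W_scalar · 12.011 with
   fPARchl = (EVI − 0.1)·1.25, T_scalar = (Ta−Tmin)(Ta−Tmax)/
   [(Ta−Tmin)(Ta−Tmax) − (Ta−Topt)²] and W_scalar = (1+LSWI)/(1+LSWImax),
   with ε₀ calibrated as the through-origin regression slope against
   eddy-covariance tower GPP.
4. **Time series** (`timeseries_stats`): weighted double-logistic fitting
   (y = f₁ + f₂ − max(c₁+d₁, c₂+d₂)), daily reconstruction with residual
   re-injection, and standardized anomalies y_sd = (y_d − ȳ_d)/σ.
5. **Land cover** (`landcover`): pluggable SVM classification of six cover
   classes and confusion-matrix accuracy metrics.
6. **Carbon accounting** (`carbon_accounting`): growing-season totals
   (Apr 1–Oct 31), percent reductions against pre/post-disturbance years,
   per-hectare losses (t C ha⁻¹) and regional upscaling (Mt C).
7. **Synthetic scenes** (`synthetic_scene`): land-cover rasters, per-class
   phenology with a prescribed mid-season defoliation notch, reflectance
   rendered through the forward model plus noise, meteorology and tower GPP.

## Worked example

Recompute the headline defoliation-impact numbers from published
growing-season statistics (seasonal GPP totals in g C m⁻², mean LAI in
m² m⁻², for 2020/2021/2022):

```python
from defolicarbon.carbon_accounting import (
    percent_reduction, mean_reduction, per_hectare_loss, regional_upscale,
)

# deciduous forest: GPP totals 1338 / 868 / 1367, mean LAI 3.66 / 2.74 / 3.53
print(percent_reduction(1338, 868))            # 35.13  -> "35% GPP reduction vs 2020"
print(percent_reduction(1367, 868))            # 36.50  -> "36% vs 2022"
r = (percent_reduction(3.66, 2.74), percent_reduction(3.53, 2.74))
print(r, mean_reduction(*r))                   # (25.14, 22.38) 23.76 -> "~24% LAI loss"
print(per_hectare_loss(1338 - 868, 1367 - 868))  # 4.845 -> "4.84 t C/ha"
print(regional_upscale({"deciduous": 470, "mixed": 276},
                       {"deciduous": 36574, "mixed": 23936}))  # 23.80 Mt C vs 2020
```

Run the full synthetic-infestation experiment (64 × 64 scene, three years,
~20 observation dates per season, a 25%/17% prescribed seasonal LAI
depression in deciduous/mixed classes in the middle year):

```python
from defolicarbon.pipeline import run_pipeline
from defolicarbon.synthetic_scene import SceneConfig

result = run_pipeline(SceneConfig(seed=1))
print(result.epsilon0)                         # 0.0500 (calibrated quantum yield)
print(result.report[["class_name", "gpp_reduction_vs_pre_pct",
                     "lai_reduction_mean_pct"]].round(2))
```

```
    class_name  gpp_reduction_vs_pre_pct  lai_reduction_mean_pct
0  agriculture                      0.52                   -0.05
1      conifer                     -0.10                   -0.00
2    deciduous                     14.28                   24.70
3        mixed                      9.64                   16.66
```

The retrieved LAI depressions (24.7%/16.7%) recover the prescribed
25%/17%; the deciduous GPP reduction (14.3%) matches the scene's true
reduction (14.5%, smaller than the LAI signal because fPARchl saturates at
high EVI); unaffected classes sit at zero.  The same run is available from
the shell:

```bash
defolicarbon run --config config.yaml --out results/
defolicarbon report --results results/
```

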