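# daisel

**BLUP-based drought adaptation index (DAI) selection pipeline for
multi-environment single-plant yield trials.**

`daisel` is aimed at plant breeders and quantitative geneticists screening
large germplasm panels (the motivating case: 404 switchgrass genotypes grown
under a rainout-shelter drought treatment, CV, and an irrigated control, UC,
over four years) who need to turn noisy per-plant biomass yields into a
ranked, classified set of drought-adapted genotypes. It covers the full path
from raw plot records to selection decisions:

1. **Curation** — drop yields below 50 g·plant⁻¹, flag outliers whose
   median-absolute-deviation distance `|x − median| / (1.4826 · MAD)`
   exceeds 6, report Shapiro–Wilk and QQ diagnostics per year × treatment.
2. **Spatial adjustment** — a 2-D thin plate spline (basis `r² log r`,
   smoothing chosen by generalized cross-validation) over field (row,
   column); adjusted yield = grand mean + spline residual.
3. **BLUP engine** — per year × treatment the random-genotype mixed model
   `y_ij = μ + g_i + ε_ij`, `g_i ~ N(0, Vg)`, fitted by REML; repeatability
   `R = Vg / (Vg + Ve)`; yield-scale predictions `μ̂ + ĝ_i` assembled into a
   genotype × environment matrix (environments `CV19 … UC22`).
4. **Stress indices** — the DAI plus nine classical indices per genotype-year:

       DAI = (Y_CV · Y_UC) / (Ȳ_CV · Ȳ_UC)
       SSI, TOL, MP, GMP, STI, YSI, YI, HM, DSI

   with year-wise Pearson correlation matrices among indices and across-year
   DAI stability correlations.
5. **Adaptation classes** — DAI isoline thresholds
   `C1_k = (Ȳ_CV + k·s_CV)(Ȳ_UC + k·s_UC) / (Ȳ_CV·Ȳ_UC)` at SD levels
   k = 0, 1, 2 (`C1_0 = 1` by construction) cut the panel into
   very well-adapted / well-adapted / adapted / unadapted.
6. **AMMI** — two-way ANOVA plus SVD of the double-centred interaction:
   IPCA axes with Gollob degrees of freedom `g + e − 1 − 2k`, √λ-scaled
   scores, biplot coordinate export; missing cells imputed with the
   environment-column minimum.
7. **GGE** — environment-centred SVD with configurable singular-value
   partitioning and the four analytical views: which-won-where (convex hull
   + sector winners), mean vs stability along the average-environment
   coordination (AEC) axis, ideal-genotype ranking, environment
   discrimination/representativeness.

A synthetic-trial generator with known ground truth (`daisel.simulate`)
reproduces the study design — grids of 7 × 58 (CV) and 14 × 29 (UC) per
block, three blocks, right-skewed residuals, smooth spatial trend, missing
plants and filler positions — so every stage is testable without field data.

## Worked example

Run the whole pipeline on a simulated study-scale trial:

```sh
daisel all --out-dir demo --seed 7
```

This simulates 404 genotypes × 2 treatments × 3 blocks × 4 years
(~9,700 plants), curates, spatially adjusts, and fits the eight
environments. The variance-component summary it prints (also written to
`demo/variance_components.csv`):

```
 year treatment        Vg        Ve    R
 2019        CV 298123.08 220293.26 0.58
 2020        CV 284094.47 311834.06 0.48
 2021        CV 289080.02 243125.99 0.54
 2022        CV 289530.84 251048.30 0.54
 2019        UC 317552.33 218232.29 0.59
 2020        UC 280677.78 267318.18 0.51
 2021        UC 288368.93 263444.29 0.52
 2022        UC 345693.85 347075.24 0.50
```

`R ≈ 0.5` means about half the plot-level phenotypic variance is genetic —
consistent with the simulator's true `Vg/(Vg+Ve) = 400000/700000 ≈ 0.57`
after curation and spatial adjustment. `demo/c1_thresholds.csv` holds the
isoline constants (2019: `C1 = 1, 1.54, 2.21`; level 0 is always exactly 1),
and `demo/classes.csv` the classification — for 2019: 207 unadapted, 145
adapted, 45 well-adapted, 7 very well-adapted genotypes, with 1 genotype
very well-adapted in all four years. The GGE stage reports

```
PC1+PC2 explain 81.63% of G+GE variation
```

together with the winner per environment from the which-won-where view.
Every stage can also be run separately (`daisel simulate | curate | spatial
| blup | indices | classify | ammi | gge`) on its input/output CSVs; see
`daisel --help`.

## Documentation

`docs/methods.md` describes the statistical methods, default parameters,
what the simulator does and does not emulate, and known limitations.
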