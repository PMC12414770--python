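# Methods

This note documents the statistical procedures implemented in `daisel`,
the defaults chosen where the underlying methodology left the design open,
and the limits of what the synthetic-data tests demonstrate.

## Data model

One observation is a single plant: genotype, year, treatment (CV =
covered/drought, UC = uncovered/irrigated control), block, 1-based field
(row, column), and masses in grams. Per-plant dry yield is estimated from
the whole-plant fresh weight and an oven-dried subsample:
`dry_yield = fresh_weight · subsample_dry / subsample_fresh`. Missing
values are empty CSV fields; zero is a measurement. Filler (border) plants
are carried through files but excluded from every statistic. Coordinates
are taken as given — the package never assumes blocks are contiguous or
non-overlapping in (row, col).

## Curation

Yields below 50 g·plant⁻¹ are removed first ("below" read strictly, so a
50 g plant is kept); such plants reflect failed establishment rather than
genotype performance. Outliers are then screened on the filtered data — in
that order, so the sub-threshold spike cannot drag the median — using the
MAD distance `|x_i − med| / (c · MAD)` with cutoff 6. The scale constant
defaults to the normal-consistency value c = 1.4826; c = 1 (raw MAD) is a
config option because either convention is defensible and they differ only
in how the cutoff is calibrated. Screening is done within each
year × treatment group (configurable): pooling environments would confound
level shifts between environments with genuine outliers. Shapiro–Wilk
(scipy's Royston approximation) and normal QQ coordinates at plotting
positions (i − 0.5)/n are reported per group for diagnostics only — the
pipeline never gates on normality, relying on BLUP shrinkage instead of a
transformation.

## Spatial adjustment

Per year × treatment field, a thin plate spline with basis `r² log r` and
an affine null space is fitted to yield over (row, col), minimising
`Σ(y − f)² + λJ(f)`. Implementation: project the kernel onto the
orthocomplement of the affine design (QR), eigendecompose once, and reuse
the eigenvalues for every λ; effective degrees of freedom are
`tr A(λ) = n − λ Σ 1/(d_k + λ)`. λ is chosen by GCV,
`n·RSS/(n − tr A)²`, on a 40-point log-spaced grid spanning ten orders of
magnitude around the mean kernel eigenvalue, ties broken toward the
smoother fit. λ → ∞ recovers the best affine surface; λ = 0 interpolates
distinct points.

Adjusted yield = grand mean of the field + spline residual, which
preserves the field mean to machine precision (the residuals sum to zero
because the intercept lies in the null space). "Mean per plot" is read as
the grand mean of the fitted dataset — plots are single plants, so there
is no within-plot mean to use. By default one surface is fitted per field
with all blocks pooled; per-block surfaces are a flag. Records whose
adjustment would go negative are clipped at zero (yields are masses).

## Mixed model, BLUP and repeatability

Per environment: `y_ij = μ + g_i + ε_ij`, genotype random, no block term —
the spatial adjustment is assumed to have absorbed field effects (a
fixed-block variant would be a sensitivity analysis, not the default).
REML estimation profiles the criterion down to the variance ratio
γ = Vg/Ve, for which the per-genotype quadratic forms are closed-form; a
bounded deterministic scalar search (tolerance 1e-10 on log γ, bounds
1e-8…1e8) finds the optimum, which is compared against the γ = 0 boundary
so `Vg ≥ 0` always holds. On balanced data this coincides with the ANOVA
estimator `Vg = (MSG − MSE)/r` truncated at zero (verified to 1e-6
relative in tests, and against statsmodels/lme4 on unbalanced data).

BLUPs are `ĝ_i = [Vg/(Vg + Ve/n_i)](ȳ_i − μ̂)`; predictions are on the
yield scale, `μ̂ + ĝ_i`, because every downstream index is a function of
yields. Repeatability is `R = Vg/(Vg + Ve)` on the single-plot basis —
Ve is *not* divided by the replicate count — matching how the reference
variance-component table combines its columns; the mean-basis variant is
available (`mean_basis=True`) but off by default.

## Stress indices

All ten indices (DAI, SSI, TOL, MP, GMP, STI, YSI, YI, HM, DSI) are
computed from BLUP-predicted values, not raw means, and per year. Two
renderings were genuinely ambiguous and are resolved as follows:

* **DAI** defaults to the product form
  `(Y_CV·Y_UC)/(Ȳ_CV·Ȳ_UC)` without a square root. The geometric-mean
  variant (`sqrt=True`) is implemented but not default: isoline threshold
  constants near 4.8 at SD level 2 arise naturally from the product form
  with yield CVs around 0.6, whereas the sqrt form would compress them
  toward √4.84 = 2.2.
* **YI** defaults to `Ys/Ȳp` (non-stress grand mean in the denominator) as
  printed in the index compilation followed here; the more common
  `Ys/Ȳs` is available via a flag. Within a year the two variants differ
  only by a positive constant, so genotype rankings are identical.

SSI is undefined (reported missing, logged) when the stress and
non-stress grand means coincide. Division by zero anywhere yields a
missing cell, never an exception, so one degenerate genotype cannot abort
a year. Correlation matrices use the complete-observation policy: only
genotypes with all ten indices enter. Year-to-year DAI stability is the
Pearson correlation over genotypes present in both years of each pair
(missing if fewer than 3 shared).

## Isolines and adaptation classes

The threshold constant at SD level k is
`C1_k = (Ȳ_CV + k·s_CV)(Ȳ_UC + k·s_UC)/(Ȳ_CV·Ȳ_UC)` with sample SDs
(n − 1), computed on the same BLUP-predicted values used for the DAI. This
product form is an inference from observable behaviour of the published
constants (level 0 equals 1 in every year; levels 1–2 scale like the yield
coefficients of variation); it is isolated in one function and
flag-switchable (population SD, raw-yield moments) should the exact
original definition be published. Classification: DAI ≥ C1_2 → very
well-adapted; C1_1 ≤ DAI < C1_2 → well-adapted; C1_0 ≤ DAI < C1_1 →
adapted; below C1_0 → unadapted. Boundaries are closed from below so the
classes are exhaustive and classification is monotone in DAI. Isoline
curves are the level sets `Y_UC = C1·Ȳ_CV·Ȳ_UC / Y_CV`, exported as
coordinate CSVs.

## AMMI

The BLUP matrix is completed by imputing each missing cell with its
environment-column minimum (a deliberately conservative fill that cannot
create winners), then decomposed: main-effect sums of squares from the
margins, SVD of the double-centred residual for the interaction.
Conventions, chosen to reproduce the internal arithmetic of the reference
ANOVA table:

* axis df follow Gollob, `g + e − 1 − 2k` (29 and 27 at 24 × 8);
* scores are scaled by √λ on both sides, so each side's squared scores sum
  to λ and the squared sum of squared scores recovers the axis SS;
* F ratios: genotypes and environments against the interaction MS, each
  IPCA against the AMMI-residual MS — there is no plot-level error term in
  a matrix of predictions, so textbook error-based tests are unavailable;
* each axis's sign is fixed by making the largest-magnitude environment
  score positive (SVD signs are arbitrary; published tables may differ by
  a global per-axis flip);
* a zero denominator MS (perfectly additive or exactly low-rank input)
  leaves the F ratio as missing rather than infinite.

## GGE

Environment-centred (column-mean) SVD, no scaling. Singular-value
partitioning defaults: symmetric for which-won-where, genotype-focused for
mean/stability and ideal-genotype views, environment-focused for
environment ranking — the conventional pairing; all configurable. All
views are 2-D and always report the PC1+PC2 variance fraction; a rank-1
solution is padded with a zero second axis so the geometry stays defined.
Which-won-where: sector boundaries are the outward normals of the convex
hull edges (equivalently, the directions where two vertices tie on inner
product), environments on a boundary join the counter-clockwise sector,
and every winner equals the genotype maximising the score inner product
with that environment — asserted exhaustively in tests.

## Synthetic trials

The generator reproduces the study design (404 genotypes, CV 7 × 58 and UC
14 × 29 per block, 3 blocks, 4 years) with an additive gram-scale model:
environment means (μ = 1800 g, treatment gap 250 g, year effects
±300 g — magnitudes anchored to the reference environment means), genotype
effects `N(0, Vg = 400 000)`, low-rank GEI (outer products, per-cell SD
150 g, rank 1 by default so AMMI recovery has known truth), a smooth
random cosine-mixture surface per block (SD 300 g, length scale 8 plants),
and shifted-lognormal residuals re-centred to mean zero with variance
`Ve = 300 000` (σ = 0.8), giving the right-skewed marginals seen in field
biomass data. Plants go missing at 5% and become fillers; blocks are laid
side by side along the column axis with a 2-column gap so coordinates are
globally unique. One integer seed drives everything through spawned
substreams; a (config, seed) pair regenerates the trial bit-identically.

What the simulator does **not** emulate: spatial correlation of residuals
beyond the smooth trend, genotype-specific missingness (mortality is
independent of genotype), year-to-year carry-over in perennial stands,
treatment-dependent error variance, and the discreteness of real harvest
workflows. Passing parameter-recovery tests therefore demonstrates
correctness of the estimators under the stated generative model, not
robustness to every field pathology.

Test and acceptance runs use down-scaled configurations (24–150 genotypes,
1–3 blocks, reduced grids) — the package's own choice of desk-scale
problem sizes; the full study-scale pipeline runs in well under a minute.

## Numerical choices and degenerate inputs

* TPS kernel eigenvalues are clipped at zero (the kernel is conditionally
  positive definite up to round-off); λ = 0 with duplicated coordinates is
  rejected.
* REML search is deterministic (no random starts); `Vg = 0` is returned
  whenever the boundary criterion is at least as good as the interior
  optimum.
* MAD = 0 (majority-tied data) flags nothing and warns — the distance is
  undefined.
* Matrix CSVs round-trip bit-identically (shortest-representation floats
  on write, `float_precision="round_trip"` on read).
* AMMI residual SS is floored at zero against cancellation.

## Known limitations

* No multi-environment joint mixed model, pedigree/kinship, or spatial
  correlation inside the LMM; the spatial spline and the genotype model
  are sequential, not joint.
* No anisotropic or row/column (AR1×AR1) spatial models.
* The C1 functional form is an inference (see above).
* GGE axis-significance is not tested formally; mega-environments are
  descriptive.
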