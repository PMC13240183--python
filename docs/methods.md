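# Methods

This note documents the models implemented in `thetaprime`, their assumptions,
the parameter defaults and why they were chosen, the design choices made where
the design was genuinely open, and the limits of what the synthetic tests
establish.

## 1. The photoacclimation model and the stress index

The observed carbon-to-chlorophyll ratio Θ_obs = C_phyto/Chl
(mgC mgChl⁻¹) mixes two physiological signals: acclimation of cellular
pigment to the mixed-layer light environment, and down-regulation of
chlorophyll synthesis when nutrient supply suppresses division rate. The
light component is modeled as a deep-mixing baseline times a shallow-mixing
correction,

Θ_photo = Θ_DM · ΔΘ_SM,  ΔΘ_SM = (1 + e^(−0.15·PAR)) / (1 + e^(−3·I_ML)),
I_ML = PAR·e^(−K_PAR·MLD/2),

and the nutrient-stress index is Θ′ = Θ_photo/Θ_obs. Θ_photo is computed
mechanistically from light and mixing fields only, so it is statistically
independent of Θ_obs; their ratio isolates the nutrient signal. Lower Θ′
means stronger stress.

Key properties, all enforced by tests:

- ΔΘ_SM ∈ (0, 2], equals 1 at PAR = 0 and, for any PAR, exactly at
  K_PAR·MLD = 2·ln(20) ≈ 6 optical depths — the deep-mixing criterion emerges
  from the algebra rather than being imposed.
- As printed, the expression gives ΔΘ_SM < 1 for mixing much deeper than six
  optical depths (moderate PAR), i.e. Θ_photo below the baseline. Whether the
  original model clamps the correction there is ambiguous, so both readings
  are exposed: the default evaluates the expression at all MLD;
  `clamp_deep_mixing=True` pins ΔΘ_SM = 1 beyond 2·ln(20) optical depths.
- Θ_DM defaults to 150 mgC mgChl⁻¹ (a mission-mean constant) and is a config
  value, never re-estimated from data.

Profile-derived quantities use ordinary linear interpolation: nutricline
depth Z_NO3 is the shallowest crossing of the 3 μM nitrate horizon (surface
already ≥ 3 μM → 0 m; never reached → an `inf` sentinel meaning "absent",
deliberately distinct from NaN missing data, because an absent nutricline is
an observation). Mixed-layer depth uses the 0.03 kg m⁻³ density-threshold
criterion referenced to 10 m (a common hydrographic convention; configurable);
profiles that never cross are reported bottom-limited at the deepest level.
The K_490 → K_PAR conversion uses the Morel-style polynomial
K_PAR = 0.0864 + 0.884·K490 − 0.00137/K490 (valid for K490 ≳ 0.016 m⁻¹, i.e.
all ocean water) and can be bypassed when K_PAR is supplied directly.

## 2. The chemostat simulation and the choice of formulation

`thetaprime.chemostat` reconstructs the argument for the ratio formulation
with a two-endmember Chl:C mixture,

Chl:C(I, f) = chlc_dark·e^(−I/b) + f·chlc_sat·(1 − e^(−I/b)),

where f is the relative nutrient-regulated division-rate multiplier (f = 1 is
the nutrient-limited baseline), chlc_dark = 0.05 mgChl mgC⁻¹ is the single
value all nutrient conditions converge to as irradiance → 0 (division is
entirely light-limited there), chlc_sat = 0.01 is the baseline value at
saturating light, and b = 75 μmol photon m⁻² s⁻¹ sets the photoacclimation
transition so that curves are effectively light-saturated near
i_sat = 200 μmol photon m⁻² s⁻¹. Division rate is
μ = f·μ_sat·min(1, ramp(I/i_sat)) with μ_sat = 0.75 day⁻¹ and a saturating
exponential ramp normalized to reach 1 at i_sat exactly.

This parametric form was chosen over a literal "baseline plus f-scaled
departure from the dark value" combination because the latter cannot satisfy
positivity, convergence at I = 0, *and* Chl:C increasing with nutrient supply
simultaneously once f > 1; the mixture satisfies all three, and makes the
central result an algebraic identity: Θ′(f) = Chl:C(I,f)/Chl:C(I,1) is exactly
linear in f (equal to f when the dark term is negligible), while the inverse
and normalized-difference variants have strictly positive curvature. The
laboratory Chl:C data behind the original figure are not tabulated anywhere,
so only the structural conclusion (linearity vs curvature) is reproduced, not
species-specific values.

## 3. The synthetic ocean

`generate_scene` builds a latent stress field

S(x,t) = g(Z(x)) · seasonal(x,t) · mode(x,t) · (1 + ρ(x)·t) · fast(x,t)

and then *derives* the observables from it: Θ_photo from seasonally cycling
PAR/K_PAR/MLD fields, Θ_obs = Θ_photo/(S·ε) with mean-one lognormal
observation noise ε, and C_phyto = Θ_obs·Chl over a static background Chl
field. Recomputing Θ′ from the observables therefore returns S·ε identically —
the round-trip is exact at noise_cv = 0, and noise-consistent otherwise.

Components and defaults:

- **Nutricline map** Z(x): smooth field, deep (175 m) in subtropical-gyre
  bands, shallow (30 m) at the equator and poleward edges.
- **Stress map** g(Z) = 0.5 + 3.0/(1 + e^((Z−80)/25)): monotone decreasing,
  spanning mean Θ′ ≈ 3.5 over shallow/absent nutriclines down to ≈ 0.5 where
  the nutricline is deeper than 150 m, matching the observed dynamic range.
- **Seasonality**: hemisphere-phased annual cycle (amplitude 0.35, summer
  maximum) plus a tropical semiannual component (0.25) — chosen so the
  seasonal factor carries the majority of the variance, as in the satellite
  record where ~59% of Θ′ variance is seasonal.
- **Climate mode**: one zonal-dipole pattern in the tropics times a
  quasi-periodic index (two incommensurate periods, 3.4 and 5.3 years,
  standardized), amplitude 0.15. `generate_climate_index` resamples it
  monthly and adds AR(1) distractor series (lag-1 autocorrelation 0.5).
- **Trend**: relative slope ρ(x) with mean −0.001 yr⁻¹ and smooth spatial
  spread ±0.003 yr⁻¹; the planted absolute Θ′ slope g(Z)·ρ is stored as
  ground truth. SST carries an independent trend field with mean
  +0.023 °C yr⁻¹.
- **Noise**: `stress_cv` (default 0.15) is a fast per-composite lognormal
  fluctuation *of the latent state* — real stress varies on sub-seasonal
  timescales — while `noise_cv` (default 0.05) is pure observation noise on
  Θ_obs. Both are mean-one lognormals (ratio quantities are scale variables).
- **Sampling**: biomarker samples follow random-walk cruise tracks advancing
  one composite per station (emulating ship-survey spatial autocorrelation);
  a uniform mode exists for unit tests. Ω markers respond logistically to the
  latent stress averaged over a 40-day window (the characteristic
  physiology–genomics equilibration timescale) or to nutricline depth, plus
  Gaussian noise. N-stress markers rise with stress; P- and Fe-markers follow
  the opposing biogeography.
- **Gene tables**: flexible-gene copies per genome respond log-linearly to
  standardized stress with planted coefficients {+0.6, −0.6, 0} (the three
  trait classes); coverage = copies × SCCG mean × lognormal noise, so SCCG
  normalization must undo sequencing depth exactly.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; scenes embed their full spec as a JSON attribute.

What the generator does *not* emulate: ocean dynamics (advection, eddies),
spatially correlated retrieval errors, cloud-driven gap structure, realistic
coastlines (land is rectangular blocks, enough to exercise masking), or
biological covariance beyond the planted logistic rules. Passing the
round-trip tests therefore shows the *pipeline* is correct and calibrated, not
that the index is unbiased on real retrievals.

## 4. Matchups, timescale scan, and forests

`colocate` averages Θ′ (unweighted) over a window from the standard menu —
1×1/3×3/5×5 pixels or 1°/2°/5° boxes, centered on the sample coordinates (not
snapped to pixel boundaries), crossed with temporal half-widths ±2…±30 days —
and reports the contributing-cell count; a fully masked window yields a
missing matchup. Complete-case analysis throughout; no imputation.

Variance explained is the out-of-bag R² of a 500-tree random forest
(scikit-learn `RandomForestRegressor`, library-default split parameters,
fixed seed), with in-bag R² reported alongside for transparency. The
timescale scan fits one forest per window combination and takes the argmax of
out-of-bag R². Out-of-bag was chosen over a train/test split because it uses
every sample and is the default convention of the reference forest
implementations; both are computable from the returned objects.

Gene statistics: copies per genome = coverage / per-sample mean SCCG
coverage; z-scores standardize each gene across samples (ddof = 1); per-gene
Pearson r (+ two-sided p) against Θ′ matched at the 2°×2°/±20-day window.
Correlations are reported raw (no multiple-testing correction), with a
Benjamini–Hochberg flag available downstream if needed.

## 5. Spatiotemporal statistics

- **Detrend/trends**: per-pixel OLS against time in years; slopes, intercepts
  and slope standard errors retained. Domain summaries are the median slope
  and the fraction of pixels with positive slope (unweighted by area; a
  cos-latitude weighting flag is deliberately absent from the default path
  since the analysis domain is 40°S–40°N where weights vary modestly).
- **EOF**: SVD of the demeaned time × space matrix; pixels with > 20% missing
  steps excluded listwise (threshold configurable); modes ordered by variance;
  sign fixed so each mode's largest-|loading| is positive; zero-variance modes
  dropped. Variance fractions sum to 1 over all modes; reconstruction from all
  modes reproduces the input on retained pixels to machine precision.
  Interannual modes are selected by a spectral criterion — periodogram
  dominant period > 1.5 years — rather than by fixed mode number, because the
  ordinal position of climate-mode PCs is dataset-dependent.
- **PSD**: plain periodogram (`scipy.signal.periodogram`), frequencies in
  cycles per year. Note the frequency-bin quantization: a planted period is
  recovered exactly only when it divides the record length.
- **Lowess**: local first-degree weighted regression with tricube weights
  (statsmodels), 20-point window expressed as a bandwidth fraction,
  no robustness iterations — a line passes through unchanged.
- **Variance partition**: 8-day composites are binned to calendar months,
  then each pixel gets a two-factor fixed-effects decomposition (month-of-year
  × year, no interaction). Fractions are factor SS over total SS, computed as
  type-II sums of squares so unbalanced (gappy) pixels are handled and
  balanced designs reduce exactly to the textbook orthogonal decomposition.
  Pixels sharing a missingness pattern are solved in one multi-RHS least
  squares call.
- **Anomalies**: monthly = subtract the pixel's month-of-year climatology
  (anomalies re-averaged by month are exactly zero); annual = calendar-year
  mean minus record mean; phase composites average annual anomalies over a
  user-listed year set (phase year sets are inputs, not detected).
- **Climate-index correlation**: the monthly index is linearly interpolated
  onto PC time stamps (restricted to the overlap) and correlated (Pearson).
- **Regional bootstrap**: pixels classified hemisphere × nutricline class
  (shallower/deeper than 50 m = highNut/lowNut); regional mean trends get 95%
  percentile-bootstrap CIs from 10⁴ pixel resamples. The bootstrap treats
  pixels as independent, ignoring spatial autocorrelation — a documented
  limitation that makes the CIs anti-conservative on strongly correlated
  fields.

## 6. Numerical and scale choices

Desk-scale problem sizes used by the test suite and the acceptance script:
the reference synthetic decade is 40 × 80 pixels × 10 years of 8-day
composites (~1.4 M ocean cells), which resolves the planted seasonal share to
a couple of percentage points and the interannual PC to |r| > 0.95 in well
under a minute per stage. The timescale scan uses 2-day composites over 1.5
years on a 20 × 40 grid so the ±2-day window ladder is actually resolvable,
with the fast stress fluctuation (`stress_cv = 0.4`) dominating the latent
variance — on an 8-day grid adjacent window sizes select identical composite
sets and the argmax is undefined at that resolution. Bootstrap calibration
uses 200 replications of 150-pixel Gaussian slope fields.

Degenerate inputs: single-pixel or single-time scenes are generated with a
warning; all-masked Θ_obs warns rather than fails; constant gene vectors
report NaN correlations; rank-deficient EOF inputs drop zero-variance modes;
ties in the timescale argmax resolve to the smallest window.

## 7. Known limitations

- Θ_photo's deep-mixing behavior is a modeling choice (see §1); the two
  readings diverge only where K_PAR·MLD ≫ 6 optical depths.
- The b_bp443 → C_phyto conversion is out of scope; the pipeline consumes
  C_phyto (or accepts a user-supplied linear stand-in).
- Ω biomarker indices are consumed as inputs; computing them from raw reads
  (trimming, mapping, pangenome clustering) is outside the package.
- EOF significance testing (North's rule, etc.) is not implemented; modes are
  characterized by variance fraction and spectral content only.
- The cruise-track sampler emulates along-track autocorrelation only
  statistically; it does not follow real hydrographic sections.
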