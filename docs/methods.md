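# Methods

This note documents the models behind `surfir`: what the synthetic-data
generator emulates, the statistical procedures, the defaults and why, and
what the tests do and do not establish about real instrument data.

## Signal model of the synthetic spectra

Each lipid is represented by a library of Gaussian absorption bands
ε(ν) = Σ aᵢ exp(−(ν − cᵢ)²/2σᵢ²), with centres placed in the standard
mid-IR assignment regions for surfactant lipids (CH₂ antisymmetric /
symmetric stretches near 2920/2850 cm⁻¹, ester C=O near 1740 cm⁻¹, the
sphingolipid amide I/II at ~1648/1540 cm⁻¹, the phosphate PO₂⁻
antisymmetric stretch at 1240–1260 cm⁻¹ for phospholipids only, P–O–R and
C–O–C modes at 1055–1095 cm⁻¹, and the choline band near 970 cm⁻¹).
Species-specific centre offsets of a few cm⁻¹ within each region mimic
real chemical shifts (gel-phase DPPC's CH stretches sit at the low edge of
the region, unsaturated POPC's a few cm⁻¹ higher, with a weak oleoyl C=C
stretch in the 1650 region). Cholesterol carries neither a phosphate nor
an ester-carbonyl band. Band σ values (5–9 cm⁻¹) give FWHMs comparable to
the assignment-region widths; relative absorptivities are scaled so the
mid-point calibration mixture has a noiseless 2920 cm⁻¹ peak height of
0.210 absorbance at unit route gain.

A measurement of composition **c** under a route model is

```
A(ν) = g · u · Σₗ cₗ εₗ(ν) + b(ν) + e(ν)
```

* `g` — route gain (dimensionless): mean effective signal of the
  preparation route, standing in for film coverage and coupling to the
  ATR evanescent field;
* `u = exp(N(0, s²))` — log-normal multiplicative run (film) effect,
  shared by all scans of one deposition: film thickness/coverage scales
  the whole spectrum;
* `b(ν)` — smooth quadratic per-run baseline drift with configurable
  amplitude;
* `e(ν)` — additive white scan noise.

Noiseless absorbance is therefore exactly linear in every concentration
(Beer–Lambert), which the tests verify by finite differences.

### Default study conditions

The nested repeatability defaults encode the two-route study they emulate:
route gains 1.0441 (solvent route, "DCM-dry") and 2.5207 (aqueous route,
"AQ-dry") make the noiseless mid-point peak heights 0.210 and 0.507;
run-level log-SDs of 0.235 and 0.162 make the within-route CVs of the
2920 cm⁻¹ peak height ≈ 23.5 % and 16.2 %; the scan-noise SD of 2.6 × 10⁻⁴
puts the residual variance component near 6.6 × 10⁻⁸. Under these values
the closed-form variance components are σ²ᵣₒᵤₜₑ ≈ 0.044, σ²ᵣᵤₙ ≈ 0.005,
i.e. a ~90 % route variance fraction — the regime the repeatability
machinery is designed to resolve.

The calibration workflow uses a separate default
(`CALIBRATION_MEASUREMENT_MODEL`, aqueous gain with run-level log-SD
0.05). The reasoning: a *global multiplicative* film effect at the
free-deposition level (16 % CV) would bound any linear calibration of
DPPC — whose whole design range spans only ±12 % about its mean — near
R² ≈ 0, because gain and concentration scale the spectrum identically.
Quantitative calibration protocols control deposition far more tightly
(standards, fixed aliquots, replicate films), so the calibration defaults
assume a 5 % film-scale repeatability while leaving the parameter fully
configurable. At that level the per-lipid difficulty ordering emerges
naturally: S (unique amide band, wide range) and PG (wide relative range)
calibrate best, cholesterol well, DPPC/L moderately, POPC — nearly
collinear with DPPC — worst.

### Mixture designs and cohorts

Calibration compositions live in the five-lipid box DPPC 1.035–1.308,
POPC 0.508–0.632, S 0.273–0.853, PG 0.008–0.333, Chol 0.207–0.310 mM.
The `vertices_plus_center` scheme takes all 2⁵ corner points plus the
mid-point (33 points, topped up with seeded Latin-hypercube fill when more
samples are requested); `latin_hypercube` is a space-filling alternative.
The exact extreme-vertices point set used historically for this domain is
not recoverable, so the corner scheme is a documented substitute with the
same bounds.

Reference cohorts draw true L/S values from truncated normals
(non-RDS: mean 3.0, SD 0.8; RDS: mean 1.6, SD 0.5; truncated below at
0.2), sizes defaulting to 74 non-RDS / 59 RDS. The class locations/scales
are simulator defaults chosen for plausible separation — they are not
measured cohort parameters.

## Preprocessing

Offset (subtract the absorbance at the grid point nearest 2800 cm⁻¹; ties
break toward the higher wavenumber) → truncate to the closed interval
[850, 4000] cm⁻¹ → Savitzky–Golay second derivative (15 points, 3rd
order). The stage order is kept even though a constant offset cannot
survive a second derivative, because the non-derivative intermediate feeds
the quality metrics. Derivatives are taken with respect to wavenumber
(absorbance · cm²)⁻¹-scaled via the physical grid spacing, so features are
comparable across grids; on a descending axis even-order derivatives are
direction-invariant. Edge points use a shrinking-window local polynomial
fit, preserving vector length; interior points are the classical SG
convolution, and both are verified against a brute-force per-point
least-squares oracle. The default grid is 4000–850 cm⁻¹ at 2 cm⁻¹ spacing
(a 4 cm⁻¹-resolution instrument typically exports ≤ 2 cm⁻¹ point
spacing), making the 15-point window span ~28 cm⁻¹ — narrow relative to
lipid bands.

## Quality metrics

Peak height is the window maximum minus a two-anchor linear baseline
evaluated at the argmax (CH window 2935–2905 cm⁻¹, anchors 3000/2800;
carbonyl window 1750–1730, anchors 1780/1700). The anchors are plain
config — the original proprietary peak software's baseline algorithm is
unspecified, and a two-anchor line is the simplest reproducible
operationalisation. RMS noise is the residual RMS about the least-squares
line over the featureless 2200–2000 cm⁻¹ region; SNR is their ratio (and
is undefined, not infinite, at zero noise). %RSD uses the n−1 sample SD.
SNR and %RSD are invariant under positive rescaling of the spectrum.

## Nested ANOVA and variance components

The design is balanced: a routes (fixed), r runs per route (random,
nested), n scans per run (residual). Sums of squares follow the standard
balanced decomposition; F_route = MS_route/MS_run on (a−1, a(r−1)) df and
F_run = MS_run/MS_res on (a(r−1), ar(n−1)) df. Components come from the
EMS relations with truncation at zero. For the fixed route factor the
tabulated "σ²" is the EMS-based quasi-component
max(0, (MS_route − MS_run)/(r·n)) — a reporting convention that lets
variance fractions sum to 100 %, not a true random-effect variance.
p-values are floored at the smallest positive subnormal double (≈ 5 ×
10⁻³²⁴) so that astronomically significant F statistics report a
representable number instead of zero. Unbalanced tables are rejected with
the offending cell named; REML for unbalanced designs is out of scope.

Cohen's d pools the SD over all spectra (n₁+n₂−2 denominator). Whether an
effect size of this kind should be computed over individual scans or run
means is genuinely ambiguous; the per-scan convention is the default and
the run-mean alternative is a caller-side aggregation away.

PCA route separation takes the first right singular vector of the
column-centred matrix of preprocessed (second-derivative) spectra, with
the sign fixed so the largest-magnitude loading is positive, and reports
|d| of the PC1 scores between routes. Second-derivative input is the
default because that is the space the calibration models see; raw spectra
can be passed instead.

## PLSR

Single-response NIPALS: w ∝ Xᵀy, t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then
deflation of X and y. The compact regression vector b = W(PᵀW)⁻¹q
reproduces the sequential predictions (checked to 1 × 10⁻⁸), so a
serialised model is just (x̄, ȳ, b) plus the component vectors. X is
centred but not variance-scaled — second-derivative spectra are already on
a common scale — and scaling remains available upstream. Requesting more
components than the data's effective rank raises an error naming the
maximum usable count.

Latent-variable count is selected by grouped k-fold CV (k = 5 by default;
folds split by sample so replicate scans never straddle a fold),
minimising mean CV MSE (or maximising mean R²; the two agree when fold
target variances are equal), with ties broken toward fewer components;
max_lv defaults to 10. The 80/20 train/test split is likewise by sample.
L is modelled as its own regression target (y = DPPC + POPC), not as the
sum of two model predictions.

## Jackknife+-after-bootstrap intervals

B bootstrap resamples (default 30) are drawn *at the sample level* — the
exchangeable units are physical samples, consistent with sample-wise
splitting — and one PLSR model is fitted per resample. For each training
row, the out-of-bag aggregate (mean of models whose resample excluded that
row's sample) provides a leave-one-out surrogate prediction and an
absolute residual Rᵢ. For a new spectrum, the interval endpoints are the
conservative ⌈(1−α)(n+1)⌉ order statistics of {μ₋ᵢ(x) + Rᵢ} and the
mirrored rank of {μ₋ᵢ(x) − Rᵢ}; the point prediction is the full-ensemble
mean. If some training row is never out-of-bag, resampling continues (same
stream) until every row is, with a logged warning; a resample that cannot
support the requested component count is fitted at its own maximal rank.
Theory guarantees ≥ 1 − 2α coverage under exchangeability; empirically the
method sits near 1 − α, which the test suite and acceptance script
measure (≈ 95 % at α = 0.05 over 50 seeded datasets).

## L/S diagnostics

Component uncertainties are symmetrised by taking the larger of the upper
and lower interval half-widths, then propagated to the ratio by the
first-order quotient rule δ(L/S) = (L/S)·√((h_L/L)² + (h_S/S)²); an
interval-arithmetic alternative (extreme endpoint ratios) is available via
`method="interval"`. Orientation: L/S *below* 2.2 is the test-positive
(RDS-risk) call. A case whose closed interval [L/S − h, L/S + h] contains
the threshold is indeterminate; the grey zone around the cut-off is
(2.2 − h, 2.2 + h) with h the mean test-set ratio half-width (per-case
intervals are also supported). Intention-to-diagnose accounting converts
indeterminates into false negatives among reference positives and false
positives among reference negatives, so sensitivity and specificity can
only be penalised by abstention. ROC analysis sweeps the decision
threshold over the predicted-L/S scores (positive call = score ≤
threshold) and integrates trapezoidally; the AUC equals the Mann–Whitney
concordance probability with ties counted half, which the tests verify
exactly.

## Workflows, seeds, problem sizes

A single global seed is fanned out to stage seeds via
`SeedSequence([seed, counter])`, so each stage is independently
reproducible and all derived seeds stay below 2³¹. The repeatability
workflow runs the full 2 × 9 × 9 design (162 spectra) on the 2 cm⁻¹ grid.
The calibration workflow defaults to 60 samples (33 corner/centre points +
27 Latin-hypercube) with 3 scans per film, giving a 12-sample test set.
Simulation-heavy verification (coverage over 50 seeds, 200-replicate
variance-component recovery) runs on coarser grids (16 and 4 cm⁻¹
spacing) — every checked quantity is either grid-independent or computed
against a closed form on the grid in use.

## What the tests show — and what they cannot

Passing tests establish that the implementations are internally correct
(oracle equivalence for the SG filter, OLS and scikit-learn equivalence
for PLSR at full rank, statsmodels agreement for the ANOVA sums of
squares, Mann–Whitney agreement for AUC), that the variance-component
estimators recover known generative components within Monte-Carlo error,
and that the conformal intervals meet their distribution-free guarantee on
exchangeable synthetic data. The generator reproduces the *variance
consequences* of film formation — not ATR optics, molecular orientation,
coffee-ring spatial structure, atmospheric interference or clinical-matrix
chemistry. Quantities that depend on real measured spectra (absolute SNR
values, per-lipid R²/RMSE, the ±0.23 grey-zone half-width, AUC on real
mixtures) are therefore *conditions of the simulation*, not reproduced
results: with the default calibration noise the simulated grey zone is
wider (≈ ±0.6–0.95) than a well-controlled instrument would give, and it
narrows as the film-scale SD is reduced. Known limitations: balanced
designs only for the ANOVA; single-response PLSR (no PLS2); intervals
assume exchangeability across samples and will under-cover under covariate
shift.
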