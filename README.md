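# surfir

Chemometrics for dried-film ATR-FTIR quantification of pulmonary
surfactant lipids, aimed at lung-maturity assessment in neonatal
respiratory distress syndrome (nRDS).

Clinical motivation: the lecithin/sphingomyelin ratio (L/S, with
L = DPPC + POPC) is a biochemical marker of foetal lung maturity with a
widely used cut-off of 2.2 mol/mol. Infrared spectroscopy of a dried lipid
film on an ATR crystal can estimate the five major surfactant lipid
concentrations — DPPC, POPC, sphingomyelin (S), phosphatidylglycerol (PG)
and cholesterol — in minutes, but the result is only as good as the film:
how the deposition liquid dries (organic solvent vs. aqueous resuspension)
dominates measurement variability. This package implements the full
analysis chain for that problem:

* **Synthetic data generation** — Beer–Lambert mixture spectra built from
  per-lipid Gaussian band libraries, a nested route/run/scan replicate
  structure with multiplicative film effects and additive scan noise, and
  reference L/S cohorts with RDS labels. Everything downstream is testable
  without instrument data.
* **Preprocessing** — baseline offset at 2800 cm⁻¹, truncation to
  4000–850 cm⁻¹, Savitzky–Golay 15-point 3rd-order 2nd-derivative filter
  (physical wavenumber units, shrinking-window edges).
* **Spectral quality** — 2920 cm⁻¹ CH₂ peak height over a two-anchor
  linear baseline, RMS noise in 2200–2000 cm⁻¹, peak SNR, 2945–2880 cm⁻¹
  peak area, 1740 cm⁻¹ carbonyl height, %RSD.
* **Repeatability** — balanced two-factor mixed nested ANOVA (fixed
  preparation route, random run nested in route) with expected-mean-square
  variance components σ²ᵣₒᵤₜₑ = max(0, (MS_route − MS_run)/(r·n)),
  σ²ᵣᵤₙ = max(0, (MS_run − MS_res)/n), σ²ᵣₑₛ = MS_res, variance fractions,
  Cohen's d, and PC1 route-separation effect sizes.
* **Calibration** — single-response PLSR implemented from first principles
  (NIPALS), sample-wise 80/20 splitting and grouped k-fold CV for
  latent-variable selection.
* **Uncertainty** — jackknife+-after-bootstrap 95 % prediction intervals
  (distribution-free, ≥ 1 − 2α coverage guarantee for exchangeable data),
  implemented in-package.
* **Diagnostics** — first-order quotient-rule propagation of interval
  half-widths to L/S, a grey zone around the 2.2 threshold
  (interval spans the cut-off ⇒ indeterminate), intention-to-diagnose
  sensitivity/specificity, and ROC/AUC by trapezoidal integration.

## Worked example

Simulate the nested repeatability study (2 routes × 9 films × 9 scans of
the mid-point mixture) and decompose the 2920 cm⁻¹ peak-height variance:

```sh
surfir repro-repeatability --seed 7 --out runs/repeatability
```

prints (abridged):

```json
{
  "n_spectra": 162,
  "route_variance_fraction_percent": 94.40,
  "run_variance_fraction_percent": 5.60,
  "residual_variance_fraction_percent": 0.0003,
  "percent_rsd_by_route": {"AQ-dry": 8.87, "DCM-dry": 17.59},
  "pc1_route_abs_cohens_d": 6.15,
  "mean_peak_height_by_route": {"AQ-dry": 0.480, "DCM-dry": 0.227}
}
```

Read: the drying route dominates total variance (~94 % here), run-to-run
film deposition contributes most of the remainder, and scan-to-scan noise
is negligible — the variance hierarchy that makes film preparation, not
the instrument, the repeatability bottleneck. The aqueous route gives
roughly 2.1× the mean signal and about half the relative dispersion of the
solvent route, and the two routes separate cleanly on the first principal
component of the derivative spectra (|d| ≈ 6).

The calibration-to-diagnostics pipeline (60 mixtures, 6 PLSR models,
conformal intervals, L/S grey zone on a simulated 133-infant cohort, ROC):

```sh
surfir repro-calibration --seed 7 --out runs/calibration
```

reports per-target test metrics — e.g. S: R² = 0.99, RMSE = 0.022 mM with
4 latent variables; POPC, spectrally collinear with DPPC, is hardest
(R² = 0.90) — an L/S test R² of 0.986 (RMSE 0.219), AUC = 1.0 on the test
mixtures, and a grey-zone half-width of ±0.95 L/S units at these
simulation noise settings, under which 60 % of the simulated cohort falls
in the indeterminate zone. Lower film variability shrinks the grey zone
accordingly (see `docs/methods.md`).

Library use mirrors the CLI; every stage is an importable function
(`surfir.simulate_nested_measurements`, `surfir.preprocess_for_model`,
`surfir.nested_anova`, `surfir.fit_plsr`, `surfir.jab_intervals`,
`surfir.apply_grey_zone`, ...).

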