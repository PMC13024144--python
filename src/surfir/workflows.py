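"""End-to-end study workflows.

Two reproducible pipelines mirror the package's intended use:

* the *repeatability study* — simulate the nested route/run/scan replicate
  design for the mid-point mixture, extract quality metrics, decompose the
  2920 cm^-1 peak-height variance by nested ANOVA, and check the route
  separation on PC1 of the preprocessed spectra;
* the *calibration study* — simulate an aqueous-route mixture calibration
  set, preprocess, split by sample, select latent variables per target,
  fit the six PLSR models (five lipids + lecithin), attach J+aB prediction
  intervals, propagate to L/S, project the grey zone onto a reference
  cohort, and run ROC analysis.

A single global seed is fanned out to stage-local seeds through a
counter-based scheme so each stage is independently reproducible.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import (LS_THRESHOLD, apply_grey_zone, ls_with_uncertainty,
                          mean_test_half_width, roc_curve)
from .intervals import JabConfig, jab_intervals, jab_train, max_interval_summary
from .plsr import (CalibrationDataset, evaluate, fit_plsr, grouped_split,
                   select_n_lv)
from .preprocess import PreprocessConfig, preprocess_matrix
from .quality import quality_metrics
from .repeatability import nested_anova, pca_pc1_scores, route_separation_effect
from .spectrum import WavenumberGrid
from .synthetic import (CALIBRATION_MEASUREMENT_MODEL, DEFAULT_MEASUREMENT_MODELS,
                        CohortSpec, LipidComposition, MeasurementModel,
                        NestedDesign, build_reference_library,
                        midpoint_composition, sample_mixture_compositions,
                        simulate_cohort_ls, simulate_mixture_measurements,
                        simulate_nested_measurements)

STAGE_SEED_MODULUS = 2**31


def stage_seed(global_seed: int, counter: int) -> int:
    """Deterministic stage-local seed derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), int(counter)])
    return int(ss.generate_state(1)[0] % STAGE_SEED_MODULUS)


def _write_manifest(out_dir: Path, name: str, seed: int, payload: dict) -> None:
    manifest = {"workflow": name, "seed": seed, "surfir_version": __version__,
                **payload}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_repeatability_study(
    out_dir: str | Path,
    seed: int = 0,
    grid: WavenumberGrid | None = None,
    composition: LipidComposition | None = None,
    models: dict[str, MeasurementModel] | None = None,
    design: NestedDesign = NestedDesign(),
    preprocess_cfg: PreprocessConfig = PreprocessConfig(),
) -> dict:
    """Simulate -> preprocess -> QC -> nested ANOVA -> PCA. Returns a
    summary dict; artifacts land in ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = grid or WavenumberGrid()
    composition = composition or midpoint_composition()
    models = models or DEFAULT_MEASUREMENT_MODELS

    library = build_reference_library(grid=grid)
    data = simulate_nested_measurements(
        composition, library, models, design, seed=stage_seed(seed, 0))
    data.write(out_dir / "spectra.csv", out_dir / "meta.csv")

    metric_rows = []
    for spec in data.spectra():
        m = quality_metrics(spec)
        for name, value in asdict(m).items():
            metric_rows.append({"spectrum_id": spec.meta["spectrum_id"],
                                "metric": name, "value": value})
    metrics = pd.DataFrame(metric_rows)
    metrics.to_csv(out_dir / "metrics.csv", index=False)

    heights = metrics[metrics["metric"] == "peak_height_2920"].set_index(
        "spectrum_id")["value"]
    table = data.meta[["route", "run", "scan"]].copy()
    table["value"] = heights.loc[data.meta["spectrum_id"]].to_numpy()
    decomposition = nested_anova(table)
    (out_dir / "anova.json").write_text(json.dumps(decomposition.to_dict(), indent=2))

    rsd = {
        route: float(100.0 * grp["value"].std(ddof=1) / grp["value"].mean())
        for route, grp in table.groupby("route")
    }

    nu, d2 = preprocess_matrix(data.wavenumbers, data.absorbance, preprocess_cfg)
    scores, explained = pca_pc1_scores(d2)
    pd.DataFrame({"spectrum_id": data.meta["spectrum_id"],
                  "route": data.meta["route"], "pc1_score": scores}
                 ).to_csv(out_dir / "scores.csv", index=False)
    pc1_d = route_separation_effect(scores, data.meta["route"].to_numpy())

    summary = {
        "n_spectra": len(data),
        "route_variance_fraction_percent": decomposition.route.variance_fraction_percent,
        "run_variance_fraction_percent": decomposition.run.variance_fraction_percent,
        "residual_variance_fraction_percent": decomposition.residual.variance_fraction_percent,
        "f_route": decomposition.route.f,
        "percent_rsd_by_route": rsd,
        "pc1_explained_variance_fraction": explained,
        "pc1_route_abs_cohens_d": pc1_d,
        "mean_peak_height_by_route": {
            route: float(grp["value"].mean()) for route, grp in table.groupby("route")
        },
    }
    _write_manifest(out_dir, "repeatability", seed, {
        "n_spectra": len(data),
        "design": asdict(design),
        "composition": asdict(composition),
        "stage_seeds": {"simulate": stage_seed(seed, 0)},
        "artifacts": ["spectra.csv", "meta.csv", "metrics.csv", "anova.json",
                      "scores.csv"],
    })
    return summary


TARGET_ORDER = ("dppc", "popc", "s", "pg", "chol", "l")


def run_calibration_study(
    out_dir: str | Path,
    seed: int = 0,
    grid: WavenumberGrid | None = None,
    n_samples: int = 60,
    scans_per_sample: int = 3,
    model: MeasurementModel | None = None,
    cohort: CohortSpec | None = None,
    threshold: float = LS_THRESHOLD,
    k_folds: int = 5,
    max_lv: int = 10,
    n_bootstrap: int = 30,
    alpha: float = 0.05,
    test_fraction: float = 0.2,
    preprocess_cfg: PreprocessConfig = PreprocessConfig(),
) -> dict:
    """Full calibration-to-diagnostics pipeline on synthetic mixtures."""
    out_dir = Path(out_dir)
    (out_dir / "models").mkdir(parents=True, exist_ok=True)
    grid = grid or WavenumberGrid()
    model = model or CALIBRATION_MEASUREMENT_MODEL

    compositions = sample_mixture_compositions(
        n_samples=n_samples, scheme="vertices_plus_center",
        seed=stage_seed(seed, 1))
    library = build_reference_library(grid=grid)
    data = simulate_mixture_measurements(
        compositions, library, model, scans_per_sample,
        seed=stage_seed(seed, 2))
    data.write(out_dir / "spectra.csv", out_dir / "meta.csv")

    _, d2 = preprocess_matrix(data.wavenumbers, data.absorbance, preprocess_cfg)
    ds = CalibrationDataset.from_spectra(d2, data.meta)
    train, test = grouped_split(ds, test_fraction, seed=stage_seed(seed, 3))

    per_target: dict[str, dict] = {}
    intervals_by_target: dict[str, list] = {}
    pred_rows = []
    for i, target in enumerate(TARGET_ORDER):
        n_lv = select_n_lv(train, target, k_folds=k_folds, max_lv=max_lv,
                           seed=stage_seed(seed, 10 + i))
        plsr_model = fit_plsr(train, target, n_lv)
        plsr_model.to_json(out_dir / "models" / f"{target}.json")
        metrics = evaluate(plsr_model, test)
        ensemble = jab_train(train, target, n_lv,
                             JabConfig(n_bootstrap=n_bootstrap, alpha=alpha,
                                       seed=stage_seed(seed, 20 + i)))
        ivs = jab_intervals(ensemble, test.X)
        intervals_by_target[target] = ivs
        max_up, max_lo = max_interval_summary(ivs)
        per_target[target] = {"n_lv": n_lv, "r2": metrics.r2, "rmse": metrics.rmse,
                              "max_upper_half_width": max_up,
                              "max_lower_half_width": max_lo}
        for sid, y_true, iv in zip(test.sample_ids, test.target_values(target), ivs):
            pred_rows.append({"sample_id": sid, "target": target,
                              "true": y_true, "point": iv.point,
                              "lower": iv.lower, "upper": iv.upper,
                              "half_width": iv.half_width})
    pd.DataFrame(pred_rows).to_csv(out_dir / "predictions.csv", index=False)

    # L/S propagation on the test set
    ls_estimates = [
        ls_with_uncertainty(l_iv, s_iv)
        for l_iv, s_iv in zip(intervals_by_target["l"], intervals_by_target["s"])
    ]
    ls_true = test.target_values("l") / test.target_values("s")
    ls_points = np.array([e.ls_point for e in ls_estimates])
    ls_resid = ls_points - ls_true
    ls_sst = float(((ls_true - ls_true.mean()) ** 2).sum())
    ls_r2 = 1.0 - float((ls_resid**2).sum()) / ls_sst if ls_sst > 0 else float("nan")
    ls_rmse = float(np.sqrt((ls_resid**2).mean()))
    grey_half_width = mean_test_half_width([e.ls_half_width for e in ls_estimates])

    # grey-zone projection onto the reference cohort
    cohort_spec = cohort or CohortSpec(seed=stage_seed(seed, 4))
    cohort_df = simulate_cohort_ls(cohort_spec)
    report = apply_grey_zone(cohort_df["ls"], cohort_df["rds"],
                             grey_half_width, threshold)
    (out_dir / "greyzone.json").write_text(json.dumps(report.to_dict(), indent=2))

    # ROC on the synthetic test mixtures: true label from true L/S, score =
    # predicted L/S point estimate
    labels = (ls_true < threshold).astype(int)
    roc_summary: dict = {"auc": None}
    if labels.min() != labels.max():
        roc = roc_curve(ls_points, labels)
        pd.DataFrame({"threshold": roc.thresholds, "fpr": roc.fpr,
                      "tpr": roc.tpr}).to_csv(out_dir / "roc.csv", index=False)
        roc_summary = {"auc": roc.auc}

    summary = {
        "n_samples": n_samples, "n_train_samples": train.n_samples,
        "n_test_samples": test.n_samples, "per_target": per_target,
        "ls_r2": ls_r2, "ls_rmse": ls_rmse,
        "grey_zone_half_width": grey_half_width,
        "grey_zone_bounds": (threshold - grey_half_width,
                             threshold + grey_half_width),
        "cohort": report.to_dict(), **roc_summary,
    }
    _write_manifest(out_dir, "calibration", seed, {
        "n_samples": n_samples, "scans_per_sample": scans_per_sample,
        "targets": list(TARGET_ORDER),
        "stage_seeds": {"design": stage_seed(seed, 1),
                        "simulate": stage_seed(seed, 2),
                        "split": stage_seed(seed, 3),
                        "cohort": stage_seed(seed, 4)},
        "artifacts": ["spectra.csv", "meta.csv", "predictions.csv",
                      "greyzone.json", "roc.csv",
                      *(f"models/{t}.json" for t in TARGET_ORDER)],
    })
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
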