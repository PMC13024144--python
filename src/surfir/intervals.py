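"""Jackknife+-after-bootstrap (J+aB) prediction intervals for PLSR.

A bootstrap ensemble of B PLSR fits is drawn by resampling *samples* (not
scans) with replacement; for each training row the out-of-bag (OOB)
aggregate — the mean prediction of the models whose resample excluded that
row's sample — plays the role of the leave-one-out surrogate. For a new
point x, the interval endpoints are order statistics of
{mu_-i(x) - R_i} and {mu_-i(x) + R_i}, with R_i = |y_i - mu_-i(x_i)| the
OOB absolute residuals. Under exchangeability this construction carries the
distribution-free >= 1-2*alpha coverage guarantee of jackknife+, and in
practice covers at about 1-alpha.

The point prediction is the mean over the full ensemble; the reported
bounds are order statistics and need not be symmetric about it (nor, in
pathological cases, contain it), which is why the symmetric summary uses
the *larger* half-width.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, RankDeficiencyError
from .plsr import CalibrationDataset, PLSRModel, fit_plsr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class JabConfig:
    n_bootstrap: int = 30
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 10:
            raise ConfigError("n_bootstrap must be >= 10")
        if not (0 < self.alpha < 0.5):
            raise ConfigError("alpha must lie in (0, 0.5)")


@dataclass(frozen=True)
class PredictionWithInterval:
    point: float
    lower: float
    upper: float

    @property
    def half_width(self) -> float:
        """Symmetric uncertainty: the larger of the two half-widths."""
        return max(self.upper - self.point, self.point - self.lower)


@dataclass
class JabEnsemble:
    """Trained bootstrap ensemble with OOB bookkeeping."""

    models: list[PLSRModel]
    inbag: np.ndarray          # (B, n_rows) bool: sample of row i in resample b
    residuals: np.ndarray      # (n_rows,) OOB absolute residuals
    alpha: float

    @property
    def n_rows(self) -> int:
        return self.inbag.shape[1]


def jab_train(train: CalibrationDataset, target: str, n_lv: int,
              cfg: JabConfig = JabConfig()) -> JabEnsemble:
    """Fit the bootstrap ensemble and record OOB residuals.

    Resampling is at sample_id granularity. If any training row's sample is
    in-bag for every resample, further resamples are drawn (same stream)
    until all rows have OOB coverage; the extension is logged.
    """
    if train.X.shape[0] == 0:
        raise DataError("empty training set")
    ids = pd.unique(train.sample_ids)
    n_ids = len(ids)
    id_index = {sid: j for j, sid in enumerate(ids)}
    row_sample = np.array([id_index[sid] for sid in train.sample_ids])
    rng = np.random.default_rng(cfg.seed)

    models: list[PLSRModel] = []
    inbag_rows: list[np.ndarray] = []

    def draw_one() -> None:
        picks = rng.integers(0, n_ids, size=n_ids)
        member = np.zeros(n_ids, dtype=bool)
        member[picks] = True
        row_mask = np.concatenate([np.flatnonzero(row_sample == s) for s in picks])
        resample = train.subset(row_mask)
        try:
            model = fit_plsr(resample, target, n_lv)
        except RankDeficiencyError as err:
            # a resample may duplicate samples enough to lose rank; fit the
            # member at the rank it supports rather than aborting the ensemble
            if err.max_usable < 1:
                raise
            model = fit_plsr(resample, target, err.max_usable)
        models.append(model)
        inbag_rows.append(member[row_sample])

    for _ in range(cfg.n_bootstrap):
        draw_one()
    inbag = np.vstack(inbag_rows)
    extra = 0
    while (~inbag).sum(axis=0).min() == 0:
        draw_one()
        extra += 1
        inbag = np.vstack(inbag_rows)
        if extra > 10 * cfg.n_bootstrap:
            raise DataError("could not achieve out-of-bag coverage for all rows")
    if extra:
        logger.warning("extended bootstrap ensemble by %d resamples so every "
                       "training point is out-of-bag at least once", extra)

    preds = np.vstack([m.predict(train.X) for m in models])  # (B, n_rows)
    oob = ~inbag
    with np.errstate(invalid="ignore"):
        oob_agg = (preds * oob).sum(axis=0) / oob.sum(axis=0)
    y = train.target_values(target)
    return JabEnsemble(models=models, inbag=inbag,
                       residuals=np.abs(y - oob_agg), alpha=cfg.alpha)


def jab_intervals(state: JabEnsemble, X_new: np.ndarray,
                  alpha: float | None = None) -> list[PredictionWithInterval]:
    """J+aB intervals for new spectra.

    Uses the conservative ceil((1-alpha)(n+1)) order-statistic rank, clipped
    to the sample.
    """
    alpha = state.alpha if alpha is None else alpha
    if not (0 < alpha < 0.5):
        raise ConfigError("alpha must lie in (0, 0.5)")
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    preds = np.vstack([m.predict(X_new) for m in state.models])  # (B, m)
    points = preds.mean(axis=0)
    oob = ~state.inbag                                           # (B, n)
    counts = oob.sum(axis=0).astype(float)                       # (n,)
    # mu_{-i}(x) for every training row i and each new point: (n, m)
    mu = (oob.T @ preds) / counts[:, None]
    n = state.n_rows
    k = min(n, math.ceil((1 - alpha) * (n + 1)))
    lo_stats = np.sort(mu - state.residuals[:, None], axis=0)  # (n, m)
    hi_stats = np.sort(mu + state.residuals[:, None], axis=0)
    lowers = lo_stats[n - k]
    uppers = hi_stats[k - 1]
    return [PredictionWithInterval(float(p), float(lo), float(hi))
            for p, lo, hi in zip(points, lowers, uppers)]


def max_interval_summary(intervals: list[PredictionWithInterval]) -> tuple[float, float]:
    """(max upper half-width, max lower half-width) across predictions."""
    if not intervals:
        raise DataError("no intervals to summarise")
    return (max(iv.upper - iv.point for iv in intervals),
            max(iv.point - iv.lower for iv in intervals))
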