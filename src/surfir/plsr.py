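"""Partial least squares regression (single-y NIPALS) with grouped
cross-validation for latent-variable selection.

The calibration dataset groups replicate scans by physical sample; all
splitting (train/test and CV folds) is sample-wise so that scans of one
film never straddle a partition — replicate scans are strongly dependent
and would otherwise leak.

NIPALS for one response: at each component, the weight vector is the
(normalised) covariance X'y, scores t = Xw, loadings p = X't/t't and
q = y't/t't, followed by deflation of X (and y). The compact regression
vector b = W (P'W)^-1 q reproduces the sequential predictions, so a fitted
model is just (x_mean, y_mean, b).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, RankDeficiencyError, UndefinedMetricError
from .synthetic import LIPIDS

TARGETS = LIPIDS + ("l",)

_DEFLATION_TOL = 1e-12


@dataclass
class CalibrationDataset:
    """Preprocessed spectra with per-row composition targets.

    ``y`` holds one column per lipid (mM); the derived lecithin target
    ``l`` = dppc + popc is computed on demand.
    """

    X: np.ndarray
    y: pd.DataFrame
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.sample_ids = np.asarray(self.sample_ids)
        if len(self.y) != self.X.shape[0] or len(self.sample_ids) != self.X.shape[0]:
            raise DataError("X, y and sample_ids row counts differ")

    def target_values(self, target: str) -> np.ndarray:
        t = target.lower()
        if t == "l":
            return (self.y["dppc"] + self.y["popc"]).to_numpy(dtype=float)
        if t not in LIPIDS:
            raise ConfigError(f"unknown target '{target}'; expected one of {TARGETS}")
        return self.y[t].to_numpy(dtype=float)

    def subset(self, row_mask: np.ndarray) -> "CalibrationDataset":
        return CalibrationDataset(self.X[row_mask], self.y.iloc[row_mask].reset_index(drop=True),
                                  self.sample_ids[row_mask])

    @property
    def n_samples(self) -> int:
        return len(pd.unique(self.sample_ids))

    @classmethod
    def from_spectra(cls, spectra_matrix: np.ndarray, meta: pd.DataFrame) -> "CalibrationDataset":
        """Build from a preprocessed matrix plus a metadata table carrying
        ``sample_id`` and ``{lipid}_mM`` columns."""
        y = pd.DataFrame({n: meta[f"{n}_mM"].to_numpy(dtype=float) for n in LIPIDS})
        return cls(spectra_matrix, y, meta["sample_id"].to_numpy())


def grouped_split(ds: CalibrationDataset, test_fraction: float = 0.2,
                  seed: int = 0) -> tuple[CalibrationDataset, CalibrationDataset]:
    """Sample-wise train/test partition; no sample straddles the split."""
    ids = pd.unique(ds.sample_ids)
    if len(ids) < 5:
        raise DataError("grouped split needs at least 5 distinct samples")
    if not (0 < test_fraction < 1):
        raise ConfigError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_test = max(1, int(round(test_fraction * len(ids))))
    test_ids = set(ids[perm[:n_test]])
    test_mask = np.array([sid in test_ids for sid in ds.sample_ids])
    return ds.subset(~test_mask), ds.subset(test_mask)


@dataclass
class PLSRModel:
    """Fitted single-response PLSR model."""

    n_lv: int
    target: str
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # (n_lv, p) W
    x_loadings: np.ndarray   # (n_lv, p) P
    y_loadings: np.ndarray   # (n_lv,)   q
    b: np.ndarray            # (p,) regression vector

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.b.shape[0]:
            raise DataError(
                f"feature count {X_new.shape[1]} does not match model ({self.b.shape[0]})"
            )
        return (X_new - self.x_mean) @ self.b + self.y_mean

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "surfir-plsr", "version": 1,
            "n_lv": self.n_lv, "target": self.target,
            "x_mean": self.x_mean.tolist(), "y_mean": self.y_mean,
            "weights": self.weights.tolist(), "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(), "b": self.b.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSRModel":
        d = json.loads(Path(path).read_text())
        if d.get("format") != "surfir-plsr":
            raise ConfigError(f"{path} is not a surfir PLSR model file")
        return cls(
            n_lv=d["n_lv"], target=d["target"],
            x_mean=np.array(d["x_mean"]), y_mean=float(d["y_mean"]),
            weights=np.array(d["weights"]), x_loadings=np.array(d["x_loadings"]),
            y_loadings=np.array(d["y_loadings"]), b=np.array(d["b"]),
        )


def _nipals(X: np.ndarray, y: np.ndarray, n_lv: int
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core NIPALS loop on centred data. Returns (W, P, q)."""
    Xc = X.copy()
    yc = y.copy()
    p_dim = X.shape[1]
    W = np.zeros((n_lv, p_dim))
    P = np.zeros((n_lv, p_dim))
    q = np.zeros(n_lv)
    x_scale = np.linalg.norm(X) or 1.0
    for a in range(n_lv):
        w = Xc.T @ yc
        w_norm = np.linalg.norm(w)
        if w_norm <= _DEFLATION_TOL * x_scale * (np.linalg.norm(y) or 1.0):
            raise RankDeficiencyError(n_lv, a)
        w /= w_norm
        t = Xc @ w
        tt = float(t @ t)
        if tt <= _DEFLATION_TOL:
            raise RankDeficiencyError(n_lv, a)
        p = Xc.T @ t / tt
        qa = float(yc @ t) / tt
        Xc -= np.outer(t, p)
        yc = yc - qa * t
        W[a], P[a], q[a] = w, p, qa
    return W, P, q


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    # b = W (P'W)^-1 q ; rows of W/P are the per-component vectors, so the
    # (a, b) entry of P'W in column convention is P[a] . W[b]
    R = np.linalg.solve(P @ W.T, q)
    return W.T @ R


def fit_plsr(train: CalibrationDataset, target: str, n_lv: int) -> PLSRModel:
    """Fit a single-lipid (or lecithin ``l``) PLSR model with ``n_lv``
    latent variables on centred data (no variance scaling)."""
    y = train.target_values(target)
    n, p = train.X.shape
    max_lv = min(n - 1, p)
    if not (1 <= n_lv <= max_lv):
        raise RankDeficiencyError(n_lv, max_lv)
    x_mean = train.X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q = _nipals(train.X - x_mean, y - y_mean, n_lv)
    return PLSRModel(
        n_lv=n_lv, target=target.lower(), x_mean=x_mean, y_mean=y_mean,
        weights=W, x_loadings=P, y_loadings=q, b=_regression_vector(W, P, q),
    )


def predict(model: PLSRModel, X_new: np.ndarray) -> np.ndarray:
    return model.predict(X_new)


@dataclass(frozen=True)
class ModelMetrics:
    r2: float
    rmse: float


def evaluate(model: PLSRModel, test: CalibrationDataset,
             target: str | None = None) -> ModelMetrics:
    """Test-set R^2 (about the test mean) and RMSE."""
    target = target or model.target
    y = test.target_values(target)
    if y.size == 0:
        raise DataError("empty test set")
    pred = model.predict(test.X)
    sse = float(((y - pred) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise UndefinedMetricError("R^2 undefined: zero-variance test targets")
    return ModelMetrics(r2=1.0 - sse / sst, rmse=float(np.sqrt(sse / y.size)))


def _grouped_folds(sample_ids: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Row masks of k sample-wise folds, seeded shuffle."""
    ids = pd.unique(sample_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.array_split(ids[perm], k)
    return [np.isin(sample_ids, fold) for fold in folds]


def select_n_lv(train: CalibrationDataset, target: str, k_folds: int = 5,
                max_lv: int = 10, criterion: str = "min_mse",
                seed: int = 0) -> int:
    """Latent-variable count minimising CV MSE (or maximising mean R^2).

    Folds are grouped by sample. Ties break toward fewer components.
    """
    if k_folds < 2:
        raise ConfigError("k_folds must be >= 2")
    if criterion not in ("min_mse", "max_r2"):
        raise ConfigError("criterion must be 'min_mse' or 'max_r2'")
    if train.n_samples < k_folds:
        raise DataError("fewer samples than folds")
    y_all = train.target_values(target)
    folds = _grouped_folds(train.sample_ids, k_folds, seed)
    # usable LV ceiling across folds
    cap = min(
        min((~m).sum() for m in folds) - 1, train.X.shape[1], max_lv
    )
    if cap < 1:
        raise DataError("training folds too small for even one latent variable")
    per_lv_scores = np.zeros((cap, k_folds))
    for f, mask in enumerate(folds):
        sub_train = train.subset(~mask)
        X_val, y_val = train.X[mask], y_all[mask]
        x_mean = sub_train.X.mean(axis=0)
        y_fit = sub_train.target_values(target)
        y_mean = y_fit.mean()
        try:
            W, P, q = _nipals(sub_train.X - x_mean, y_fit - y_mean, cap)
            usable = cap
        except RankDeficiencyError as err:
            usable = err.max_usable
            if usable < 1:
                raise
            W, P, q = _nipals(sub_train.X - x_mean, y_fit - y_mean, usable)
        for a in range(cap):
            aa = min(a + 1, usable)
            b = _regression_vector(W[:aa], P[:aa], q[:aa])
            pred = (X_val - x_mean) @ b + y_mean
            err2 = float(((y_val - pred) ** 2).mean())
            if criterion == "min_mse":
                per_lv_scores[a, f] = err2
            else:
                sst = float(((y_val - y_val.mean()) ** 2).mean())
                per_lv_scores[a, f] = 1.0 - err2 / sst if sst > 0 else -np.inf
    mean_scores = per_lv_scores.mean(axis=1)
    if criterion == "min_mse":
        best = int(np.argmin(mean_scores)) + 1
    else:
        best = int(np.argmax(mean_scores)) + 1
    return best
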