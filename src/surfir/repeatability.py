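"""Repeatability analysis: mixed nested ANOVA, Cohen's d, PCA separation.

The design is balanced two-level nested: a fixed preparation-route factor
(a levels), a random run factor nested within route (r runs per route), and
n repeat scans per run as the residual stratum. Variance components come
from the expected-mean-square relations

    sigma2_residual = MS_res
    sigma2_run      = max(0, (MS_run  - MS_res) / n)
    sigma2_route    = max(0, (MS_route - MS_run) / (r * n))

The route term is a fixed factor; its "sigma2" is the EMS-based
quasi-component conventionally tabulated alongside the random components so
that variance fractions sum to 100% — a reporting convention, not a true
random-effect variance. Negative estimates truncate to zero. p-values are
floored at the smallest positive subnormal double.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateDataError, UndefinedMetricError

P_FLOOR = float(np.nextafter(0, 1))  # 4.9e-324


@dataclass(frozen=True)
class SourceRow:
    df: int
    mean_square: float
    f: float | None
    p: float | None
    sigma2: float
    variance_fraction_percent: float


@dataclass(frozen=True)
class VarianceDecomposition:
    route: SourceRow
    run: SourceRow
    residual: SourceRow
    total_df: int
    total_mean_square: float
    total_sigma2: float

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "route": self.route, "run(route)": self.run, "residual": self.residual,
        }
        df = pd.DataFrame(
            {name: {"df": r.df, "mean_square": r.mean_square, "F": r.f,
                    "p": r.p, "sigma2": r.sigma2,
                    "variance_fraction_percent": r.variance_fraction_percent}
             for name, r in rows.items()}
        ).T
        df.loc["corrected total"] = {
            "df": self.total_df, "mean_square": self.total_mean_square,
            "F": None, "p": None, "sigma2": self.total_sigma2,
            "variance_fraction_percent": 100.0,
        }
        return df

    def to_dict(self) -> dict:
        return {
            "route": vars(self.route), "run": vars(self.run),
            "residual": vars(self.residual),
            "corrected_total": {"df": self.total_df,
                                "mean_square": self.total_mean_square,
                                "sigma2": self.total_sigma2},
        }


def _p_value(f: float, df1: int, df2: int) -> float:
    return max(float(stats.f.sf(f, df1, df2)), P_FLOOR)


def variance_components_from_mean_squares(
    ms_route: float, ms_run: float, ms_res: float,
    a: int, r: int, n: int,
) -> VarianceDecomposition:
    """Assemble the decomposition from mean squares of a balanced design.

    Useful for recomputing published ANOVA tables where only MS values are
    available; ``nested_anova`` delegates here after computing sums of
    squares from raw data.
    """
    df_route, df_run, df_res = a - 1, a * (r - 1), a * r * (n - 1)
    f_route = ms_route / ms_run if ms_run > 0 else float("inf")
    f_run = ms_run / ms_res if ms_res > 0 else float("inf")
    s2_res = ms_res
    s2_run = max(0.0, (ms_run - ms_res) / n)
    s2_route = max(0.0, (ms_route - ms_run) / (r * n))
    total = s2_route + s2_run + s2_res
    if total == 0:
        raise DegenerateDataError("all variance components are zero")
    frac = [100.0 * v / total for v in (s2_route, s2_run, s2_res)]
    df_tot = df_route + df_run + df_res
    ss_tot = ms_route * df_route + ms_run * df_run + ms_res * df_res
    return VarianceDecomposition(
        route=SourceRow(df_route, ms_route, f_route,
                        _p_value(f_route, df_route, df_run), s2_route, frac[0]),
        run=SourceRow(df_run, ms_run, f_run,
                      _p_value(f_run, df_run, df_res), s2_run, frac[1]),
        residual=SourceRow(df_res, ms_res, None, None, s2_res, frac[2]),
        total_df=df_tot, total_mean_square=ss_tot / df_tot, total_sigma2=total,
    )


def _check_balance(table: pd.DataFrame) -> tuple[int, int, int]:
    counts = table.groupby(["route", "run"], sort=True).size()
    n = counts.iloc[0]
    if (counts != n).any():
        bad = counts[counts != n].index[0]
        raise DataError(
            f"unbalanced design: cell route={bad[0]!r}, run={bad[1]!r} has "
            f"{counts.loc[bad]} scans, expected {n}"
        )
    runs_per_route = table.groupby("route")["run"].nunique()
    r = runs_per_route.iloc[0]
    if (runs_per_route != r).any():
        bad = runs_per_route[runs_per_route != r].index[0]
        raise DataError(
            f"unbalanced design: route {bad!r} has {runs_per_route.loc[bad]} "
            f"runs, expected {r}"
        )
    a = table["route"].nunique()
    if a < 2 or r < 2 or n < 2:
        raise DataError("nested ANOVA needs >= 2 routes, runs and scans")
    return a, int(r), int(n)


def nested_anova(table: pd.DataFrame, value_col: str = "value") -> VarianceDecomposition:
    """Balanced two-factor mixed nested ANOVA.

    ``table`` needs columns ``route``, ``run``, ``scan`` and the response.
    """
    for col in ("route", "run", "scan", value_col):
        if col not in table.columns:
            raise DataError(f"observation table lacks required column '{col}'")
    a, r, n = _check_balance(table)
    y = table[value_col].astype(float)
    grand = y.mean()
    route_means = table.groupby("route")[value_col].mean()
    cell_means = table.groupby(["route", "run"])[value_col].mean()
    ss_route = r * n * float(((route_means - grand) ** 2).sum())
    ss_run = n * float(
        ((cell_means - route_means.reindex(
            cell_means.index.get_level_values("route")).to_numpy()) ** 2).sum()
    )
    resid = y.to_numpy() - cell_means.loc[
        pd.MultiIndex.from_frame(table[["route", "run"]])].to_numpy()
    ss_res = float((resid**2).sum())
    if ss_route + ss_run + ss_res == 0:
        raise DegenerateDataError("all observations are identical")
    return variance_components_from_mean_squares(
        ss_route / (a - 1), ss_run / (a * (r - 1)), ss_res / (a * r * (n - 1)),
        a, r, n,
    )


def cohens_d(group_a, group_b) -> float:
    """Standardised mean difference with the pooled (n_a+n_b-2) SD.

    Signed; callers wanting the magnitude take ``abs``.
    """
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DataError("Cohen's d needs >= 2 values per group")
    pooled_var = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) \
        / (x.size + y.size - 2)
    if pooled_var == 0:
        raise UndefinedMetricError("Cohen's d undefined: zero pooled SD")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def pca_pc1_scores(matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """PC1 scores and explained-variance fraction of a spectra matrix.

    Rows are spectra. The matrix is column-mean-centred; PC1 is the first
    right singular vector with its sign fixed so the largest-magnitude
    loading is positive.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if X.shape[0] < 2:
        raise DataError("PCA needs at least two spectra")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise DegenerateDataError("constant matrix: no variance to decompose")
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    loading = vt[0]
    if loading[np.argmax(np.abs(loading))] < 0:
        loading = -loading
    scores = Xc @ loading
    explained = float(svals[0] ** 2 / (svals**2).sum())
    return scores, explained


def route_separation_effect(scores: np.ndarray, routes) -> float:
    """|Cohen's d| of PC1 scores between the two routes."""
    routes = np.asarray(routes)
    levels = pd.unique(routes)
    if len(levels) != 2:
        raise DataError("route separation needs exactly two route labels")
    scores = np.asarray(scores, dtype=float)
    return abs(cohens_d(scores[routes == levels[0]], scores[routes == levels[1]]))
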