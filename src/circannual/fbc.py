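"""Seasonality models for full-blood-count tables.

Two designs are covered: a month-based cosinor for tables where only the
month of bleed is known (no covariates, one visit per donor), and a
Fourier-terms model with sex and an age spline for dated tables from
cohorts with strong non-sinusoidal seasonality.  Both report an F test of
the seasonal block against the covariate-only model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats

from circannual.cosinor import MIN_P, TWO_PI, RankDeficiencyError, day_fractions
from circannual.tables import FBCTable

__all__ = ["SeasonFTest", "month_cosinor", "fourier_season_model"]


@dataclass
class SeasonFTest:
    """F test of the seasonal columns for one blood-count response."""

    response: str
    statistic: float
    df: tuple[int, int]
    p_value: float
    n_obs: int
    coef: dict[str, float]

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _ols_rss(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _block_f_test(y, X_full, X_null, names, q: int, response: str) -> SeasonFTest:
    n, p = X_full.shape
    if np.linalg.matrix_rank(X_full) < p:
        raise RankDeficiencyError(f"design for {response!r} is rank deficient")
    beta, rss1 = _ols_rss(y, X_full)
    _, rss0 = _ols_rss(y, X_null)
    df2 = n - p
    if rss0 <= 1e-12 * max(float(y @ y), 1.0):
        # null model already fits perfectly (e.g. constant response)
        return SeasonFTest(response, 0.0, (q, df2), 1.0, n, dict(zip(names, beta)))
    if rss1 <= 1e-12 * max(rss0, 1.0):
        return SeasonFTest(response, np.inf, (q, df2), MIN_P, n,
                           dict(zip(names, beta)))
    f = ((rss0 - rss1) / q) / (rss1 / df2)
    f = max(f, 0.0)
    p_val = max(float(stats.f.sf(f, q, df2)), MIN_P)
    return SeasonFTest(response, float(f), (q, df2), p_val, n, dict(zip(names, beta)))


def month_cosinor(table: FBCTable, response: str,
                  month_to_t=lambda m: m / 12.0) -> SeasonFTest:
    """Cosinor fit on month of bleed: OLS of the response on sin/cos(2*pi*m/12).

    Requires at least 3 distinct months; tests the two seasonal columns
    against the intercept-only model with an F test on (2, n - 3) df.
    The month-to-year-fraction mapping is configurable; the default is m/12.
    """
    if response not in table.data.columns:
        raise ValueError(f"response {response!r} not in table")
    months = pd.to_numeric(table.data["month"]).to_numpy(dtype=float)
    if len(np.unique(np.mod(months, 12))) < 3:
        raise RankDeficiencyError("need at least 3 distinct months for a cosinor fit")
    y = table.data[response].to_numpy(dtype=float)
    t = month_to_t(months)
    X = np.column_stack([np.ones_like(t), np.sin(TWO_PI * t), np.cos(TWO_PI * t)])
    X0 = X[:, :1]
    return _block_f_test(y, X, X0, ["intercept", "sin_m", "cos_m"], 2, response)


def fourier_season_model(table: FBCTable, response: str, k: int = 3,
                         age_spline_df: int = 4,
                         include_covariates: bool = True) -> SeasonFTest:
    """Linear model with sex, an age spline, and ``k`` Fourier harmonics.

    The design is intercept + sex + natural-cubic-spline(age, df) +
    sum over harmonics h=1..k of sin(2*pi*h*t) and cos(2*pi*h*t), with t the
    fraction of year of the bleed date (month/12 when only months are
    known).  The 2k seasonal columns are tested jointly against the
    covariate-only model.  With ``include_covariates=False`` the base design
    is intercept-only (at k=1 on monthly data this reproduces
    :func:`month_cosinor` exactly).
    """
    if response not in table.data.columns:
        raise ValueError(f"response {response!r} not in table")
    if k < 1:
        raise ValueError("need at least one Fourier harmonic")
    d = table.data
    y = d[response].to_numpy(dtype=float)
    if "date" in d.columns and d["date"].notna().all():
        t = day_fractions(d["date"])
    else:
        t = pd.to_numeric(d["month"]).to_numpy(dtype=float) / 12.0

    if include_covariates:
        age = pd.to_numeric(d["age"]).to_numpy(dtype=float)
        if np.ptp(age) <= 0:
            raise RankDeficiencyError("age is constant: spline basis is degenerate")
        sex = d["sex"].map({"F": 0.0, "M": 1.0}).to_numpy(dtype=float)
        # the natural-cubic basis spans constants, so it replaces the intercept
        spline = np.asarray(dmatrix("cr(age, df=df) - 1",
                                    {"age": age, "df": age_spline_df}))
        base_cols = [sex] + [spline[:, j] for j in range(spline.shape[1])]
        base_names = ["sex"] + [f"age_spline_{j+1}" for j in range(spline.shape[1])]
    else:
        base_cols = [np.ones(len(y))]
        base_names = ["intercept"]
    seas_cols, seas_names = [], []
    for h in range(1, k + 1):
        seas_cols += [np.sin(TWO_PI * h * t), np.cos(TWO_PI * h * t)]
        seas_names += [f"sin_{h}t", f"cos_{h}t"]
    X_full = np.column_stack(base_cols + seas_cols)
    X_null = np.column_stack(base_cols)
    return _block_f_test(y, X_full, X_null, base_names + seas_names, 2 * k, response)


def scan_fbc(table: FBCTable, model: str = "month_cosinor", **kwargs) -> pd.DataFrame:
    """Run the chosen seasonal model over every response column of a table."""
    fitter = {"month_cosinor": month_cosinor, "fourier": fourier_season_model}[model]
    rows = []
    for response in table.responses:
        res = fitter(table, response, **kwargs)
        rows.append((response, res.statistic, res.df[0], res.df[1],
                     res.p_value, res.n_obs))
    return pd.DataFrame(rows, columns=["response", "F", "df1", "df2", "p", "n"])
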