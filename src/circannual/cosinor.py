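"""Per-feature cosinor models with a one-year period and the season test.

The seasonal model regresses a (possibly transformed) response on
``sin(2*pi*t)`` and ``cos(2*pi*t)``, where ``t`` is the calendar day of the
sampling date divided by the number of days in that year, alongside
cohort-specific fixed covariates and optional random intercepts.  The null
model drops the two seasonal columns.  Comparing the two fits gives the
per-feature season test: a chi-square(2) likelihood-ratio test when random
intercepts are present, an exact F test with (2, n - p) degrees of freedom
otherwise.

All mixed-model likelihoods are maximum likelihood (not REML) so that
likelihood-ratio comparisons of fixed effects and BIC are coherent.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from circannual._mixed import GroupedDesign, fit_random_intercept_ml, ols_ml
from circannual.tables import ClimateSeries, ExpressionStudy, parse_date

__all__ = [
    "TimePoint", "ModelSpec", "CosinorFit", "SeasonTestResult",
    "RankDeficiencyError", "day_fraction", "day_fractions",
    "fit_cosinor", "fit_null", "fit_climate_predictor", "season_test",
    "weekly_mean_exposure", "fit_study",
]

TWO_PI = 2.0 * np.pi
#: Smallest positive double; p-values are floored here instead of underflowing to 0.
MIN_P = np.nextafter(0.0, 1.0)


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; ``columns`` names the suspects."""

    def __init__(self, message: str, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


@dataclass(frozen=True)
class TimePoint:
    """Time of year as a fraction in (0, 1]."""

    t: float

    def __post_init__(self):
        if not 0.0 < self.t <= 1.0:
            raise ValueError(f"time fraction must lie in (0, 1], got {self.t}")


def day_fraction(date) -> TimePoint:
    """Map a calendar date to its fraction of the year.

    The ordinal day of the year is divided by the number of days in that
    year (365, or 366 in leap years), so 15 July of a non-leap year maps to
    196/365.
    """
    d = parse_date(date)
    days_in_year = (dt.date(d.year, 12, 31) - dt.date(d.year - 1, 12, 31)).days
    return TimePoint(d.timetuple().tm_yday / days_in_year)


def day_fractions(dates) -> np.ndarray:
    """Vectorised :func:`day_fraction`: returns a float array."""
    return np.array([day_fraction(d).t for d in dates])


@dataclass
class ModelSpec:
    """What goes into the model besides the seasonal terms.

    fixed_covariates
        Metadata column names; ``sex`` is coded F=0 / M=1 and ``a:b`` denotes
        an interaction of two listed columns.
    random_intercepts
        Grouping columns.  One entry uses the fast profiled-likelihood
        fitter; several fall back to ``statsmodels`` variance components.
    response_transform
        ``identity`` (expression matrices are already log2), ``log`` or
        ``log2`` for raw positive responses.
    """

    fixed_covariates: list[str] = field(default_factory=list)
    random_intercepts: list[str] = field(default_factory=list)
    response_transform: str = "identity"

    def __post_init__(self):
        if self.response_transform not in ("identity", "log", "log2"):
            raise ValueError(f"unknown response transform {self.response_transform!r}")


@dataclass
class CosinorFit:
    """A fitted (seasonal or null) per-feature model.

    ``bic = n_params * ln(n_obs) - 2 * loglik`` where ``n_params`` counts the
    fixed coefficients plus all variance parameters (random-intercept
    variances and the residual variance).
    """

    b_hat: float | None
    c_hat: float | None
    coef: dict[str, float]
    re_var: dict[str, float]
    resid_var: float
    loglik: float
    n_obs: int
    n_params: int
    converged: bool = True
    rss: float | None = None  # OLS path only

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_obs) - 2.0 * self.loglik

    @property
    def has_seasonal_terms(self) -> bool:
        return self.b_hat is not None

    @property
    def amplitude(self) -> float:
        if not self.has_seasonal_terms:
            return 0.0
        return float(np.hypot(self.b_hat, self.c_hat))

    @property
    def n_fixed(self) -> int:
        return len(self.coef) + (2 if self.has_seasonal_terms else 0)


@dataclass
class SeasonTestResult:
    """Season-test outcome: LRT against chi-square(2) or an exact F test."""

    statistic: float
    df: tuple
    p_value: float
    family: str  # "LRT_chisq" or "F"

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# design construction

def _encode_column(meta: pd.DataFrame, name: str) -> np.ndarray:
    if name == "sex":
        codes = meta["sex"].map({"F": 0.0, "M": 1.0})
        if codes.isna().any():
            bad = meta.loc[codes.isna(), "sex"].iloc[0]
            raise ValueError(f"cannot encode sex value {bad!r} (need M/F)")
        return codes.to_numpy(dtype=float)
    if name not in meta.columns:
        raise ValueError(f"covariate {name!r} not found in sample metadata")
    vals = pd.to_numeric(meta[name], errors="coerce")
    if vals.isna().any():
        raise ValueError(f"covariate {name!r} has missing/non-numeric entries")
    return vals.to_numpy(dtype=float)


def build_design(meta: pd.DataFrame, spec: ModelSpec, *,
                 seasonal: bool = True, t: np.ndarray | None = None,
                 exposure: np.ndarray | None = None):
    """Assemble the fixed-effects design matrix and its column names."""
    n = len(meta)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for cov in spec.fixed_covariates:
        if ":" in cov:
            a, b = cov.split(":", 1)
            cols.append(_encode_column(meta, a) * _encode_column(meta, b))
        else:
            cols.append(_encode_column(meta, cov))
        names.append(cov)
    if seasonal:
        if t is None:
            t = day_fractions(meta["date"])
        cols.append(np.sin(TWO_PI * t))
        cols.append(np.cos(TWO_PI * t))
        names.extend(["sin_t", "cos_t"])
    if exposure is not None:
        cols.append(np.asarray(exposure, dtype=float))
        names.append("exposure")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # flag columns collinear with the preceding ones via greedy QR ranks
        suspects = [names[j] for j in range(1, X.shape[1])
                    if np.linalg.matrix_rank(X[:, :j + 1]) == np.linalg.matrix_rank(X[:, :j])]
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"collinear columns: {suspects}", suspects)
    return X, names


def _transform_response(y: np.ndarray, spec: ModelSpec) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")
    if spec.response_transform == "log":
        return np.log(y)
    if spec.response_transform == "log2":
        return np.log2(y)
    return y


# ---------------------------------------------------------------------------
# fitting

def _fit(y, X, names, meta, spec: ModelSpec, seasonal: bool) -> CosinorFit:
    n = len(y)
    if n < 8:
        raise ValueError(f"need at least 8 observations, got {n}")
    if not spec.random_intercepts:
        beta, rss, s2, ll = ols_ml(y, X)
        fit = _pack(beta, names, seasonal, {}, s2, ll, n, X.shape[1] + 1)
        fit.rss = rss
        return fit
    if len(spec.random_intercepts) == 1:
        key = spec.random_intercepts[0]
        codes, uniques = pd.factorize(meta[key])
        design = GroupedDesign(X, codes, len(uniques))
        res = fit_random_intercept_ml(y, design)
        fit = _pack(res.beta, names, seasonal, {key: res.sigma_u2},
                    res.sigma_e2, res.loglik, n, X.shape[1] + 2)
        fit.converged = res.converged
        return fit
    return _fit_multi_re(y, X, names, meta, spec, seasonal)


def _fit_multi_re(y, X, names, meta, spec: ModelSpec, seasonal: bool) -> CosinorFit:
    """Several random intercepts: statsmodels MixedLM variance components."""
    import statsmodels.api as sm

    keys = spec.random_intercepts
    frame = pd.DataFrame(X[:, 1:], columns=names[1:])
    frame["_y"] = np.asarray(y, dtype=float)
    for k in keys:
        frame[k] = np.asarray(meta[k]).astype(str)
    fixed = " + ".join(f"Q('{c}')" for c in names[1:]) or "1"
    vc = {k: f"0 + C(Q('{k}'))" for k in keys[1:]}
    model = sm.MixedLM.from_formula(f"_y ~ {fixed}", groups=keys[0],
                                    re_formula="1", vc_formula=vc or None,
                                    data=frame)
    with np.errstate(all="ignore"):
        res = model.fit(reml=False, method="lbfgs", maxiter=200)
    beta = np.array([res.params.get("Intercept", 0.0)]
                    + [res.params[f"Q('{c}')"] for c in names[1:]])
    re_var = {keys[0]: float(res.cov_re.iloc[0, 0])}
    for j, k in enumerate(keys[1:]):
        re_var[k] = float(res.vcomp[j])
    fit = _pack(beta, names, seasonal, re_var, float(res.scale),
                float(res.llf), len(y), X.shape[1] + len(keys) + 1)
    fit.converged = bool(res.converged)
    return fit


def _pack(beta, names, seasonal, re_var, resid_var, loglik, n, n_params) -> CosinorFit:
    coef = dict(zip(names, np.asarray(beta, dtype=float)))
    b = c = None
    if seasonal:
        b = coef.pop("sin_t")
        c = coef.pop("cos_t")
    return CosinorFit(b_hat=b, c_hat=c, coef=coef, re_var=re_var,
                      resid_var=float(resid_var), loglik=float(loglik),
                      n_obs=int(n), n_params=int(n_params))


def fit_cosinor(y, meta: pd.DataFrame, spec: ModelSpec,
                t: np.ndarray | None = None) -> CosinorFit:
    """Fit the seasonal cosinor model to one feature.

    Parameters
    ----------
    y : array-like
        Response vector, one value per metadata row.
    meta : DataFrame
        Sample metadata (``date`` column required unless ``t`` is given).
    spec : ModelSpec
        Covariates, random intercepts, response transform.
    t : array, optional
        Precomputed year fractions (avoids re-parsing dates in a scan loop).
    """
    y = _transform_response(y, spec)
    X, names = build_design(meta, spec, seasonal=True, t=t)
    return _fit(y, X, names, meta, spec, seasonal=True)


def fit_null(y, meta: pd.DataFrame, spec: ModelSpec) -> CosinorFit:
    """Fit the matching model without the seasonal terms."""
    y = _transform_response(y, spec)
    X, names = build_design(meta, spec, seasonal=False)
    return _fit(y, X, names, meta, spec, seasonal=False)


def fit_climate_predictor(y, meta: pd.DataFrame, exposure, spec: ModelSpec) -> CosinorFit:
    """Replace the sin/cos pair with a single measured exposure column.

    The returned fit carries the exposure coefficient under ``coef['exposure']``
    and is comparable with the cosinor fit by log-likelihood or BIC.
    """
    exposure = np.asarray(exposure, dtype=float)
    if len(exposure) != len(meta):
        raise ValueError("need exactly one exposure value per sample")
    y = _transform_response(y, spec)
    X, names = build_design(meta, spec, seasonal=False, exposure=exposure)
    return _fit(y, X, names, meta, spec, seasonal=False)


def season_test(fit_seasonal: CosinorFit, fit_null_: CosinorFit) -> SeasonTestResult:
    """Compare the seasonal and null fits for one feature.

    With random intercepts this is a likelihood-ratio test against
    chi-square with 2 degrees of freedom; for pure fixed-effects fits the
    exact F test on the residual sums of squares is used.
    """
    if not fit_seasonal.has_seasonal_terms or fit_null_.has_seasonal_terms:
        raise ValueError("expected (seasonal, null) fits in that order")
    if fit_seasonal.n_obs != fit_null_.n_obs:
        raise ValueError("fits are not on the same data")
    if fit_seasonal.n_fixed - len(fit_null_.coef) != 2:
        raise ValueError("fits are not nested with 2 extra seasonal columns")
    if fit_seasonal.rss is not None and fit_null_.rss is not None:
        n, p = fit_seasonal.n_obs, fit_seasonal.n_fixed
        df2 = n - p
        if fit_seasonal.rss <= 0.0:
            return SeasonTestResult(np.inf, (2, df2), MIN_P, "F")
        f = ((fit_null_.rss - fit_seasonal.rss) / 2.0) / (fit_seasonal.rss / df2)
        f = max(f, 0.0)
        p_val = float(stats.f.sf(f, 2, df2))
        return SeasonTestResult(float(f), (2, df2), max(p_val, MIN_P), "F")
    stat = 2.0 * (fit_seasonal.loglik - fit_null_.loglik)
    if stat < -1e-6 * max(1.0, abs(fit_null_.loglik)):
        raise ValueError(
            f"seasonal log-likelihood below null ({stat/2:.3g}): optimizer failure")
    stat = max(stat, 0.0)
    p_val = float(stats.chi2.sf(stat, 2))
    return SeasonTestResult(float(stat), (2,), max(p_val, MIN_P), "LRT_chisq")


def weekly_mean_exposure(series: ClimateSeries, date, column: str = "tmean_c") -> float:
    """Mean daily exposure over the 7 days strictly before ``date``."""
    return float(series.window(date, 7, column).mean())


# ---------------------------------------------------------------------------
# whole-study scan

RESULT_COLUMNS = ["feature_id", "b_hat", "c_hat", "loglik_s", "loglik_0",
                  "bic_s", "bic_0", "statistic", "df", "p_season",
                  "mean_expr", "n_obs", "converged"]


def fit_study(study: ExpressionStudy, spec: ModelSpec) -> pd.DataFrame:
    """Run the seasonal-vs-null comparison for every feature of a study.

    Designs and grouping structures are built once and reused across
    features.  Features whose optimizer fails are reported with
    ``converged = False`` and NaN statistics rather than being dropped
    silently.
    """
    meta = study.samples
    t = day_fractions(meta["date"])
    Xs, names_s = build_design(meta, spec, seasonal=True, t=t)
    X0, names_0 = build_design(meta, spec, seasonal=False)
    single_re = len(spec.random_intercepts) == 1
    if single_re:
        codes, uniques = pd.factorize(meta[spec.random_intercepts[0]])
        des_s = GroupedDesign(Xs, codes, len(uniques))
        des_0 = GroupedDesign(X0, codes, len(uniques))
    rows = []
    values = study.matrix.to_numpy(dtype=float)
    for j, feature_id in enumerate(study.matrix.index):
        y = _transform_response(values[j], spec)
        try:
            if not spec.random_intercepts:
                beta_s, rss_s, s2_s, ll_s = ols_ml(y, Xs)
                fs = _pack(beta_s, names_s, True, {}, s2_s, ll_s, len(y), Xs.shape[1] + 1)
                fs.rss = rss_s
                beta_0, rss_0, s2_0, ll_0 = ols_ml(y, X0)
                f0 = _pack(beta_0, names_0, False, {}, s2_0, ll_0, len(y), X0.shape[1] + 1)
                f0.rss = rss_0
            elif single_re:
                rs = fit_random_intercept_ml(y, des_s)
                fs = _pack(rs.beta, names_s, True,
                           {spec.random_intercepts[0]: rs.sigma_u2},
                           rs.sigma_e2, rs.loglik, len(y), Xs.shape[1] + 2)
                fs.converged = rs.converged
                r0 = fit_random_intercept_ml(y, des_0)
                f0 = _pack(r0.beta, names_0, False,
                           {spec.random_intercepts[0]: r0.sigma_u2},
                           r0.sigma_e2, r0.loglik, len(y), X0.shape[1] + 2)
                f0.converged = r0.converged
            else:
                fs = _fit(y, Xs, names_s, meta, spec, seasonal=True)
                f0 = _fit(y, X0, names_0, meta, spec, seasonal=False)
            test = season_test(fs, f0)
        except (ValueError, np.linalg.LinAlgError):
            rows.append((feature_id, np.nan, np.nan, np.nan, np.nan, np.nan,
                         np.nan, np.nan, "", np.nan, float(np.mean(y)),
                         len(y), False))
            continue
        ok = fs.converged and f0.converged
        rows.append((feature_id, fs.b_hat, fs.c_hat, fs.loglik, f0.loglik,
                     fs.bic, f0.bic, test.statistic,
                     ",".join(str(d) for d in test.df), test.p_value,
                     float(np.mean(y)), fs.n_obs, ok))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS).set_index("feature_id", drop=False)
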