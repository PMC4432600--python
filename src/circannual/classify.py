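"""Winter/summer calls, significance gating, and fold changes.

A significant feature is a *winter* feature when its fitted seasonal curve
``r(t) = b*sin(2*pi*t) + c*cos(2*pi*t)`` is strictly positive on every day of
December-February and strictly negative on every day of June-August of a
365-day calendar; a *summer* feature satisfies the reverse; anything else is
*unclassified*.  Fold change is ``2**|r(day 15) - r(day 196)|`` (15 January
vs 15 July).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from circannual.cosinor import TWO_PI, CosinorFit, TimePoint

__all__ = ["SeasonWindows", "relative_expression", "bonferroni_threshold",
           "classify_season", "fold_change", "select_seasonal"]

_DAYS_IN_YEAR = 365
_JAN15 = 15 / _DAYS_IN_YEAR
_JUL15 = 196 / _DAYS_IN_YEAR


def _doy_range(first: int, last: int) -> tuple[int, ...]:
    return tuple(range(first, last + 1))


@dataclass(frozen=True)
class SeasonWindows:
    """Day-of-year windows on a fixed 365-day calendar (February = 28 days)."""

    # Jan 1-31 and Feb 1-28 are days 1-59; Dec 1-31 are days 335-365.
    winter_days: tuple = field(default=_doy_range(1, 59) + _doy_range(335, 365))
    # Jun 1 is day 152, Aug 31 day 243.
    summer_days: tuple = field(default=_doy_range(152, 243))

    def __post_init__(self):
        if set(self.winter_days) & set(self.summer_days):
            raise ValueError("winter and summer windows overlap")


def _coeffs(fit) -> tuple[float, float]:
    if isinstance(fit, CosinorFit):
        if not fit.has_seasonal_terms:
            raise ValueError("fit has no seasonal terms")
        b, c = fit.b_hat, fit.c_hat
    else:
        b, c = fit
    if not (np.isfinite(b) and np.isfinite(c)):
        raise ValueError("non-finite seasonal coefficients")
    return float(b), float(c)


def relative_expression(fit, t) -> float:
    """Seasonal component ``r(t)`` of the fitted curve at year fraction ``t``.

    ``fit`` may be a :class:`CosinorFit` or a plain ``(b, c)`` pair.
    """
    b, c = _coeffs(fit)
    if isinstance(t, TimePoint):
        t = t.t
    t = np.asarray(t, dtype=float)
    out = b * np.sin(TWO_PI * t) + c * np.cos(TWO_PI * t)
    return float(out) if out.ndim == 0 else out


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold ``alpha / m`` for ``m`` tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def classify_season(fit, windows: SeasonWindows | None = None) -> str:
    """Label a fitted curve winter / summer / unclassified by its day-grid signs."""
    windows = windows or SeasonWindows()
    b, c = _coeffs(fit)
    r_winter = relative_expression((b, c), np.array(windows.winter_days) / _DAYS_IN_YEAR)
    r_summer = relative_expression((b, c), np.array(windows.summer_days) / _DAYS_IN_YEAR)
    if (r_winter > 0).all() and (r_summer < 0).all():
        return "winter"
    if (r_winter < 0).all() and (r_summer > 0).all():
        return "summer"
    return "unclassified"


def fold_change(fit) -> float:
    """Fold change between 15 January and 15 July: ``2**|r(15/365) - r(196/365)|``."""
    b, c = _coeffs(fit)
    delta = relative_expression((b, c), _JAN15) - relative_expression((b, c), _JUL15)
    return float(2.0 ** abs(delta))


def select_seasonal(results: pd.DataFrame, threshold: float,
                    mean_expr_min: float | None = None,
                    windows: SeasonWindows | None = None) -> pd.DataFrame:
    """Apply the significance (and optional mean-expression) gates and label features.

    Parameters
    ----------
    results : DataFrame
        Per-feature scan output with at least ``feature_id``, ``p_season``,
        ``b_hat``, ``c_hat`` and ``mean_expr`` columns (see ``fit_study``).
    threshold : float
        Bonferroni-corrected p-value gate, typically ``alpha / n_features``.
    mean_expr_min : float, optional
        Minimum mean log2 expression; omitted when None (some cohorts in
        practice are gated on significance only).

    Returns
    -------
    DataFrame indexed like ``results`` with ``passes_bonferroni``,
    ``passes_expression_filter``, ``label`` and ``fold_change`` columns.
    Features failing a gate get label ``not_seasonal`` and fold change NaN.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    windows = windows or SeasonWindows()
    out = results.copy()
    p = out["p_season"].to_numpy(dtype=float)
    out["passes_bonferroni"] = (p < threshold) & np.isfinite(p)
    if mean_expr_min is None:
        out["passes_expression_filter"] = True
    else:
        out["passes_expression_filter"] = out["mean_expr"] >= mean_expr_min
    selected = out["passes_bonferroni"] & out["passes_expression_filter"]
    labels, folds = [], []
    for sel, b, c in zip(selected, out["b_hat"], out["c_hat"]):
        if not sel:
            labels.append("not_seasonal")
            folds.append(np.nan)
        else:
            labels.append(classify_season((b, c), windows))
            folds.append(fold_change((b, c)))
    out["label"] = labels
    out["fold_change"] = folds
    return out


def summarize_labels(classified: pd.DataFrame) -> dict:
    """Counts per label plus mean fold change of winter and summer features."""
    counts = classified["label"].value_counts().to_dict()
    summary = {lab: int(counts.get(lab, 0))
               for lab in ("winter", "summer", "unclassified", "not_seasonal")}
    summary["n_selected"] = summary["winter"] + summary["summer"] + summary["unclassified"]
    for lab in ("winter", "summer"):
        sub = classified.loc[classified["label"] == lab, "fold_change"]
        summary[f"mean_fold_change_{lab}"] = float(sub.mean()) if len(sub) else None
    return summary
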