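"""Cross-cohort replication: BIC preference, candidate gating, Fisher's method.

Within each cohort group, candidate features are those significant at the
Bonferroni gate in at least one member cohort; a candidate replicates when
the seasonal model's BIC beats the null model's in *every* member cohort.
The common set is the intersection across groups.  Evidence is combined over
cohorts with Fisher's product method, and phase concordance is judged on the
hemisphere-adjusted sign of the cosine coefficient (a southern-hemisphere
cohort is expected to show the inverted raw phase).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from circannual.cosinor import MIN_P, CosinorFit

__all__ = ["CohortResult", "PairingPlan", "bic_prefers_seasonal",
           "candidate_features", "common_seasonal", "fisher_combine"]

logger = logging.getLogger(__name__)

_REQUIRED = ("feature_id", "p_season", "bic_s", "bic_0", "b_hat", "c_hat")


@dataclass
class CohortResult:
    """Per-feature scan results for one cohort, as produced by ``fit_study``."""

    cohort: str
    results: pd.DataFrame = field(repr=False)
    hemisphere: str = "north"

    def __post_init__(self):
        missing = [c for c in _REQUIRED if c not in self.results.columns]
        if missing:
            raise ValueError(f"cohort {self.cohort!r} results missing columns {missing}")
        if self.hemisphere not in ("north", "south"):
            raise ValueError(f"hemisphere must be north/south, got {self.hemisphere!r}")
        self.results = self.results.set_index(
            self.results["feature_id"].astype(str), drop=False)


@dataclass
class PairingPlan:
    """Which cohorts share a candidate gate and must agree on BIC.

    Each group is a list of cohort names; the common set is the intersection
    of the per-group replicated sets.  ``gate`` is the Bonferroni-corrected
    p-value threshold used for candidacy within every group.
    """

    groups: list[list[str]]
    gate: float = 0.05 / 33297

    def __post_init__(self):
        if not self.groups or any(not g for g in self.groups):
            raise ValueError("pairing plan needs at least one non-empty cohort group")


def bic_prefers_seasonal(fit_s, fit_0) -> bool:
    """True iff the seasonal model has the strictly smaller BIC."""
    bic_s = fit_s.bic if isinstance(fit_s, CosinorFit) else float(fit_s)
    bic_0 = fit_0.bic if isinstance(fit_0, CosinorFit) else float(fit_0)
    if not (np.isfinite(bic_s) and np.isfinite(bic_0)):
        raise ValueError("non-finite BIC: fits not comparable")
    return bool(bic_s < bic_0)


def candidate_features(result_a: CohortResult, result_b: CohortResult,
                       gate: float) -> set[str]:
    """Features below the gate in at least one of the two cohorts."""
    ids_a, ids_b = set(result_a.results.index), set(result_b.results.index)
    shared = ids_a & ids_b
    if not shared:
        raise ValueError(
            f"cohorts {result_a.cohort!r} and {result_b.cohort!r} share no features")
    hits = set()
    for res in (result_a, result_b):
        p = res.results["p_season"]
        hits |= set(res.results.index[(p < gate) & p.notna()])
    return hits & shared


def fisher_combine(p_values) -> float:
    """Fisher's product method: ``-2 * sum(log p)`` against chi-square(2k).

    Exact zeros (underflow upstream) are clamped to the smallest positive
    double with a warning; values outside (0, 1] raise.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p > 1.0).any() or (p < 0.0).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    if (p == 0.0).any():
        logger.warning("clamping %d zero p-value(s) before Fisher combination",
                       int((p == 0.0).sum()))
        p = np.maximum(p, MIN_P)
    x = -2.0 * np.sum(np.log(p))
    return float(max(stats.chi2.sf(x, 2 * p.size), MIN_P))


def _adjusted_sign(c_hat: float, hemisphere: str) -> float:
    s = np.sign(c_hat)
    return -s if hemisphere == "south" else s


def common_seasonal(cohort_results: list[CohortResult],
                    plan: PairingPlan | None = None) -> pd.DataFrame:
    """Identify features whose seasonality replicates across cohorts.

    Returns one row per common feature with per-cohort BIC differences
    (``bic_delta_<cohort>`` = seasonal - null, negative means preferred), the
    Fisher-combined p-value over all cohorts, a ``concordant_phase`` flag
    (all hemisphere-adjusted cosine signs agree), and per-cohort
    ``phase_inverted_<cohort>`` flags relative to the first cohort's raw sign.
    """
    if not cohort_results:
        raise ValueError("need at least one cohort")
    by_name = {r.cohort: r for r in cohort_results}
    if plan is None:
        plan = PairingPlan(groups=[[r.cohort for r in cohort_results]])
    for group in plan.groups:
        for name in group:
            if name not in by_name:
                raise ValueError(f"pairing plan references unknown cohort {name!r}")

    common: set[str] | None = None
    for group in plan.groups:
        members = [by_name[name] for name in group]
        shared = set.intersection(*(set(m.results.index) for m in members))
        if not shared:
            raise ValueError(f"cohort group {group} shares no features")
        cand = set()
        for m in members:
            p = m.results["p_season"]
            cand |= set(m.results.index[(p < plan.gate) & p.notna()])
        cand &= shared
        replicated = set()
        for fid in cand:
            ok = True
            for m in members:
                if fid not in m.results.index:
                    ok = False
                    break
                row = m.results.loc[fid]
                if not (np.isfinite(row["bic_s"]) and np.isfinite(row["bic_0"])
                        and row["bic_s"] < row["bic_0"]):
                    ok = False
                    break
            if ok:
                replicated.add(fid)
        common = replicated if common is None else (common & replicated)

    all_cohorts = sorted({name for group in plan.groups for name in group})
    ref_name = plan.groups[0][0]
    rows = []
    for fid in sorted(common):
        row: dict = {"feature_id": fid}
        adj_signs, ps = [], []
        ref_sign = np.sign(by_name[ref_name].results.loc[fid, "c_hat"])
        for name in all_cohorts:
            res = by_name[name]
            rec = res.results.loc[fid]
            row[f"bic_delta_{name}"] = float(rec["bic_s"] - rec["bic_0"])
            row[f"phase_inverted_{name}"] = bool(np.sign(rec["c_hat"]) == -ref_sign)
            adj_signs.append(_adjusted_sign(rec["c_hat"], res.hemisphere))
            ps.append(float(rec["p_season"]))
        row["combined_p"] = fisher_combine(ps)
        row["concordant_phase"] = bool(len(set(adj_signs)) == 1 and adj_signs[0] != 0)
        rows.append(row)
    cols = (["feature_id"]
            + [f"bic_delta_{n}" for n in all_cohorts]
            + [f"phase_inverted_{n}" for n in all_cohorts]
            + ["combined_p", "concordant_phase"])
    return pd.DataFrame(rows, columns=cols)
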