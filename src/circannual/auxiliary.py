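"""PCA-based helper analyses: sex inference from Y-linked markers and the
self-reported-infection effect test.

Both summarize a feature x sample expression block by its first principal
component over samples (centered, unscaled -- the inputs share units).  The
PC sign is arbitrary, so sex calls anchor the orientation to the mean marker
expression: samples with higher Y-gene expression get positive scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["Y_MARKER_GENES", "SexCall", "InfectionTest", "infer_sex",
           "infection_effect_test"]

#: Y-chromosome expressed genes used for sex inference in PBMC data.
Y_MARKER_GENES = ("DDX3Y", "KDM5D", "USP9Y", "RPS4Y1")


@dataclass
class SexCall:
    sample_id: str
    pc1_score: float
    call: str | None  # "M", "F", or None when the score is exactly 0


@dataclass
class InfectionTest:
    group_sizes: tuple[int, int]
    pc1_variance_explained: float
    statistic: float
    p_value: float


def _pc1_scores(values: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC scores of samples for a feature x sample block.

    Returns (scores, fraction of variance explained).  Features are centered;
    no scaling.
    """
    centered = values - values.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise ValueError("zero-variance expression block: no principal component")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = s[0] * vt[0]
    explained = float(s[0] ** 2 / np.sum(s ** 2))
    return scores, explained


def infer_sex(expr: pd.DataFrame, markers=Y_MARKER_GENES) -> list[SexCall]:
    """Call sample sex from the first PC of Y-marker gene expression.

    ``expr`` is a feature x sample matrix containing all four marker rows.
    PC1 is oriented so that higher mean marker expression maps to positive
    scores; positive scores are called male, negative female, and an exact
    zero is left uncalled.
    """
    missing = [m for m in markers if m not in expr.index]
    if missing:
        raise ValueError(f"missing marker features: {missing}")
    sub = expr.loc[list(markers)]
    if sub.shape[1] < 2:
        raise ValueError("need at least 2 samples to infer sex")
    values = sub.to_numpy(dtype=float)
    scores, _ = _pc1_scores(values)
    marker_mean = values.mean(axis=0)
    # orient PC1: high Y expression -> positive score
    corr = np.dot(scores - scores.mean(), marker_mean - marker_mean.mean())
    if corr < 0:
        scores = -scores
    calls = []
    for sample_id, score in zip(sub.columns, scores):
        call = "M" if score > 0 else "F" if score < 0 else None
        calls.append(SexCall(str(sample_id), float(score), call))
    return calls


def infection_effect_test(expr: pd.DataFrame, infection_status) -> InfectionTest:
    """One-way ANOVA of PC1 expression scores on binary infection status.

    ``expr`` holds the seasonal (or module) features x samples; ``infection_status``
    is 0 (no reported infection) or 1 (at least one), one entry per sample.
    """
    status = np.asarray(infection_status)
    if len(status) != expr.shape[1]:
        raise ValueError("need one infection status per sample")
    status = (pd.to_numeric(pd.Series(status)) > 0).to_numpy()
    n0, n1 = int((~status).sum()), int(status.sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both infection groups must be non-empty")
    scores, explained = _pc1_scores(expr.to_numpy(dtype=float))
    f_stat, p = stats.f_oneway(scores[~status], scores[status])
    return InfectionTest((n0, n1), explained, float(f_stat), float(p))
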