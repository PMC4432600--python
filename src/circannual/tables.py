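"""Core data containers: expression studies, climate series, blood-count tables.

Sample metadata is carried as a :class:`pandas.DataFrame` with a documented
schema rather than per-row objects; the columns are listed in
``SAMPLE_COLUMNS``.  Dates are ISO 8601 strings or ``datetime.date``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionStudy", "ClimateSeries", "FBCTable", "SAMPLE_COLUMNS",
           "parse_date", "validate_samples"]

#: Recognised sample-metadata columns.  ``sample_id``, ``subject_id`` and
#: ``date`` are required; the rest are optional and cohort-specific.
SAMPLE_COLUMNS = (
    "sample_id", "subject_id", "family_id", "zygosity", "date", "age",
    "sex", "cohort", "disease_phase", "infections_reported",
)


def parse_date(value) -> dt.date:
    """Parse an ISO 8601 date string (or pass through a ``date``)."""
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValueError(f"unparseable date {value!r}: {exc}") from None


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate sample metadata; returns a copy with dates parsed.

    Raises ``ValueError`` naming the offending row for malformed entries.
    """
    for col in ("sample_id", "subject_id", "date"):
        if col not in samples.columns:
            raise ValueError(f"sample metadata is missing required column {col!r}")
    out = samples.copy()
    dates = []
    for idx, value in out["date"].items():
        try:
            dates.append(parse_date(value))
        except ValueError as exc:
            raise ValueError(f"row {idx!r}: {exc}") from None
    out["date"] = dates
    if out["sample_id"].duplicated().any():
        dup = out.loc[out["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r}")
    if "age" in out.columns:
        ages = pd.to_numeric(out["age"], errors="coerce")
        if (ages.dropna() < 0).any():
            bad = out.index[ages < 0][0]
            raise ValueError(f"row {bad!r}: negative age")
    return out


@dataclass
class ExpressionStudy:
    """One cohort: a log2 feature x sample matrix plus per-sample metadata.

    ``truth`` is present only for simulated studies and holds the planted
    per-feature seasonal coefficients and labels.
    """

    name: str
    matrix: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame | None = None
    hemisphere: str = "north"

    def __post_init__(self):
        self.samples = validate_samples(self.samples)
        if list(self.matrix.columns) != list(self.samples["sample_id"]):
            if set(self.matrix.columns) != set(self.samples["sample_id"]):
                raise ValueError(
                    f"study {self.name!r}: matrix columns do not match sample_id set"
                )
            self.matrix = self.matrix[list(self.samples["sample_id"])]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ClimateSeries:
    """Daily climate exposures: mean temperature (C) and sunlight hours."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        for col in ("date", "tmean_c", "sun_hours"):
            if col not in self.data.columns:
                raise ValueError(f"climate series is missing column {col!r}")
        d = self.data.copy()
        d["date"] = [parse_date(v) for v in d["date"]]
        self.data = d.sort_values("date").reset_index(drop=True)
        self._by_date = self.data.set_index("date")

    def window(self, end_date, n_days: int, column: str) -> np.ndarray:
        """Daily values for the ``n_days`` days strictly before ``end_date``."""
        end = parse_date(end_date)
        days = [end - dt.timedelta(days=k) for k in range(n_days, 0, -1)]
        missing = [d for d in days if d not in self._by_date.index]
        if missing:
            raise ValueError(f"climate series is missing days: {missing[:3]}"
                             + ("..." if len(missing) > 3 else ""))
        return self._by_date.loc[days, column].to_numpy(dtype=float)


@dataclass
class FBCTable:
    """Full-blood-count table: one row per donor with month/date, age, sex."""

    data: pd.DataFrame = field(repr=False)
    responses: tuple[str, ...] = ()

    def __post_init__(self):
        cols = set(self.data.columns)
        if "month" not in cols and "date" not in cols:
            raise ValueError("FBC table needs a 'month' or 'date' column")
        if "month" in cols:
            months = pd.to_numeric(self.data["month"])
            if ((months < 1) | (months > 12)).any():
                raise ValueError("month values must lie in 1..12")
        if not self.responses:
            reserved = {"donor_id", "month", "date", "age", "sex"}
            self.responses = tuple(c for c in self.data.columns if c not in reserved)
        for r in self.responses:
            vals = pd.to_numeric(self.data[r], errors="coerce")
            if not np.isfinite(vals).all():
                raise ValueError(f"response {r!r} contains non-finite values")

    @property
    def n_donors(self) -> int:
        return len(self.data)
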