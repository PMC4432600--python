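"""Synthetic cohorts, climate series, and blood-count tables.

The generators mirror the structure the fitting code assumes: log2
expression equal to a baseline plus optional covariate effects, a per-subject
random intercept, an annual sinusoid ``b*sin(2*pi*t) + c*cos(2*pi*t)`` for
the seasonal fraction of features, and Gaussian residuals.  Simulated
studies carry a truth table with the planted coefficients and labels so
recovery can be scored downstream.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from circannual.classify import classify_season
from circannual.cosinor import TWO_PI, day_fractions
from circannual.tables import ClimateSeries, ExpressionStudy, FBCTable, parse_date

__all__ = ["SimulationConfig", "simulate_cohort", "simulate_climate",
           "simulate_fbc", "ExpressionStudy", "ClimateSeries", "FBCTable"]

# acrophase (peak time, fraction of year) bands per mode; the winter band is
# centered on mid-January so planted features satisfy the strict winter /
# summer day-window geometry with margin
_PEAK_BANDS = {"winter": (-0.05, 0.10), "summer": (0.45, 0.60), "uniform": (0.0, 1.0)}


@dataclass
class SimulationConfig:
    """Knobs for one synthetic expression cohort.

    Variance magnitudes are config, not claims: real cohorts do not publish
    their per-gene variance components, so defaults are round numbers on the
    log2 scale.
    """

    n_subjects: int = 50
    visits_per_subject: int = 4
    date_range: tuple[str, str] = ("2010-01-01", "2012-12-31")
    n_features: int = 200
    frac_seasonal: float = 0.25
    amplitude_range: tuple[float, float] = (0.3, 0.8)
    acrophase_mode: str = "uniform"
    subject_sd: float = 0.5
    residual_sd: float = 0.5
    covariate_effects: dict = field(default_factory=dict)  # {"age": .., "sex": ..}
    hemisphere: str = "north"
    baseline_mean: float = 8.0
    age_range: tuple[float, float] = (1.0, 10.0)
    seed: int = 0
    cohort: str = "sim"

    def validate(self):
        if self.n_subjects <= 0 or self.visits_per_subject <= 0 or self.n_features <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.frac_seasonal <= 1.0:
            raise ValueError("frac_seasonal must lie in [0, 1]")
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.acrophase_mode not in _PEAK_BANDS:
            raise ValueError(f"unknown acrophase_mode {self.acrophase_mode!r}")
        if self.hemisphere not in ("north", "south"):
            raise ValueError(f"hemisphere must be north/south, got {self.hemisphere!r}")
        start, end = (parse_date(d) for d in self.date_range)
        if start >= end:
            raise ValueError("date_range start must precede end")
        return start, end


def simulate_cohort(config: SimulationConfig) -> ExpressionStudy:
    """Generate one synthetic cohort with planted seasonal features.

    Seasonal coefficients are drawn as ``(b, c) = A*(sin, cos)(2*pi*t_peak)``
    with the amplitude uniform over ``amplitude_range`` and the peak time
    drawn inside the band for ``acrophase_mode``.  A southern-hemisphere
    cohort negates ``(b, c)``, shifting every acrophase by half a year.
    Covariate effects apply to centered covariates so ``baseline_mean``
    remains the marginal mean.
    """
    start, end = config.validate()
    rng = np.random.default_rng(config.seed)
    n_sub, n_vis = config.n_subjects, config.visits_per_subject
    n_samples = n_sub * n_vis

    subjects = np.repeat([f"S{i:04d}" for i in range(n_sub)], n_vis)
    sex_per_subject = rng.choice(["F", "M"], size=n_sub)
    age0 = rng.uniform(*config.age_range, size=n_sub)
    span_days = (end - start).days
    offsets = np.sort(rng.integers(0, span_days + 1, size=(n_sub, n_vis)), axis=1)
    dates = [start + dt.timedelta(days=int(o)) for o in offsets.ravel()]
    ages = (np.repeat(age0, n_vis) + offsets.ravel() / 365.25).round(3)
    samples = pd.DataFrame({
        "sample_id": [f"V{i:05d}" for i in range(n_samples)],
        "subject_id": subjects,
        "family_id": subjects,
        "zygosity": "singleton",
        "date": [d.isoformat() for d in dates],
        "age": ages,
        "sex": np.repeat(sex_per_subject, n_vis),
        "cohort": config.cohort,
    })
    t = day_fractions(samples["date"])

    n_seasonal = int(round(config.frac_seasonal * config.n_features))
    amp = rng.uniform(*config.amplitude_range, size=n_seasonal)
    lo, hi = _PEAK_BANDS[config.acrophase_mode]
    t_peak = np.mod(rng.uniform(lo, hi, size=n_seasonal), 1.0)
    b = amp * np.sin(TWO_PI * t_peak)
    c = amp * np.cos(TWO_PI * t_peak)
    if config.hemisphere == "south":
        b, c = -b, -c
    b_all = np.concatenate([b, np.zeros(config.n_features - n_seasonal)])
    c_all = np.concatenate([c, np.zeros(config.n_features - n_seasonal)])

    u = rng.normal(0.0, config.subject_sd, size=(config.n_features, n_sub))
    subj_effect = np.repeat(u, n_vis, axis=1)
    cov = np.zeros(n_samples)
    if config.covariate_effects.get("age"):
        cov = cov + config.covariate_effects["age"] * (ages - ages.mean())
    if config.covariate_effects.get("sex"):
        sex_num = (samples["sex"] == "M").to_numpy(dtype=float)
        cov = cov + config.covariate_effects["sex"] * (sex_num - sex_num.mean())

    seasonal = np.outer(b_all, np.sin(TWO_PI * t)) + np.outer(c_all, np.cos(TWO_PI * t))
    noise = rng.normal(0.0, config.residual_sd, size=(config.n_features, n_samples))
    values = config.baseline_mean + cov[None, :] + subj_effect + seasonal + noise

    feature_ids = [f"G{j:05d}" for j in range(config.n_features)]
    matrix = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                          columns=samples["sample_id"])
    truth = pd.DataFrame({
        "feature_id": feature_ids,
        "seasonal": [j < n_seasonal for j in range(config.n_features)],
        "b": b_all,
        "c": c_all,
        "label": [classify_season((bj, cj)) if j < n_seasonal else "not_seasonal"
                  for j, (bj, cj) in enumerate(zip(b_all, c_all))],
    }).set_index("feature_id", drop=False)
    return ExpressionStudy(name=config.cohort, matrix=matrix, samples=samples,
                           truth=truth, hemisphere=config.hemisphere)


def simulate_climate(date_range, seed: int = 0, *, mean_temp: float = 10.0,
                     temp_amplitude: float = 8.0, peak_frac: float = 196 / 365,
                     noise_sd: float = 2.0, ar: float = 0.7,
                     sun_base: float = 8.0, sun_amplitude: float = 4.0,
                     sun_noise_sd: float = 1.0) -> ClimateSeries:
    """Daily temperature / sunlight series: annual sinusoid + AR(1) noise.

    With ``noise_sd = sun_noise_sd = 0`` the series is exactly sinusoidal,
    which the tests exploit for closed-form window means.  Sunlight hours
    are clipped at zero.
    """
    start, end = (parse_date(d) for d in date_range)
    if start > end:
        raise ValueError("empty date range")
    rng = np.random.default_rng(seed)
    dates = [start + dt.timedelta(days=k) for k in range((end - start).days + 1)]
    t = day_fractions(dates)
    n = len(dates)
    seasonal = np.cos(TWO_PI * (t - peak_frac))

    def ar1(sd):
        if sd == 0.0:
            return np.zeros(n)
        innov = rng.normal(0.0, sd * np.sqrt(1 - ar ** 2), size=n)
        out = np.empty(n)
        out[0] = rng.normal(0.0, sd)
        for k in range(1, n):
            out[k] = ar * out[k - 1] + innov[k]
        return out

    temp = mean_temp + temp_amplitude * seasonal + ar1(noise_sd)
    sun = np.clip(sun_base + sun_amplitude * seasonal + ar1(sun_noise_sd), 0.0, None)
    data = pd.DataFrame({"date": [d.isoformat() for d in dates],
                         "tmean_c": temp, "sun_hours": sun})
    return ClimateSeries(data)


#: default log-scale baselines for simulated blood-count responses (arbitrary
#: but positive; units are whatever the analyser reports)
_FBC_BASELINES = {"wbc": 6.5, "lymphocytes": 2.0, "monocytes": 0.5,
                  "neutrophils": 4.0, "platelets": 250.0}


def simulate_fbc(n_donors: int, seasonal_amplitudes: dict[str, float],
                 seed: int = 0, *, baselines: dict[str, float] | None = None,
                 peak_frac: float = 15 / 365, noise_sd: float = 0.15,
                 age_effect: float = 0.0, sex_effect: float = 0.0,
                 with_dates: bool = False) -> FBCTable:
    """One-visit-per-donor blood-count table with log-scale seasonal means.

    Each response is ``exp(log(baseline) + A*cos(2*pi*(t - peak)) + effects
    + noise)``, so counts are strictly positive and the log-mean carries the
    requested first-harmonic seasonal term of amplitude ``A``.
    """
    if n_donors <= 0:
        raise ValueError("n_donors must be positive")
    if any(a < 0 for a in seasonal_amplitudes.values()):
        raise ValueError("seasonal amplitudes must be >= 0")
    baselines = dict(_FBC_BASELINES if baselines is None else baselines)
    for r in seasonal_amplitudes:
        baselines.setdefault(r, 1.0)
    rng = np.random.default_rng(seed)
    month = rng.integers(1, 13, size=n_donors)
    age = rng.uniform(18.0, 75.0, size=n_donors).round(1)
    sex = rng.choice(["F", "M"], size=n_donors)
    t = month / 12.0
    data = {"donor_id": [f"D{i:05d}" for i in range(n_donors)],
            "month": month, "age": age, "sex": sex}
    if with_dates:
        data["date"] = [f"2014-{m:02d}-15" for m in month]
    sex_num = (sex == "M").astype(float)
    for resp, base in baselines.items():
        amp = seasonal_amplitudes.get(resp, 0.0)
        logmu = (np.log(base) + amp * np.cos(TWO_PI * (t - peak_frac))
                 + age_effect * (age - age.mean()) / 10.0
                 + sex_effect * (sex_num - 0.5)
                 + rng.normal(0.0, noise_sd, size=n_donors))
        data[resp] = np.exp(logmu)
    return FBCTable(pd.DataFrame(data), responses=tuple(baselines))
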