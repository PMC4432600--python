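"""End-to-end orchestration: simulate/load -> fit -> classify -> cross-cohort.

A pipeline run is driven by a single config (dict or YAML) holding cohort
sources, per-cohort model specs, gates, and one seed; all outputs land in
the configured directory and a machine-readable summary is returned and
written as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from circannual import io
from circannual.classify import bonferroni_threshold, select_seasonal, summarize_labels
from circannual.cosinor import ModelSpec, fit_study
from circannual.crosscohort import CohortResult, PairingPlan, common_seasonal
from circannual.simulate import SimulationConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CohortSpec:
    name: str
    model: ModelSpec
    hemisphere: str = "north"
    simulate: SimulationConfig | None = None
    paths: dict | None = None

    def validate(self):
        if (self.simulate is None) == (self.paths is None):
            raise ValueError(
                f"cohort {self.name!r}: exactly one of 'simulate' or 'paths' required")
        if self.paths is not None:
            for key in ("matrix", "samples"):
                if key not in self.paths:
                    raise ValueError(f"cohort {self.name!r}: missing path {key!r}")
                if not Path(self.paths[key]).exists():
                    raise ValueError(
                        f"cohort {self.name!r}: path {self.paths[key]!r} does not exist")
        if self.simulate is not None:
            self.simulate.validate()


@dataclasses.dataclass
class PipelineConfig:
    cohorts: list[CohortSpec]
    output_dir: str = "circannual_out"
    seed: int = 0
    alpha: float = 0.05
    mean_expr_min: float | None = None
    pairing_groups: list[list[str]] | None = None
    gate_m: int | None = None  # Bonferroni denominator for the cross-cohort gate

    def validate(self):
        if not self.cohorts:
            raise ValueError("pipeline needs at least one cohort")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        names = [c.name for c in self.cohorts]
        if len(set(names)) != len(names):
            raise ValueError("cohort names must be unique")
        for c in self.cohorts:
            c.validate()
        if self.pairing_groups:
            known = set(names)
            for group in self.pairing_groups:
                unknown = [n for n in group if n not in known]
                if unknown:
                    raise ValueError(f"pairing plan references unknown cohorts {unknown}")


def load_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    cohorts = []
    for entry in raw.get("cohorts", []):
        model = ModelSpec(**entry.get("model", {}))
        sim = None
        if "simulate" in entry:
            sim = SimulationConfig(**{"cohort": entry["name"],
                                      "hemisphere": entry.get("hemisphere", "north"),
                                      **entry["simulate"]})
        cohorts.append(CohortSpec(name=entry["name"], model=model,
                                  hemisphere=entry.get("hemisphere", "north"),
                                  simulate=sim, paths=entry.get("paths")))
    gates = raw.get("gates", {})
    pairing = raw.get("pairing", {})
    return PipelineConfig(
        cohorts=cohorts,
        output_dir=raw.get("output_dir", "circannual_out"),
        seed=int(raw.get("seed", 0)),
        alpha=float(gates.get("alpha", 0.05)),
        mean_expr_min=gates.get("mean_expr_min"),
        pairing_groups=pairing.get("groups"),
        gate_m=pairing.get("gate_m"),
    )


def _recovery_metrics(classified, truth) -> dict:
    """Score calls against the planted truth of a simulated cohort."""
    merged = classified.join(truth[["seasonal", "label"]].rename(
        columns={"label": "true_label"}), how="inner")
    called = merged["label"].isin(["winter", "summer", "unclassified"])
    seasonal = merged["seasonal"].astype(bool)
    tp = int((called & seasonal).sum())
    fp = int((called & ~seasonal).sum())
    fn = int((~called & seasonal).sum())
    labels_match = merged.loc[called & seasonal, "label"] == \
        merged.loc[called & seasonal, "true_label"]
    return {
        "sensitivity": tp / max(tp + fn, 1),
        "false_positives": fp,
        "label_accuracy": float(labels_match.mean()) if tp else None,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the run summary.

    All randomness derives from ``config.seed``; simulated cohorts get
    ``seed + index`` so cohorts are distinct but the run is reproducible.
    Validation runs up front: a bad config produces no partial outputs.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    summary: dict = {"seed": config.seed, "cohorts": {}}
    cohort_results = []
    for idx, cspec in enumerate(config.cohorts):
        logger.info("stage=load cohort=%s", cspec.name)
        if cspec.simulate is not None:
            sim = dataclasses.replace(cspec.simulate, seed=config.seed + idx)
            study = simulate_cohort(sim)
        else:
            study = io.read_study(cspec.paths["matrix"], cspec.paths["samples"],
                                  cspec.paths.get("truth"), name=cspec.name,
                                  hemisphere=cspec.hemisphere)
        logger.info("stage=fit cohort=%s n_features=%d", cspec.name, study.n_features)
        results = fit_study(study, cspec.model)
        n_failed = int((~results["converged"].astype(bool)).sum())
        if n_failed:
            logger.warning("stage=fit cohort=%s failed_features=%d", cspec.name, n_failed)
        threshold = bonferroni_threshold(config.alpha, study.n_features)
        classified = select_seasonal(results, threshold,
                                     mean_expr_min=config.mean_expr_min)
        io.write_results(classified, out_dir / f"{cspec.name}.results.tsv")
        cohort_summary = summarize_labels(classified)
        cohort_summary["n_features"] = study.n_features
        cohort_summary["n_samples"] = study.n_samples
        cohort_summary["n_not_converged"] = n_failed
        cohort_summary["bonferroni_threshold"] = threshold
        if study.truth is not None:
            cohort_summary["recovery"] = _recovery_metrics(classified, study.truth)
        summary["cohorts"][cspec.name] = cohort_summary
        cohort_results.append(CohortResult(cohort=cspec.name, results=classified,
                                           hemisphere=cspec.hemisphere))

    if len(cohort_results) >= 2:
        groups = config.pairing_groups or [[c.cohort for c in cohort_results]]
        m = config.gate_m or max(len(r.results) for r in cohort_results)
        plan = PairingPlan(groups=groups, gate=bonferroni_threshold(config.alpha, m))
        logger.info("stage=crosscohort groups=%s gate=%.3g", groups, plan.gate)
        common = common_seasonal(cohort_results, plan)
        io.write_results(common, out_dir / "common_seasonal.tsv")
        summary["common"] = {
            "n_common": int(len(common)),
            "n_concordant_phase": int(common["concordant_phase"].sum()) if len(common) else 0,
            "gate": plan.gate,
        }

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
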