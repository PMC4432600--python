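"""Plain-text readers/writers for the package's table schemas.

Expression matrices travel as TSV (first column ``feature_id``, one column
per sample), metadata and climate/FBC tables as CSV with ISO 8601 dates, and
per-feature results as TSV.  Readers are tolerant of extra columns and
report the offending row on schema violations.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from circannual.tables import ClimateSeries, ExpressionStudy, FBCTable

__all__ = ["write_study", "read_study", "write_climate", "read_climate",
           "write_fbc", "read_fbc", "write_results", "read_results"]

_FLOAT_FMT = "%.10g"


def write_study(study: ExpressionStudy, directory) -> dict[str, Path]:
    """Write matrix TSV + samples CSV (+ truth TSV for simulated studies)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["matrix"] = directory / f"{study.name}.expression.tsv"
    matrix = study.matrix.copy()
    matrix.index.name = "feature_id"
    matrix.to_csv(paths["matrix"], sep="\t", float_format=_FLOAT_FMT)
    paths["samples"] = directory / f"{study.name}.samples.csv"
    samples = study.samples.copy()
    samples["date"] = [d.isoformat() for d in samples["date"]]
    samples.to_csv(paths["samples"], index=False)
    if study.truth is not None:
        paths["truth"] = directory / f"{study.name}.truth.tsv"
        study.truth.to_csv(paths["truth"], sep="\t", index=False,
                           float_format=_FLOAT_FMT)
    return paths


def read_study(matrix_path, samples_path, truth_path=None, name=None,
               hemisphere: str = "north") -> ExpressionStudy:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, dtype={"sample_id": str, "subject_id": str})
    truth = None
    if truth_path is not None:
        truth = pd.read_csv(truth_path, sep="\t")
        truth = truth.set_index("feature_id", drop=False)
    name = name or Path(matrix_path).stem.split(".")[0]
    matrix.columns = matrix.columns.astype(str)
    return ExpressionStudy(name=name, matrix=matrix, samples=samples,
                           truth=truth, hemisphere=hemisphere)


def write_climate(series: ClimateSeries, path) -> Path:
    path = Path(path)
    out = series.data.copy()
    out["date"] = [d.isoformat() for d in out["date"]]
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_climate(path) -> ClimateSeries:
    return ClimateSeries(pd.read_csv(path))


def write_fbc(table: FBCTable, path) -> Path:
    path = Path(path)
    table.data.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_fbc(path, responses: tuple[str, ...] = ()) -> FBCTable:
    return FBCTable(pd.read_csv(path, dtype={"donor_id": str}), responses=responses)


def write_results(results: pd.DataFrame, path) -> Path:
    path = Path(path)
    results.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_results(path) -> pd.DataFrame:
    out = pd.read_csv(path, sep="\t")
    if "feature_id" in out.columns:
        out = out.set_index(out["feature_id"].astype(str), drop=False)
    return out
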