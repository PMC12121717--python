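"""Reading and writing cohort tables and analysis reports.

Two delimited-text inputs are supported, matching common laboratory exports:

* pyro run table: ``sample_id, run_id, cpg_<site>...`` — one row per
  sequencing run per sample, percentages on the 0-100 scale, empty cells or
  ``NA`` for sites the instrument failed to call;
* clinical table: ``sample_id, age_years, sex, os_months, event``.

The delimiter is auto-detected between comma and tab from the header line
(an explicit override is accepted everywhere).  Outputs are a JSON report,
a tab-separated candidate table and plot-ready Kaplan-Meier step tables;
unbounded interval ends are serialized as ``inf`` / ``-inf`` tokens.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from grayzone.errors import ConfigError, DataValidationError, DuplicateError, SchemaError
from grayzone.types import ClinicalRecord, PyroRun

_MISSING_TOKENS = {"", "na"}
_EVENT_TRUE = {"1", "true", "dead"}
_EVENT_FALSE = {"0", "false", "alive"}


def detect_delimiter(path: str | Path) -> str:
    """Choose tab if the header line contains one, else comma."""
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_rows(path: str | Path, delimiter: Optional[str]) -> tuple[list[str], list[list[str]]]:
    delim = delimiter or detect_delimiter(path)
    with open(path, "r", newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        rows = [row for row in reader if row and any(cell.strip() for cell in row)]
    if not rows:
        raise SchemaError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    return header, rows[1:]


def read_pyro_runs(
    path: str | Path,
    site_ids: Sequence[int],
    delimiter: Optional[str] = None,
) -> list[PyroRun]:
    """Parse the pyrosequencing run table.

    Raises :class:`SchemaError` for a missing column,
    :class:`DataValidationError` (citing the data-row number) for a value
    outside [0, 100], and :class:`DuplicateError` for a repeated
    (sample_id, run_id) pair.
    """
    site_ids = tuple(int(s) for s in site_ids)
    header, rows = _read_rows(path, delimiter)
    required = ["sample_id", "run_id"] + [f"cpg_{s}" for s in site_ids]
    for col in required:
        if col not in header:
            raise SchemaError(f"{path}: missing required column {col!r}")
    idx = {col: header.index(col) for col in required}

    runs: list[PyroRun] = []
    seen: set[tuple[str, str]] = set()
    for rownum, row in enumerate(rows, start=1):
        sample_id = row[idx["sample_id"]].strip()
        run_id = row[idx["run_id"]].strip()
        key = (sample_id, run_id)
        if key in seen:
            raise DuplicateError(f"{path}: duplicate (sample_id, run_id) = {key} at data row {rownum}")
        seen.add(key)
        values: list[Optional[float]] = []
        for site in site_ids:
            cell = row[idx[f"cpg_{site}"]].strip()
            if cell.lower() in _MISSING_TOKENS:
                values.append(None)
                continue
            try:
                v = float(cell)
            except ValueError as exc:
                raise DataValidationError(
                    f"{path}: unparseable value {cell!r} in cpg_{site} at data row {rownum}"
                ) from exc
            if not 0.0 <= v <= 100.0:
                raise DataValidationError(
                    f"{path}: cpg_{site} value {v} outside [0, 100] at data row {rownum}"
                )
            values.append(v)
        runs.append(PyroRun(sample_id, run_id, site_ids, tuple(values)))
    return runs


def _normalize_sex(raw: str) -> str:
    s = raw.strip().lower()
    if s in ("male", "m"):
        return "male"
    if s in ("female", "f"):
        return "female"
    return "unknown"


def read_clinical(path: str | Path, delimiter: Optional[str] = None) -> list[ClinicalRecord]:
    """Parse the clinical table (sample_id, age_years, sex, os_months, event)."""
    header, rows = _read_rows(path, delimiter)
    required = ["sample_id", "age_years", "sex", "os_months", "event"]
    for col in required:
        if col not in header:
            raise SchemaError(f"{path}: missing required column {col!r}")
    idx = {col: header.index(col) for col in required}

    records: list[ClinicalRecord] = []
    seen: set[str] = set()
    for rownum, row in enumerate(rows, start=1):
        sample_id = row[idx["sample_id"]].strip()
        if sample_id in seen:
            raise DuplicateError(f"{path}: duplicate sample_id {sample_id!r} at data row {rownum}")
        seen.add(sample_id)
        try:
            age = float(row[idx["age_years"]])
            os_months = float(row[idx["os_months"]])
        except ValueError as exc:
            raise DataValidationError(f"{path}: unparseable number at data row {rownum}") from exc
        ev_raw = row[idx["event"]].strip().lower()
        if ev_raw in _EVENT_TRUE:
            ev = True
        elif ev_raw in _EVENT_FALSE:
            ev = False
        else:
            raise DataValidationError(
                f"{path}: event value {ev_raw!r} at data row {rownum} not in "
                "{0,1,true,false,dead,alive}"
            )
        if not os_months > 0:
            raise DataValidationError(
                f"{path}: os_months must be > 0, got {os_months} at data row {rownum}"
            )
        records.append(ClinicalRecord(sample_id, age, _normalize_sex(row[idx["sex"]]), os_months, ev))
    return records


def write_pyro_runs(runs: Sequence[PyroRun], path: str | Path, delimiter: str = ",") -> None:
    """Write runs back in the exact input dialect (missing -> empty cell)."""
    if not runs:
        raise ConfigError("write_pyro_runs: no runs to write")
    site_ids = runs[0].site_ids
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["sample_id", "run_id"] + [f"cpg_{s}" for s in site_ids])
        for run in runs:
            writer.writerow(
                [run.sample_id, run.run_id]
                + ["" if v is None else format(v, ".10g") for v in run.methylation]
            )


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path, delimiter: str = ",") -> None:
    if not records:
        raise ConfigError("write_clinical: no records to write")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["sample_id", "age_years", "sex", "os_months", "event"])
        for r in records:
            writer.writerow(
                [r.sample_id, format(r.age_years, ".10g"), r.sex, format(r.os_months, ".10g"), int(r.event)]
            )


def fmt_number(x: object, digits: int = 6) -> str:
    """Serialize a number for TSV output; infinities become inf/-inf tokens."""
    if x is None:
        return "NA"
    if isinstance(x, str):
        return x
    xf = float(x)
    if math.isnan(xf):
        return "NA"
    if math.isinf(xf):
        return "inf" if xf > 0 else "-inf"
    if float(xf).is_integer() and abs(xf) < 1e15:
        return str(int(xf))
    return format(xf, f".{digits}g")


def write_candidate_table(results: Sequence, path: str | Path) -> None:
    """Tab-separated per-candidate model summary (gray-zone sweep + binary row).

    ``results`` are :class:`grayzone.method.CandidateResult` records; the
    binary (no-gray-zone) model appears as a row with an empty ``g``.
    """
    if not results:
        raise ConfigError("write_candidate_table: results must be non-empty")
    cols = [
        "g",
        "M",
        "n_methylated",
        "n_gray_zone",
        "n_unmethylated",
        "median_os_methylated",
        "median_os_methylated_lo",
        "median_os_methylated_hi",
        "median_os_gray_zone",
        "median_os_gray_zone_lo",
        "median_os_gray_zone_hi",
        "median_os_unmethylated",
        "median_os_unmethylated_lo",
        "median_os_unmethylated_hi",
        "hr_age",
        "hr_age_lo",
        "hr_age_hi",
        "p_age",
        "hr_meth_vs_gray",
        "hr_meth_vs_gray_lo",
        "hr_meth_vs_gray_hi",
        "p_meth_vs_gray",
        "hr_unmeth_vs_gray",
        "hr_unmeth_vs_gray_lo",
        "hr_unmeth_vs_gray_hi",
        "p_unmeth_vs_gray",
        "loglik",
        "score_stat",
        "score_p",
        "lrt_stat",
        "lrt_p",
        "qualifies",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for res in results:
            writer.writerow([fmt_number(v) for v in res.as_row()])


def write_km_table(curves: dict[str, "np.ndarray | object"], path: str | Path) -> None:
    """Plot-ready KM step tables: one block of rows per category.

    ``curves`` maps a category label to a :class:`grayzone.survival.KMEstimate`.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["category", "time_months", "survival", "ci_lower", "ci_upper"])
        for label, km in curves.items():
            for t, s, lo, hi in zip(km.event_times, km.survival, km.ci_lower, km.ci_upper):
                writer.writerow([label, fmt_number(t), fmt_number(s), fmt_number(lo), fmt_number(hi)])


def _sanitize(obj):
    """Make a report JSON-serializable and strictly valid (no bare Infinity)."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        if math.isnan(x):
            return None
        if math.isinf(x):
            return "inf" if x > 0 else "-inf"
        return x
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _sanitize(obj.tolist())
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Deterministic JSON report (sorted keys, no timestamps)."""
    with open(path, "w") as fh:
        json.dump(_sanitize(report), fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
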