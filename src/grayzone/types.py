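"""Domain types: pyrosequencing runs, clinical records, category specs."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from grayzone.errors import DataValidationError

UNMETHYLATED = "unmethylated"
GRAY = "gray_zone"
METHYLATED = "methylated"

CATEGORY_ORDER = (METHYLATED, GRAY, UNMETHYLATED)


@dataclass(frozen=True)
class PyroRun:
    """One pyrosequencing run of one tumor sample.

    ``methylation`` holds per-CpG percentages on the 0-100 scale, aligned to
    ``site_ids``; ``None`` marks a site where the instrument failed to report
    a value.
    """

    sample_id: str
    run_id: str
    site_ids: tuple[int, ...]
    methylation: tuple[Optional[float], ...]

    def __post_init__(self) -> None:
        if len(self.methylation) != len(self.site_ids):
            raise DataValidationError(
                f"run {self.sample_id}/{self.run_id}: {len(self.methylation)} values "
                f"for {len(self.site_ids)} sites"
            )
        for site, value in zip(self.site_ids, self.methylation):
            if value is not None and not (0.0 <= value <= 100.0):
                raise DataValidationError(
                    f"run {self.sample_id}/{self.run_id}: cpg_{site} value {value!r} "
                    "outside [0, 100]"
                )

    @property
    def is_complete(self) -> bool:
        return all(v is not None for v in self.methylation)

    @property
    def mean_across_sites(self) -> float:
        """Mean methylation across all sites; requires a complete run."""
        if not self.is_complete:
            raise DataValidationError(
                f"run {self.sample_id}/{self.run_id} has missing sites; "
                "mean across sites is undefined"
            )
        return float(np.mean([v for v in self.methylation]))


@dataclass(frozen=True)
class ClinicalRecord:
    """Clinical follow-up for one sample: age, sex, overall survival."""

    sample_id: str
    age_years: float
    sex: str  # "male" | "female" | "unknown"
    os_months: float
    event: bool  # True = death observed

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise DataValidationError(f"{self.sample_id}: negative age {self.age_years}")
        if not self.os_months > 0:
            raise DataValidationError(
                f"{self.sample_id}: os_months must be > 0, got {self.os_months}"
            )
        if self.sex not in ("male", "female", "unknown"):
            raise DataValidationError(f"{self.sample_id}: bad sex value {self.sex!r}")


@dataclass
class Cohort:
    """Pyrosequencing runs plus clinical follow-up sharing one CpG panel."""

    runs: list[PyroRun]
    clinical: list[ClinicalRecord]
    site_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        for run in self.runs:
            if tuple(run.site_ids) != tuple(self.site_ids):
                raise DataValidationError(
                    f"run {run.sample_id}/{run.run_id} panel {run.site_ids} differs "
                    f"from cohort panel {self.site_ids}"
                )
        seen: set[str] = set()
        for rec in self.clinical:
            if rec.sample_id in seen:
                raise DataValidationError(f"duplicate clinical record {rec.sample_id}")
            seen.add(rec.sample_id)

    def clinical_by_id(self) -> dict[str, ClinicalRecord]:
        return {rec.sample_id: rec for rec in self.clinical}


@dataclass
class SampleMethylation:
    """Aggregated per-sample methylation: mean of per-run values per site,
    then mean across sites; replicate variability from per-run means."""

    sample_id: str
    site_ids: tuple[int, ...]
    per_site_mean: np.ndarray
    mean_methylation: float
    n_runs: int
    run_means: tuple[float, ...]
    replicate_sd: Optional[float]  # None when n_runs == 1


@dataclass(frozen=True)
class CategorySpec:
    """Methylation classification.

    Binary (``g is None``): unmethylated [0, M), methylated [M, 100].
    Three-category: unmethylated [0, g), gray zone [g, M), methylated [M, 100].
    Bounds are inclusive-lower / exclusive-upper, matching clinical reporting
    of "unmethylated < g%" and "methylated >= M%".
    """

    M: int
    g: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1 <= self.M <= 100:
            raise DataValidationError(f"methylated threshold M={self.M} outside 1..100")
        if self.g is not None and not 1 <= self.g < self.M:
            raise DataValidationError(f"gray-zone bound g={self.g} must satisfy 1 <= g < M={self.M}")

    @property
    def is_binary(self) -> bool:
        return self.g is None

    def categorize(self, mean_methylation: float) -> str:
        if not (0.0 <= mean_methylation <= 100.0) or math.isnan(mean_methylation):
            raise DataValidationError(f"mean methylation {mean_methylation} outside [0, 100]")
        if mean_methylation >= self.M:
            return METHYLATED
        if self.g is not None and mean_methylation >= self.g:
            return GRAY
        return UNMETHYLATED

    @property
    def categories(self) -> tuple[str, ...]:
        if self.is_binary:
            return (METHYLATED, UNMETHYLATED)
        return CATEGORY_ORDER

    def label(self) -> str:
        if self.is_binary:
            return f"binary_{self.M}"
        return f"{self.g}-{self.M}"


@dataclass(frozen=True)
class AgeGroupSpec:
    """Dichotomized age: indicator is 1 iff age_years >= cutoff."""

    cutoff_years: float = 65.0

    def indicator(self, age_years: float | np.ndarray) -> np.ndarray:
        return (np.asarray(age_years, dtype=float) >= self.cutoff_years).astype(float)
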