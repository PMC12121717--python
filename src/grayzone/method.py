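"""The gray-zone search: univariate screen, candidate sweep, selection.

Given an aggregated cohort and a methylated threshold M (supplied by the
laboratory or derived by the 50/50 split rule), every integer g with
1 <= g < M defines a candidate three-category classification

    unmethylated [0, g)   gray zone [g, M)   methylated [M, 100].

Each candidate is fitted as a multivariate Cox proportional-hazards model on
the age-group indicator and the two category indicators with the gray zone
as the reference level, so the reported hazard ratios are the clinically
interpretable contrasts methylated:gray and unmethylated:gray.  The candidate
is compared with the binary (no-gray-zone) model on the identical subjects by
a likelihood-ratio test with one degree of freedom — merging the gray zone
into the unmethylated category recovers the binary model exactly, which is
what makes the pair nested.

A candidate qualifies when the methylated:gray HR is significantly below 1,
the unmethylated:gray HR is significantly above 1, and the LRT against the
binary model is significant (all at the configured alpha, default 0.05, with
no multiplicity correction across candidates — deliberately, since the sweep
is a model-selection device rather than simultaneous inference, and the
report says so).  The optimal gray zone is the qualifying candidate with the
largest LRT statistic; "none" is a valid outcome, reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from grayzone import io as gio
from grayzone import qc as gqc
from grayzone.errors import (
    ConfigError,
    DegenerateCovariateError,
    GrayzoneError,
    InsufficientDataError,
)
from grayzone.survival import CoxModel, KMEstimate, SurvivalData, cox_fit, km_fit, lrt_nested
from grayzone.types import (
    GRAY,
    METHYLATED,
    UNMETHYLATED,
    AgeGroupSpec,
    CategorySpec,
    ClinicalRecord,
    Cohort,
    SampleMethylation,
)

_DEFAULT_SITES = tuple(range(72, 84))


@dataclass
class RunConfig:
    """Analysis configuration; unknown keys are rejected at load time."""

    site_ids: tuple[int, ...] = _DEFAULT_SITES
    meth_threshold: int | str = "derive"  # integer M, or "derive" for the 50/50 rule
    age_cutoff: float = 65.0
    alpha: float = 0.05
    include_sex: bool = False
    ties: str = "efron"
    outlier_action: str = "flag_only"
    outlier_quantile: float = 0.975
    delimiter: Optional[str] = None

    _KEYS = (
        "site_ids",
        "meth_threshold",
        "age_cutoff",
        "alpha",
        "include_sex",
        "ties",
        "outlier_action",
        "outlier_quantile",
        "delimiter",
    )

    def __post_init__(self) -> None:
        self.site_ids = tuple(int(s) for s in self.site_ids)
        if isinstance(self.meth_threshold, str):
            if self.meth_threshold != "derive":
                raise ConfigError(
                    f"meth_threshold must be an integer or 'derive', got {self.meth_threshold!r}"
                )
        elif not 1 <= int(self.meth_threshold) <= 100:
            raise ConfigError(f"meth_threshold {self.meth_threshold} outside 1..100")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha {self.alpha} must be in (0, 1)")
        if self.ties not in ("efron", "breslow"):
            raise ConfigError(f"ties must be efron or breslow, got {self.ties!r}")
        if self.outlier_action not in ("flag_only", "exclude_and_rerun"):
            raise ConfigError(f"unknown outlier_action {self.outlier_action!r}")
        if not 0.0 < self.outlier_quantile < 1.0:
            raise ConfigError(f"outlier_quantile {self.outlier_quantile} must be in (0, 1)")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        unknown = set(mapping) - set(cls._KEYS)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    def to_report(self) -> dict:
        d = {k: getattr(self, k) for k in self._KEYS}
        d["site_ids"] = list(self.site_ids)
        return d


def enumerate_candidates(M: int) -> list[CategorySpec]:
    """All three-category specs with gray-zone lower bound g in 1..M-1."""
    if M < 1:
        raise ConfigError(f"methylated threshold M={M} must be >= 1")
    return [CategorySpec(M=M, g=g) for g in range(1, M)]


def assemble_frame(
    samples: Sequence[SampleMethylation], clinical: Sequence[ClinicalRecord]
) -> tuple[pd.DataFrame, int]:
    """Join aggregated methylation with clinical records on sample_id.

    Returns the analysis frame plus the count of aggregated samples dropped
    for lack of a clinical record.
    """
    by_id = {rec.sample_id: rec for rec in clinical}
    rows = []
    dropped = 0
    for s in samples:
        rec = by_id.get(s.sample_id)
        if rec is None:
            dropped += 1
            continue
        rows.append(
            {
                "sample_id": s.sample_id,
                "mean_methylation": s.mean_methylation,
                "age_years": rec.age_years,
                "sex": rec.sex,
                "os_months": rec.os_months,
                "event": rec.event,
            }
        )
    return pd.DataFrame(rows), dropped


def _hr_entry(model: CoxModel, name: str) -> dict:
    i = model.names.index(name)
    return {
        "hr": float(model.hr[i]),
        "ci": (float(model.hr_ci[i, 0]), float(model.hr_ci[i, 1])),
        "p": float(model.wald_p[i]),
    }


def _km_summary(km: Optional[KMEstimate]) -> dict:
    if km is None:
        return {"n": 0, "median": None, "median_ci": (None, None)}
    return {"n": km.n, "median": km.median, "median_ci": km.median_ci}


@dataclass
class CandidateResult:
    """One row of the candidate table (a fitted classification model)."""

    spec: CategorySpec
    n_per_category: dict[str, int]
    km_per_category: dict[str, Optional[KMEstimate]]
    model: Optional[CoxModel]
    hr_age: Optional[dict]
    hr_meth_vs_gray: Optional[dict]
    hr_unmeth_vs_gray: Optional[dict]
    lrt_stat: Optional[float]
    lrt_p: Optional[float]
    score_diff: Optional[float]
    qualifies: bool
    failed_criteria: tuple[str, ...] = ()
    note: Optional[str] = None

    def as_row(self) -> list:
        def km3(cat):
            km = self.km_per_category.get(cat)
            if km is None:
                return [None, None, None]
            return [km.median, km.median_ci[0], km.median_ci[1]]

        def hr4(entry):
            if entry is None:
                return [None, None, None, None]
            return [entry["hr"], entry["ci"][0], entry["ci"][1], entry["p"]]

        return (
            [self.spec.g, self.spec.M]
            + [self.n_per_category.get(c, 0) for c in (METHYLATED, GRAY, UNMETHYLATED)]
            + km3(METHYLATED)
            + km3(GRAY)
            + km3(UNMETHYLATED)
            + hr4(self.hr_age)
            + hr4(self.hr_meth_vs_gray)
            + hr4(self.hr_unmeth_vs_gray)
            + [
                self.model.loglik_fit if self.model else None,
                self.model.score_stat if self.model else None,
                self.model.score_p if self.model else None,
                self.lrt_stat,
                self.lrt_p,
                self.qualifies,
            ]
        )

    def to_report(self) -> dict:
        return {
            "g": self.spec.g,
            "M": self.spec.M,
            "n_per_category": self.n_per_category,
            "median_os": {c: _km_summary(self.km_per_category.get(c)) for c in self.n_per_category},
            "hr_age": self.hr_age,
            "hr_meth_vs_gray": self.hr_meth_vs_gray,
            "hr_unmeth_vs_gray": self.hr_unmeth_vs_gray,
            "loglik": self.model.loglik_fit if self.model else None,
            "score_stat": self.model.score_stat if self.model else None,
            "score_p": self.model.score_p if self.model else None,
            "converged": self.model.converged if self.model else None,
            "lrt_stat": self.lrt_stat,
            "lrt_p": self.lrt_p,
            "score_diff": self.score_diff,
            "qualifies": self.qualifies,
            "failed_criteria": list(self.failed_criteria),
            "note": self.note,
        }


def _category_series(frame: pd.DataFrame, spec: CategorySpec) -> pd.Series:
    return frame["mean_methylation"].map(spec.categorize)


def _covariates(
    frame: pd.DataFrame,
    spec: CategorySpec,
    age_cutoff: float,
    include_sex: bool,
) -> pd.DataFrame:
    """Model matrix: age-group indicator, category indicators (gray or
    methylated reference), optional male indicator."""
    cats = _category_series(frame, spec)
    cols = {"age_over_cutoff": AgeGroupSpec(age_cutoff).indicator(frame["age_years"].to_numpy())}
    if spec.is_binary:
        cols["unmethylated"] = (cats == UNMETHYLATED).astype(float).to_numpy()
    else:
        cols["methylated"] = (cats == METHYLATED).astype(float).to_numpy()
        cols["unmethylated"] = (cats == UNMETHYLATED).astype(float).to_numpy()
    if include_sex:
        cols["male"] = (frame["sex"] == "male").astype(float).to_numpy()
    return pd.DataFrame(cols, index=frame.index)


def _km_by_category(frame: pd.DataFrame, spec: CategorySpec) -> dict[str, Optional[KMEstimate]]:
    cats = _category_series(frame, spec)
    out: dict[str, Optional[KMEstimate]] = {}
    for c in spec.categories:
        sub = frame[cats == c]
        out[c] = km_fit(sub["os_months"].to_numpy(), sub["event"].to_numpy()) if len(sub) else None
    return out


def fit_binary_model(
    frame: pd.DataFrame,
    M: int,
    *,
    age_cutoff: float = 65.0,
    include_sex: bool = False,
    ties: str = "efron",
) -> tuple[CoxModel, CandidateResult]:
    """Binary (no-gray-zone) reference model: age group + unmethylated
    indicator (methylated as reference), reported as the last table row."""
    spec = CategorySpec(M=M)
    X = _covariates(frame, spec, age_cutoff, include_sex)
    data = SurvivalData(frame["os_months"].to_numpy(), frame["event"].to_numpy(), X)
    model = cox_fit(data, ties=ties)
    cats = _category_series(frame, spec)
    n_per = {c: int((cats == c).sum()) for c in spec.categories}
    n_per[GRAY] = 0
    result = CandidateResult(
        spec=spec,
        n_per_category=n_per,
        km_per_category=_km_by_category(frame, spec),
        model=model,
        hr_age=_hr_entry(model, "age_over_cutoff"),
        hr_meth_vs_gray=None,
        hr_unmeth_vs_gray=_hr_entry(model, "unmethylated"),  # unmethylated:methylated here
        lrt_stat=None,
        lrt_p=None,
        score_diff=None,
        qualifies=False,
        note="binary reference model (no gray zone); HR contrast is unmethylated:methylated",
    )
    return model, result


def fit_candidate_model(
    frame: pd.DataFrame,
    spec: CategorySpec,
    binary_model: CoxModel,
    *,
    alpha: float = 0.05,
    age_cutoff: float = 65.0,
    include_sex: bool = False,
    ties: str = "efron",
) -> CandidateResult:
    """Fit one three-category candidate and test it against the binary model.

    An empty category (or any other degeneracy) yields an inestimable result
    with ``qualifies=False`` rather than an exception, so sparse candidates
    stay visible in the table.
    """
    cats = _category_series(frame, spec)
    n_per = {c: int((cats == c).sum()) for c in spec.categories}
    km_per = _km_by_category(frame, spec)

    empty = [c for c, n in n_per.items() if n == 0]
    if empty:
        return CandidateResult(
            spec=spec,
            n_per_category=n_per,
            km_per_category=km_per,
            model=None,
            hr_age=None,
            hr_meth_vs_gray=None,
            hr_unmeth_vs_gray=None,
            lrt_stat=None,
            lrt_p=None,
            score_diff=None,
            qualifies=False,
            failed_criteria=("inestimable",),
            note=f"empty categories: {sorted(empty)}; model inestimable",
        )

    X = _covariates(frame, spec, age_cutoff, include_sex)
    data = SurvivalData(frame["os_months"].to_numpy(), frame["event"].to_numpy(), X)
    try:
        model = cox_fit(data, ties=ties)
    except (DegenerateCovariateError, np.linalg.LinAlgError) as exc:
        return CandidateResult(
            spec=spec,
            n_per_category=n_per,
            km_per_category=km_per,
            model=None,
            hr_age=None,
            hr_meth_vs_gray=None,
            hr_unmeth_vs_gray=None,
            lrt_stat=None,
            lrt_p=None,
            score_diff=None,
            qualifies=False,
            failed_criteria=("inestimable",),
            note=f"degenerate model: {exc}",
        )

    hr_age = _hr_entry(model, "age_over_cutoff")
    hr_mg = _hr_entry(model, "methylated")
    hr_ug = _hr_entry(model, "unmethylated")
    lrt_stat, lrt_df, lrt_p = lrt_nested(model, binary_model)
    score_diff = (
        float(model.score_stat - binary_model.score_stat)
        if np.isfinite(model.score_stat) and np.isfinite(binary_model.score_stat)
        else None
    )

    failed = []
    if not (hr_mg["hr"] < 1.0 and hr_mg["p"] < alpha):
        failed.append("hr_meth_vs_gray")
    if not (hr_ug["hr"] > 1.0 and hr_ug["p"] < alpha):
        failed.append("hr_unmeth_vs_gray")
    if not lrt_p < alpha:
        failed.append("lrt")
    return CandidateResult(
        spec=spec,
        n_per_category=n_per,
        km_per_category=km_per,
        model=model,
        hr_age=hr_age,
        hr_meth_vs_gray=hr_mg,
        hr_unmeth_vs_gray=hr_ug,
        lrt_stat=lrt_stat,
        lrt_p=lrt_p,
        score_diff=score_diff,
        qualifies=not failed,
        failed_criteria=tuple(failed),
    )


@dataclass
class GrayZoneDecision:
    """Outcome of the sweep: the optimum (or none) and the full trace."""

    optimal: Optional[CategorySpec]
    candidates: list[CandidateResult]
    binary: CandidateResult
    rationale: list[dict]

    def to_report(self) -> dict:
        return {
            "optimal_g": self.optimal.g if self.optimal else None,
            "optimal_M": self.optimal.M if self.optimal else None,
            "gray_zone_found": self.optimal is not None,
            "rationale": self.rationale,
        }


def select_optimal(candidates: Sequence[CandidateResult], alpha: float = 0.05) -> GrayZoneDecision:
    """Pick the qualifying candidate with the largest LRT statistic.

    Ties break to the smaller g (the wider gray zone, i.e. the larger safety
    margin).  Candidates whose HR contrasts are both significant but whose
    LRT is not are recorded as near-misses in the rationale.
    """
    candidates = list(candidates)
    if not candidates:
        raise ConfigError("select_optimal: empty candidate list")
    rationale = []
    for c in candidates:
        entry = {
            "g": c.spec.g,
            "qualifies": c.qualifies,
            "failed": list(c.failed_criteria),
            "lrt_stat": c.lrt_stat,
        }
        if not c.qualifies and list(c.failed_criteria) == ["lrt"]:
            entry["near_miss"] = True
        rationale.append(entry)
    qualifying = [c for c in candidates if c.qualifies]
    optimal = None
    if qualifying:
        best = max(qualifying, key=lambda c: (c.lrt_stat, -c.spec.g))
        optimal = best.spec
        rationale.append(
            {
                "selected_g": best.spec.g,
                "rule": "largest significant LRT statistic among candidates with "
                "both HR contrasts significant in the expected directions",
            }
        )
    else:
        rationale.append({"selected_g": None, "rule": "no candidate qualified"})
    # find binary row among inputs? kept separate by the caller
    return GrayZoneDecision(optimal=optimal, candidates=candidates, binary=None, rationale=rationale)  # type: ignore[arg-type]


def univariate_screen(
    frame: pd.DataFrame,
    *,
    age_cutoff: float = 65.0,
    ties: str = "efron",
    candidates: Optional[Sequence[CategorySpec]] = None,
) -> dict:
    """Single-covariate Cox screens plus the per-candidate unadjusted sweep.

    Rows: sex (male:female), age continuous (per year), age group
    (>=cutoff:<cutoff), mean methylation continuous (per percent).  For every
    candidate spec an unadjusted three-category fit (gray-zone reference) and
    per-category Kaplan-Meier medians are reported — the table feeding the
    per-categorization survival-curve figure.
    """
    time = frame["os_months"].to_numpy()
    event = frame["event"].to_numpy()

    def one(name: str, values: np.ndarray) -> dict:
        try:
            data = SurvivalData(time, event, pd.DataFrame({name: values}, index=frame.index))
            m = cox_fit(data, ties=ties)
            return _hr_entry(m, name)
        except (DegenerateCovariateError, GrayzoneError) as exc:
            return {"inestimable": True, "note": str(exc)}

    out: dict = {
        "sex_male_vs_female": one("male", (frame["sex"] == "male").astype(float).to_numpy()),
        "age_continuous": one("age_years", frame["age_years"].to_numpy()),
        "age_group": one(
            "age_over_cutoff", AgeGroupSpec(age_cutoff).indicator(frame["age_years"].to_numpy())
        ),
        "mean_methylation_continuous": one(
            "mean_methylation", frame["mean_methylation"].to_numpy()
        ),
    }
    if candidates:
        sweep = []
        for spec in candidates:
            cats = _category_series(frame, spec)
            n_per = {c: int((cats == c).sum()) for c in spec.categories}
            km_per = _km_by_category(frame, spec)
            entry = {
                "g": spec.g,
                "M": spec.M,
                "n_per_category": n_per,
                "median_os": {c: _km_summary(km_per.get(c)) for c in spec.categories},
            }
            if all(n > 0 for n in n_per.values()):
                X = pd.DataFrame(
                    {
                        "methylated": (cats == METHYLATED).astype(float).to_numpy(),
                        "unmethylated": (cats == UNMETHYLATED).astype(float).to_numpy(),
                    },
                    index=frame.index,
                )
                try:
                    m = cox_fit(SurvivalData(time, event, X), ties=ties)
                    entry["hr_meth_vs_gray"] = _hr_entry(m, "methylated")
                    entry["hr_unmeth_vs_gray"] = _hr_entry(m, "unmethylated")
                except (DegenerateCovariateError, GrayzoneError) as exc:
                    entry["inestimable"] = str(exc)
            else:
                entry["inestimable"] = "empty category"
            sweep.append(entry)
        out["candidate_sweep"] = sweep
    return out


def analyze_cohort(cohort: Cohort, config: RunConfig) -> dict:
    """Run the full stepwise analysis on an in-memory cohort.

    Returns the report dict; the fitted decision objects are attached under
    the non-serialized key ``"_objects"`` for programmatic use (stripped
    before writing).
    """
    report: dict = {"config": config.to_report()}

    kept, excluded = gqc.exclude_failed_runs(cohort.runs)
    samples = gqc.aggregate_replicates(kept)
    if not samples:
        raise InsufficientDataError("no complete runs; nothing to analyze")

    counts = {
        "n_runs_total": len(cohort.runs),
        "n_runs_excluded": len(excluded),
        "n_runs_kept": len(kept),
        "n_samples_aggregated": len(samples),
    }

    # QC summaries
    qc_section: dict = {}
    if len(samples) >= 2:
        qcsum = gqc.cpg_summary_and_correlation(samples)
        qc_section = qcsum.to_report()
    else:
        qc_section = {"note": "fewer than 2 samples; distribution summaries unavailable"}

    # outlier flagging
    n_sites = len(cohort.site_ids)
    outlier_section: dict
    flagged: tuple[str, ...] = ()
    if len(samples) > n_sites:
        try:
            d2 = gqc.mahalanobis_distances(samples)
            rep = gqc.flag_outliers(
                d2,
                [s.sample_id for s in samples],
                n_sites,
                quantile=config.outlier_quantile,
                action=config.outlier_action,
            )
            outlier_section = rep.to_report()
            flagged = rep.flagged
        except gqc.SingularCovarianceError as exc:
            outlier_section = {"note": f"outlier detection skipped: {exc}"}
    else:
        outlier_section = {
            "note": "outlier detection skipped: need more samples than CpG sites"
        }
    report["outliers"] = outlier_section

    core = _analyze_samples(samples, cohort.clinical, config, counts)
    replicate_qc = core.pop("qc_replicates", {})
    report.update(core)
    report["qc"] = {**qc_section, **replicate_qc}

    if config.outlier_action == "exclude_and_rerun" and flagged:
        kept_samples = [s for s in samples if s.sample_id not in flagged]
        rerun_counts = dict(counts)
        rerun_counts["n_samples_aggregated"] = len(kept_samples)
        rerun_counts["n_outliers_excluded"] = len(flagged)
        rerun = _analyze_samples(kept_samples, cohort.clinical, config, rerun_counts)
        rerun.pop("_objects", None)
        rerun.pop("qc_replicates", None)
        report["rerun_without_outliers"] = rerun

    return report


def _analyze_samples(
    samples: list[SampleMethylation],
    clinical: Sequence[ClinicalRecord],
    config: RunConfig,
    counts: dict,
) -> dict:
    """Threshold, screen, sweep and selection on aggregated samples."""
    out: dict = {}
    counts = dict(counts)

    if config.meth_threshold == "derive":
        M = gqc.derive_binary_threshold(samples)
        threshold_source = "derived (50/50 split rule)"
    else:
        M = int(config.meth_threshold)
        threshold_source = "configured"
    means = np.array([s.mean_methylation for s in samples])
    out["threshold"] = {
        "M": M,
        "source": threshold_source,
        "pct_methylated": float(100.0 * np.mean(means >= M)),
    }

    # replicate variability relative to M
    try:
        sd_all, sd_below = gqc.replicate_sd_summary(samples, M)
        out["qc_replicates"] = {
            "replicate_sd_overall": sd_all,
            "replicate_sd_below_threshold": sd_below,
        }
    except InsufficientDataError:
        out["qc_replicates"] = {"note": "no multi-run samples; replicate SD unavailable"}

    frame, n_no_clinical = assemble_frame(samples, clinical)
    counts["n_samples_without_clinical"] = n_no_clinical
    if config.include_sex:
        known = frame["sex"] != "unknown"
        counts["n_dropped_unknown_sex"] = int((~known).sum())
        frame = frame[known].reset_index(drop=True)
    if len(frame) == 0 or not frame["event"].any():
        raise InsufficientDataError("no analyzable subjects with an observed event")
    counts["n_analyzed"] = int(len(frame))
    counts["n_events"] = int(frame["event"].sum())
    out["counts"] = counts

    fit_kwargs = dict(age_cutoff=config.age_cutoff, include_sex=config.include_sex, ties=config.ties)
    binary_model, binary_row = fit_binary_model(frame, M, **fit_kwargs)
    specs = enumerate_candidates(M)
    candidates = [
        fit_candidate_model(frame, spec, binary_model, alpha=config.alpha, **fit_kwargs)
        for spec in specs
    ]

    if candidates:
        decision = select_optimal(candidates, alpha=config.alpha)
        decision.binary = binary_row
    else:
        decision = GrayZoneDecision(
            optimal=None,
            candidates=[],
            binary=binary_row,
            rationale=[{"selected_g": None, "rule": "no admissible candidate (M <= 1)"}],
        )

    out["univariate"] = univariate_screen(
        frame, age_cutoff=config.age_cutoff, ties=config.ties, candidates=specs
    )
    out["binary"] = binary_row.to_report()
    out["candidates"] = [c.to_report() for c in candidates]
    out["decision"] = decision.to_report()
    out["multiplicity_note"] = (
        "p-values across the candidate sweep are unadjusted; the sweep is a "
        "model-selection device, not simultaneous inference"
    )

    # discordance under the binary spec and (when found) the optimal spec
    binary_spec = CategorySpec(M=M)
    disc_binary = sorted(gqc.detect_discordant(samples, binary_spec))
    disc_section = {"binary": disc_binary, "n_binary": len(disc_binary)}
    if decision.optimal is not None:
        disc_opt = sorted(gqc.detect_discordant(samples, decision.optimal))
        disc_section.update(
            {
                "optimal": disc_opt,
                "n_optimal": len(disc_opt),
                "n_additional_vs_binary": len(set(disc_opt) - set(disc_binary)),
            }
        )
    out["discordance"] = disc_section

    out["_objects"] = {"decision": decision, "binary_model": binary_model, "frame": frame}
    return out


def run_grayzone_analysis(
    pyro_path: str | Path,
    clinical_path: str | Path,
    config: RunConfig,
    out_dir: Optional[str | Path] = None,
) -> dict:
    """Read the two input tables, run the full analysis, optionally write
    report.json, candidates.tsv and km_curves.tsv into ``out_dir``."""
    try:
        runs = gio.read_pyro_runs(pyro_path, config.site_ids, delimiter=config.delimiter)
        clinical = gio.read_clinical(clinical_path, delimiter=config.delimiter)
    except GrayzoneError as exc:
        raise type(exc)(f"input stage: {exc}") from exc
    cohort = Cohort(runs=runs, clinical=clinical, site_ids=config.site_ids)
    report = analyze_cohort(cohort, config)
    objects = report.pop("_objects", None)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        gio.write_report(report, out_dir / "report.json")
        if objects is not None:
            decision: GrayZoneDecision = objects["decision"]
            rows = list(decision.candidates) + [decision.binary]
            gio.write_candidate_table(rows, out_dir / "candidates.tsv")
            frame = objects["frame"]
            spec = decision.optimal if decision.optimal is not None else decision.binary.spec
            curves = {
                c: km
                for c, km in _km_by_category(frame, spec).items()
                if km is not None
            }
            gio.write_km_table(curves, out_dir / "km_curves.tsv")
    if objects is not None:
        report["_objects"] = objects
    return report
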