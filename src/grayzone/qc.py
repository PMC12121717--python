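"""Replicate QC, aggregation, distribution summaries and outlier detection.

The laboratory protocol runs pyrosequencing twice per tumor sample.  A run
that failed to report the methylation percentage at one or more CpG sites is
excluded outright (no imputation); a sample survives as long as at least one
complete run remains.  Per-sample methylation is then the mean across kept
runs at each site, and the sample's average methylation is the mean of those
per-site means.  Replicate variability is summarized by the sample standard
deviation of the per-run mean-across-sites values.

Multivariate outliers are flagged by the squared Mahalanobis distance of each
sample's per-site profile from the cohort mean profile, against a chi-squared
cutoff with one degree of freedom per site.  Flagging is advisory by default:
flagged samples stay in the analysis, mirroring a review-then-retain workflow,
with an exclude-and-rerun mode available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from grayzone.errors import ConfigError, InsufficientDataError, SingularCovarianceError
from grayzone.types import CategorySpec, PyroRun, SampleMethylation


def exclude_failed_runs(runs: Sequence[PyroRun]) -> tuple[list[PyroRun], list[PyroRun]]:
    """Split runs into (kept, excluded); excluded iff any site value missing."""
    kept = [r for r in runs if r.is_complete]
    excluded = [r for r in runs if not r.is_complete]
    return kept, excluded


def aggregate_replicates(kept_runs: Sequence[PyroRun]) -> list[SampleMethylation]:
    """Mean-of-means aggregation, one record per sample in first-seen order.

    ``replicate_sd`` is the sample SD (denominator n-1) of the per-run
    mean-across-sites values; undefined (None) for single-run samples.
    """
    by_sample: dict[str, list[PyroRun]] = {}
    for run in kept_runs:
        by_sample.setdefault(run.sample_id, []).append(run)

    out: list[SampleMethylation] = []
    for sample_id, runs in by_sample.items():
        mat = np.array([[float(v) for v in r.methylation] for r in runs])
        per_site = mat.mean(axis=0)
        run_means = tuple(float(m) for m in mat.mean(axis=1))
        sd = float(np.std(run_means, ddof=1)) if len(runs) >= 2 else None
        out.append(
            SampleMethylation(
                sample_id=sample_id,
                site_ids=runs[0].site_ids,
                per_site_mean=per_site,
                mean_methylation=float(per_site.mean()),
                n_runs=len(runs),
                run_means=run_means,
                replicate_sd=sd,
            )
        )
    return out


def replicate_sd_summary(
    samples: Sequence[SampleMethylation], threshold: float
) -> tuple[float, float]:
    """Mean replicate SD over all multi-run samples, and over those with
    mean methylation below ``threshold``.  NaN for the below-threshold mean
    when no multi-run sample falls below it."""
    sds = [s.replicate_sd for s in samples if s.replicate_sd is not None]
    if not sds:
        raise InsufficientDataError("no sample has two or more runs")
    below = [
        s.replicate_sd
        for s in samples
        if s.replicate_sd is not None and s.mean_methylation < threshold
    ]
    mean_all = float(np.mean(sds))
    mean_below = float(np.mean(below)) if below else float("nan")
    return mean_all, mean_below


@dataclass
class QCSummary:
    """Per-site distribution summaries and the site-by-site correlation."""

    site_ids: tuple[int, ...]
    per_site: pd.DataFrame  # index = site id; min, q1, median, q3, max, mean, sd
    correlation: np.ndarray  # pairwise Pearson r; NaN where undefined
    cohort_mean: float  # mean of per-sample average methylation
    cohort_sd: float
    n_samples: int

    def to_report(self) -> dict:
        return {
            "site_ids": list(self.site_ids),
            "per_site": {
                str(site): {k: float(v) for k, v in row.items()}
                for site, row in self.per_site.iterrows()
            },
            "correlation": self.correlation,
            "cohort_mean_methylation": self.cohort_mean,
            "cohort_sd_methylation": self.cohort_sd,
            "n_samples": self.n_samples,
        }


def cpg_summary_and_correlation(samples: Sequence[SampleMethylation]) -> QCSummary:
    """Five-number summaries plus mean/SD per site, and Pearson correlations
    of per-site means across samples (NaN, not 0, for zero-variance sites)."""
    if len(samples) < 2:
        raise InsufficientDataError("need at least 2 samples for distribution summaries")
    mat = np.array([s.per_site_mean for s in samples])
    site_ids = samples[0].site_ids
    q = np.quantile(mat, [0.0, 0.25, 0.5, 0.75, 1.0], axis=0)
    per_site = pd.DataFrame(
        {
            "min": q[0],
            "q1": q[1],
            "median": q[2],
            "q3": q[3],
            "max": q[4],
            "mean": mat.mean(axis=0),
            "sd": mat.std(axis=0, ddof=1),
        },
        index=list(site_ids),
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    sd = mat.std(axis=0, ddof=1)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    overall = np.array([s.mean_methylation for s in samples])
    return QCSummary(
        site_ids=site_ids,
        per_site=per_site,
        correlation=corr,
        cohort_mean=float(overall.mean()),
        cohort_sd=float(overall.std(ddof=1)),
        n_samples=len(samples),
    )


def mahalanobis_distances(
    samples: Sequence[SampleMethylation], pseudo_inverse: bool = False
) -> np.ndarray:
    """Squared Mahalanobis distance of each per-site profile from the cohort
    mean, using the unbiased (n-1) sample covariance.

    With the unbiased covariance the distances satisfy
    ``sum(d2) == (n - 1) * n_sites`` exactly, which downstream code uses as a
    self-check.  A singular covariance raises unless ``pseudo_inverse`` is
    set, in which case the Moore-Penrose pseudo-inverse is substituted and
    distances are computed within the support of the data.
    """
    mat = np.array([s.per_site_mean for s in samples], dtype=float)
    n, p = mat.shape
    if n <= p and not pseudo_inverse:
        raise InsufficientDataError(
            f"need more samples ({n}) than sites ({p}) for an invertible covariance"
        )
    mu = mat.mean(axis=0)
    centered = mat - mu
    cov = np.cov(mat, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if pseudo_inverse:
        prec = np.linalg.pinv(cov)
    else:
        try:
            prec = np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:
            raise SingularCovarianceError(
                "sample covariance of per-site means is singular; "
                "rerun with pseudo_inverse=True"
            ) from exc
        # inv() can succeed numerically on an effectively singular matrix
        if np.linalg.cond(cov) > 1e12:
            raise SingularCovarianceError(
                "sample covariance of per-site means is numerically singular; "
                "rerun with pseudo_inverse=True"
            )
    d2 = np.einsum("ij,jk,ik->i", centered, prec, centered)
    return np.clip(d2, 0.0, None)


@dataclass
class OutlierReport:
    """Mahalanobis flagging result at a chi-squared quantile cutoff."""

    distances: np.ndarray
    cutoff: float
    quantile: float
    flagged: tuple[str, ...]
    action: str  # "flag_only" | "exclude_and_rerun"

    def to_report(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "quantile": self.quantile,
            "n_flagged": len(self.flagged),
            "flagged": list(self.flagged),
            "action": self.action,
            "distances": self.distances,
        }


def flag_outliers(
    distances: np.ndarray,
    sample_ids: Sequence[str],
    n_sites: int,
    quantile: float = 0.975,
    action: str = "flag_only",
) -> OutlierReport:
    """Flag samples with d2 above the chi-squared(n_sites) quantile cutoff."""
    if not 0.0 < quantile < 1.0:
        raise ConfigError(f"outlier quantile {quantile} must be in (0, 1)")
    if action not in ("flag_only", "exclude_and_rerun"):
        raise ConfigError(f"unknown outlier action {action!r}")
    cutoff = float(stats.chi2.ppf(quantile, df=n_sites))
    distances = np.asarray(distances, dtype=float)
    flagged = tuple(sid for sid, d2 in zip(sample_ids, distances) if d2 > cutoff)
    return OutlierReport(distances=distances, cutoff=cutoff, quantile=quantile, flagged=flagged, action=action)


def derive_binary_threshold(samples: Sequence[SampleMethylation]) -> int:
    """Integer threshold splitting the cohort closest to 50% methylated.

    A sample is methylated when its mean methylation is >= t; candidates are
    t in 1..99 and ties in |#methylated - n/2| break to the smallest t (the
    choice that labels more samples methylated).
    """
    if len(samples) < 2:
        raise InsufficientDataError("need at least 2 samples to derive a threshold")
    means = np.array([s.mean_methylation for s in samples])
    n = len(means)
    best_t, best_gap = None, None
    for t in range(1, 100):
        gap = abs(int(np.sum(means >= t)) - n / 2.0)
        if best_gap is None or gap < best_gap:
            best_t, best_gap = t, gap
    return int(best_t)


def detect_discordant(
    samples: Sequence[SampleMethylation], spec: CategorySpec
) -> set[str]:
    """Samples whose per-run mean-across-sites values straddle a category
    boundary of ``spec`` (single-run samples cannot be discordant)."""
    discordant: set[str] = set()
    for s in samples:
        cats = {spec.categorize(m) for m in s.run_means}
        if len(cats) > 1:
            discordant.add(s.sample_id)
    return discordant
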