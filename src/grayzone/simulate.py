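"""Synthetic cohort generator.

Emulates the statistical structure the gray-zone method assumes, so the whole
pipeline is testable without patient data:

* per-sample latent mean methylation from a two-component truncated-normal
  mixture on the percent scale (a low "unmethylated" mode and a broad
  "methylated" mode), reproducing a bimodal cohort with roughly half the
  samples at or above the methylated threshold;
* strongly correlated CpG sites via a single shared factor — the latent mean
  itself — plus independent per-site residuals whose spread is solved from
  the requested target inter-site correlation;
* ``n_runs`` replicate runs per sample, differing by a per-run offset whose
  SD grows linearly with the latent mean (replicate scatter in pyrosequencing
  is larger for more methylated samples);
* overall survival from a proportional-hazards model (Weibull baseline,
  exponential by default) with category-dependent hazards relative to the
  gray zone and an age-group effect, censored administratively at a
  follow-up drawn uniformly over the accrual window.

Everything is driven by one integer seed through a single
``numpy.random.Generator``; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from grayzone.errors import ConfigError
from grayzone.types import CategorySpec, ClinicalRecord, Cohort, PyroRun


@dataclass
class SimConfig:
    """Generator parameters (percent scale for methylation, months for time)."""

    n_samples: int = 308
    seed: int = 0
    site_ids: tuple[int, ...] = tuple(range(72, 84))
    n_runs: int = 2

    # latent mean mixture: P(high mode) = weight_methylated
    weight_methylated: float = 0.53
    low_mode: tuple[float, float] = (3.0, 3.0)  # (mean, sd), truncated to [0, 100]
    high_mode: tuple[float, float] = (38.0, 18.0)

    cpg_correlation: float = 0.90  # target off-diagonal Pearson r of per-site means
    replicate_sd: float = 0.89  # per-run offset SD at 0% latent mean
    replicate_sd_slope: float = 0.04  # increase in offset SD per percent latent mean

    true_M: int = 12
    true_g: int = 5

    median_survival_months: float = 12.5  # baseline (gray zone, under age cutoff)
    baseline_shape: float = 1.0  # Weibull shape; 1.0 = exponential
    hr_meth_vs_gray: float = 0.53
    hr_unmeth_vs_gray: float = 1.8
    hr_age: float = 2.5
    age_cutoff: float = 65.0

    age_mean: float = 57.5
    age_sd: float = 12.0
    age_range: tuple[float, float] = (18.0, 90.0)
    male_fraction: float = 0.64

    follow_up_months: float = 38.0  # accrual window; censoring ~ U(min, max)
    follow_up_min_months: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.weight_methylated < 1.0:
            raise ConfigError("weight_methylated must be in (0, 1)")
        if not 0.0 < self.cpg_correlation <= 1.0:
            raise ConfigError("cpg_correlation must be in (0, 1]")
        if self.replicate_sd < 0 or self.replicate_sd_slope < 0:
            raise ConfigError("replicate SDs must be non-negative")
        for hr in (self.hr_meth_vs_gray, self.hr_unmeth_vs_gray, self.hr_age):
            if not hr > 0:
                raise ConfigError("hazard ratios must be positive")
        if not self.follow_up_months > 0:
            raise ConfigError("follow-up window must be positive")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        self.site_ids = tuple(int(s) for s in self.site_ids)

    @classmethod
    def development_like(cls, **overrides) -> "SimConfig":
        """Defaults: the development-cohort regime (12 CpG sites, M = 12,
        true gray zone [5, 12), ~60% events at a 38-month accrual window)."""
        return cls(**overrides)

    @classmethod
    def validation_like(cls, **overrides) -> "SimConfig":
        """A smaller cohort with short follow-up and a sparse intermediate
        methylation band (6 CpG sites, M = 10, ~40% events) — the regime in
        which the search is under-powered and "no gray zone" is expected."""
        params = dict(
            n_samples=115,
            site_ids=tuple(range(74, 80)),
            weight_methylated=0.50,
            low_mode=(2.0, 2.0),
            high_mode=(30.0, 16.0),
            true_M=10,
            true_g=5,
            follow_up_months=13.0,
        )
        params.update(overrides)
        return cls(**params)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _mixture_moments(config: SimConfig) -> tuple[float, float]:
    """Mean and variance of the latent-mean mixture (truncated-normal moments)."""
    parts = []
    for mean, sd in (config.low_mode, config.high_mode):
        if sd == 0:
            parts.append((mean, 0.0))
            continue
        a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
        m, v = stats.truncnorm.stats(a, b, loc=mean, scale=sd, moments="mv")
        parts.append((float(m), float(v)))
    w = config.weight_methylated
    (m_lo, v_lo), (m_hi, v_hi) = parts
    mean_mix = (1 - w) * m_lo + w * m_hi
    var_mix = (1 - w) * (v_lo + (m_lo - mean_mix) ** 2) + w * (v_hi + (m_hi - mean_mix) ** 2)
    return mean_mix, var_mix


@dataclass
class GroundTruth:
    """Per-sample generating truth plus generator-level diagnostics."""

    frame: pd.DataFrame  # sample_id, latent_mean, true_mean, true_category, ...
    config: SimConfig
    clip_fraction: float  # fraction of emitted percentages clipped to [0, 100]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def simulate_methylation_profiles(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[PyroRun], GroundTruth]:
    """Draw per-sample CpG profiles and emit ``n_runs`` replicate runs each.

    The sample's *true* category is assigned from its true mean methylation
    (the mean over sites of the pre-replicate-noise profile) under
    ``(true_g, true_M)`` — replicate noise then blurs what the pipeline
    observes, exactly as repeat pyrosequencing does.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_samples
    p = len(config.site_ids)

    high = rng.random(n) < config.weight_methylated
    latent = np.empty(n)
    latent[~high] = _truncnorm(rng, *config.low_mode, int((~high).sum()))
    latent[high] = _truncnorm(rng, *config.high_mode, int(high.sum()))

    # Per-site residuals scale with the latent mean: unmethylated samples have
    # all sites pinned near 0 while methylated samples spread more, and the
    # proportional form avoids truncation bias at the 0% floor.  The slope c
    # is solved so the inter-site Pearson correlation of the emitted profiles
    # hits the target: corr = V_m / (V_m + c^2 E[m^2]) = rho.
    rho = config.cpg_correlation
    mean_m, v_m = _mixture_moments(config)
    e2_m = v_m + mean_m**2
    c_site = np.sqrt(v_m * (1.0 - rho) / (rho * e2_m)) if rho < 1.0 else 0.0

    profiles_raw = latent[:, None] * (1.0 + c_site * rng.standard_normal((n, p)))
    profiles = np.clip(profiles_raw, 0.0, 100.0)
    true_mean = profiles.mean(axis=1)

    tau = np.maximum(0.0, config.replicate_sd + config.replicate_sd_slope * latent)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    spec = CategorySpec(M=config.true_M, g=config.true_g)
    true_cat = [spec.categorize(float(np.clip(m, 0, 100))) for m in true_mean]

    runs: list[PyroRun] = []
    n_clipped = int(np.sum(profiles_raw != profiles))
    n_values = profiles_raw.size
    for r in range(config.n_runs):
        offsets = rng.standard_normal(n) * tau
        run_vals_raw = profiles + offsets[:, None]
        run_vals = np.clip(run_vals_raw, 0.0, 100.0)
        n_clipped += int(np.sum(run_vals_raw != run_vals))
        n_values += run_vals_raw.size
        for i, sid in enumerate(sample_ids):
            runs.append(
                PyroRun(
                    sample_id=sid,
                    run_id=f"R{r + 1}",
                    site_ids=config.site_ids,
                    methylation=tuple(float(v) for v in run_vals[i]),
                )
            )

    truth = GroundTruth(
        frame=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "latent_mean": latent,
                "true_mean": true_mean,
                "true_category": true_cat,
            }
        ),
        config=config,
        clip_fraction=n_clipped / n_values,
    )
    return runs, truth


def simulate_survival(
    config: SimConfig,
    sample_ids: Sequence[str],
    categories: Sequence[str],
    ages: Sequence[float],
    sexes: Sequence[str],
    rng: np.random.Generator,
) -> list[ClinicalRecord]:
    """Draw right-censored overall survival for given true categories/ages.

    Times follow S(t) = exp(-(lambda0 * t)^k * theta) with theta the product
    of the category and age-group hazard ratios (gray zone, under-cutoff
    reference) and lambda0 set so the baseline median is
    ``median_survival_months``.  Censoring is administrative: uniform over
    the accrual window; an infinite window yields no censoring.
    """
    n = len(sample_ids)
    k = config.baseline_shape
    lam0 = (np.log(2.0) ** (1.0 / k)) / config.median_survival_months

    hr_cat = {
        "methylated": config.hr_meth_vs_gray,
        "gray_zone": 1.0,
        "unmethylated": config.hr_unmeth_vs_gray,
    }
    theta = np.array(
        [
            hr_cat[c] * (config.hr_age if a >= config.age_cutoff else 1.0)
            for c, a in zip(categories, ages)
        ]
    )
    e = rng.exponential(1.0, size=n)
    t_event = (e / theta) ** (1.0 / k) / lam0

    if np.isinf(config.follow_up_months):
        censor = np.full(n, np.inf)
    else:
        censor = rng.uniform(config.follow_up_min_months, config.follow_up_months, size=n)
    os_months = np.minimum(t_event, censor)
    event = t_event <= censor
    return [
        ClinicalRecord(
            sample_id=sid,
            age_years=float(a),
            sex=sx,
            os_months=float(max(t, 1e-6)),
            event=bool(ev),
        )
        for sid, a, sx, t, ev in zip(sample_ids, ages, sexes, os_months, event)
    ]


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Compose methylation profiles, demographics and survival into a Cohort."""
    rng = np.random.default_rng(config.seed)
    runs, truth = simulate_methylation_profiles(config, rng)

    n = config.n_samples
    lo, hi = config.age_range
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), lo, hi)
    sexes = np.where(rng.random(n) < config.male_fraction, "male", "female")

    frame = truth.frame
    clinical = simulate_survival(
        config,
        frame["sample_id"].tolist(),
        frame["true_category"].tolist(),
        ages,
        sexes.tolist(),
        rng,
    )
    frame["age_years"] = ages
    frame["sex"] = sexes
    frame["os_months"] = [c.os_months for c in clinical]
    frame["event"] = [c.event for c in clinical]

    cohort = Cohort(runs=runs, clinical=clinical, site_ids=config.site_ids)
    return cohort, truth
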