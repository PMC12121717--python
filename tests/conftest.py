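"""Shared fixtures: tiny hand-built cohorts and file writers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from grayzone.types import ClinicalRecord, PyroRun

SITES = tuple(range(72, 84))


def make_run(sample_id: str, run_id: str, values, sites=SITES) -> PyroRun:
    return PyroRun(sample_id, run_id, tuple(sites), tuple(values))


def flat_run(sample_id: str, run_id: str, value: float, sites=SITES) -> PyroRun:
    return make_run(sample_id, run_id, [value] * len(sites), sites)


@pytest.fixture
def pyro_csv(tmp_path):
    """Complete two-row pyro table over the 12-site panel."""
    path = tmp_path / "pyro.csv"
    header = "sample_id,run_id," + ",".join(f"cpg_{s}" for s in SITES)
    row1 = "S1,R1," + ",".join("10.0" for _ in SITES)
    row2 = "S1,R2," + ",".join("12.0" for _ in SITES)
    path.write_text(header + "\n" + row1 + "\n" + row2 + "\n")
    return path


@pytest.fixture
def clinical_csv(tmp_path):
    path = tmp_path / "clinical.csv"
    path.write_text(
        "sample_id,age_years,sex,os_months,event\n"
        "S1,57.5,female,10.5,1\n"
        "S2,70.0,M ,8.0,dead\n"
        "S3,44.0,other,30.0,alive\n"
    )
    return path


@pytest.fixture
def survival_frame():
    """Small analysis frame with all three categories populated."""
    rng = np.random.default_rng(7)
    n = 60
    mm = np.concatenate([rng.uniform(0, 4, 25), rng.uniform(5, 11, 12), rng.uniform(13, 60, 23)])
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "mean_methylation": mm,
            "age_years": rng.uniform(30, 85, n),
            "sex": rng.choice(["male", "female"], n),
            "os_months": rng.exponential(12, n) + 0.5,
            "event": rng.random(n) < 0.7,
        }
    )
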