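"""Replicate handling, QC summaries, Mahalanobis outliers, threshold rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grayzone import qc
from grayzone.errors import ConfigError, InsufficientDataError, SingularCovarianceError
from grayzone.types import CategorySpec, PyroRun, SampleMethylation

from conftest import SITES, flat_run, make_run


class TestExcludeFailedRuns:
    def test_run_missing_one_site_excluded(self):
        vals = [5.0] * 12
        vals[3] = None
        incomplete = make_run("S1", "R1", vals)
        complete = flat_run("S1", "R2", 5.0)
        kept, excluded = qc.exclude_failed_runs([incomplete, complete])
        assert excluded == [incomplete] and kept == [complete]

    def test_partition_preserves_everything(self):
        runs = [flat_run(f"S{i}", "R1", float(i)) for i in range(5)]
        kept, excluded = qc.exclude_failed_runs(runs)
        assert kept == runs and excluded == []

    def test_sample_with_only_failed_runs_vanishes_downstream(self):
        vals = [5.0] * 12
        vals[0] = None
        runs = [make_run("S1", "R1", vals), make_run("S1", "R2", vals), flat_run("S2", "R1", 9.0)]
        kept, _ = qc.exclude_failed_runs(runs)
        samples = qc.aggregate_replicates(kept)
        assert [s.sample_id for s in samples] == ["S2"]


class TestAggregateReplicates:
    def test_two_runs_closed_form(self):
        runs = [flat_run("S1", "R1", 10.0), flat_run("S1", "R2", 12.0)]
        (s,) = qc.aggregate_replicates(runs)
        assert np.allclose(s.per_site_mean, 11.0)
        assert s.mean_methylation == pytest.approx(11.0)
        assert s.replicate_sd == pytest.approx(np.sqrt(2.0), abs=1e-12)
        assert s.n_runs == 2 and s.run_means == (10.0, 12.0)

    def test_single_run_identity_with_undefined_sd(self):
        vals = [float(i) for i in range(12)]
        (s,) = qc.aggregate_replicates([make_run("S1", "R1", vals)])
        assert np.allclose(s.per_site_mean, vals)
        assert s.replicate_sd is None

    def test_run_order_irrelevant(self):
        runs = [flat_run("S1", "R1", 10.0), flat_run("S1", "R2", 12.0)]
        a = qc.aggregate_replicates(runs)[0]
        b = qc.aggregate_replicates(runs[::-1])[0]
        assert np.allclose(a.per_site_mean, b.per_site_mean)
        assert a.replicate_sd == pytest.approx(b.replicate_sd)

    def test_idempotent_on_single_run_cohort(self):
        rng = np.random.default_rng(0)
        runs = [make_run(f"S{i}", "R1", list(rng.uniform(0, 100, 12))) for i in range(6)]
        samples = qc.aggregate_replicates(runs)
        for run, s in zip(runs, samples):
            assert tuple(s.per_site_mean) == run.methylation  # exact


class TestReplicateSdSummary:
    def test_identical_replicates_give_zero(self):
        runs = [flat_run("S1", "R1", 5.0), flat_run("S1", "R2", 5.0)]
        samples = qc.aggregate_replicates(runs)
        assert qc.replicate_sd_summary(samples, 12) == (0.0, 0.0)

    def test_two_sample_arithmetic(self):
        runs = [
            flat_run("S1", "R1", 4.0),
            flat_run("S1", "R2", 6.0),  # sd = sqrt(2)
            flat_run("S2", "R1", 8.0),
            flat_run("S2", "R2", 8.0),  # sd = 0
        ]
        samples = qc.aggregate_replicates(runs)
        mean_all, mean_below = qc.replicate_sd_summary(samples, 12)
        assert mean_all == pytest.approx(np.sqrt(2) / 2)
        assert mean_below == pytest.approx(np.sqrt(2) / 2, abs=1e-12)

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(11)
        runs = []
        for i in range(5):
            base = rng.uniform(0, 40)
            for r in range(3):
                runs.append(flat_run(f"S{i}", f"R{r}", base + rng.uniform(-1, 1)))
        samples = qc.aggregate_replicates(runs)
        mean_all, mean_below = qc.replicate_sd_summary(samples, 25)
        # independent recomputation from the raw runs
        by = {}
        for r in runs:
            by.setdefault(r.sample_id, []).append(np.mean([v for v in r.methylation]))
        sds = {k: np.std(v, ddof=1) for k, v in by.items()}
        means = {k: np.mean(v) for k, v in by.items()}
        exp_all = np.mean(list(sds.values()))
        exp_below = np.mean([sds[k] for k in sds if means[k] < 25])
        assert mean_all == pytest.approx(exp_all, abs=1e-12)
        assert mean_below == pytest.approx(exp_below, abs=1e-12)

    def test_no_multirun_sample_is_an_error(self):
        samples = qc.aggregate_replicates([flat_run("S1", "R1", 5.0)])
        with pytest.raises(InsufficientDataError):
            qc.replicate_sd_summary(samples, 12)


class TestCpgSummaryAndCorrelation:
    def _samples(self, mat, sites):
        runs = [make_run(f"S{i}", "R1", list(row), sites) for i, row in enumerate(mat)]
        return qc.aggregate_replicates(runs)

    def test_linear_site_has_unit_correlation(self):
        sites = (1, 2)
        a = np.array([1.0, 5.0, 9.0, 20.0])
        mat = np.column_stack([a, 2 * a + 1])
        out = qc.cpg_summary_and_correlation(self._samples(mat, sites))
        assert out.correlation[0, 1] == pytest.approx(1.0)

    def test_constant_site_gives_nan_not_zero(self):
        sites = (1, 2)
        mat = np.column_stack([[1.0, 2.0, 3.0], [7.0, 7.0, 7.0]])
        out = qc.cpg_summary_and_correlation(self._samples(mat, sites))
        assert np.isnan(out.correlation[0, 1]) and np.isnan(out.correlation[1, 0])
        assert np.isnan(out.correlation[1, 1])

    def test_matches_hand_computed_pearson(self):
        sites = (1, 2, 3)
        mat = np.array([[0.0, 2.0, 10.0], [4.0, 3.0, 12.0], [8.0, 7.0, 11.0], [2.0, 4.0, 30.0]])
        out = qc.cpg_summary_and_correlation(self._samples(mat, sites))
        # independent elementwise Pearson computation
        for i in range(3):
            for j in range(3):
                x, y = mat[:, i], mat[:, j]
                r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                    np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
                )
                assert out.correlation[i, j] == pytest.approx(r, abs=1e-12)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            qc.cpg_summary_and_correlation(self._samples(np.array([[1.0, 2.0]]), (1, 2)))


def _samples_from_matrix(mat, sites=None):
    sites = sites or tuple(range(mat.shape[1]))
    runs = [make_run(f"S{i}", "R1", list(row), sites) for i, row in enumerate(mat)]
    return qc.aggregate_replicates(runs)


class TestMahalanobis:
    def test_sample_at_mean_has_zero_distance(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(5, 50, size=(4, 2))
        mat = np.vstack([base, base.mean(axis=0)])  # appending the mean keeps it the mean
        d2 = qc.mahalanobis_distances(_samples_from_matrix(mat))
        assert d2[-1] == pytest.approx(0.0, abs=1e-10)

    def test_univariate_reduction(self):
        x = np.array([[1.0], [4.0], [5.0], [10.0], [2.0]])
        d2 = qc.mahalanobis_distances(_samples_from_matrix(x))
        mu, s2 = x.mean(), x.var(ddof=1)
        assert np.allclose(d2, ((x[:, 0] - mu) ** 2) / s2)

    def test_two_site_toy_matches_explicit_inverse(self):
        mat = np.array(
            [[1.0, 2.0], [2.0, 1.0], [3.0, 5.0], [6.0, 4.0], [4.0, 6.0], [2.0, 3.0]]
        )
        d2 = qc.mahalanobis_distances(_samples_from_matrix(mat))
        mu = mat.mean(axis=0)
        c = mat - mu
        S = c.T @ c / (len(mat) - 1)
        det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
        Sinv = np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / det  # 2x2 inverse by hand
        expected = np.array([v @ Sinv @ v for v in c])
        assert np.allclose(d2, expected, atol=1e-10)

    def test_distance_sum_identity(self):
        rng = np.random.default_rng(5)
        mat = rng.uniform(0, 100, size=(40, 6))
        d2 = qc.mahalanobis_distances(_samples_from_matrix(mat))
        assert d2.sum() == pytest.approx((40 - 1) * 6, abs=1e-6)

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        mat = rng.uniform(10, 60, size=(30, 4))
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        b = rng.normal(size=4)
        # keep transformed values in [0,100] by scaling into range
        tmat = (mat @ A.T + b)
        tmat = (tmat - tmat.min()) / (tmat.max() - tmat.min()) * 100  # affine, in range
        d2a = qc.mahalanobis_distances(_samples_from_matrix(mat))
        d2b = qc.mahalanobis_distances(_samples_from_matrix(tmat))
        assert np.allclose(d2a, d2b, atol=1e-8)

    def test_singular_covariance_suggests_pseudo_inverse(self):
        base = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])  # col2 = 2*col1
        with pytest.raises(SingularCovarianceError, match="pseudo_inverse"):
            qc.mahalanobis_distances(_samples_from_matrix(base))
        d2 = qc.mahalanobis_distances(_samples_from_matrix(base), pseudo_inverse=True)
        assert np.all(np.isfinite(d2))


class TestFlagOutliers:
    def test_no_flags_below_cutoff(self):
        rep = qc.flag_outliers(np.array([0.1, 0.5, 1.0]), ["a", "b", "c"], n_sites=12)
        assert rep.flagged == ()

    def test_displaced_sample_flagged(self):
        rng = np.random.default_rng(9)
        mat = rng.normal(20, 2, size=(50, 2))
        mat[7] += np.array([20.0, -18.0])  # ~10 SD displacement on both sites
        samples = _samples_from_matrix(np.clip(mat, 0, 100))
        d2 = qc.mahalanobis_distances(samples)
        rep = qc.flag_outliers(d2, [s.sample_id for s in samples], n_sites=2, quantile=0.975)
        assert "S7" in rep.flagged

    def test_bad_quantile_rejected(self):
        with pytest.raises(ConfigError):
            qc.flag_outliers(np.array([1.0]), ["a"], n_sites=2, quantile=1.5)


class TestDeriveBinaryThreshold:
    def test_tie_break_prefers_smallest_threshold(self):
        samples = _samples_from_matrix(np.array([[v] for v in [1.0, 2.0, 3.0, 20.0, 21.0, 22.0]]))
        assert qc.derive_binary_threshold(samples) == 4  # any t in 4..20 splits 3/3

    @given(st.lists(st.floats(min_value=0, max_value=100, allow_nan=False), min_size=2, max_size=40))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_agrees_with_exhaustive_search(self, means):
        samples = _samples_from_matrix(np.array([[m] for m in means]))
        t_got = qc.derive_binary_threshold(samples)
        n = len(means)
        arr = np.array(means)
        best = min(range(1, 100), key=lambda t: (abs(int(np.sum(arr >= t)) - n / 2), t))
        assert t_got == best

    def test_odd_cohort_cannot_split_evenly(self):
        samples = _samples_from_matrix(np.array([[1.0], [2.0], [50.0]]))
        t = qc.derive_binary_threshold(samples)
        imbalance = abs(np.sum([s.mean_methylation >= t for s in samples]) - 1.5)
        assert imbalance >= 0.5


class TestDetectDiscordant:
    def _sample(self, run_values):
        runs = [flat_run("S1", f"R{i}", v) for i, v in enumerate(run_values)]
        return qc.aggregate_replicates(runs)

    def test_runs_straddling_gray_lower_bound(self):
        samples = self._sample([4.8, 5.2])
        assert qc.detect_discordant(samples, CategorySpec(M=12, g=5)) == {"S1"}

    def test_identical_runs_concordant(self):
        samples = self._sample([6.0, 6.0])
        assert qc.detect_discordant(samples, CategorySpec(M=12, g=5)) == set()

    def test_straddling_methylated_bound_discordant_under_both_specs(self):
        samples = self._sample([11.9, 12.1])
        assert qc.detect_discordant(samples, CategorySpec(M=12)) == {"S1"}
        assert qc.detect_discordant(samples, CategorySpec(M=12, g=5)) == {"S1"}

    def test_three_category_discordance_superset_of_binary(self):
        """Adding the gray boundary can only add discordant samples when the
        methylated boundary is kept (the finer partition splits no kept cut)."""
        rng = np.random.default_rng(21)
        runs = []
        for i in range(40):
            base = rng.uniform(0, 20)
            runs.append(flat_run(f"S{i}", "R1", base))
            runs.append(flat_run(f"S{i}", "R2", float(np.clip(base + rng.normal(0, 1.5), 0, 100))))
        samples = qc.aggregate_replicates(runs)
        disc_bin = qc.detect_discordant(samples, CategorySpec(M=12))
        disc_tri = qc.detect_discordant(samples, CategorySpec(M=12, g=5))
        assert disc_bin <= disc_tri
        assert len(disc_tri) > len(disc_bin)  # boundary-straddling replicates exist
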