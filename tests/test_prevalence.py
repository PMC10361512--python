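"""Sampling pmf, prevalence predictions, and relative error."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import afmacro as am
from conftest import freqs_from_matrix


class TestSamplingPmf:
    def test_zero_count_reduces_to_absence_form(self):
        # (1 + D fbar / beta)^-beta with beta=1, fbar*D=1 -> 1/2
        assert am.sampling_pmf(0, 100, 0.01, 1.0) == pytest.approx(0.5)
        assert am.sampling_pmf(0, 100, 0.01, 1.0) == pytest.approx(
            am.absence_probability(100, 0.01, 1.0)
        )

    def test_normalization(self):
        A = np.arange(0, 5000)
        total = am.sampling_pmf(A, 100, 0.05, 2.0).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_negative_binomial(self):
        """Independent cross-check: the pmf is NB(beta, beta/(beta+fbar D))."""
        A = np.arange(0, 50)
        for fbar, beta, D in [(0.05, 2.0, 100), (0.01, 0.5, 40), (0.3, 5.0, 20)]:
            ours = am.sampling_pmf(A, D, fbar, beta)
            ref = stats.nbinom.pmf(A, beta, beta / (beta + fbar * D))
            np.testing.assert_allclose(ours, ref, rtol=1e-10)

    def test_matches_monte_carlo_mixture(self):
        """Brute-force oracle: f ~ Gamma(beta, beta/fbar), A ~ Poisson(D f)."""
        rng = np.random.default_rng(0)
        n = 200_000
        fbar, beta, D = 0.05, 2.0, 100
        f = rng.gamma(beta, fbar / beta, n)
        A = rng.poisson(D * f)
        for a in range(15):
            p_hat = (A == a).mean()
            se = np.sqrt(p_hat * (1 - p_hat) / n)
            assert abs(am.sampling_pmf(a, D, fbar, beta) - p_hat) < 4 * max(se, 1e-5)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            am.sampling_pmf(-1, 100, 0.05, 1.0)


class TestAbsenceProbability:
    def test_zero_depth_means_certain_absence_of_signal(self):
        assert am.absence_probability(0, 0.05, 1.0) == 1.0

    def test_monotone_decreasing_in_depth_and_mean(self):
        D = np.array([10, 50, 100, 500])
        vals = am.absence_probability(D, 0.05, 1.0)
        assert (np.diff(vals) < 0).all()
        means = [am.absence_probability(100, fb, 1.0) for fb in (0.01, 0.05, 0.2)]
        assert (np.diff(means) < 0).all()

    def test_large_beta_limit_is_poisson_absence(self):
        # beta -> infinity collapses the gamma to a point mass: e^{-D fbar}
        assert am.absence_probability(100, 0.05, 1e6) == pytest.approx(
            np.exp(-5.0), rel=1e-4
        )


class TestPredictedPrevalence:
    def test_single_host_hand_arithmetic(self):
        # 1 - (1 + 100*0.05/1)^-1 = 5/6
        assert am.predicted_prevalence([100], 0.05, 1.0) == pytest.approx(5 / 6)

    def test_limits(self):
        assert am.predicted_prevalence([1e12] * 4, 0.05, 1.0) == pytest.approx(1.0, abs=1e-6)
        assert am.predicted_prevalence([100] * 4, 1e-12, 1.0) == pytest.approx(0.0, abs=1e-6)

    def test_empty_host_list_rejected(self):
        with pytest.raises(ValueError):
            am.predicted_prevalence([], 0.05, 1.0)

    def test_cutoff_of_one_reduces_to_untruncated(self):
        D = [30, 50, 100]
        assert am.predicted_prevalence_truncated(D, 0.05, 1.0, a_cutoff=1) == pytest.approx(
            am.predicted_prevalence(D, 0.05, 1.0)
        )

    def test_truncated_matches_partial_sum_oracle(self):
        """Term-by-term oracle: 1 - mean_m sum_{a<cutoff} pmf(a, D_m)."""
        D = np.array([25.0, 40.0, 80.0, 300.0])
        fbar, beta, cutoff = 0.08, 1.5, 10
        oracle = 1 - np.mean(
            [sum(am.sampling_pmf(a, d, fbar, beta) for a in range(cutoff)) for d in D]
        )
        ours = am.predicted_prevalence_truncated(D, fbar, beta, a_cutoff=cutoff)
        assert ours == pytest.approx(oracle, abs=1e-12)

    @given(
        fbar=st.floats(1e-4, 0.5),
        beta=st.floats(0.05, 10.0),
        d=st.integers(20, 500),
    )
    def test_truncation_only_removes_probability(self, fbar, beta, d):
        D = [d, 2 * d]
        trunc = am.predicted_prevalence_truncated(D, fbar, beta, a_cutoff=10)
        untrunc = am.predicted_prevalence(D, fbar, beta)
        assert trunc <= untrunc + 1e-12


class TestObservedPrevalenceAndError:
    def test_observed_prevalence_counts_detections(self):
        assert am.observed_prevalence([0, 0.1, 0.3, 0]) == 0.5
        assert am.observed_prevalence([0, 0, 0]) == 0.0
        assert am.observed_prevalence([0.1, 0.2]) == 1.0

    def test_relative_error_values(self):
        assert am.relative_error(0.5, 0.5) == 0.0
        assert am.relative_error(0.5, 0.25) == 0.5
        assert am.relative_error(0.2, 0.3) == pytest.approx(0.5)

    def test_relative_error_needs_positive_observation(self):
        with pytest.raises(ValueError):
            am.relative_error(0.0, 0.3)


class TestSiteMoments:
    def test_hand_arithmetic(self):
        freqs = freqs_from_matrix([[0.2, 0.0, 0.0, 0.2]])
        m = am.site_moments_for_prediction(freqs)
        assert m["fbar"].iloc[0] == pytest.approx(0.1)
        assert m["var"].iloc[0] == pytest.approx(0.01)
        assert m["beta"].iloc[0] == pytest.approx(1.0)

    def test_degenerate_sites_excluded(self):
        freqs = freqs_from_matrix([[0.1, 0.1, 0.1], [0.0, 0.0, 0.0], [0.0, 0.1, 0.3]])
        m = am.site_moments_for_prediction(freqs)
        assert list(m["site_id"]) == ["s0002"]

    def test_beta_recovery_from_large_site(self):
        rng = np.random.default_rng(0)
        f = rng.gamma(2.0, 0.05 / 2.0, size=(1, 500))
        m = am.site_moments_for_prediction(freqs_from_matrix(f))
        assert m["beta"].iloc[0] == pytest.approx(2.0, rel=0.10)

    def test_nonzero_only_variant(self):
        freqs = freqs_from_matrix([[0.2, 0.0, 0.0, 0.4]])
        m = am.site_moments_for_prediction(freqs, include_zeros=False)
        assert m["fbar"].iloc[0] == pytest.approx(0.3)


class TestPrevalenceCurve:
    def test_monotone_and_consistent(self):
        D = [30, 50, 100]
        grid = np.logspace(-3, np.log10(0.3), 25)
        curve = am.prevalence_curve(grid, 1.0, D, a_cutoff=10)
        assert (np.diff(curve["predicted"]) >= -1e-12).all()
        assert curve["predicted"].iloc[0] == pytest.approx(0.0, abs=1e-2)
        site_value = am.predicted_prevalence_truncated(D, grid[10], 1.0, a_cutoff=10)
        assert curve["predicted"].iloc[10] == pytest.approx(site_value)


class TestPredictCohort:
    def test_truncated_bounded_by_untruncated(self, mixed_cohort):
        _, counts, _ = mixed_cohort
        freqs = am.apply_detection_filter(counts)
        rec = am.predict_cohort(freqs)
        assert ((rec["predicted"] <= rec["predicted_untruncated"] + 1e-9)).all()
        assert rec["observed"].between(0, 1).all()
        assert rec["predicted"].between(0, 1).all()

    def test_epsilon_definition(self, mixed_cohort):
        _, counts, _ = mixed_cohort
        freqs = am.apply_detection_filter(counts)
        rec = am.predict_cohort(freqs)
        np.testing.assert_allclose(
            rec["epsilon"], np.abs(rec["observed"] - rec["predicted"]) / rec["observed"]
        )
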