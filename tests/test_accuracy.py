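"""Error summaries, binned prevalence, permutation tests, strain-structure scan."""

import numpy as np
import pandas as pd
import pytest

import afmacro as am


def records(observed, epsilon, predicted=None):
    observed = np.asarray(observed, dtype=float)
    if predicted is None:
        predicted = observed
    return pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(observed.size)],
            "observed": observed,
            "predicted": predicted,
            "epsilon": epsilon,
        }
    )


class TestErrorSummary:
    def test_fraction_within_threshold(self):
        s = am.error_summary(records([0.5, 0.5], [0.05, 0.5]))
        assert s.fraction_within == 0.5

    def test_threshold_is_inclusive(self):
        assert am.error_summary(records([0.5], [0.1])).fraction_within == 1.0

    def test_mean_log10(self):
        s = am.error_summary(records([0.5, 0.5], [0.01, 1.0]))
        assert s.mean_log10_error == pytest.approx(-1.0)

    def test_zero_errors_counted_but_not_logged(self):
        s = am.error_summary(records([0.5, 0.5], [0.0, 0.01]))
        assert s.n_zero_error == 1
        assert s.mean_log10_error == pytest.approx(-2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            am.error_summary(records([], []))


class TestRescaleErrors:
    def test_zscore(self):
        rng = np.random.default_rng(0)
        out = am.rescale_error_distribution(rng.exponential(0.3, 100))
        assert out.z.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.z.std() == pytest.approx(1.0, abs=1e-9)


class TestBinObservedVsPredicted:
    def test_perfect_predictions_on_identity(self):
        rng = np.random.default_rng(1)
        obs = 10 ** rng.uniform(-2, 0, 500)
        binned = am.bin_observed_vs_predicted(records(obs, np.zeros(500)), n_bins=10)
        np.testing.assert_allclose(binned["median_predicted"], binned["median_observed"])

    def test_systematic_underprediction_visible(self):
        rng = np.random.default_rng(2)
        obs = 10 ** rng.uniform(-2, 0, 500)
        binned = am.bin_observed_vs_predicted(
            records(obs, np.full(500, 0.5), predicted=obs / 2), n_bins=10
        )
        np.testing.assert_allclose(
            binned["median_predicted"], binned["median_observed"] / 2, rtol=1e-9
        )

    def test_sparse_bins_dropped(self):
        obs = np.concatenate([np.full(20, 0.5), [0.001]])
        binned = am.bin_observed_vs_predicted(records(obs, np.zeros(21)), n_bins=5)
        assert binned["n_sites"].min() >= 5


class TestErrorPrevalenceCorrelation:
    def test_deterministic_monotone_case_is_significant(self):
        obs = np.logspace(-2, 0, 50)
        eps = 1.0 / obs  # exactly decreasing in prevalence
        res = am.error_prevalence_correlation(records(obs, eps), n_perm=500, seed=0)
        assert res.statistic < 0
        assert res.significant

    def test_independent_inputs_usually_inside_null(self):
        rng = np.random.default_rng(3)
        hits = sum(
            am.error_prevalence_correlation(
                records(10 ** rng.uniform(-2, 0, 80), rng.exponential(1.0, 80)),
                n_perm=300,
                seed=rng,
            ).significant
            for _ in range(60)
        )
        assert hits <= 9  # ~5% expected

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            am.error_prevalence_correlation(
                records(np.full(20, 0.5), np.arange(20.0)), n_perm=100, seed=0
            )


class TestStrainStructureScan:
    def _species(self, rng, n, eps_scale):
        obs = 10 ** rng.uniform(-2, 0, n)
        eps = rng.exponential(eps_scale, n)
        return records(obs, eps)

    def test_identical_strain_fractions_are_undefined(self):
        rng = np.random.default_rng(4)
        by_sp = {f"sp{i}": self._species(rng, 100, 0.3) for i in range(5)}
        scan = am.strain_structure_scan(
            by_sp, {sp: 0.3 for sp in by_sp}, n_perm=100, seed=0
        )
        assert np.isnan(scan.correlation).all()

    def test_error_scale_tied_to_strain_fraction_is_detected(self):
        """High-prevalence errors that shrink with strain fraction are flagged.

        The permutation null preserves each species' overall error level, so
        the signal must live in how errors depend on prevalence within a
        species: here every species has the same mean error, but its errors
        above prevalence 0.1 are smaller the more strain-rich the species.
        """
        rng = np.random.default_rng(5)
        fracs = {f"sp{i}": 0.1 + 0.1 * i for i in range(6)}
        by_sp = {}
        for i, (sp, frac) in enumerate(fracs.items()):
            n = 400
            obs = 10 ** rng.uniform(-2, 0, n)
            high = obs >= 0.1
            hi_level = 1.0 - 1.2 * frac  # decreasing in strain fraction
            lo_level = (0.5 * n - hi_level * high.sum()) / (~high).sum()
            eps = np.where(high, hi_level, lo_level) + rng.normal(0, 0.02, n)
            by_sp[sp] = records(obs, np.abs(eps))
        scan = am.strain_structure_scan(by_sp, fracs, n_perm=500, seed=1)
        tail = scan.thresholds >= 0.1
        assert (scan.correlation[tail] < -0.5).all()
        outside = scan.correlation[tail] < scan.null_lower[tail]
        assert outside.mean() > 0.8

    def test_min_sites_rule_excludes_sparse_species(self):
        rng = np.random.default_rng(6)
        by_sp = {f"sp{i}": self._species(rng, 200, 0.3) for i in range(5)}
        # one species with only 9 sites above the highest threshold region
        by_sp["sp4"] = records(np.full(9, 0.6), rng.exponential(0.3, 9))
        fracs = {sp: 0.1 + 0.1 * i for i, sp in enumerate(sorted(by_sp))}
        scan = am.strain_structure_scan(by_sp, fracs, min_sites=10, n_perm=100, seed=0)
        assert (scan.n_sites.loc["sp4"] == 9).all()
        assert (scan.n_species <= 4).any() or (scan.n_species == 4).any()
        # removing the rule changes which species contribute (guard)
        scan_all = am.strain_structure_scan(by_sp, fracs, min_sites=1, n_perm=100, seed=0)
        assert (scan_all.n_species >= scan.n_species).all()
        assert (scan_all.n_species != scan.n_species).any()

    def test_generated_ensemble_shows_negative_low_threshold_correlation(self):
        """More evolutionary alleles in low-strain-structure species raise
        their mean error, giving a negative across-species correlation in the
        threshold range where those alleles are observable."""
        base = am.CohortSpec(n_hosts=120, n_strain_sites=800, n_evo_sites=200)
        ens = am.generate_ensemble(8, base_spec=base, seed=33)
        recs, fracs = {}, {}
        for sp, item in ens.items():
            freqs = am.apply_detection_filter(item["counts"])
            recs[sp] = am.predict_cohort(freqs)
            fracs[sp] = item["strain_fraction"]
        scan = am.strain_structure_scan(recs, fracs, n_perm=500, seed=7)
        low = scan.correlation[1:8]
        assert (low < 0).all()
        assert low.min() < -0.5

    def test_too_few_species_rejected(self):
        rng = np.random.default_rng(7)
        by_sp = {f"sp{i}": self._species(rng, 50, 0.3) for i in range(3)}
        with pytest.raises(ValueError, match="at least 5"):
            am.strain_structure_scan(by_sp, {sp: 0.2 for sp in by_sp})
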