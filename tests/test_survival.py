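"""Kaplan-Meier estimator, log-rank test, PSI stratification, cutpoint scan."""

import numpy as np
import pandas as pd
import pytest

from splicescreen import (
    ClinicalTable, CohortConfig, SurvivalStratification, gen_cohort,
    km_estimate, logrank_test, scan_cutpoints, stratify_by_psi,
)
from splicescreen.survival import _logrank


def _clinical(times, events, patients=None):
    patients = patients or [f"P{i}" for i in range(len(times))]
    return ClinicalTable(pd.DataFrame({
        "patient_id": patients,
        "time_days": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=int),
    }))


class TestKaplanMeier:
    def test_hand_product_limit(self):
        """Three deaths at t=1,2,3, no censoring: S = 2/3, 1/3, 0; median 2."""
        km = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(km.event_times, [1, 2, 3])
        np.testing.assert_array_equal(km.at_risk, [3, 2, 1])
        assert km.median_survival == 2

    def test_censoring_between_deaths(self):
        # death at 1 (n=4), censor at 2, death at 3 (n=2): S = 3/4, 3/8
        km = km_estimate([1, 2, 3, 5], [1, 0, 1, 0])
        np.testing.assert_allclose(km.survival, [0.75, 0.375])
        assert km.median_survival == 3  # first event time with S <= 0.5

    def test_median_undefined_when_curve_stays_high(self):
        km = km_estimate([1, 2, 3, 5, 6], [1, 0, 0, 0, 0])
        np.testing.assert_allclose(km.survival, [0.8])
        assert np.isnan(km.median_survival)

    def test_all_censored_flat_curve(self):
        km = km_estimate([5, 8, 13], [0, 0, 0])
        assert km.event_times.size == 0
        np.testing.assert_allclose(km.survival_at([0, 10, 100]), 1.0)
        assert np.isnan(km.median_survival)

    def test_tied_deaths_aggregated(self):
        km = km_estimate([2, 2, 5], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [1 / 3, 0.0])
        np.testing.assert_array_equal(km.n_events, [2, 1])

    def test_conservation_of_deaths(self, rng):
        times = rng.exponential(50, 200) + 1
        events = rng.integers(0, 2, 200)
        km = km_estimate(times, events)
        assert km.n_events.sum() == events.sum()

    def test_oracle_equivalence_lifelines(self, rng):
        """S(t) matches the established implementation within 1e-12."""
        from lifelines import KaplanMeierFitter

        for _ in range(10):
            n = 50
            t = np.round(rng.exponential(100, n), 1) + 1
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            km = km_estimate(t, e)
            ref = KaplanMeierFitter().fit(t, e)
            ref_s = ref.survival_function_at_times(km.event_times).to_numpy()
            np.testing.assert_allclose(km.survival, ref_s, atol=1e-12)

    def test_empty_and_nonpositive_errors(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            km_estimate([0, 1], [1, 1])


class TestLogRank:
    def test_identical_strata_null(self):
        clin = _clinical([10, 20, 30, 10, 20, 30], [1, 1, 0, 1, 1, 0])
        psi = pd.Series([5, 5, 5, 1, 1, 1], index=clin.table["patient_id"])
        res = logrank_test(stratify_by_psi(clin, psi, 4.0))
        assert res.chi_square == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_label_swap_symmetry(self, rng):
        t = rng.exponential(100, 40) + 1
        e = rng.integers(0, 2, 40)
        psi = rng.uniform(0, 10, 40)
        clin = _clinical(t, e)
        s = pd.Series(psi, index=clin.table["patient_id"])
        a = logrank_test(stratify_by_psi(clin, s, 5.0))
        b = logrank_test(stratify_by_psi(clin, 10.0 - s, 5.0))  # flips arms
        assert a.chi_square == pytest.approx(b.chi_square, rel=1e-9)
        assert a.p == pytest.approx(b.p, rel=1e-9)

    def test_observed_equals_expected_total(self, rng):
        t = rng.exponential(100, 60) + 1
        e = rng.integers(0, 2, 60)
        clin = _clinical(t, e)
        s = pd.Series(rng.uniform(0, 10, 60), index=clin.table["patient_id"])
        res = logrank_test(stratify_by_psi(clin, s, 5.0))
        assert sum(res.observed.values()) == pytest.approx(sum(res.expected.values()))

    def test_no_events_warns_p_one(self):
        clin = _clinical([10, 20, 30, 40], [0, 0, 0, 0])
        psi = pd.Series([1, 1, 9, 9], index=clin.table["patient_id"])
        with pytest.warns(UserWarning, match="no events"):
            res = logrank_test(stratify_by_psi(clin, psi, 5.0))
        assert res.chi_square == 0.0 and res.p == 1.0

    def test_monotone_time_transform_invariance(self, rng):
        """The statistic is rank-based: exp() of all times changes nothing."""
        t1, e1 = rng.exponential(2, 30) + 0.1, rng.integers(0, 2, 30)
        t2, e2 = rng.exponential(1, 25) + 0.1, rng.integers(0, 2, 25)
        a = _logrank(t1, e1, t2, e2)
        b = _logrank(np.exp(t1), e1, np.exp(t2), e2)
        assert a.chi_square == pytest.approx(b.chi_square, rel=1e-12)

    def test_oracle_equivalence_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        for _ in range(10):
            t1, e1 = rng.exponential(80, 30) + 1, rng.integers(0, 2, 30)
            t2, e2 = rng.exponential(50, 35) + 1, rng.integers(0, 2, 35)
            mine = _logrank(t1, e1, t2, e2)
            ref = ll_logrank(t1, t2, e1, e2)
            assert mine.chi_square == pytest.approx(ref.test_statistic, abs=1e-8)
            assert mine.p == pytest.approx(ref.p_value, abs=1e-10)


class TestStratify:
    def test_boundary_goes_to_high(self):
        clin = _clinical([10, 20, 30], [1, 1, 1])
        psi = pd.Series([2.0, 5.0, 4.07], index=clin.table["patient_id"])
        coh = stratify_by_psi(clin, psi, 4.07)
        strata = coh.table.set_index("patient_id")["stratum"]
        assert strata.tolist() == ["low", "high", "high"]

    def test_missing_psi_excluded_and_counted(self):
        clin = _clinical([10, 20, 30], [1, 1, 1])
        psi = pd.Series([2.0, np.nan, 9.0], index=clin.table["patient_id"])
        coh = stratify_by_psi(clin, psi, 4.0)
        assert len(coh.table) == 2
        assert coh.n_excluded_missing_psi == 1

    def test_empty_stratum_is_error(self):
        clin = _clinical([10, 20], [1, 1])
        psi = pd.Series([1.0, 2.0], index=clin.table["patient_id"])
        with pytest.raises(ValueError, match="empty stratum: high"):
            stratify_by_psi(clin, psi, 50.0)


class TestScanCutpoints:
    def test_constant_psi_no_admissible_threshold(self):
        clin = _clinical([10, 20, 30, 40], [1, 1, 1, 1])
        psi = pd.Series([5.0] * 4, index=clin.table["patient_id"])
        with pytest.raises(ValueError, match="no admissible"):
            scan_cutpoints(psi, clin, grid=5)

    def test_single_point_grid_equals_direct_call(self, rng):
        t = rng.exponential(100, 40) + 1
        e = rng.integers(0, 2, 40)
        clin = _clinical(t, e)
        psi = pd.Series(rng.uniform(0, 10, 40), index=clin.table["patient_id"])
        scan = scan_cutpoints(psi, clin, grid=np.array([5.0]))
        direct = logrank_test(stratify_by_psi(clin, psi, 5.0))
        assert scan.best_threshold == 5.0
        assert scan.scan_table["p"].iloc[0] == pytest.approx(direct.p)
        assert scan.multiple_testing_caveat

    def test_planted_cut_recovered(self):
        """A hazard switch planted at the PSI threshold is found within one
        grid step in seeded replicates."""
        hits = 0
        grid_q = np.linspace(0.05, 0.95, 19)
        for seed in range(5):
            cfg = CohortConfig(n_patients=300, hazard_ratio=4.0, seed=seed,
                               n_genes=2, n_planted_deg=0)
            clin, psi, _, truth = gen_cohort(cfg)
            grid = np.quantile(psi.to_numpy(), grid_q)
            scan = scan_cutpoints(psi, clin, grid=grid, min_group_frac=0.05)
            steps = np.sort(np.unique(grid))
            i_best = np.searchsorted(steps, scan.best_threshold)
            i_true = np.searchsorted(steps, truth["threshold_true"])
            hits += abs(i_best - i_true) <= 1
        assert hits >= 4


class TestStratificationModel:
    def test_hr3_separation_direction(self):
        """Planted hazard ratio 3: the high-PSI arm has the shorter median
        and the log-rank flags the separation."""
        cfg = CohortConfig(n_patients=500, hazard_ratio=3.0, seed=3,
                           n_genes=2, n_planted_deg=0)
        clin, psi, _, truth = gen_cohort(cfg)
        res = SurvivalStratification(clin, psi, truth["threshold_true"]).fit()
        med = res.median_survival
        assert med["high"] < med["low"]
        assert res.logrank.p < 0.01
        assert "log-rank" in res.summary()
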