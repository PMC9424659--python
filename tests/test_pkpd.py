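"""Monte-Carlo exposures, PTA/CFR computation, and trough safety screening."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import daptopk as dp
from daptopk.exceptions import DomainError
from daptopk.physiology import CATEGORY_ORDER
from daptopk.pkpd import DEFAULT_MIC_GRID, PDTarget

C = dp.RenalFunctionCategory


@pytest.fixture(scope="module")
def adult_exposures(adult_subject, adult_model, drug):
    regimen = dp.DosingRegimen(6.0, 24.0, 0.5, 5)
    return dp.monte_carlo_exposures(
        adult_subject, adult_model, regimen, n=10_000, seed=11, drug=drug
    )


class TestMICDistribution:
    def test_default_grid(self):
        dist = dp.generate_mic_distribution("MRSA_LIKE")
        assert dist.mics == DEFAULT_MIC_GRID
        assert sum(dist.frequencies) == pytest.approx(1.0, abs=1e-12)

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(DomainError):
            dp.MICDistribution((0.5, 1.0), (0.5, 0.6))

    def test_mics_strictly_increasing(self):
        with pytest.raises(DomainError):
            dp.MICDistribution((1.0, 0.5), (0.5, 0.5))


class TestExposureSampling:
    def test_zero_cv_degenerates_to_deterministic(self, adult_subject, adult_model, drug):
        regimen = dp.DosingRegimen(6.0, 24.0, 0.5, 5)
        s = dp.monte_carlo_exposures(
            adult_subject, adult_model, regimen, n=50, seed=3, cv_cl=0.0, cv_v=0.0, drug=drug
        )
        assert np.allclose(s.auc_0_24, s.deterministic_auc_0_24)
        assert np.allclose(s.cmin_ss, s.deterministic_cmin_ss)

    def test_median_auc_near_deterministic(self, adult_exposures):
        med = np.median(adult_exposures.auc_0_24)
        assert med == pytest.approx(adult_exposures.deterministic_auc_0_24, rel=0.03)

    def test_auc_anticorrelates_with_clearance(self, adult_subject, adult_model, drug):
        regimen = dp.DosingRegimen(6.0, 24.0, 0.5, 5)
        pop = dp.sample_virtual_population(adult_subject, 2000, 0.25, 0.15, seed=5)
        s = dp.monte_carlo_exposures(
            adult_subject, adult_model, regimen, n=2000, seed=5, drug=drug
        )
        rho = spearmanr(pop.cl_multipliers, s.auc_0_24).statistic
        assert rho == pytest.approx(-1.0, abs=1e-9)

    def test_seeded_reproducibility(self, adult_subject, adult_model, drug):
        regimen = dp.DosingRegimen(6.0, 24.0, 0.5, 5)
        a = dp.monte_carlo_exposures(adult_subject, adult_model, regimen, n=100, seed=9, drug=drug)
        b = dp.monte_carlo_exposures(adult_subject, adult_model, regimen, n=100, seed=9, drug=drug)
        assert np.array_equal(a.auc_0_24, b.auc_0_24)
        assert np.array_equal(a.cmin_ss, b.cmin_ss)

    def test_deterministic_trough_matches_analytic(self, adult_subject, adult_model, drug):
        regimen = dp.DosingRegimen(6.0, 24.0, 0.5, 5)
        s = dp.monte_carlo_exposures(
            adult_subject, adult_model, regimen, n=1, seed=0, cv_cl=0.0, cv_v=0.0, drug=drug
        )
        expected = dp.steady_state_trough(adult_subject, drug, adult_model, regimen)
        assert s.deterministic_cmin_ss == pytest.approx(expected, rel=1e-9)


class TestPTA:
    def test_direct_count(self):
        assert dp.pta(np.array([600.0, 700.0, 800.0]), 1.0, dp.MRSA_TARGET) == pytest.approx(2 / 3)

    def test_vanishing_mic_attains(self):
        assert dp.pta(np.array([10.0, 20.0]), 1e-9, dp.MRSA_TARGET) == 1.0

    def test_all_below_target(self):
        assert dp.pta(np.full(10, 500.0), 1.0, dp.MRSA_TARGET) == 0.0

    def test_empty_samples_rejected(self):
        with pytest.raises(DomainError):
            dp.pta(np.array([]), 1.0, dp.MRSA_TARGET)

    def test_monotone_in_mic_and_matches_brute_force(self, adult_subject, adult_model, drug):
        regimen = dp.DosingRegimen(6.0, 24.0, 0.5, 5)
        s = dp.monte_carlo_exposures(adult_subject, adult_model, regimen, n=100, seed=2, drug=drug)
        curve = dp.pta_curve(s, dp.MRSA_TARGET)
        assert all(a >= b for a, b in zip(curve.values, curve.values[1:]))
        # brute-force enumeration over (subject, MIC) pairs
        for mic, value in zip(curve.mics, curve.values):
            brute = sum(1 for auc in s.auc_0_24 if auc / mic >= 666.0) / s.n
            assert value == brute

    def test_monotone_in_dose(self, adult_subject, adult_model, drug):
        lo = dp.monte_carlo_exposures(
            adult_subject, adult_model, dp.DosingRegimen(4.0, 24.0, 0.5, 5), n=2000, seed=4, drug=drug
        )
        hi = dp.monte_carlo_exposures(
            adult_subject, adult_model, dp.DosingRegimen(8.0, 24.0, 0.5, 5), n=2000, seed=4, drug=drug
        )
        for mic in DEFAULT_MIC_GRID:
            assert dp.pta(hi, mic, dp.MRSA_TARGET) >= dp.pta(lo, mic, dp.MRSA_TARGET)

    def test_zero_cv_converges_to_indicator(self, adult_subject, adult_model, drug):
        regimen = dp.DosingRegimen(6.0, 24.0, 0.5, 5)
        s = dp.monte_carlo_exposures(
            adult_subject, adult_model, regimen, n=10_000, seed=1, cv_cl=0.0, cv_v=0.0, drug=drug
        )
        for mic in DEFAULT_MIC_GRID:
            expected = 1.0 if s.deterministic_auc_0_24 / mic >= 666.0 else 0.0
            assert dp.pta(s, mic, dp.MRSA_TARGET) == expected

    def test_pta_increases_with_renal_impairment(self, adult_subject, adult_model, drug):
        """At MIC 1 mg/L, worse renal function means higher exposure and higher PTA."""
        values = []
        for cat in CATEGORY_ORDER:
            subj = dp.with_category(adult_subject, cat)
            model = dp.apply_renal_impairment(adult_model, subj)
            s = dp.monte_carlo_exposures(
                subj, model, dp.DosingRegimen(6.0, 24.0, 0.5, 5), n=4000, seed=8, drug=drug
            )
            values.append(dp.pta(s, 1.0, dp.MRSA_TARGET))
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))


class TestCFR:
    def test_weighted_sum(self):
        dist = dp.MICDistribution((0.5, 1.0, 2.0), (0.6, 0.3, 0.1))
        value = dp.cfr({0.5: 1.0, 1.0: 0.5, 2.0: 0.0}, dist)
        assert value == pytest.approx(0.75)

    def test_all_attain(self):
        dist = dp.generate_mic_distribution("MRSA_LIKE")
        assert dp.cfr({m: 1.0 for m in dist.mics}, dist) == pytest.approx(1.0)

    def test_degenerate_distribution(self):
        dist = dp.MICDistribution((1.0,), (1.0,))
        assert dp.cfr({1.0: 0.37}, dist) == pytest.approx(0.37)

    def test_missing_pta_for_weighted_mic_rejected(self):
        dist = dp.MICDistribution((0.5, 1.0), (0.5, 0.5))
        with pytest.raises(DomainError):
            dp.cfr({0.5: 1.0}, dist)

    def test_cfr_within_pta_range(self, adult_exposures):
        dist = dp.generate_mic_distribution("MRSA_LIKE")
        curve = dp.pta_curve(adult_exposures, dp.MRSA_TARGET, dist.mics)
        value = dp.cfr(curve, dist)
        assert min(curve.values) <= value <= max(curve.values)

    def test_equals_brute_force_enumeration(self, adult_subject, adult_model, drug):
        regimen = dp.DosingRegimen(6.0, 24.0, 0.5, 5)
        s = dp.monte_carlo_exposures(adult_subject, adult_model, regimen, n=50, seed=6, drug=drug)
        dist = dp.generate_mic_distribution("MRSA_LIKE")
        value = dp.cfr(dp.pta_curve(s, dp.MRSA_TARGET, dist.mics), dist)
        brute = sum(
            freq * (auc / mic >= 666.0)
            for mic, freq in dist.items()
            for auc in s.auc_0_24
        ) / s.n
        assert value == pytest.approx(brute, abs=1e-12)


class TestSafetyFlag:
    def test_fraction_count(self):
        res = dp.cmin_safety_flag(np.array([10.0, 20.0, 30.0]), threshold=24.3)
        assert res.fraction_above == pytest.approx(1 / 3)

    def test_all_zero(self):
        res = dp.cmin_safety_flag(np.zeros(5), deterministic_cmin=0.0)
        assert res.fraction_above == 0.0
        assert not res.flag

    def test_zero_threshold(self):
        res = dp.cmin_safety_flag(np.array([1.0, 2.0]), threshold=1e-12)
        assert res.fraction_above == 1.0

    def test_flag_follows_deterministic_subject(self):
        res = dp.cmin_safety_flag(np.array([1.0, 50.0]), deterministic_cmin=30.0)
        assert res.flag
        res2 = dp.cmin_safety_flag(np.array([1.0, 50.0]), deterministic_cmin=10.0)
        assert not res2.flag
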