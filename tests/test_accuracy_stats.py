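import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from burnsim.accuracy_stats import (
    FidelityHypothesis,
    RaterRecord,
    describe,
    one_sided_t_test,
    run_fidelity_study,
    signed_errors,
)

TOTAL_ERRORS = [-0.5, 9.0, 7.0, 0.0, 5.5, 2.5, 10.5, 3.5, -4.0]


class TestSignedErrors:
    def test_total_errors_from_study(self, rater_records):
        np.testing.assert_allclose(
            signed_errors(rater_records, "total"), TOTAL_ERRORS
        )

    def test_third_degree_last_record(self, rater_records):
        errs = signed_errors(rater_records, "3rd")
        assert errs[-1] == pytest.approx(16.0 - 25.0)

    def test_identical_pairs_give_zero_vector(self):
        recs = [
            RaterRecord("x", 10, 10, 5, 5, 15, 15),
            RaterRecord("y", 20, 20, 0, 0, 20, 20),
        ]
        assert np.all(signed_errors(recs, "total") == 0.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="at least one"):
            signed_errors([], "total")

    def test_unknown_category_raises(self, rater_records):
        with pytest.raises(ValueError, match="category"):
            signed_errors(rater_records, "4th")


class TestDescribe:
    def test_population_sd_convention(self, rater_records):
        mean, sd = describe(signed_errors(rater_records, "total"))
        assert mean == pytest.approx(np.mean(TOTAL_ERRORS))
        assert sd == pytest.approx(np.std(TOTAL_ERRORS, ddof=0))
        assert round(mean, 1) == 3.7 and round(sd, 1) == 4.5

    def test_constant_vector_has_zero_sd(self):
        mean, sd = describe([3.0, 3.0, 3.0])
        assert mean == 3.0 and sd == 0.0

    def test_single_observation_raises(self):
        with pytest.raises(ValueError, match="at least two"):
            describe([1.0])


class TestOneSidedT:
    def test_symmetric_about_mu0_gives_half(self):
        t, p = one_sided_t_test([9.0, 11.0, 9.0, 11.0], mu0=10.0)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5)

    def test_zero_sd_raises(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            one_sided_t_test([5.0, 5.0, 5.0], mu0=10.0)

    def test_shift_invariance(self):
        """Adding c to all errors and to mu0 leaves t and p unchanged."""
        rng = np.random.default_rng(11)
        e = rng.normal(3, 4, size=9)
        t1, p1 = one_sided_t_test(e, mu0=10.0)
        t2, p2 = one_sided_t_test(e + 7.5, mu0=17.5)
        assert t1 == pytest.approx(t2) and p1 == pytest.approx(p2)

    def test_p_monotone_in_mean_error(self):
        rng = np.random.default_rng(5)
        noise = rng.normal(0, 4, size=9)
        ps = [
            one_sided_t_test(noise + shift, mu0=10.0)[1]
            for shift in (0.0, 2.0, 4.0, 6.0)
        ]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n=st.integers(3, 30),
        mu0=st.floats(0.5, 20.0),
    )
    def test_relation_to_sample_sd_reference(self, seed, n, mu0):
        """t equals scipy's one-sample t times sqrt(n/(n-1)).

        scipy.stats.ttest_1samp uses the sample-SD convention; the population
        convention used here differs by exactly that factor.
        """
        rng = np.random.default_rng(seed)
        e = rng.normal(3, 4, size=n)
        t_pop, p_pop = one_sided_t_test(e, mu0=mu0)
        ref = stats.ttest_1samp(e, popmean=mu0, alternative="less")
        assert t_pop == pytest.approx(
            ref.statistic * np.sqrt(n / (n - 1)), rel=1e-10
        )
        # p from the same df, evaluated at the convention-scaled statistic
        assert p_pop == pytest.approx(float(stats.t.cdf(t_pop, n - 1)), rel=1e-12)


class TestFidelityStudy:
    def test_reproduces_published_statistics(self, rater_records):
        res = run_fidelity_study(rater_records)
        assert res["2nd"].rounded()[:3] == (3.8, 2.5, -1.41)
        assert res["3rd"].rounded() == (-0.1, 3.9, -3.96, 0.0021)
        assert res["total"].rounded()[:3] == (3.7, 4.5, -4.2)

    def test_constant_errors_rejected(self):
        recs = [RaterRecord(str(i), 15, 10, 5, 5, 20, 15) for i in range(5)]
        with pytest.raises(ValueError, match="zero standard deviation"):
            run_fidelity_study(recs)

    def test_rejection_rate_matches_monte_carlo_oracle(self):
        """Power at (mean 3, sd 4, n 9, mu0 10) agrees with a direct oracle.

        The oracle recomputes each replicate's decision from first principles
        (mean, population SD, Student-t lower tail) with no calls into the
        module under test.
        """
        rng = np.random.default_rng(1234)
        alpha = 0.05
        n, reps = 9, 1000
        draws = rng.normal(3.0, 4.0, size=(reps, n))

        rejected_module = 0
        for row in draws:
            recs = [
                RaterRecord(str(i), 10.0 + v, 10.0, 5.0 + v, 5.0, 10.0 + v, 10.0)
                for i, v in enumerate(row)
            ]
            res = run_fidelity_study(recs, FidelityHypothesis())
            rejected_module += res["total"].p_value < alpha

        m = draws.mean(axis=1)
        s = draws.std(axis=1, ddof=0)
        t_oracle = (m - 10.0) / (s / np.sqrt(n))
        rejected_oracle = int((stats.t.cdf(t_oracle, n - 1) < alpha).sum())

        assert rejected_module == rejected_oracle
        assert rejected_oracle / reps == pytest.approx(0.97, abs=0.05)
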