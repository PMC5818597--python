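import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iscpipe.dose_response import (DoseResponseSeries, bootstrap_departure_p,
                                   determine_noel_loel, derive_test_seed,
                                   fit_spline, mn_frequency)
from iscpipe.dose_response import test_departures as departure_test


def make_series(doses, groups, **kw):
    return DoseResponseSeries(endpoint=kw.get("endpoint", "e"),
                              chemical=kw.get("chemical", "c"),
                              doses=np.asarray(doses, float),
                              responses=[np.asarray(g, float) for g in groups])


class TestSplineFit:
    DOSES = np.array([0, 1, 2, 5, 10, 20, 50, 100, 200], float)

    def test_flat_data_fits_grand_mean(self):
        s = make_series(self.DOSES, [[2.0, 2.0, 2.0]] * len(self.DOSES))
        fit = fit_spline(s)
        np.testing.assert_allclose(fit.fitted, 2.0)

    def test_noiseless_hill_recovered_within_1pct(self):
        hill = 1 + 3 * self.DOSES**1.5 / (self.DOSES**1.5 + 20**1.5)
        s = make_series(self.DOSES, [[v] * 3 for v in hill])
        fit = fit_spline(s)
        np.testing.assert_allclose(fit.fitted, hill, rtol=0.01)

    def test_heavy_penalty_gives_monotone_fit_on_monotone_data(self):
        y = np.linspace(0, 5, len(self.DOSES)) ** 1.3
        s = make_series(self.DOSES, [[v, v + 0.1] for v in y])
        fit = fit_spline(s, lam=1e6)
        assert np.all(np.diff(fit.fitted) >= -1e-9)

    def test_fewer_than_4_doses_falls_back_to_means(self):
        s = make_series([0, 10, 100], [[1, 2], [3, 4], [5, 6]])
        fit = fit_spline(s)
        assert fit.spline is None
        np.testing.assert_allclose(fit.fitted, [1.5, 3.5, 5.5])

    def test_vehicle_anchored_one_decade_below_lowest_dose(self):
        s = make_series(self.DOSES, [[v] * 2 for v in self.DOSES])
        assert fit_spline(s).pseudo_dose == pytest.approx(0.1)


class TestBootstrapDeparture:
    def test_extreme_separation_reaches_minimal_p(self):
        # all treated values above every vehicle value, n=3 vs 3
        p = bootstrap_departure_p(np.array([[10.0, 10.5, 11.0]]),
                                  np.array([1.0, 1.2, 0.8]),
                                  n_resamples=999,
                                  rng=np.random.default_rng(0))
        assert p[0] == pytest.approx(1.0 / 1000.0)

    def test_zero_variance_identical_groups_give_p_one(self):
        p = bootstrap_departure_p(np.array([[2.0, 2.0, 2.0]]),
                                  np.array([2.0, 2.0, 2.0]),
                                  n_resamples=999,
                                  rng=np.random.default_rng(0))
        assert p[0] == 1.0

    def test_zero_variance_different_groups_give_minimal_p(self):
        p = bootstrap_departure_p(np.array([[3.0, 3.0, 3.0]]),
                                  np.array([2.0, 2.0, 2.0]),
                                  n_resamples=999,
                                  rng=np.random.default_rng(0))
        assert p[0] == pytest.approx(1.0 / 1000.0)

    def test_replicate_order_does_not_change_p(self):
        """The bootstrap seed derives from labels, not data, so permuting
        replicates leaves every p-value unchanged."""
        doses = [0, 1, 10, 100]
        groups = [[1.0, 1.4, 0.9], [1.2, 1.1, 1.3], [2.0, 1.8, 2.2], [3.0, 2.5, 2.8]]
        s1 = make_series(doses, groups)
        s2 = make_series(doses, [g[::-1] for g in groups])
        p1, _ = departure_test(s1, n_resamples=499)
        p2, _ = departure_test(s2, n_resamples=499)
        np.testing.assert_array_equal(p1, p2)

    def test_seed_depends_on_labels_and_global_seed(self):
        a = derive_test_seed("chemA", "MN", 0)
        assert a == derive_test_seed("chemA", "MN", 0)
        assert a != derive_test_seed("chemB", "MN", 0)
        assert a != derive_test_seed("chemA", "MN", 1)
        assert 0 <= a < 2**31


class TestNoelLoel:
    def test_no_significant_dose(self):
        res = determine_noel_loel([1, 10, 100], [0.4, 0.3, 0.2])
        assert res.loel is None
        assert res.noel == 100.0

    def test_rule_application(self):
        res = determine_noel_loel([1, 10, 100], [0.2, 0.03, 0.01])
        assert res.loel == 10.0
        assert res.noel == 1.0

    def test_loel_at_lowest_dose_leaves_noel_undefined(self):
        res = determine_noel_loel([1, 10, 100], [0.01, 0.2, 0.01])
        assert res.loel == 1.0
        assert res.noel is None

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            determine_noel_loel([1, 10], [0.5, 1.5])

    @given(p=st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_loel_never_below_noel(self, p):
        doses = np.arange(1.0, len(p) + 1)
        res = determine_noel_loel(doses, p)
        if res.loel is not None and res.noel is not None:
            assert res.noel < res.loel
        # adding a higher significant dose never raises the LOEL
        res2 = determine_noel_loel(np.append(doses, doses[-1] + 1),
                                   np.append(p, 0.0))
        if res.loel is not None:
            assert res2.loel <= res.loel

    def test_holm_is_more_conservative(self):
        plain = determine_noel_loel([1, 10, 100], [0.03, 0.2, 0.3])
        holm = determine_noel_loel([1, 10, 100], [0.03, 0.2, 0.3], holm=True)
        assert plain.loel == 1.0
        assert holm.loel is None


class TestMNFrequency:
    @pytest.mark.parametrize("mn,scored,expected", [
        (45, 9000, 0.5),
        (0, 9000, 0.0),
        (90, 9000, 1.0),
    ])
    def test_arithmetic(self, mn, scored, expected):
        assert mn_frequency(mn, scored) == pytest.approx(expected)

    def test_more_mn_than_scored_rejected(self):
        with pytest.raises(ValueError):
            mn_frequency(9001, 9000)

    def test_binomial_simulation_recovers_rate(self, rng):
        """Mean frequency over binomial draws at p=0.01, 9000 cells, stays
        inside the exact binomial standard-error band."""
        n_sim = 400
        draws = rng.binomial(9000, 0.01, size=n_sim)
        freq = mn_frequency(draws, np.full(n_sim, 9000))
        se = 100 * np.sqrt(0.01 * 0.99 / 9000 / n_sim)
        assert abs(freq.mean() - 1.0) < 4 * se
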