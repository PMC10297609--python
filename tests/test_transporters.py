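"""Transporter hazard model: binding law, fates, scheduled release."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gluspill import (TransporterBook, TransporterSpec,
                      assign_fate_and_schedule, binding_probability,
                      release_due, release_schedule_cdf,
                      sample_release_delays, update_and_sample_binding)
from gluspill.transporters import FATE_TRANSLOCATE, FATE_UNBIND, FREE


class TestBindingProbability:
    def test_closed_form_values(self):
        assert binding_probability(0.0, 1.0) == 0.0
        assert binding_probability(1.0, 1.0) == pytest.approx(1 - np.exp(-1),
                                                              abs=1e-12)

    @given(t=st.floats(0, 50), psi=st.floats(0.01, 10))
    @settings(deadline=None, max_examples=50)
    def test_is_probability_and_monotone(self, t, psi):
        p = binding_probability(t, psi)
        # mathematically in [0, 1); float rounding may saturate at 1.0
        assert 0.0 <= p <= 1.0
        assert binding_probability(t + 0.1, psi) >= p

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            binding_probability(-0.1, 1.0)
        with pytest.raises(ValueError):
            binding_probability(1.0, 0.0)


class TestHazardSampling:
    def simulate_waiting_times(self, n, dt, psi, seed, t_max=20.0):
        """Reference loop: particles in permanent contact; record the step at
        which each binds."""
        book = TransporterBook.empty(n)
        rng = np.random.default_rng(seed)
        bind_time = np.full(n, np.nan)
        contact = np.ones(n, dtype=bool)
        t = 0.0
        while t < t_max and np.isnan(bind_time).any():
            t += dt
            newly = update_and_sample_binding(book, contact, dt, psi, rng)
            bind_time[newly] = t
        return bind_time

    def test_mean_waiting_time_is_psi(self):
        """Exponential waiting-time oracle: permanent contact gives mean
        time-to-binding ~ psi."""
        wt = self.simulate_waiting_times(20_000, dt=0.05, psi=1.0, seed=0)
        wt = wt[~np.isnan(wt)]
        # discretisation shifts the mean by ~dt/2; allow 3 SE plus that bias
        se = wt.std(ddof=1) / np.sqrt(wt.size)
        assert abs(wt.mean() - 1.0) < 3 * se + 0.05

    @pytest.mark.parametrize("dt", [0.02, 0.01])
    def test_cumulative_cdf_matches_first_order_law(self, dt):
        """Empirical binding CDF equals 1 - exp(-t/psi) at t in {0.5, 1, 2} ms
        within binomial error, independent of the step size (dt halving)."""
        n = 20_000
        wt = self.simulate_waiting_times(n, dt=dt, psi=1.0, seed=1)
        for t in (0.5, 1.0, 2.0):
            p_emp = np.mean(np.nan_to_num(wt, nan=np.inf) <= t + 1e-9)
            p_true = 1 - np.exp(-t)
            se = np.sqrt(p_true * (1 - p_true) / n)
            assert abs(p_emp - p_true) < 3 * se + dt  # dt: discretisation bias

    def test_clock_resets_on_departure(self):
        """Leaving the 5 nm shell and returning restarts the contact clock."""
        book = TransporterBook.empty(1)
        rng = np.random.default_rng(0)
        dt, psi = 0.1, 1e9       # hazard ~ 0: no binding interferes
        update_and_sample_binding(book, np.array([True]), dt, psi, rng)
        update_and_sample_binding(book, np.array([True]), dt, psi, rng)
        assert book.contact_clock[0] == pytest.approx(0.2)
        update_and_sample_binding(book, np.array([False]), dt, psi, rng)
        assert book.contact_clock[0] == 0.0
        update_and_sample_binding(book, np.array([True]), dt, psi, rng)
        assert book.contact_clock[0] == pytest.approx(0.1)


class TestReleaseSchedule:
    def test_cdf_is_cumulative_gaussian(self):
        """The S-function crosses 0.5 exactly at 4 ms with sigma = 2 ms."""
        assert release_schedule_cdf(4.0) == pytest.approx(0.5, abs=1e-15)
        assert release_schedule_cdf(2.0) == pytest.approx(
            stats.norm.cdf(-1.0), abs=1e-12)
        assert release_schedule_cdf(6.0) + release_schedule_cdf(2.0) == \
            pytest.approx(1.0, abs=1e-12)

    def test_sampled_delays_positive_and_match_truncated_law(self):
        spec = TransporterSpec()
        rng = np.random.default_rng(2)
        d = sample_release_delays(100_000, spec, rng)
        assert np.all(d > 0)
        # empirical CDF at 4 and 2 ms vs the zero-truncated Gaussian,
        # computed independently from standard normal CDF values
        z = stats.norm.cdf
        for t in (4.0, 2.0):
            expect = (z((t - 4) / 2) - z(-2)) / (1 - z(-2))
            emp = np.mean(d <= t)
            se = np.sqrt(expect * (1 - expect) / d.size)
            assert abs(emp - expect) < 3.5 * se


class TestFates:
    def test_unbound_fraction_near_default(self):
        spec = TransporterSpec()
        rng = np.random.default_rng(3)
        fates, release = assign_fate_and_schedule(np.arange(50_000), 1.0,
                                                  spec, rng)
        frac = np.mean(fates == FATE_UNBIND)
        se = np.sqrt(0.35 * 0.65 / fates.size)
        assert abs(frac - 0.35) < 3 * se
        assert np.all(np.isinf(release[fates == FATE_TRANSLOCATE]))
        assert np.all(release[fates == FATE_UNBIND] > 1.0)

    def test_p_unbind_zero_retains_everything(self):
        spec = TransporterSpec(p_unbind=0.0)
        rng = np.random.default_rng(4)
        fates, release = assign_fate_and_schedule(np.arange(1000), 0.5, spec,
                                                  rng)
        assert np.all(fates == FATE_TRANSLOCATE)
        assert np.all(np.isinf(release))

    def test_cycle_fates_independent(self):
        """Successive bind-release cycles draw independent fates
        (chi-square on the 2x2 contingency of two cycles)."""
        spec = TransporterSpec()
        rng = np.random.default_rng(5)
        f1, _ = assign_fate_and_schedule(np.arange(20_000), 1.0, spec, rng)
        f2, _ = assign_fate_and_schedule(np.arange(20_000), 5.0, spec, rng)
        table = np.array([[np.sum((f1 == a) & (f2 == b)) for b in (1, 2)]
                          for a in (1, 2)])
        p = stats.chi2_contingency(table).pvalue
        assert p > 0.01


class TestReleaseDue:
    def _bound_book(self):
        book = TransporterBook.empty(3)
        status = np.full(3, 1, dtype=np.int8)
        book.bound[:] = True
        book.bind_time[:] = 1.0
        book.fate[:] = [FATE_UNBIND, FATE_UNBIND, FATE_TRANSLOCATE]
        book.release_time[:] = [5.0, 7.0, np.inf]
        return book, status

    def test_nothing_due_before_schedule(self):
        book, status = self._bound_book()
        released = release_due(book, status, t_now=4.9)
        assert released.size == 0
        assert np.all(status == 1)

    def test_release_at_scheduled_time(self):
        """A particle bound at 1 ms with a 4 ms delay is free again at 5 ms
        and eligible for re-binding."""
        book, status = self._bound_book()
        released = release_due(book, status, t_now=5.0)
        assert released.tolist() == [0]
        assert status[0] == FREE
        assert not book.bound[0]
        assert book.contact_clock[0] == 0.0
        # the translocation-fated particle is never released
        release_due(book, status, t_now=1e9)
        assert book.bound[2]


def test_spec_validation():
    with pytest.raises(ValueError):
        TransporterSpec(psi_ms=0.0)
    with pytest.raises(ValueError):
        TransporterSpec(p_unbind=1.5)
    with pytest.raises(ValueError):
        TransporterSpec(unbind_sigma_ms=0.0)
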