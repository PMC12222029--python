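import numpy as np
import pytest

from oncoclock.initiation import (
    InitiationParams,
    f_integral,
    mrca_time_horizon,
    p_eca_given_mrca,
    p_mrca,
    p_mrca_curve,
    population_size,
    sample_event_times,
)

FAST = InitiationParams(
    mu1=3e-4, mu2=3e-4, r=1.2, s=5.0, lam1=1.0, delta1=0.8,
    lam2=0.8, delta2=1.0, T=30.0,
)


class TestPopulationSize:
    def test_initial_condition(self):
        assert population_size(0.0, FAST) == pytest.approx(1.0)

    def test_continuity_at_switch(self):
        eps = 1e-9
        below = population_size(FAST.T - eps, FAST)
        above = population_size(FAST.T + eps, FAST)
        assert below == pytest.approx(above, rel=1e-6)

    def test_direct_exponential_value(self):
        p = InitiationParams(lam1=0.2, delta1=0.1, T=100.0, lam2=0.1, delta2=0.2)
        assert population_size(100.0, p) == pytest.approx(np.exp(10.0))


class TestPMrca:
    def test_no_first_driver_means_no_mrca(self):
        assert p_mrca(50.0, FAST.with_(mu1=0.0)) == 0.0
        assert p_mrca(50.0, FAST.with_(mu2=0.0)) == 0.0

    def test_zero_at_time_zero(self):
        assert p_mrca(0.0, FAST) == pytest.approx(0.0, abs=1e-12)

    def test_non_decreasing_and_bounded(self):
        grid = np.linspace(0.0, mrca_time_horizon(FAST), 25)
        vals = p_mrca_curve(grid, FAST)
        assert np.all(np.diff(vals) >= -1e-12)
        assert np.all((vals >= 0.0) & (vals <= 1.0))

    def test_bounded_on_parameter_grid(self):
        for mu in (1e-5, 1e-3):
            for s in (2.0, 10.0):
                for r in (1.05, 1.5):
                    p = FAST.with_(mu1=mu, mu2=mu, s=s, r=r)
                    for t in (5.0, 25.0, 45.0):
                        assert 0.0 <= p_mrca(t, p) <= 1.0

    def test_curve_matches_scalar_evaluation(self):
        tm = mrca_time_horizon(FAST)
        grid = np.linspace(1.0, tm, 7)
        curve = p_mrca_curve(grid, FAST, t_horizon=tm)
        scalar = [p_mrca(t, FAST, t_horizon=tm) for t in grid]
        assert np.allclose(curve, scalar, atol=1e-5)

    def test_closed_form_printed_f_diverges_for_typical_selection(self):
        # alpha > 1 whenever s > 1: the printed integral factor is
        # non-evaluable there and must raise rather than return nonsense
        with pytest.raises(ValueError):
            f_integral(FAST, form="printed")

    def test_survival_f_bounded_by_its_limits(self):
        f = f_integral(FAST, form="survival")
        assert FAST.nu2_expansion <= f <= 1.0

    def test_closed_form_within_order_of_magnitude(self):
        branching = p_mrca(45.0, FAST)
        closed = p_mrca(45.0, FAST, method="closed_form")
        assert closed > 0
        assert 0.01 < closed / branching < 100

    def test_invalid_phase_rates_rejected(self):
        with pytest.raises(ValueError):
            p_mrca(1.0, FAST.with_(delta1=1.5))   # not expanding
        with pytest.raises(ValueError):
            p_mrca(1.0, FAST.with_(delta2=0.5))   # not declining


class TestPEcaGivenMrca:
    def test_linear_branch(self):
        assert p_eca_given_mrca(10.0, 20.0, FAST) == pytest.approx(0.5)

    def test_normalisation_as_t1_approaches_t2(self):
        assert p_eca_given_mrca(19.9999, 20.0, FAST) == pytest.approx(1.0, abs=1e-3)
        t2 = FAST.T + 20.0
        assert p_eca_given_mrca(t2 * (1 - 1e-9), t2, FAST) == pytest.approx(1.0, abs=1e-6)

    def test_continuity_at_switch_time(self):
        t2 = FAST.T + 15.0
        eps = 1e-7
        below = p_eca_given_mrca(FAST.T - eps, t2, FAST)
        above = p_eca_given_mrca(FAST.T + eps, t2, FAST)
        assert below == pytest.approx(above, rel=1e-5)

    def test_non_decreasing_in_t1(self):
        t2 = FAST.T + 25.0
        vals = [p_eca_given_mrca(t1, t2, FAST) for t1 in np.linspace(0.0, t2 * 0.999, 40)]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            p_eca_given_mrca(5.0, 5.0, FAST)


def test_sampled_event_times_are_ordered_and_reproducible():
    a1, a2 = sample_event_times(FAST, 64, np.random.default_rng(5))
    b1, b2 = sample_event_times(FAST, 64, np.random.default_rng(5))
    assert np.array_equal(a1, b1) and np.array_equal(a2, b2)
    assert np.all(a1 <= a2)
    assert np.all(a2 <= mrca_time_horizon(FAST))
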