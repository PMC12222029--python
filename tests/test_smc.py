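import numpy as np
import pytest

from oncoclock.initiation import InitiationParams, divisions_by, sample_event_times
from oncoclock.smc import (
    ABCConfig,
    Prior,
    VAFHistogram,
    abc_smc,
    fit_growth,
    fit_initiation,
    ks_distance,
)


def gaussian_mean_problem(observed_mean, noise=0.05):
    """Toy inference problem: recover the mean of a Gaussian."""
    def simulator(params):
        rng = np.random.default_rng(int(params["mean"] * 1e6) % 2**31)
        return params["mean"] + noise * rng.standard_normal()

    def distance(sim):
        return abs(sim - observed_mean)

    priors = {"mean": Prior("uniform", -5.0, 5.0)}
    return simulator, distance, priors


class TestAbcSmc:
    def test_posterior_concentrates_on_truth(self):
        sim, dist, priors = gaussian_mean_problem(1.7)
        cfg = ABCConfig(population_size=150, max_generations=6, eps_target=0.01, seed=1)
        post = abc_smc(sim, dist, priors, cfg)
        lo, hi = post.credible_interval("mean")
        assert lo <= 1.7 <= hi
        assert hi - lo < 2.0  # tighter than the prior width of 10

    def test_identical_seeds_identical_populations(self):
        sim, dist, priors = gaussian_mean_problem(0.3)
        cfg = ABCConfig(population_size=60, max_generations=4, eps_target=0.01, seed=7)
        a = abc_smc(sim, dist, priors, cfg)
        b = abc_smc(sim, dist, priors, cfg)
        assert np.array_equal(a.particles, b.particles)
        assert np.array_equal(a.weights, b.weights)

    def test_epsilon_trace_non_increasing(self):
        sim, dist, priors = gaussian_mean_problem(-2.0)
        cfg = ABCConfig(population_size=80, max_generations=6, eps_target=1e-4, seed=3)
        post = abc_smc(sim, dist, priors, cfg)
        assert all(x >= y - 1e-12 for x, y in zip(post.eps_trace, post.eps_trace[1:]))

    def test_terminates_immediately_when_target_met(self):
        sim, dist, priors = gaussian_mean_problem(0.0, noise=0.0)

        def loose_distance(sim_out):
            return 0.0  # every particle is perfect

        cfg = ABCConfig(population_size=30, max_generations=10, eps_target=0.5, seed=2)
        post = abc_smc(sim, loose_distance, priors, cfg)
        assert post.n_generations == 1

    def test_weights_normalised(self):
        sim, dist, priors = gaussian_mean_problem(1.0)
        cfg = ABCConfig(population_size=50, max_generations=3, eps_target=0.01, seed=9)
        post = abc_smc(sim, dist, priors, cfg)
        assert post.weights.sum() == pytest.approx(1.0)

    def test_degenerate_prior_rejected(self):
        with pytest.raises(ValueError):
            Prior("uniform", 1.0, 1.0)
        with pytest.raises(ValueError):
            Prior("loguniform", 0.0, 1.0)


class TestKsDistance:
    def test_identical_samples_distance_zero(self):
        x = np.array([0.1, 0.5, 0.9])
        assert ks_distance(x, x) == 0.0

    def test_disjoint_samples_distance_one(self):
        assert ks_distance(np.zeros(5), np.ones(5)) == 1.0


class TestFitInitiation:
    def test_empty_eca_set_flagged_and_fit_runs(self):
        truth = InitiationParams(mu1=1e-5, mu2=1e-5)
        rng = np.random.default_rng(0)
        _, t2 = sample_event_times(truth, 15, rng)
        m2 = truth.mu / 3.3e9 * np.asarray(divisions_by(t2, truth))
        cfg = ABCConfig(population_size=30, max_generations=2, eps_target=1e-3, seed=4)
        post = fit_initiation(m2, [], cfg, base_params=truth, n_sim=40)
        assert post.flags["eca_empty"]
        assert post.eps_trace[-1] <= post.eps_trace[0] + 1e-12

    def test_requires_ten_tumours(self):
        cfg = ABCConfig(population_size=20, max_generations=2, seed=0)
        with pytest.raises(ValueError, match="10"):
            fit_initiation([1e-8] * 5, [], cfg)


class TestFitGrowth:
    def test_all_clonal_histogram_refused(self):
        hist = VAFHistogram(
            a_grid=np.linspace(100, 900, 10),
            m_obs=np.full(10, 3.0),
            n_cells=1000.0,
        )
        cfg = ABCConfig(population_size=20, max_generations=2, seed=0)
        with pytest.raises(ValueError, match="subclonal"):
            fit_growth(hist, cfg)

    def test_histogram_binning_counts_cumulatively(self):
        v = np.array([0.06, 0.1, 0.2, 0.4, 0.44, 0.5])  # 0.5 is clonal, excluded
        hist = VAFHistogram.from_pseudo_vafs(v, n_cells=1000.0, n_bins=5)
        assert hist.m_obs[0] == 5
        assert np.all(np.diff(hist.m_obs) <= 0)
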