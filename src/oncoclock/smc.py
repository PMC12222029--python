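"""Approximate Bayesian computation with sequential Monte-Carlo.

A standard ABC-SMC sampler: generation 0 draws from the prior and keeps
every particle; each later generation resamples the previous weighted
population, perturbs with a Gaussian kernel whose covariance is twice
the weighted sample covariance, and accepts particles whose simulated
summary lies within the current tolerance epsilon. Epsilon follows the
adaptive median schedule (next epsilon = median accepted distance) and
the run stops at the generation cap or once epsilon reaches the target.

Parameters are handled internally on transformed scales (log for
log-uniform priors) so the kernel is Gaussian in a space where the prior
is flat.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from . import growth as growth_mod
from . import initiation as init_mod

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Prior:
    """A one-dimensional prior: uniform or log-uniform on [low, high]."""

    dist: str                 # "uniform" | "loguniform"
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.dist not in ("uniform", "loguniform"):
            raise ValueError(f"unknown prior distribution {self.dist!r}")
        if not self.high > self.low:
            raise ValueError("prior requires high > low")
        if self.dist == "loguniform" and self.low <= 0:
            raise ValueError("log-uniform prior requires low > 0")

    def transform(self, x: float | np.ndarray) -> float | np.ndarray:
        return np.log(x) if self.dist == "loguniform" else x

    def untransform(self, y: float | np.ndarray) -> float | np.ndarray:
        return np.exp(y) if self.dist == "loguniform" else y

    @property
    def bounds_t(self) -> tuple[float, float]:
        return (float(self.transform(self.low)), float(self.transform(self.high)))

    def sample_t(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lo, hi = self.bounds_t
        return rng.uniform(lo, hi, n)


@dataclass
class ABCConfig:
    population_size: int = 1000
    max_generations: int = 25
    eps_target: float = 0.05
    seed: int = 0
    max_attempts_per_particle: int = 500

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population size must be >= 2")
        if self.eps_target <= 0:
            raise ValueError("epsilon target must be > 0")


@dataclass
class PosteriorSample:
    """Weighted accepted parameter sets with the epsilon trace."""

    names: list[str]
    particles: np.ndarray          # (n, d) on the natural scale
    weights: np.ndarray            # normalised to 1
    distances: np.ndarray
    eps_trace: list[float] = field(default_factory=list)
    n_generations: int = 0
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {n: self.particles[:, j] for j, n in enumerate(self.names)}

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Weighted credible interval cutting (1 - level)/2 per tail."""
        j = self.names.index(name)
        x = self.particles[:, j]
        order = np.argsort(x)
        cw = np.cumsum(self.weights[order])
        cw /= cw[-1]
        tail = (1.0 - level) / 2.0
        lo = float(np.interp(tail, cw, x[order]))
        hi = float(np.interp(1.0 - tail, cw, x[order]))
        return lo, hi

    def posterior_mean(self, name: str) -> float:
        j = self.names.index(name)
        return float(np.sum(self.weights * self.particles[:, j]))

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.particles, columns=self.names)
        df["weight"] = self.weights
        df["distance"] = self.distances
        return df


def abc_smc(
    simulator: Callable[[Mapping[str, float]], object],
    distance: Callable[[object], float],
    priors: Mapping[str, Prior],
    config: ABCConfig,
    rng: np.random.Generator | None = None,
) -> PosteriorSample:
    """Run ABC-SMC; ``distance`` compares a simulation with the observed
    summary (already closed over it)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    names = list(priors)
    d = len(names)
    n = config.population_size
    bounds = np.array([priors[k].bounds_t for k in names])

    def run(theta_t: np.ndarray) -> float:
        natural = {
            k: float(priors[k].untransform(theta_t[j])) for j, k in enumerate(names)
        }
        return float(distance(simulator(natural)))

    # generation 0: sample the prior, keep everything
    theta = np.column_stack([priors[k].sample_t(rng, n) for k in names])
    dists = np.array([run(theta[i]) for i in range(n)])
    weights = np.full(n, 1.0 / n)
    eps = float(np.median(dists))
    eps_trace = [eps]
    gen = 1

    while gen < config.max_generations and eps > config.eps_target:
        cov = 2.0 * np.cov(theta, rowvar=False, aweights=weights).reshape(d, d)
        cov += 1e-12 * np.eye(d)
        chol = np.linalg.cholesky(cov)
        new_theta = np.empty_like(theta)
        new_dists = np.empty(n)
        new_weights = np.empty(n)
        accepted = 0
        attempts = 0
        max_attempts = config.max_attempts_per_particle * n
        inv_cov = np.linalg.inv(cov)
        while accepted < n and attempts < max_attempts:
            attempts += 1
            j = rng.choice(n, p=weights)
            prop = theta[j] + chol @ rng.standard_normal(d)
            if np.any(prop < bounds[:, 0]) or np.any(prop > bounds[:, 1]):
                continue
            dist = run(prop)
            if dist > eps:
                continue
            diff = theta - prop[None, :]
            log_k = -0.5 * np.einsum("ij,jk,ik->i", diff, inv_cov, diff)
            denom = float(np.sum(weights * np.exp(log_k - log_k.max())))
            new_weights[accepted] = math.exp(-log_k.max()) / max(denom, 1e-300)
            new_theta[accepted] = prop
            new_dists[accepted] = dist
            accepted += 1
        if accepted < n:
            logger.warning(
                "SMC generation %d stalled (%d/%d accepted); stopping", gen, accepted, n
            )
            break
        theta, dists = new_theta, new_dists
        weights = new_weights / new_weights.sum()
        eps = float(np.median(dists))
        eps_trace.append(eps)
        gen += 1

    particles = np.column_stack(
        [priors[k].untransform(theta[:, j]) for j, k in enumerate(names)]
    )
    return PosteriorSample(
        names=names,
        particles=particles,
        weights=weights / weights.sum(),
        distances=dists,
        eps_trace=eps_trace,
        n_generations=gen,
    )


# ---------------------------------------------------------------------------
# distances


def ks_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Sup-norm distance between the empirical CDFs of two samples."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    allv = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, allv, side="right") / len(a)
    cdf_b = np.searchsorted(b, allv, side="right") / len(b)
    return float(np.max(np.abs(cdf_a - cdf_b)))


# ---------------------------------------------------------------------------
# model-specific fits


DEFAULT_INITIATION_PRIORS: dict[str, Prior] = {
    "mu1": Prior("loguniform", 1e-8, 1e-4),
    "mu2": Prior("loguniform", 1e-8, 1e-4),
}


def fit_initiation(
    m_mrca: Sequence[float],
    m_eca: Sequence[float],
    config: ABCConfig,
    base_params: init_mod.InitiationParams | None = None,
    priors: Mapping[str, Prior] | None = None,
    n_sim: int | None = None,
) -> PosteriorSample:
    """Fit the initiation model to cohort ECA/MRCA density distributions.

    Free parameters (given by ``priors``, default the two driver
    probabilities) replace fields of ``base_params``. The distance is the
    mean of the sup-norm ECDF distances of model-simulated vs observed
    MRCA densities and ECA densities; with no observed ECA densities the
    MRCA term alone is used and the result is flagged.
    """
    m_mrca = np.asarray(m_mrca, dtype=float)
    m_eca = np.asarray(m_eca, dtype=float)
    if len(m_mrca) < 10:
        raise ValueError("need >= 10 tumours with MRCA densities")
    base = base_params or init_mod.InitiationParams()
    priors = dict(priors or DEFAULT_INITIATION_PRIORS)
    n_sim = n_sim or max(100, len(m_mrca))
    eca_empty = len(m_eca) == 0
    sim_rng = np.random.default_rng(config.seed + 1)

    def simulator(free: Mapping[str, float]):
        params = base.with_(**free)
        # local generator reseeded per call for determinism of the fit
        local = np.random.default_rng(sim_rng.integers(2**31))
        t1, t2 = init_mod.sample_event_times(params, n_sim, local)
        per_bp = params.mu / 3.3e9
        dens2 = per_bp * np.asarray(init_mod.divisions_by(t2, params))
        dens1 = per_bp * np.asarray(init_mod.divisions_by(t1, params))
        return dens1, dens2

    def distance(sim) -> float:
        dens1, dens2 = sim
        d2 = ks_distance(dens2, m_mrca)
        if eca_empty:
            return d2
        d1 = ks_distance(dens1, m_eca)
        return 0.5 * (d1 + d2)

    post = abc_smc(simulator, distance, priors, config)
    post.flags["eca_empty"] = eca_empty
    return post


DEFAULT_GROWTH_PRIORS: dict[str, Prior] = {
    "mu": Prior("loguniform", 0.1, 1000.0),
    "ratio": Prior("uniform", 0.0, 0.999),
}

MIN_SUBCLONAL_VARIANTS = 30


@dataclass
class VAFHistogram:
    """Cumulative pseudo-heterozygous VAF histogram of one tumour.

    ``a_grid`` are cell-count thresholds and ``m_obs[i]`` the number of
    subclonal variants carried by at least ``a_grid[i]`` cells.
    """

    a_grid: np.ndarray
    m_obs: np.ndarray
    n_cells: float            # final tumour size N_T(t_end)
    k: int = 2                # copy number of the contributing regions

    @classmethod
    def from_pseudo_vafs(
        cls,
        pseudo_vafs: np.ndarray,
        n_cells: float,
        vaf_low: float = 0.05,
        vaf_high: float = 0.45,
        n_bins: int = 20,
        k: int = 2,
    ) -> "VAFHistogram":
        """Bin subclonal pseudo-VAFs into a cumulative cell-count histogram.

        A pseudo-heterozygous VAF v corresponds to 2 v N_T carrier cells.
        The fit window [vaf_low, vaf_high] reflects typical WGS
        sensitivity below and the clonal boundary above.
        """
        v = np.asarray(pseudo_vafs, dtype=float)
        v = v[(v >= vaf_low) & (v <= vaf_high)]
        grid_v = np.linspace(vaf_low, vaf_high, n_bins)
        a_grid = 2.0 * grid_v * n_cells
        m_obs = np.array([(v >= gv).sum() for gv in grid_v], dtype=float)
        return cls(a_grid=a_grid, m_obs=m_obs, n_cells=n_cells, k=k)


def fit_growth(
    hist: VAFHistogram,
    config: ABCConfig,
    priors: Mapping[str, Prior] | None = None,
    simulator: str = "expectation",
    tree_cells: int = 300,
) -> PosteriorSample:
    """Fit (mu, delta_T/lambda_T) to a cumulative VAF histogram.

    The distance is the RMS difference between observed and simulated
    cumulative histograms, both divided by the observed value at the
    lower cutoff so that scale (mu) and shape (delta/lambda) both
    contribute.

    ``simulator`` selects what the model generates per parameter set:

    * ``"expectation"`` — the deterministic birth-death expectation
      M_k(a) at the tumour's final size (fast; posterior width is then
      governed by the ABC tolerance alone);
    * ``"tree"`` — a Gillespie tumour of ``tree_cells`` cells binned into
      the same fractional-VAF histogram. Subclonal window counts are
      nearly independent of tumour size, so a small tree reproduces the
      genealogical fluctuations of the data and the posterior carries
      the model's real sampling variability — required for calibrated
      credible intervals when the observed tumour is itself stochastic.
    """
    priors = dict(priors or DEFAULT_GROWTH_PRIORS)
    if hist.m_obs[0] < MIN_SUBCLONAL_VARIANTS:
        raise ValueError(
            f"only {hist.m_obs[0]:.0f} subclonal variants in the fit window "
            f"(need >= {MIN_SUBCLONAL_VARIANTS})"
        )
    norm = float(hist.m_obs[0])
    obs = hist.m_obs / norm
    b_upper = hist.n_cells

    if simulator == "expectation":
        def run(free: Mapping[str, float]):
            params = growth_mod.GrowthParams.for_final_size(
                n_end=hist.n_cells, ratio=free["ratio"], mu=free["mu"]
            )
            return growth_mod.cumulative_histogram_grid(
                hist.a_grid, b_upper, params.mu, hist.k, params
            )
    elif simulator == "tree":
        from .simulate import simulate_growth_tree

        # fractional thresholds of the observed grid, reused on the tree
        frac_grid = hist.a_grid / hist.n_cells
        seed_rng = np.random.default_rng(config.seed + 99_991)

        def run(free: Mapping[str, float]):
            params = growth_mod.GrowthParams(
                lam=1.0, delta=free["ratio"], mu=free["mu"] / hist.k, t_end=0.0
            )
            try:
                carriers, n_new = simulate_growth_tree(
                    params, tree_cells, seed=int(seed_rng.integers(2**31 - 1)),
                    max_tries=25, max_events=30_000,
                )
            except RuntimeError:
                return None   # proposal cannot grow a tumour of this size
            frac = carriers / tree_cells
            return np.array(
                [n_new[frac >= f].sum() for f in frac_grid], dtype=float
            ) * hist.k
    else:
        raise ValueError(f"unknown simulator {simulator!r}")

    def distance(sim: np.ndarray | None) -> float:
        if sim is None:
            return float("inf")
        return float(np.sqrt(np.mean((sim / norm - obs) ** 2)))

    return abc_smc(run, distance, priors, config)
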