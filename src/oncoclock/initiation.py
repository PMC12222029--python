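"""Two-driver model of tumour initiation in a transient progenitor pool.

The tissue of origin is modelled as a population that expands
exponentially at rate lambda1 - delta1 (division rate lambda1,
differentiation rate delta1) until time T and then declines at
lambda2 - delta2 < 0. Two consecutive drivers arise with probabilities
mu1 and mu2 per division and act by reducing differentiation by factors
r and s; the first spawns the pre-malignant clone (its origin is the
ECA), the second the malignant clone (the MRCA). The closed-form
probability that the MRCA has occurred by time t splits into a phase-I
term (both drivers during expansion) and two decline-phase terms for
second drivers arising in clones founded before or after T.

The phase-I integral factor F averages, over first-driver birth times,
the survival probability of a second-driver lineage. Its adopted form is
the finite-time birth-death survival probability

    F = int_0^1 nu2E / (1 - (1 - nu2E) z^alpha) dz,

with nu2E = 1 - delta1/(s lambda1) and alpha = (delta1 - s lambda1) /
(delta1 - lambda1); it tends to 1 as z -> 1 (lineages born at the end of
phase I always "survive" to T) and to nu2E as z -> 0. A simpler variant
that drops the (1 - nu2E) z^alpha term, F = 1/(1 - alpha), is available
via ``f_form="printed"`` but diverges for alpha >= 1 and is kept only
for comparison.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad

logger = logging.getLogger(__name__)

CLAMP_WARN_TOL = 1e-9


@dataclass(frozen=True)
class InitiationParams:
    """Rates and selection coefficients of the two-driver model.

    All rates are per day. ``mu`` is the neutral SNV yield per haploid
    genome per division, used to convert event times to densities.
    """

    mu1: float = 3e-6       # first-driver probability per division
    mu2: float = 3e-6       # second-driver probability per division
    r: float = 3.0          # selection of the first driver (differentiation / r)
    s: float = 10.0         # selection of the second driver (differentiation / s)
    mu: float = 3.3         # neutral SNVs per haploid genome per division
    lam1: float = 0.13      # division rate, expansion phase
    delta1: float = 0.10    # differentiation rate, expansion phase
    lam2: float = 0.10      # division rate, decline phase
    delta2: float = 0.12    # differentiation rate, decline phase
    T: float = 266.0        # switch time expansion -> decline (days)
    N0: float = 1.0         # initial progenitor count

    def validate(self) -> None:
        for name in ("mu1", "mu2", "r", "s", "mu", "lam1", "delta1",
                     "lam2", "delta2", "T", "N0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lam1 <= self.delta1:
            raise ValueError("expansion phase requires lambda1 > delta1")
        if self.lam2 >= self.delta2:
            raise ValueError("decline phase requires lambda2 < delta2")
        if not self.mu1 < 1 or not self.mu2 < 1:
            raise ValueError("driver probabilities must be < 1")

    @property
    def nu2_decline(self) -> float:
        """Survival probability of a second-driver cell during decline."""
        return 1.0 - self.delta2 / (self.s * self.lam2)

    @property
    def nu2_expansion(self) -> float:
        """Survival probability of a second-driver cell during expansion."""
        return 1.0 - self.delta1 / (self.s * self.lam1)

    @property
    def alpha(self) -> float:
        return (self.delta1 - self.s * self.lam1) / (self.delta1 - self.lam1)

    def with_(self, **kw) -> "InitiationParams":
        return replace(self, **kw)


def population_size(t: float | np.ndarray, params: InitiationParams) -> float | np.ndarray:
    """Deterministic progenitor population size N(t)."""
    p = params
    t = np.asarray(t, dtype=float)
    n_t = np.where(
        t < p.T,
        p.N0 * np.exp((p.lam1 - p.delta1) * t),
        p.N0 * np.exp((p.lam1 - p.delta1) * p.T)
        * np.exp((p.lam2 - p.delta2) * (np.maximum(t, p.T) - p.T)),
    )
    return float(n_t) if n_t.ndim == 0 else n_t


def f_integral(params: InitiationParams, form: str = "survival") -> float:
    """Phase-I integral factor F over first-driver birth times."""
    p = params
    nu = p.nu2_expansion
    alpha = p.alpha
    if form == "printed":
        if alpha >= 1.0:
            raise ValueError(
                "printed F = 1/(1 - alpha) diverges for alpha >= 1 "
                f"(alpha = {alpha:.3f}); use form='survival'"
            )
        return 1.0 / (1.0 - alpha)
    if form != "survival":
        raise ValueError(f"unknown F form {form!r}")
    if nu <= 0.0:
        return 0.0
    if nu >= 1.0:
        return 1.0
    val, _ = quad(lambda z: nu / (1.0 - (1.0 - nu) * z**alpha), 0.0, 1.0)
    return float(val)


def _neg_exp1m(x: float) -> float:
    """1 - exp(-x), computed stably; clamps negative x at 0 growth."""
    return float(-math.expm1(-x))


def _p_phase1(t: float, params: InitiationParams, f_form: str) -> float:
    p = params
    n_t = float(population_size(min(t, p.T), p))
    first = _neg_exp1m(p.mu1 * (n_t - p.N0))
    F = f_integral(p, form=f_form)
    rate = p.mu1 * p.mu2 * p.lam1 * p.T * n_t * F / (1.0 - p.delta1 / p.lam1)
    second = _neg_exp1m(rate)
    return first * second


def _p_phase2(t: float, params: InitiationParams) -> float:
    """Second driver in a pre-T first clone, arising during decline."""
    p = params
    if t <= p.T:
        return 0.0
    n_T = float(population_size(p.T, p))
    g = p.lam2 - p.delta2 / p.r
    dt = t - p.T
    if abs(g) < 1e-12:
        growth = dt
    else:
        growth = (math.exp(g * dt) - 1.0) / g
    rate = p.mu1 * p.mu2 * p.lam1 * p.lam2 * p.nu2_decline * p.T * n_T * growth
    return _neg_exp1m(rate)


def _p_phase3(t: float, params: InitiationParams) -> float:
    """Both drivers during the decline phase."""
    p = params
    if t <= p.T:
        return 0.0
    n_T = float(population_size(p.T, p))
    dt = t - p.T
    g1 = p.lam2 - p.delta2
    g2 = p.lam2 - p.delta2 / p.r

    def _expr(g: float) -> float:
        if abs(g) < 1e-12:
            return dt
        return (math.exp(g * dt) - 1.0) / g

    brace = _expr(g1) - _expr(g2)
    coeff = (
        p.mu1 * p.mu2 * p.lam2**2 * p.nu2_decline * n_T
        / (p.delta2 * (1.0 / p.r - 1.0))
    )
    return _neg_exp1m(coeff * brace)


def _bd_alpha_beta(lam: float, delta: float, tau: float) -> tuple[float, float]:
    """Extinction probability and geometric parameter of a linear
    birth-death process after time tau."""
    if tau <= 0:
        return 0.0, 0.0
    g = lam - delta
    if abs(g) < 1e-12:
        x = lam * tau / (1.0 + lam * tau)
        return x, x
    egt = math.exp(g * tau)
    denom = lam * egt - delta
    return delta * (egt - 1.0) / denom, lam * (egt - 1.0) / denom


def _nu2_survival(v: np.ndarray, params: InitiationParams, t_horizon: float) -> np.ndarray:
    """Probability that a second-driver cell born at time v still has
    living descendants at the horizon (selection s reduces its
    differentiation rate; phases compose through the extinction law)."""
    p = params
    out = np.empty(len(v))
    # extinction by the horizon for a malignant cell in the decline phase
    for i, vi in enumerate(v):
        if vi >= p.T:
            a, _ = _bd_alpha_beta(p.lam2, p.delta2 / p.s, t_horizon - vi)
            out[i] = 1.0 - a
        else:
            q_star, _ = _bd_alpha_beta(p.lam2, p.delta2 / p.s, t_horizon - p.T)
            a1, b1 = _bd_alpha_beta(p.lam1, p.delta1 / p.s, p.T - vi)
            q = a1 + (1.0 - a1) * (1.0 - b1) * q_star / (1.0 - b1 * q_star)
            out[i] = 1.0 - q
    return np.clip(out, 0.0, 1.0)


def _branching_hazard(
    t: float, params: InitiationParams, t_horizon: float, n_steps: int = 1200
) -> float:
    """Expected number of first-driver clones founded by t whose lineage
    produces at least one malignant clone surviving to the horizon, per
    unit founder martingale W.

    The per-clone success probability w(u) = 1 - h(u) follows the
    backward equation of the type-1 branching process (division rate
    lambda, differentiation delta/r, second drivers at divisions with
    probability mu2 and survival nu2):

        -dh/dv = lam (1-mu2) h^2 + lam mu2 (1-nu2(v)) h
                 + delta/r - (lam + delta/r) h,   h(t) = 1.
    """
    p = params
    if t <= 0:
        return 0.0
    # backward grid from t to 0 with the phase switch as a grid point
    grid = np.linspace(0.0, t, n_steps + 1)
    if 0.0 < p.T < t:
        grid = np.unique(np.concatenate([grid, [p.T]]))
    nu2 = _nu2_survival(grid, p, t_horizon)
    h = np.empty(len(grid))
    h[-1] = 1.0

    def rhs(v_idx_lam_delta, h_val, nu2_val):
        lam, delta_r = v_idx_lam_delta
        return -(
            lam * (1.0 - p.mu2) * h_val**2
            + lam * p.mu2 * (1.0 - nu2_val) * h_val
            + delta_r
            - (lam + delta_r) * h_val
        )

    for i in range(len(grid) - 1, 0, -1):
        v1, v0 = grid[i], grid[i - 1]
        dv = v1 - v0
        mid_v = 0.5 * (v0 + v1)
        lam, delta = (p.lam1, p.delta1) if mid_v < p.T else (p.lam2, p.delta2)
        coeff = (lam, delta / p.r)
        nu_mid = 0.5 * (nu2[i] + nu2[i - 1])
        # RK4 backward step
        k1 = rhs(coeff, h[i], nu2[i])
        k2 = rhs(coeff, h[i] - 0.5 * dv * k1, nu_mid)
        k3 = rhs(coeff, h[i] - 0.5 * dv * k2, nu_mid)
        k4 = rhs(coeff, h[i] - dv * k3, nu2[i - 1])
        h[i - 1] = h[i] - dv * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
    h = np.clip(h, 0.0, 1.0)
    lam_u = np.where(grid < p.T, p.lam1, p.lam2)
    n_u = np.asarray(population_size(grid, p)) / p.N0
    integrand = p.mu1 * lam_u * n_u * (1.0 - h)
    return float(np.trapezoid(integrand, grid)) * p.N0


def p_mrca(
    t: float,
    params: InitiationParams,
    method: str = "branching",
    f_form: str = "survival",
    t_horizon: float | None = None,
    n_steps: int = 1200,
) -> float:
    """Probability that the MRCA (first malignant clone surviving to the
    population horizon) has occurred by time t.

    ``method="branching"`` (default) evaluates the Poisson hazard of
    successful first-driver clones with an exact per-clone success
    probability from the type-1 branching process, and integrates out
    the founder-population fluctuations (N(t) ~ W e^{gamma t} with W a
    point mass at zero of weight delta1/lambda1 plus an exponential):
    P = 1 - [q + (1-q)/(1 + hazard/(1-q))] with q = delta1/lambda1.
    It agrees with exact Gillespie simulation within Monte-Carlo error.

    ``method="closed_form"`` evaluates the factorised expression
    (phase-I product frozen at T, combined with the two decline-phase
    terms as 1 - (1-P_I)(1-P_II)(1-P_III)), with the phase-I integral
    factor selected by ``f_form``; it is retained for comparison and is
    accurate only in order of magnitude.
    """
    params.validate()
    if t < 0:
        raise ValueError("t must be >= 0")
    if params.mu1 == 0.0 or params.mu2 == 0.0:
        return 0.0
    if method == "branching":
        horizon = t_horizon if t_horizon is not None else mrca_time_horizon(params)
        lam_bar = _branching_hazard(min(t, horizon), params, horizon, n_steps=n_steps)
        q = params.delta1 / params.lam1
        val = 1.0 - (q + (1.0 - q) / (1.0 + lam_bar / (1.0 - q)))
    elif method == "closed_form":
        if t < params.T:
            val = _p_phase1(t, params, f_form)
        else:
            p1 = _p_phase1(params.T, params, f_form)
            p2 = _p_phase2(t, params)
            p3 = _p_phase3(t, params)
            val = 1.0 - (1.0 - p1) * (1.0 - p2) * (1.0 - p3)
    else:
        raise ValueError(f"unknown method {method!r}")
    if val < -CLAMP_WARN_TOL or val > 1.0 + CLAMP_WARN_TOL:
        logger.warning("p_mrca clamped from %.3e", val)
    return min(1.0, max(0.0, val))


def p_mrca_curve(
    t_grid: np.ndarray,
    params: InitiationParams,
    t_horizon: float | None = None,
    n_steps: int = 1200,
) -> np.ndarray:
    """Branching-method P_MRCA at many times in one backward sweep.

    All target times share the master grid; each target's per-clone
    success probability h activates at its own cutoff (h = 1 for
    v >= t_j, so later times contribute nothing to that target's
    hazard), which lets the backward RK4 step carry one state vector.
    """
    params.validate()
    p = params
    horizon = t_horizon if t_horizon is not None else mrca_time_horizon(p)
    t_grid = np.minimum(np.asarray(t_grid, dtype=float), horizon)
    if np.any(t_grid < 0):
        raise ValueError("t must be >= 0")
    if p.mu1 == 0.0 or p.mu2 == 0.0:
        return np.zeros(len(t_grid))
    t_top = float(t_grid.max())
    master = np.linspace(0.0, t_top, n_steps + 1)
    extra = [t_grid]
    if 0.0 < p.T < t_top:
        extra.append(np.array([p.T]))
    master = np.unique(np.concatenate([master] + extra))
    nu2 = _nu2_survival(master, p, horizon)
    nm, nt = len(master), len(t_grid)
    H = np.ones((nt, nm))

    def deriv(lam, delta_r, h, nu2_val):
        return -(
            lam * (1.0 - p.mu2) * h**2
            + lam * p.mu2 * (1.0 - nu2_val) * h
            + delta_r
            - (lam + delta_r) * h
        )

    state = np.ones(nt)
    for i in range(nm - 1, 0, -1):
        v1, v0 = master[i], master[i - 1]
        dv = v1 - v0
        active = t_grid >= v1
        mid_v = 0.5 * (v0 + v1)
        lam, delta = (p.lam1, p.delta1) if mid_v < p.T else (p.lam2, p.delta2)
        dr = delta / p.r
        nu_mid = 0.5 * (nu2[i] + nu2[i - 1])
        k1 = deriv(lam, dr, state, nu2[i])
        k2 = deriv(lam, dr, state - 0.5 * dv * k1, nu_mid)
        k3 = deriv(lam, dr, state - 0.5 * dv * k2, nu_mid)
        k4 = deriv(lam, dr, state - dv * k3, nu2[i - 1])
        stepped = state - dv * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        state = np.where(active, stepped, 1.0)
        H[:, i - 1] = np.clip(state, 0.0, 1.0)
    lam_u = np.where(master < p.T, p.lam1, p.lam2)
    n_u = np.asarray(population_size(master, p))
    hazards = np.trapezoid(p.mu1 * lam_u * n_u * (1.0 - H), master, axis=1)
    q = p.delta1 / p.lam1
    vals = 1.0 - (q + (1.0 - q) / (1.0 + hazards / (1.0 - q)))
    return np.clip(vals, 0.0, 1.0)


def p_eca_given_mrca(t1: float, t2: float, params: InitiationParams) -> float:
    """Cumulative conditional probability that the ECA occurred by t1,
    given the MRCA occurred at t2.

    For t2 <= T the first-driver time is uniform on (0, t2); for
    t2 > T the decline-phase expression applies, continuous at t1 = T.
    """
    params.validate()
    if not 0.0 <= t1 < t2:
        raise ValueError(f"require 0 <= t1 < t2, got t1={t1}, t2={t2}")
    p = params
    if t2 <= p.T:
        return t1 / t2
    c = p.delta2 * (1.0 - 1.0 / p.r)
    denom = p.lam2 + p.lam1 * p.T * c - p.lam2 * math.exp(c * (p.T - t2))
    if t1 < p.T:
        num = p.lam1 * c * t1
    else:
        num = p.lam2 + p.lam1 * p.T * c - p.lam2 * math.exp(c * (p.T - t1))
    if denom <= 0:
        raise ValueError("degenerate conditional normalisation (check r > 1)")
    return min(1.0, max(0.0, num / denom))


# ---------------------------------------------------------------------------
# sampling helpers (used by the ABC fit and the synthetic cohort)


def mrca_time_horizon(params: InitiationParams, floor: float = 0.5) -> float:
    """Time at which the declining population drops below ``floor`` cells;
    MRCA probability is essentially saturated beyond it."""
    p = params
    n_T = float(population_size(p.T, p))
    if n_T <= floor:
        return p.T
    return p.T + math.log(n_T / floor) / (p.delta2 - p.lam2)


def divisions_by(t: float | np.ndarray, params: InitiationParams) -> float | np.ndarray:
    """Expected divisions experienced by a lineage up to time t."""
    p = params
    t = np.asarray(t, dtype=float)
    d = np.where(
        t < p.T,
        p.lam1 * t,
        p.lam1 * p.T + p.lam2 * (np.maximum(t, p.T) - p.T),
    )
    return float(d) if d.ndim == 0 else d


def _eca_conditional_cdf(
    t1: np.ndarray, t2: float, params: InitiationParams
) -> np.ndarray:
    """Vectorised P(ECA <= t1 | MRCA at t2)."""
    p = params
    t1 = np.asarray(t1, dtype=float)
    if t2 <= p.T:
        return t1 / t2
    c = p.delta2 * (1.0 - 1.0 / p.r)
    denom = p.lam2 + p.lam1 * p.T * c - p.lam2 * math.exp(c * (p.T - t2))
    num = np.where(
        t1 < p.T,
        p.lam1 * c * t1,
        p.lam2 + p.lam1 * p.T * c - p.lam2 * np.exp(c * (p.T - t1)),
    )
    return np.clip(num / denom, 0.0, 1.0)


def sample_event_times(
    params: InitiationParams,
    n: int,
    rng: np.random.Generator,
    n_grid: int = 96,
    n_steps: int = 240,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (t_ECA, t_MRCA) pairs from the model by inverse transform.

    MRCA times are drawn from the normalised P_MRCA CDF on a time grid
    up to the population horizon (conditioning on tumour formation);
    ECA times from the conditional CDF P(t1 | t2).
    """
    t_max = mrca_time_horizon(params)
    grid = np.linspace(1e-6, t_max, n_grid)
    cdf = p_mrca_curve(grid, params, t_horizon=t_max, n_steps=n_steps)
    total = cdf[-1]
    if total <= 0:
        raise ValueError("model assigns zero probability to tumour formation")
    cdf = cdf / total
    u = rng.random(n)
    t2 = np.interp(u, cdf, grid)
    t1 = np.empty(n)
    sub_frac = np.linspace(0.0, 1.0 - 1e-9, 64)
    for i, t2_i in enumerate(t2):
        sub = sub_frac * t2_i
        ccdf = _eca_conditional_cdf(sub, t2_i, params)
        ccdf[-1] = 1.0
        t1[i] = np.interp(rng.random(), ccdf, sub)
    return t1, t2
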