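"""Neutral site-frequency spectrum of an exponentially growing tumour.

Tumour growth from the MRCA is a supercritical linear birth-death
process with division rate lambda_T and loss rate delta_T < lambda_T.
Neutral mutations accrue at rate mu k lambda_T N_T(t) in regions of copy
number k; a mutation arising at time t is carried by i cells at t_end
with the classical birth-death clone-size law, so the expected spectrum
is S_k(i) = int_0^t_end P_1i(t_end - t) mu k lambda_T N_T(t) dt and the
cumulative histogram M_k(a) sums S_k over i in [a, b] (evaluated with
the geometric tail in closed form inside a single time integral).

The key dimensionless quantity is delta_T / lambda_T: the larger the
loss/division ratio, the heavier the subclonal tail per clonal mutation,
summarised by the effective rate mu_eff = mu / (1 - delta_T/lambda_T).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad


@dataclass(frozen=True)
class GrowthParams:
    """Birth-death growth parameters (rates per day)."""

    lam: float = 1.0          # division rate lambda_T
    delta: float = 0.2        # loss rate delta_T
    mu: float = 3.3           # neutral SNVs per haploid genome per division
    t_end: float = 25.0       # growth duration (days, in units of 1/lam if lam=1)

    def validate(self) -> None:
        if not 0.0 <= self.delta < self.lam:
            raise ValueError("require 0 <= delta_T < lambda_T")
        if self.mu < 0 or self.t_end < 0:
            raise ValueError("mu and t_end must be >= 0")

    @property
    def ratio(self) -> float:
        return self.delta / self.lam

    @property
    def mu_eff(self) -> float:
        """Effective mutation rate mu / (1 - delta_T/lambda_T)."""
        return self.mu / (1.0 - self.ratio)

    def n_t(self, t: float | np.ndarray) -> float | np.ndarray:
        """Deterministic population size exp((lambda - delta) t)."""
        return np.exp((self.lam - self.delta) * np.asarray(t, dtype=float))

    @classmethod
    def for_final_size(cls, n_end: float, ratio: float, mu: float,
                       lam: float = 1.0) -> "GrowthParams":
        """Parametrise by final size and loss/division ratio (lam = 1)."""
        delta = ratio * lam
        t_end = math.log(n_end) / (lam - delta)
        return cls(lam=lam, delta=delta, mu=mu, t_end=t_end)


def _alpha_beta(lam: float, delta: float, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extinction probability alpha_t and geometric parameter beta_t."""
    t = np.asarray(t, dtype=float)
    g = lam - delta
    egt = np.exp(g * t)
    denom = lam * egt - delta
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(t > 0, delta * (egt - 1.0) / denom, 0.0)
        beta = np.where(t > 0, lam * (egt - 1.0) / denom, 0.0)
    return alpha, beta


def beta_t(lam: float, delta: float, t: float | np.ndarray) -> float | np.ndarray:
    """beta(t) = lambda (e^{(lambda-delta) t} - 1) / (lambda e^{(lambda-delta) t} - delta)."""
    _, beta = _alpha_beta(lam, delta, np.asarray(t, dtype=float))
    return float(beta) if beta.ndim == 0 else beta


def clone_size_prob(
    i: int | np.ndarray, lam: float, delta: float, dt: float
) -> float | np.ndarray:
    """P(clone size = i at time dt | one founder): linear birth-death law.

    P(0) = alpha_t and P(i >= 1) = (1 - alpha_t)(1 - beta_t) beta_t^(i-1);
    for delta = 0 this reduces to the pure-birth geometric
    e^{-lam dt} (1 - e^{-lam dt})^(i-1).
    """
    if lam <= 0 or delta < 0 or lam <= delta:
        raise ValueError("require lambda_T > delta_T >= 0")
    if dt < 0:
        raise ValueError("dt must be >= 0")
    i = np.asarray(i)
    alpha, beta = _alpha_beta(lam, delta, np.asarray(dt, dtype=float))
    if dt == 0:
        out = np.where(i == 1, 1.0, 0.0)
    else:
        with np.errstate(invalid="ignore"):
            tail = (1.0 - alpha) * (1.0 - beta) * beta ** np.maximum(i - 1, 0)
        out = np.where(i == 0, alpha, np.where(i >= 1, tail, 0.0))
    return float(out) if out.ndim == 0 else out


def sfs(i: int, mu: float, k: int, params: GrowthParams,
        rtol: float = 1e-6) -> float:
    """Expected number of neutral mutations carried by exactly i cells."""
    params.validate()
    if mu == 0.0:
        return 0.0
    lam, delta, t_end = params.lam, params.delta, params.t_end

    def integrand(t: float) -> float:
        p = clone_size_prob(i, lam, delta, t_end - t)
        return p * mu * k * lam * float(params.n_t(t))

    val, err = quad(integrand, 0.0, t_end, epsrel=rtol, limit=200)
    if not np.isfinite(val) or (val > 0 and err > 10 * rtol * val + 1e-12):
        raise RuntimeError(
            f"sfs quadrature did not converge (value {val:.3e}, err {err:.3e})"
        )
    return float(val)


def cumulative_histogram(
    a: float, b: float, mu: float, k: int, params: GrowthParams
) -> float:
    """Expected number of mutations in at least a and fewer than b cells.

    Evaluates the closed geometric tail inside a single time integral,
    (P_1b - P_1a) / log beta per founding time, with midpoint-corrected
    bounds so the continuous-i integral tracks the discrete sum over
    [a, b); a = b is the empty range.
    """
    params.validate()
    if a > b:
        raise ValueError("require a <= b")
    if a == b or mu == 0.0:
        return 0.0
    grid, w = _gauss_grid(params.t_end, n=800)
    vals = _histogram_integrand(grid, a, b, mu, k, params)
    return float(np.sum(w * vals))


def _gauss_grid(t_end: float, n: int = 800) -> tuple[np.ndarray, np.ndarray]:
    # composite midpoint rule; the integrand is smooth and -> 0 at t_end
    edges = np.linspace(0.0, t_end, n + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    w = np.diff(edges)
    return mid, w


def _histogram_integrand(
    t: np.ndarray, a: float, b: float, mu: float, k: int, params: GrowthParams
) -> np.ndarray:
    lam, delta = params.lam, params.delta
    tau = params.t_end - t
    alpha, beta = _alpha_beta(lam, delta, tau)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_beta = np.log(beta)
        # half-integer offsets: the continuous-i integral approximates the
        # discrete sum over i in [a, b) best at midpoint bounds a-1/2, b-1/2
        p_a = (1.0 - alpha) * (1.0 - beta) * beta ** (a - 1.5)
        p_b = (1.0 - alpha) * (1.0 - beta) * beta ** (b - 1.5)
        vals = mu * k * lam * params.n_t(t) * (p_b - p_a) / log_beta
    return np.where(np.isfinite(vals), vals, 0.0)


def cumulative_histogram_grid(
    a_grid: np.ndarray, b: float, mu: float, k: int, params: GrowthParams,
    n_t: int = 400,
) -> np.ndarray:
    """Vectorised M_k(a) over a grid of lower thresholds (for fitting)."""
    params.validate()
    t, w = _gauss_grid(params.t_end, n=n_t)
    out = np.empty(len(a_grid))
    for j, a in enumerate(a_grid):
        if a >= b:
            out[j] = 0.0
        else:
            out[j] = float(np.sum(w * _histogram_integrand(t, a, b, mu, k, params)))
    return out


def pseudo_vaf(vaf: float | np.ndarray, zeta: float, k_mut: int) -> float | np.ndarray:
    """Rescale a VAF to its pseudo-heterozygous value zeta/(2 k) VAF.

    Puts subclonal tails from different copy-number states on the common
    diploid-heterozygous scale (clonal one-copy mutations map to 0.5 at
    purity 1).
    """
    if zeta <= 0:
        raise ValueError("zeta must be > 0")
    if k_mut < 1:
        raise ValueError("k_mut must be >= 1")
    return zeta / (2.0 * k_mut) * np.asarray(vaf) if np.ndim(vaf) else \
        zeta / (2.0 * k_mut) * vaf
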