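"""Real-time calibration: molecular time to calendar time.

The progenitor division rate of each tumour follows from equating the
mutational burden with the number of divisions available between
gastrulation and diagnosis: m_MRCA/mu divisions to reach the MRCA, plus
log(N_T)/mu * mu_eff divisions of the founding lineage during tumour
growth to the diagnostic size N_T = 1e9 cells, all within
t_D = age at diagnosis + 250 days of embryogenesis after gastrulation:

    lambda = (m_MRCA/mu + log(1e9) mu_eff/mu) / t_D.

Units: m_MRCA (SNV burden) and the rates mu and mu_eff are all per
haploid genome. Uncertainties propagate first order through the printed
expressions. Multiplying by mu gives the per-day SNV rate mu*lambda that
anchors the weeks-post-conception conversion of densities.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

EMBRYOGENESIS_DAYS = 250.0
DIAGNOSTIC_CELLS = 1e9


@dataclass
class DivisionRateEstimate:
    lam: float          # divisions per day
    sd: float
    t_d: float          # days from gastrulation to diagnosis


def division_rate(
    m_mrca: float,
    mu: float,
    mu_eff: float,
    age_days: float,
    sigma_m: float = 0.0,
    sigma_mu: float = 0.0,
    sigma_mu_eff: float = 0.0,
    n_tumour_cells: float = DIAGNOSTIC_CELLS,
    embryogenesis_days: float = EMBRYOGENESIS_DAYS,
) -> DivisionRateEstimate:
    """Per-tumour progenitor division rate with propagated uncertainty.

    ``m_mrca`` is the clonal SNV burden per haploid genome (density per
    bp times 3.3e9), ``mu`` and ``mu_eff`` the per-division rates per
    haploid genome from the initiation and growth fits.
    """
    if min(m_mrca, mu, mu_eff) < 0 or mu == 0:
        raise ValueError("m_mrca, mu, mu_eff must be >= 0 with mu > 0")
    if age_days is None:
        raise ValueError("age at diagnosis required for calibration")
    t_d = age_days + embryogenesis_days
    log_n = math.log(n_tumour_cells)
    lam = (m_mrca / mu + log_n * mu_eff / mu) / t_d
    # first-order propagation; each input's sensitivity is the partial
    # derivative of lambda (log N multiplies mu_eff in the mean, so it
    # multiplies sigma(mu_eff) here as well)
    sd = (
        ((m_mrca + log_n * mu_eff) / mu) * sigma_mu
        + sigma_m
        + log_n * sigma_mu_eff
    ) / (mu * t_d)
    return DivisionRateEstimate(lam=lam, sd=sd, t_d=t_d)


@dataclass
class CohortCalibration:
    mu_lambda_per_day: float        # cohort SNVs per haploid genome per day
    sd: float
    per_tumour: list[tuple[float, float]]   # (mu*lambda_i, sigma_i)


def cohort_mutation_rate_per_day(
    rates: Sequence[DivisionRateEstimate],
    mu: float,
    sigma_mu: float = 0.0,
) -> CohortCalibration:
    """Average mu*lambda across calibrated tumours.

    Per-tumour uncertainty is mu * sd(lambda) + lambda * sd(mu); the
    cohort value is the plain mean and its uncertainty the mean of the
    per-tumour uncertainties (tumour estimates share the fitted mu, so
    averaging, not pooling, is the conservative choice).
    """
    if not rates:
        raise ValueError("need at least one calibrated tumour")
    per = [(mu * r.lam, mu * r.sd + r.lam * sigma_mu) for r in rates]
    mean = sum(v for v, _ in per) / len(per)
    sd = sum(s for _, s in per) / len(per)
    return CohortCalibration(mu_lambda_per_day=mean, sd=sd, per_tumour=per)
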