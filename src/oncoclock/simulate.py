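"""Ground-truthed synthetic tumours and cohorts.

Three layers:

* ``simulate_lineage`` — exact event-driven (Gillespie) realisation of
  the two-driver initiation model: a transient progenitor population
  expands then declines; drivers arise at divisions and act by reduced
  differentiation. Returns ECA/MRCA times of the first malignant clone
  that survives, or extinction. Serves as the stochastic oracle for the
  closed-form MRCA-time law.
* ``simulate_growth_tree`` — Gillespie birth-death growth of a tumour
  from one cell with neutral mutation accumulation at divisions; yields
  the exact site-frequency spectrum of the final population, the oracle
  for the deterministic spectrum integrals and the input for growth-fit
  recovery tests.
* ``simulate_tumor_reads`` / ``simulate_cohort`` — read-level synthetic
  tumours: clonal mutations placed Poisson at chosen ECA/MRCA densities
  on the amplified and unamplified allele copies of each segment, a
  neutral subclonal tail drawn from the birth-death spectrum, binomial
  read sampling at Poisson-distributed depth, packaged in the package's
  own tabular formats together with the ground truth.

Defaults emulate the study conditions: purity 0.8, 100x coverage,
22-autosome genomes with 10-200 Mb segments, clonal densities of order
0.03-0.2 SNVs/Mb.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .growth import GrowthParams
from .initiation import InitiationParams, mrca_time_horizon, divisions_by, sample_event_times
from .io import CNSegment, SampleMeta, TumourSample, VariantObservation
from .timing import expected_vaf_peaks

_MAX_CLONES = 4096


# ---------------------------------------------------------------------------
# initiation-model Gillespie


_IMMORTAL_CAP = 256   # malignant clone size beyond which extinction is negligible


@njit(cache=True)
def _lineage_gillespie(
    mu1, mu2, r, s, lam1, delta1, lam2, delta2, T, t_max, n0_init, seed
):  # pragma: no cover - exercised via wrapper
    # Malignant (type-2) clones are strongly supercritical; once a clone
    # reaches _IMMORTAL_CAP cells its extinction probability is
    # (delta/(s lam))^cap ~ 0, so it is frozen ("immortal", size -1) and
    # generates no further events. The run ends as soon as the earliest
    # surviving malignant clone - the MRCA - is decided: clones are born
    # in time order, so the first immortal clone with every earlier-born
    # clone extinct settles both MRCA and ECA.
    np.random.seed(seed)
    t = 0.0
    n0 = n0_init
    c1_birth = np.zeros(_MAX_CLONES)
    c1_size = np.zeros(_MAX_CLONES, dtype=np.int64)
    k1 = 0
    c2_birth = np.zeros(_MAX_CLONES)
    c2_parent = np.zeros(_MAX_CLONES, dtype=np.int64)
    c2_size = np.zeros(_MAX_CLONES, dtype=np.int64)   # -1 marks immortal
    k2 = 0
    while t < t_max:
        if t < T:
            lam, delta = lam1, delta1
        else:
            lam, delta = lam2, delta2
        n1 = 0
        for j in range(k1):
            n1 += c1_size[j]
        n2 = 0
        for j in range(k2):
            if c2_size[j] > 0:
                n2 += c2_size[j]
        total = lam * (n0 + n1 + n2) + delta * n0 + (delta / r) * n1 + (delta / s) * n2
        if total <= 0.0:
            break
        dt = np.random.exponential(1.0 / total)
        if t < T and t + dt >= T:
            t = T
            continue
        t += dt
        if t >= t_max:
            break
        u = np.random.random() * total
        decided = False
        if u < lam * n0:
            # wild-type division; one daughter may carry the first driver
            if np.random.random() < mu1:
                if k1 < _MAX_CLONES:
                    c1_birth[k1] = t
                    c1_size[k1] = 1
                    k1 += 1
            else:
                n0 += 1
        elif u < lam * n0 + delta * n0:
            n0 -= 1
        elif u < lam * (n0 + n1) + delta * n0:
            # type-1 division; one daughter may carry the second driver
            target = (u - lam * n0 - delta * n0) / lam
            acc = 0.0
            jj = 0
            for j in range(k1):
                acc += c1_size[j]
                if target < acc:
                    jj = j
                    break
            if np.random.random() < mu2:
                if k2 < _MAX_CLONES:
                    c2_birth[k2] = t
                    c2_parent[k2] = jj
                    c2_size[k2] = 1
                    k2 += 1
            else:
                c1_size[jj] += 1
        elif u < lam * (n0 + n1) + delta * n0 + (delta / r) * n1:
            target = (u - lam * (n0 + n1) - delta * n0) / (delta / r)
            acc = 0.0
            for j in range(k1):
                acc += c1_size[j]
                if target < acc:
                    c1_size[j] -= 1
                    break
        else:
            # type-2 birth or death among non-immortal clones
            base = lam * (n0 + n1) + delta * n0 + (delta / r) * n1
            if u < base + lam * n2:
                target = (u - base) / lam
                birth = True
            else:
                target = (u - base - lam * n2) / (delta / s)
                birth = False
            acc = 0.0
            for j in range(k2):
                if c2_size[j] <= 0:
                    continue
                acc += c2_size[j]
                if target < acc:
                    if birth:
                        c2_size[j] += 1
                        if c2_size[j] >= _IMMORTAL_CAP:
                            c2_size[j] = -1
                            decided = True
                    else:
                        c2_size[j] -= 1
                        decided = c2_size[j] == 0
                    break
        if decided:
            # is the earliest surviving malignant clone settled?
            best = -1
            for j in range(k2):
                if c2_size[j] == -1 and (best < 0 or c2_birth[j] < c2_birth[best]):
                    best = j
            if best >= 0:
                pending = False
                for j in range(k2):
                    if c2_size[j] > 0 and c2_birth[j] < c2_birth[best]:
                        pending = True
                        break
                if not pending:
                    return c2_birth[best], c1_birth[c2_parent[best]]
    # horizon reached: earliest clone still alive or immortal is the MRCA
    mrca = -1.0
    eca = -1.0
    for j in range(k2):
        if c2_size[j] > 0 or c2_size[j] == -1:
            if mrca < 0.0 or c2_birth[j] < mrca:
                mrca = c2_birth[j]
                eca = c1_birth[c2_parent[j]]
    return mrca, eca


@dataclass
class LineageOutcome:
    formed: bool
    t_mrca: float | None = None
    t_eca: float | None = None


def simulate_lineage(
    params: InitiationParams,
    seed: int,
    t_max: float | None = None,
) -> LineageOutcome:
    """One exact stochastic realisation of the initiation model.

    Returns the ECA/MRCA times of the earliest malignant clone alive at
    ``t_max`` (default: the population extinction horizon); extinction of
    all malignant clones is a valid outcome.
    """
    params.validate()
    if t_max is None:
        t_max = mrca_time_horizon(params)
    mrca, eca = _lineage_gillespie(
        params.mu1, params.mu2, params.r, params.s,
        params.lam1, params.delta1, params.lam2, params.delta2,
        params.T, t_max, int(params.N0), seed % (2**31 - 1),
    )
    if mrca < 0:
        return LineageOutcome(formed=False)
    return LineageOutcome(formed=True, t_mrca=float(mrca), t_eca=float(eca))


def empirical_mrca_cdf(
    params: InitiationParams,
    t_grid: np.ndarray,
    n_rep: int,
    seed: int,
    t_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of replicates with a surviving MRCA by each grid time,
    with binomial standard errors (the Gillespie oracle curve)."""
    if t_max is None:
        t_max = mrca_time_horizon(params)
    times = np.full(n_rep, np.inf)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, n_rep)
    for i in range(n_rep):
        out = simulate_lineage(params, int(seeds[i]), t_max=t_max)
        if out.formed:
            times[i] = out.t_mrca
    frac = np.array([(times <= t).mean() for t in t_grid])
    se = np.sqrt(np.maximum(frac * (1 - frac), 1e-12) / n_rep)
    return frac, se


# ---------------------------------------------------------------------------
# tumour-growth Gillespie with mutation accumulation


@njit(cache=True)
def _growth_gillespie(lam, delta, mu, n_end, seed, max_events, max_tries):  # pragma: no cover
    # retries on extinction live inside the jitted loop so the work
    # arrays are allocated once per call, not once per attempt
    np.random.seed(seed)
    max_cells = n_end + 8
    cap = 4.0 * mu * n_end * lam / max(lam - delta, 1e-9)
    if cap > 1.2 * max_events:
        cap = 1.2 * max_events
    max_geno = 64 + int(cap)
    genotype = np.empty(max_cells, dtype=np.int64)   # per-cell genotype node
    parent = np.empty(max_geno, dtype=np.int64)      # genotype tree
    n_new = np.empty(max_geno, dtype=np.int64)       # mutations on each node
    for _attempt in range(max_tries):
        genotype[0] = 0
        n_geno = 1                                   # node 0 = ancestral
        n = 1
        events = 0
        while 0 < n < n_end:
            events += 1
            if events > max_events:
                n = 0
                break
            # event type only; elapsed time does not enter the spectrum
            if np.random.random() * (lam + delta) < lam:
                idx = np.random.randint(n)
                genotype[n] = genotype[idx]
                n += 1
                m = np.random.poisson(mu)
                if m > 0 and n_geno < max_geno:
                    parent[n_geno] = genotype[idx]
                    n_new[n_geno] = m
                    genotype[n - 1] = n_geno
                    n_geno += 1
            else:
                idx = np.random.randint(n)
                genotype[idx] = genotype[n - 1]
                n -= 1
        if n == 0:
            continue
        # carriers per genotype node: count leaves, push counts up the tree
        carriers = np.zeros(n_geno, dtype=np.int64)
        for i in range(n):
            carriers[genotype[i]] += 1
        for g in range(n_geno - 1, 0, -1):
            carriers[parent[g]] += carriers[g]
        return carriers[1:n_geno].copy(), n_new[1:n_geno].copy()
    return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)


def simulate_growth_tree(
    params: GrowthParams, n_end: int, seed: int, max_tries: int = 1000,
    max_events: int = 50_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Grow a tumour to ``n_end`` cells; returns (carrier counts,
    mutation multiplicities) per mutation event, conditioning on
    non-extinction by retrying. Runs exceeding ``max_events`` count as
    extinct (guards near-critical parameter proposals)."""
    params.validate()
    carriers, n_new = _growth_gillespie(
        params.lam, params.delta, params.mu, n_end,
        seed % (2**31 - 1), max_events, max_tries,
    )
    if len(carriers) == 0:
        raise RuntimeError("growth simulation went extinct in every attempt")
    keep = carriers > 0
    return carriers[keep], n_new[keep]


def sample_subclonal_tail(
    params: GrowthParams,
    n_cells: float,
    rng: np.random.Generator,
    vaf_low: float = 0.05,
    vaf_high: float = 0.45,
    k: int = 1,
    n_grid: int = 60,
) -> np.ndarray:
    """Draw pseudo-heterozygous VAFs of subclonal variants from the
    expected birth-death site-frequency spectrum.

    The number of variants in the window is Poisson with mean
    M_k(a_low) - M_k(a_high) and carrier counts follow the spectrum via
    inverse-CDF sampling on a log grid (a pseudo-het VAF v corresponds
    to 2 v N carrier cells). Model-faithful by construction, unlike a
    Gillespie tree whose realised tail carries genealogical
    fluctuations.
    """
    from .growth import cumulative_histogram_grid

    a_lo, a_hi = 2.0 * vaf_low * n_cells, 2.0 * vaf_high * n_cells
    a_grid = np.geomspace(a_lo, a_hi, n_grid)
    m = cumulative_histogram_grid(a_grid, n_cells, params.mu, k, params)
    m_span = m[0] - m[-1]
    if m_span <= 0:
        return np.array([])
    n = rng.poisson(m_span)
    u = rng.random(n) * m_span
    # m is decreasing in a: invert M(a) - M(a_hi) = u
    a_draw = np.interp(u, (m - m[-1])[::-1], a_grid[::-1])
    return a_draw / (2.0 * n_cells)


def sfs_from_tree(carriers: np.ndarray, n_new: np.ndarray) -> dict[int, int]:
    """Observed site-frequency spectrum {clone size: mutation count}."""
    out: dict[int, int] = {}
    for c, m in zip(carriers, n_new):
        out[int(c)] = out.get(int(c), 0) + int(m)
    return out


# ---------------------------------------------------------------------------
# read-level synthetic tumours


@dataclass
class SegmentSpec:
    """Blueprint of one synthetic segment."""

    chrom: str
    length: int
    cn: int = 2
    b: int = 1
    gained_at: str = "mrca"      # "eca" | "mrca"; relevant only if amplified


@dataclass
class SyntheticTruth:
    """Ground truth serialised alongside a synthetic tumour.

    ``m_mrca``/``m_eca`` are the generative densities; after read
    simulation ``realized_m_mrca`` holds the per-copy density of the
    mutations actually placed (the generative value plus its Poisson
    fluctuation), the right reference for estimator-error checks.
    """

    seed: int
    m_mrca: float                               # per bp per copy
    m_eca: float | None
    segment_timing: dict[int, str]              # segment_id -> eca|mrca|none
    params: dict = field(default_factory=dict)
    realized_m_mrca: float | None = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "m_mrca": self.m_mrca,
            "m_eca": self.m_eca,
            "segment_timing": {str(k): v for k, v in self.segment_timing.items()},
            "params": self.params,
            "realized_m_mrca": self.realized_m_mrca,
        }


# autosome lengths (hg19, Mb-rounded); whole-chromosome segments are the
# typical copy-number unit in this disease (trisomies, i17q-like events)
_AUTOSOME_MB = (249, 243, 198, 191, 181, 171, 159, 146, 141, 136, 135,
                134, 115, 107, 103, 90, 81, 78, 59, 63, 48, 51)


def default_segments(n_gained: int = 3) -> list[SegmentSpec]:
    """A 22-autosome synthetic genome of whole-chromosome segments with
    hg19-like lengths; the first ``n_gained`` autosomes carry
    single-step trisomies."""
    specs = []
    for i, mb in enumerate(_AUTOSOME_MB, start=1):
        cn = 3 if i <= n_gained else 2
        specs.append(SegmentSpec(chrom=str(i), length=mb * 1_000_000, cn=cn, b=1))
    return specs


def _subclonal_fractions(
    n: int, f_min: float, rng: np.random.Generator
) -> np.ndarray:
    """Cell fractions of subclonal variants from the neutral birth-death
    tail: P(fraction >= f) proportional to 1/f - 1 on [f_min, 1)."""
    u = rng.random(n)
    inv = 1.0 / f_min - (1.0 / f_min - 1.0) * u
    return 1.0 / inv


def simulate_tumor_reads(
    truth: SyntheticTruth,
    segments: list[SegmentSpec],
    rho: float = 0.8,
    depth: float = 100.0,
    seed: int | None = None,
    subclonal_per_bp: float = 0.0,
    pseudo_vaf_min: float = 0.05,
) -> TumourSample:
    """Generate a read-level tumour from ground-truth densities.

    Clonal mutations are placed as Poisson counts at the ECA density on
    pre-gain (amplified) copies of gained segments and at the MRCA
    density on single copies; read counts are Binomial(depth_i, expected
    VAF) at Poisson-distributed depth. An optional neutral subclonal tail
    is added below the clonal peaks.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    m_mrca = truth.m_mrca
    variants: list[VariantObservation] = []
    seg_objs: list[CNSegment] = []
    realized_num = 0.0     # mutation copies over timeable segments (per-copy law)
    realized_den = 0.0
    for seg_id, spec in enumerate(segments):
        seg = CNSegment(
            chrom=spec.chrom, start=0, end=spec.length, cn=spec.cn, b=spec.b,
            coverage_ratio=spec.cn / 2.0, segment_id=seg_id,
        )
        seg_objs.append(seg)
        if spec.cn == 0:
            continue
        peaks = expected_vaf_peaks(rho, spec.cn, spec.b)
        timing = truth.segment_timing.get(seg_id, "none")
        m_gain = truth.m_eca if (timing == "eca" and truth.m_eca is not None) else m_mrca
        # expected clonal counts per multiplicity class
        exp_counts: dict[int, float] = {m: 0.0 for m in peaks.multiplicities}
        for allele in (spec.cn - spec.b, spec.b):
            if allele == 0:
                continue
            if allele >= 2:
                exp_counts[allele] += m_gain * spec.length
                exp_counts[1] += allele * (m_mrca - m_gain) * spec.length
            else:
                exp_counts[1] += m_mrca * spec.length
        draws: list[tuple[int, float]] = []   # (count, expected VAF)
        timeable = spec.length >= 10_000_000 and 1 <= spec.cn <= 4
        if timeable:
            realized_den += spec.length
        for mult, expected in exp_counts.items():
            k = rng.poisson(expected)
            if timeable:
                realized_num += k * mult / spec.cn
            if k:
                draws.append((int(k), peaks.peaks[mult]))
        if subclonal_per_bp > 0:
            n_sub = rng.poisson(subclonal_per_bp * spec.length)
            if n_sub:
                f_min = 2.0 * pseudo_vaf_min / rho if rho > 0 else 0.1
                f_min = min(max(f_min, 1e-3), 0.5)
                fr = _subclonal_fractions(int(n_sub), f_min, rng)
                for f in fr:
                    draws.append((1, f * rho / peaks.zeta))
        for count, vaf in draws:
            d = rng.poisson(depth, count)
            nv = rng.binomial(np.maximum(d, 1), vaf)
            for dj, nvj in zip(np.maximum(d, 1), nv):
                variants.append(
                    VariantObservation(
                        chrom=spec.chrom,
                        pos=int(rng.integers(1, spec.length + 1)),
                        n_var=int(nvj),
                        n_ref=int(dj - nvj),
                        segment_id=seg_id,
                    )
                )
    truth.realized_m_mrca = realized_num / realized_den if realized_den else None
    meta = SampleMeta(
        sample_id=f"synthetic_{truth.seed}", purity=rho,
        subgroup=str(truth.params.get("subgroup", "G34")),
        age_days=truth.params.get("age_days"),
    )
    return TumourSample(meta=meta, variants=variants, segments=seg_objs)


def study_tumour(
    seed: int,
    m_mrca: float = 2e-7,
    m_eca: float | None = None,
    n_gained: int = 3,
    rho: float = 0.8,
    depth: float = 100.0,
) -> tuple[SyntheticTruth, TumourSample]:
    """One tumour under the canonical recovery-study conditions.

    Purity 0.8, 100x coverage, 22 whole-autosome segments with
    ``n_gained`` trisomies, MRCA density 0.2 SNVs/Mb per copy (within the
    cohort's reported range and enough for >= 500 clonal SNVs); gains are
    placed at the ECA when an ECA density is given, else at the MRCA.
    """
    segments = default_segments(n_gained=n_gained)
    timing = {
        i: ("eca" if m_eca is not None else "mrca")
        for i, s in enumerate(segments)
        if s.cn - s.b >= 2 or s.b >= 2
    }
    truth = SyntheticTruth(
        seed=seed, m_mrca=m_mrca, m_eca=m_eca, segment_timing=timing
    )
    sample = simulate_tumor_reads(truth, segments, rho=rho, depth=depth)
    return truth, sample


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class SyntheticCohort:
    samples: list[TumourSample]
    truths: list[SyntheticTruth]


def simulate_cohort(
    n_tumours: int,
    seed: int,
    initiation: InitiationParams | None = None,
    growth: GrowthParams | None = None,
    rho: float = 0.8,
    depth: float = 100.0,
    n_gained: int = 3,
    eca_fraction: float = 0.5,
) -> SyntheticCohort:
    """Generate a ground-truthed cohort.

    ECA/MRCA times are drawn from the initiation model (inverse-CDF
    sampling of the closed-form time law) and converted to densities via
    the neutral rate; ages at diagnosis follow from the growth model as
    the time for the malignant clone to reach 1e9 cells. A fraction of
    tumours place their gains at the ECA, the rest at the MRCA.
    """
    if n_tumours < 1:
        raise ValueError("n_tumours must be >= 1")
    init = initiation or InitiationParams()
    gp = growth or GrowthParams(lam=0.5, delta=0.35, mu=3.3, t_end=0.0)
    rng = np.random.default_rng(seed)
    t1, t2 = sample_event_times(init, n_tumours, rng)
    per_bp = init.mu / 3.3e9
    growth_days = math.log(1e9) / (gp.lam - gp.delta)
    samples, truths = [], []
    for i in range(n_tumours):
        m_mrca = float(per_bp * divisions_by(t2[i], init))
        m_eca = float(per_bp * divisions_by(t1[i], init))
        has_eca = rng.random() < eca_fraction
        segments = default_segments(n_gained=n_gained)
        timing = {
            j: ("eca" if has_eca else "mrca")
            for j, s in enumerate(segments)
            if s.cn - s.b >= 2 or s.b >= 2
        }
        age_days = max(1.0, t2[i] + growth_days - 250.0)
        truth = SyntheticTruth(
            seed=int(rng.integers(2**31)),
            m_mrca=m_mrca,
            m_eca=m_eca if has_eca else None,
            segment_timing=timing,
            params={
                "t_mrca": float(t2[i]), "t_eca": float(t1[i]),
                "age_days": age_days, "subgroup": "G34",
            },
        )
        samples.append(simulate_tumor_reads(truth, segments, rho=rho, depth=depth))
        truths.append(truth)
    return SyntheticCohort(samples=samples, truths=truths)
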