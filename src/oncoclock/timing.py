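"""Clonal mutation densities at MRCA and ECA, and timing of gains.

The mutational clock: clonal SNVs accumulate linearly with cell
divisions, so the per-copy clonal SNV density of a tumour measures the
molecular age of its most recent common ancestor (MRCA). Mutations that
are present on several copies of a gained segment ("amplified") were
acquired before the gain; if their density is significantly below the
MRCA density the gain predates the MRCA and marks an earlier common
ancestor (ECA).

Estimation proceeds in four steps:

1. expected clonal VAF peaks per segment from purity and allele-specific
   copy number;
2. assignment of each clonal mutation to a multiplicity class under a
   binomial mixture with fixed success probabilities (peak VAFs) and
   EM-fitted weights;
3. the MRCA density as the per-copy, length-normalised sum of clonal
   mutations over retained autosomal segments, with segment-bootstrap
   confidence intervals;
4. a negative-binomial test per gained segment of the amplified-mutation
   density against the MRCA expectation, a pooled ECA density over the
   significantly early segments, and a conformity re-test of each early
   segment against that pooled density.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom, nbinom, poisson

from .io import CNSegment, TumourSample
from .classify import CLONAL_LABELS

logger = logging.getLogger(__name__)

MIN_SEGMENT_LENGTH = 10_000_000   # bp; shorter segments are not timed
MAX_CN = 4                        # segments with higher total CN are not timed
EM_MAX_ITER = 200
EM_RTOL = 1e-8


class NoTimeableGenomeError(ValueError):
    """Raised when no segment survives the timing filters."""


# ---------------------------------------------------------------------------
# peaks


@dataclass
class PeakModel:
    """Expected clonal VAF peaks of one segment.

    ``peaks`` maps mutation multiplicity (copies carrying the mutation)
    to the expected VAF; multiplicities {1, b, CN - b} that coincide or
    are zero collapse/drop.
    """

    zeta: float                       # average sample copy number of the locus
    peaks: dict[int, float]           # multiplicity -> expected VAF

    @property
    def multiplicities(self) -> list[int]:
        return sorted(self.peaks)


def expected_vaf_peaks(rho: float, cn: int, b: int) -> PeakModel:
    """Clonal VAF peaks {rho/zeta, (CN-b) rho/zeta, b rho/zeta}.

    zeta = rho CN + 2 (1 - rho) is the average copy number of the locus
    in the impure sample. Peaks at multiplicity 0 are dropped.
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {rho}")
    if b < 0 or b > cn - b:
        raise ValueError(f"require 0 <= b <= CN - b, got b={b}, CN={cn}")
    zeta = rho * cn + 2.0 * (1.0 - rho)
    if zeta <= 0.0:
        raise ValueError("CN = 0 at purity 1: no sampleable locus")
    peaks = {m: m * rho / zeta for m in {1, b, cn - b} if m > 0}
    return PeakModel(zeta=zeta, peaks=peaks)


# ---------------------------------------------------------------------------
# clonal mutation counting


@dataclass
class SegmentCounts:
    """Clonal mutations of one retained segment by multiplicity class.

    Counts are filter-corrected: each retained clonal mutation enters
    with weight 1/P(it passes the subclonal filter), so the tallies are
    unbiased for the number acquired (the subclonal test deliberately
    discards ~5% of truly clonal mutations; without the correction every
    density would be biased low by the test's size).
    """

    segment: CNSegment
    n_by_mult: dict[int, float]

    @property
    def weighted_count(self) -> float:
        """n_1 + n_{CN-b} (CN-b) + n_b b — mutation copies per segment."""
        return float(sum(m * n for m, n in self.n_by_mult.items()))

    @property
    def amplified_count(self) -> float:
        """Clonal mutations on >= 2 copies (acquired before the gain)."""
        return float(sum(n for m, n in self.n_by_mult.items() if m >= 2))

    @property
    def amplified_length(self) -> int:
        """g_{l,b} + g_{l,CN-b}: segment length per amplified allele."""
        s = self.segment
        g = 0
        if s.cn - s.b >= 2:
            g += s.length
        if s.b >= 2:
            g += s.length
        return g

    @property
    def is_gained(self) -> bool:
        """Gained segments (CN >= 3 with both parental alleles present)
        are the only ones tested for an ECA; LOH (b = 0) never defines
        one."""
        return self.segment.cn >= 3 and self.segment.b >= 1


@dataclass
class ClonalCounts:
    """Per-segment clonal mutation tallies over the retained genome."""

    segments: list[SegmentCounts]
    excluded: list[tuple[CNSegment, str]] = field(default_factory=list)

    @property
    def g_total(self) -> int:
        """Total analysed genome length g (retained segments only)."""
        return sum(sc.segment.length for sc in self.segments)


def _em_multiplicity_assignment(
    n_var: np.ndarray, depth: np.ndarray, peaks: dict[int, float]
) -> np.ndarray:
    """Assign each mutation to a multiplicity class by maximum posterior.

    Success probabilities are fixed at the expected peak VAFs; only the
    mixture weights are free and are fitted by EM. Posterior ties break
    toward the lower multiplicity (conservative toward the MRCA).
    """
    mults = sorted(peaks)
    if len(mults) == 1:
        return np.full(len(n_var), mults[0])
    probs = np.array([peaks[m] for m in mults])
    # (n_mut, n_class) log-likelihood matrix, constant across EM iterations
    loglik = binom.logpmf(n_var[:, None], depth[:, None], probs[None, :])
    log_w = np.full(len(mults), -np.log(len(mults)))
    last_ll = -np.inf
    for _ in range(EM_MAX_ITER):
        joint = loglik + log_w[None, :]
        norm = logsumexp(joint, axis=1)
        ll = float(norm.sum())
        resp = np.exp(joint - norm[:, None])
        with np.errstate(divide="ignore"):
            log_w = np.log(resp.mean(axis=0))
        if abs(ll - last_ll) <= EM_RTOL * max(1.0, abs(last_ll)):
            break
        last_ll = ll
    joint = loglik + log_w[None, :]
    # argmax with ties toward lower multiplicity: argmax picks the first
    # maximal entry and mults is sorted ascending
    best = np.argmax(np.isclose(joint, joint.max(axis=1, keepdims=True)), axis=1)
    return np.array([mults[i] for i in best])


def _retention_weights(
    depth: np.ndarray, assigned: np.ndarray, peaks: dict[int, float]
) -> np.ndarray:
    """Inverse probability of passing the subclonal filter.

    A clonal mutation on ``m`` copies passes the filter when its variant
    read count reaches the 5% quantile of the one-copy binomial, which
    happens with probability sf(x* - 1; depth, peak_m); weighting each
    retained mutation by the inverse removes the ~5% downward bias the
    filter would otherwise impose. Weights are capped at 2 so single
    low-depth observations cannot dominate a segment.
    """
    from .classify import SUBCLONAL_LEVEL

    p1 = peaks[min(peaks)]
    x_star = binom.ppf(SUBCLONAL_LEVEL, depth, p1)
    out = np.empty(len(depth))
    for i, (n, m) in enumerate(zip(depth, assigned)):
        keep_prob = float(binom.sf(x_star[i] - 1, n, peaks[int(m)]))
        out[i] = min(2.0, 1.0 / max(keep_prob, 0.5))
    return out


def count_clonal_mutations(sample: TumourSample) -> ClonalCounts:
    """Tally clonal SNVs per multiplicity class on retained segments.

    Retained segments are autosomal, at least 10 Mb long and of total
    copy number 1..4. Indels and subclonal variants are excluded; clonal
    variants (labels clonal/early_clonal/late_clonal) are assigned to
    multiplicity classes under the segment's binomial mixture.
    """
    rho = sample.meta.purity
    segments: list[SegmentCounts] = []
    excluded: list[tuple[CNSegment, str]] = []
    variants_by_seg: dict[int, list] = {}
    for v in sample.variants:
        if v.segment_id is not None:
            variants_by_seg.setdefault(v.segment_id, []).append(v)

    for seg in sample.segments:
        if not seg.is_autosome:
            excluded.append((seg, "not an autosome"))
            continue
        if seg.length < MIN_SEGMENT_LENGTH:
            excluded.append((seg, "length < 10^7 bp"))
            continue
        if seg.cn > MAX_CN:
            excluded.append((seg, "CN > 4"))
            continue
        if seg.cn == 0:
            excluded.append((seg, "CN = 0"))
            continue
        peak_model = expected_vaf_peaks(rho, seg.cn, seg.b)
        clonal = [
            v
            for v in variants_by_seg.get(seg.segment_id, [])
            if v.timing_class in CLONAL_LABELS and not v.is_indel
        ]
        n_by_mult = {m: 0.0 for m in peak_model.multiplicities}
        if clonal:
            n_var = np.array([v.n_var for v in clonal])
            depth = np.array([v.depth for v in clonal])
            assigned = _em_multiplicity_assignment(n_var, depth, peak_model.peaks)
            weights = _retention_weights(depth, assigned, peak_model.peaks)
            for m, w in zip(assigned, weights):
                n_by_mult[int(m)] += float(w)
        segments.append(SegmentCounts(segment=seg, n_by_mult=n_by_mult))

    if not segments:
        raise NoTimeableGenomeError("no timeable genome")
    return ClonalCounts(segments=segments, excluded=excluded)


# ---------------------------------------------------------------------------
# densities


def _mrca_density_point(counts: list[SegmentCounts]) -> float:
    g = sum(sc.segment.length for sc in counts)
    if g == 0:
        return 0.0
    return float(
        sum(sc.weighted_count / (g * sc.segment.cn) for sc in counts)
    )


def mrca_density(
    counts: ClonalCounts,
    n_bootstrap: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, tuple[float, float]]:
    """Per-copy clonal SNV density at the MRCA with a bootstrap 95% CI.

    The point estimate sums, over retained segments l, the mutation
    copies n_1 + n_{CN-b}(CN-b) + n_b b divided by g CN_l, where g is
    the total retained genome length. The CI resamples segments with
    replacement (percentile method).
    """
    if not counts.segments:
        raise NoTimeableGenomeError("no timeable genome")
    point = _mrca_density_point(counts.segments)
    rng = np.random.default_rng() if rng is None else rng
    n_seg = len(counts.segments)
    reps = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        idx = rng.integers(0, n_seg, n_seg)
        reps[i] = _mrca_density_point([counts.segments[j] for j in idx])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return point, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# ECA detection


@dataclass
class TimingResult:
    """Densities at MRCA and (if detected) ECA, with per-segment calls."""

    m_mrca: float
    ci_mrca: tuple[float, float]
    m_eca: float | None
    ci_eca: tuple[float, float] | None
    assignments: dict[int, str]          # segment_id -> MRCA|ECA|neither|untimed
    p_adj: dict[int, float]              # adjusted P of belonging to the MRCA
    counts: ClonalCounts | None = None
    nb_size: float | None = None         # negative-binomial size used (None = Poisson)

    @property
    def has_eca(self) -> bool:
        return self.m_eca is not None


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted P values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _estimate_nb_size(counts: ClonalCounts, m_mrca: float) -> float | None:
    """Method-of-moments dispersion from inter-segment density variability.

    Weighted clonal counts per segment are compared with their MRCA
    expectation; excess variance beyond Poisson sets the negative-
    binomial size (Var = mu + mu^2 / size). Only segments that are not
    candidates for an earlier origin (non-gained) inform the estimate, so
    genuine ECA signal cannot inflate the null dispersion; under-
    dispersed samples floor at Poisson (returns None).
    """
    null_segs = [sc for sc in counts.segments if not sc.is_gained]
    if len(null_segs) < 2:
        null_segs = counts.segments
    x = np.array([sc.weighted_count for sc in null_segs])
    e = np.array([m_mrca * sc.segment.length * sc.segment.cn for sc in null_segs])
    keep = e > 0
    x, e = x[keep], e[keep]
    if len(x) < 2:
        return None
    excess = float(np.sum((x - e) ** 2 - e))
    denom = float(np.sum(e**2))
    if excess <= 0 or denom <= 0:
        return None
    inv_size = excess / denom
    return 1.0 / inv_size


def _nb_cdf(x: float, mean: float, size: float | None) -> float:
    x = math.floor(x)
    if mean <= 0:
        return 1.0
    if size is None:
        return float(poisson.cdf(x, mean))
    p = size / (size + mean)
    return float(nbinom.cdf(x, size, p))


def _nb_sf_inclusive(x: float, mean: float, size: float | None) -> float:
    """P(X >= x)."""
    x = math.ceil(x)
    if mean <= 0:
        return 1.0 if x <= 0 else 0.0
    if size is None:
        return float(poisson.sf(x - 1, mean))
    p = size / (size + mean)
    return float(nbinom.sf(x - 1, size, p))


def _eca_density_point(counts: list[SegmentCounts]) -> float:
    num = sum(sc.amplified_count for sc in counts)
    den = sum(sc.amplified_length for sc in counts)
    return num / den if den > 0 else 0.0


def detect_eca(
    counts: ClonalCounts,
    m_mrca: float,
    ci_mrca: tuple[float, float] | None = None,
    fdr: float = 0.01,
    n_bootstrap: int = 1000,
    rng: np.random.Generator | None = None,
) -> TimingResult:
    """Test gained segments for an earlier common ancestor.

    For each gained segment the observed amplified-mutation count is
    compared with its expectation under the MRCA density by a one-sided
    negative-binomial test; Benjamini–Hochberg adjusted P <= fdr marks
    the segment candidate-early. The pooled ECA density over candidates
    is then the amplified count divided by the amplified length, and each
    candidate is re-tested (two-sided) for conformity with that pooled
    density: conforming segments are assigned to the ECA, the rest to
    neither. All other gained segments belong to the MRCA.
    """
    rng = np.random.default_rng() if rng is None else rng
    if ci_mrca is None:
        ci_mrca = (m_mrca, m_mrca)
    assignments: dict[int, str] = {}
    p_adj_map: dict[int, float] = {}
    gained = [sc for sc in counts.segments if sc.is_gained]
    for sc in counts.segments:
        if not sc.is_gained:
            assignments[sc.segment.segment_id] = "untimed"

    nb_size = _estimate_nb_size(counts, m_mrca)

    if not gained:
        return TimingResult(
            m_mrca=m_mrca, ci_mrca=ci_mrca, m_eca=None, ci_eca=None,
            assignments=assignments, p_adj={}, counts=counts, nb_size=nb_size,
        )

    p_raw = np.array(
        [
            _nb_cdf(sc.amplified_count, m_mrca * sc.amplified_length, nb_size)
            for sc in gained
        ]
    )
    p_adj = _bh_adjust(p_raw)
    for sc, pa in zip(gained, p_adj):
        p_adj_map[sc.segment.segment_id] = float(pa)
    candidates = [sc for sc, pa in zip(gained, p_adj) if pa <= fdr]

    if not candidates:
        for sc in gained:
            assignments[sc.segment.segment_id] = "MRCA"
        return TimingResult(
            m_mrca=m_mrca, ci_mrca=ci_mrca, m_eca=None, ci_eca=None,
            assignments=assignments, p_adj=p_adj_map, counts=counts,
            nb_size=nb_size,
        )

    m_eca = _eca_density_point(candidates)
    reps = np.empty(n_bootstrap)
    n_cand = len(candidates)
    for i in range(n_bootstrap):
        idx = rng.integers(0, n_cand, n_cand)
        reps[i] = _eca_density_point([candidates[j] for j in idx])
    ci_eca = tuple(float(q) for q in np.percentile(reps, [2.5, 97.5]))

    # conformity of each early segment with the joint ECA density
    p_conf = []
    for sc in candidates:
        mean = m_eca * sc.amplified_length
        lo = _nb_cdf(sc.amplified_count, mean, nb_size)
        hi = _nb_sf_inclusive(sc.amplified_count, mean, nb_size)
        p_conf.append(min(1.0, 2.0 * min(lo, hi)))
    p_conf_adj = _bh_adjust(np.array(p_conf))

    eca_segments = []
    for sc, pa in zip(candidates, p_conf_adj):
        if pa <= fdr:
            assignments[sc.segment.segment_id] = "neither"
        else:
            assignments[sc.segment.segment_id] = "ECA"
            eca_segments.append(sc)
    for sc in gained:
        assignments.setdefault(sc.segment.segment_id, "MRCA")

    if not eca_segments or m_eca >= m_mrca:
        # no segment conforms to a joint earlier ancestor
        return TimingResult(
            m_mrca=m_mrca, ci_mrca=ci_mrca, m_eca=None, ci_eca=None,
            assignments=assignments, p_adj=p_adj_map, counts=counts,
            nb_size=nb_size,
        )
    return TimingResult(
        m_mrca=m_mrca, ci_mrca=ci_mrca, m_eca=m_eca, ci_eca=ci_eca,
        assignments=assignments, p_adj=p_adj_map, counts=counts,
        nb_size=nb_size,
    )


def time_sample(
    sample: TumourSample,
    fdr: float = 0.01,
    n_bootstrap: int = 1000,
    rng: np.random.Generator | None = None,
) -> TimingResult:
    """Full per-tumour timing: count, estimate m_MRCA, test for an ECA."""
    rng = np.random.default_rng() if rng is None else rng
    counts = count_clonal_mutations(sample)
    m, ci = mrca_density(counts, n_bootstrap=n_bootstrap, rng=rng)
    return detect_eca(
        counts, m, ci_mrca=ci, fdr=fdr, n_bootstrap=n_bootstrap, rng=rng
    )


# ---------------------------------------------------------------------------
# molecular time -> real time

HAPLOID_GENOME_BP = 3.3e9
GASTRULATION_DAYS = 14.0


def density_to_weeks(
    m: float,
    mu_lambda_per_day: float,
    first_trimester_weeks: float = 13.0,
    birth_weeks: float = 40.0,
    infancy_weeks: float = 92.0,
) -> tuple[float, str]:
    """Convert a per-bp haploid SNV density to weeks post conception.

    The clock starts at gastrulation (~2 weeks p.c., the matched-normal
    branch point): t = 14 d + m * 3.3e9 / (mu lambda per day). Returns
    the time in weeks p.c. and an era label.
    """
    if m < 0:
        raise ValueError(f"density must be >= 0, got {m}")
    if mu_lambda_per_day <= 0:
        raise ValueError("mu*lambda per day must be positive")
    t_days = GASTRULATION_DAYS + m * HAPLOID_GENOME_BP / mu_lambda_per_day
    weeks = t_days / 7.0
    if weeks <= first_trimester_weeks:
        era = "first trimester"
    elif weeks <= birth_weeks:
        era = "late gestation"
    elif weeks <= infancy_weeks:
        era = "infancy"
    else:
        era = "childhood"
    return weeks, era
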