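"""Clonal/subclonal/early/late classification of single mutations.

A mutation on a segment of total copy number ``k`` in a sample of purity
``rho`` has expected clonal VAF rho / (rho k + 2 (1 - rho)) when present
on one copy. It is called subclonal when the binomial lower-tail
probability of its variant read count under that success probability is
below 5% (one-sided test at the read depth). On trisomic segments
(k = 3) a clonal mutation is refined to early clonal (acquired before
the gain, so present on two copies) when its read count is compatible
with the two-copy peak 2 rho / (rho k + 2 (1 - rho)), otherwise late
clonal.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy.stats import binom

from .io import CNSegment, TumourSample, VariantObservation

SUBCLONAL_LEVEL = 0.05

CLONAL_LABELS = frozenset({"clonal", "early_clonal", "late_clonal"})


@dataclass
class MutationTimingClass:
    label: str                       # subclonal | clonal | early_clonal | late_clonal
    p_subclonal: float               # lower-tail P at the one-copy peak
    p_early: float | None = None     # lower-tail P at the two-copy peak (k = 3 only)


def clonal_success_prob(rho: float, k: int, multiplicity: int = 1) -> float:
    """Expected clonal VAF for a mutation on `multiplicity` copies."""
    return multiplicity * rho / (rho * k + 2.0 * (1.0 - rho))


def classify_mutation(
    n_var: int, n_ref: int, rho: float, k: int
) -> MutationTimingClass:
    """Label one mutation from its read counts, purity and local copy number.

    ``k = 0`` segments carry no sampleable tumour locus; such variants are
    labelled clonal by convention and are excluded from density
    estimation downstream.
    """
    n = n_var + n_ref
    if n <= 0:
        raise ValueError("n_var + n_ref must be positive")
    if not 0.0 < rho <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {rho}")
    if k < 0:
        raise ValueError(f"copy number must be >= 0, got {k}")
    if k == 0:
        return MutationTimingClass(label="clonal", p_subclonal=1.0)

    p1 = clonal_success_prob(rho, k, 1)
    p_sub = float(binom.cdf(n_var, n, p1))
    if p_sub < SUBCLONAL_LEVEL:
        return MutationTimingClass(label="subclonal", p_subclonal=p_sub)
    if k != 3:
        # early/late refinement is defined only on single-copy gains (k = 3)
        return MutationTimingClass(label="clonal", p_subclonal=p_sub)
    p2 = clonal_success_prob(rho, k, 2)
    p_early = float(binom.cdf(n_var, n, p2))
    label = "early_clonal" if p_early >= SUBCLONAL_LEVEL else "late_clonal"
    return MutationTimingClass(label=label, p_subclonal=p_sub, p_early=p_early)


def classify_variants(
    variants: Sequence[VariantObservation],
    segments: Sequence[CNSegment],
    rho: float,
) -> None:
    """Annotate ``timing_class`` in place for variants linked to segments.

    Unassigned variants keep ``timing_class = None``.
    """
    cn_by_id = {s.segment_id: s.cn for s in segments}
    for v in variants:
        if v.segment_id is None or v.segment_id not in cn_by_id:
            v.timing_class = None
            continue
        v.timing_class = classify_mutation(
            v.n_var, v.n_ref, rho, cn_by_id[v.segment_id]
        ).label


def classify_sample(sample: TumourSample) -> None:
    classify_variants(sample.variants, sample.segments, sample.meta.purity)
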