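"""Driver-event classification and chromosome-level CNV enrichment.

Large-scale CNVs are segments of at least 1 Mb whose tumour/normal
coverage ratio leaves the neutral band [0.9, 1.1]. Events spanning at
least 25% of the chromosome's p-arm length are assigned an arm label
(p, q, or both when the event crosses the centromere) and enter a
per-chromosome enrichment test: under the null each of the 24
chromosomes is equally likely to carry an event (success probability
1/24), so an exact one-sided binomial upper tail per chromosome with
Holm correction across chromosomes flags recurrently gained (or lost)
chromosomes; gains and losses are tested separately.

Focal driver calls use fixed thresholds: amplification at copy number
>= 10, homozygous deletion below 0.9 copies, translocation at event
score >= 5, plus TERT promoter hotspots and SNCAIP duplications (the
PRDM6 enhancer-hijacking event).
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom

MIN_LARGE_CNV_BP = 1_000_000
NEUTRAL_BAND = (0.9, 1.1)
ARM_FRACTION = 0.25
N_CHROMOSOMES = 24          # 22 autosomes + X + Y, as in the enrichment null
AMPLIFICATION_MIN_CN = 10.0
HOMDEL_MAX_CN = 0.9
TRANSLOCATION_MIN_SCORE = 5.0
TERT_PROMOTER = {("5", 1295228), ("5", 1295250)}


@dataclass
class ArmTable:
    """Per-chromosome arm boundaries (internal 0-based half-open)."""

    arms: dict[str, tuple[int, int, int, int]]   # chrom -> (p0, p1, q0, q1)

    @classmethod
    def load(cls, path: str | Path | None = None) -> "ArmTable":
        if path is None:
            src = resources.files("oncoclock.data") / "hg19_arms.tsv"
            df = pd.read_csv(src, sep="\t", dtype={"chrom": str})
        else:
            df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        arms = {}
        for row in df.itertuples(index=False):
            arms[str(row.chrom)] = (
                int(row.p_start) - 1, int(row.p_end),
                int(row.q_start) - 1, int(row.q_end),
            )
        return cls(arms=arms)

    def norm_chrom(self, chrom: str) -> str:
        return chrom[3:] if chrom.startswith("chr") else chrom

    def p_length(self, chrom: str) -> int:
        c = self.norm_chrom(chrom)
        if c not in self.arms:
            raise KeyError(f"chromosome {chrom!r} not in arm table")
        p0, p1, _, _ = self.arms[c]
        return p1 - p0


@dataclass
class CNVEvent:
    chrom: str
    direction: str           # gain | loss
    arm: str | None          # p | q | both | None (below the arm-size rule)
    size: int
    coverage_ratio: float

    @property
    def arm_eligible(self) -> bool:
        return self.arm is not None


def classify_large_cnv(
    chrom: str, start: int, end: int, coverage_ratio: float, arms: ArmTable
) -> CNVEvent | None:
    """Classify one CNV segment (0-based half-open) as a large-scale event.

    Returns None for events under 1 Mb or inside the neutral coverage
    band. Events at least 25% of the p-arm length get an arm label and
    are eligible for the enrichment test.
    """
    c = arms.norm_chrom(chrom)
    if c not in arms.arms:
        raise KeyError(f"chromosome {chrom!r} not in arm table")
    size = end - start
    if size < MIN_LARGE_CNV_BP:
        return None
    if NEUTRAL_BAND[0] <= coverage_ratio <= NEUTRAL_BAND[1]:
        return None
    direction = "gain" if coverage_ratio > NEUTRAL_BAND[1] else "loss"
    arm: str | None = None
    if size >= ARM_FRACTION * arms.p_length(c):
        p0, p1, q0, q1 = arms.arms[c]
        if start < p1 and end > q0:
            arm = "both"         # spans the centromere
        elif end <= p1:
            arm = "p"
        else:
            arm = "q"
    return CNVEvent(
        chrom=c, direction=direction, arm=arm, size=size,
        coverage_ratio=coverage_ratio,
    )


def _holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted P values (monotone in rank)."""
    n = len(p)
    order = np.argsort(p)
    adj = p[order] * (n - np.arange(n))
    adj = np.maximum.accumulate(adj)
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def chromosome_enrichment(
    events: list[CNVEvent], direction: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Exact binomial enrichment of one CNV direction per chromosome.

    Only arm-eligible events count. Returns a table with per-chromosome
    event counts, raw and Holm-adjusted one-sided P values (success
    probability 1/24) and a significance flag at ``alpha``.
    """
    used = [e for e in events if e.direction == direction and e.arm_eligible]
    chroms = [str(i) for i in range(1, 23)] + ["X", "Y"]
    counts = {c: 0 for c in chroms}
    for e in used:
        if e.chrom in counts:
            counts[e.chrom] += 1
    n = sum(counts.values())
    if n == 0:
        return pd.DataFrame(
            columns=["chrom", "count", "n_total", "p_raw", "p_adj", "significant"]
        )
    x = np.array([counts[c] for c in chroms])
    p_raw = binom.sf(x - 1, n, 1.0 / N_CHROMOSOMES)
    p_adj = _holm_adjust(p_raw)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "count": x,
            "n_total": n,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        }
    )


@dataclass
class DriverCall:
    locus: str
    driver_class: str
    evidence: dict


def classify_driver_mutation(record: dict, driver_genes: set[str]) -> DriverCall | None:
    """Classify a variant/CNV/SV record against the driver catalogue.

    ``record`` is a mapping with a ``type`` key in {snv, indel, cnv, sv}
    and type-specific fields (gene, region, chrom, pos, copy_number,
    event_score, sv_type). The driver gene list is supplied by the
    caller; it is not bundled.
    """
    rtype = record.get("type")
    if rtype in ("snv", "indel"):
        chrom = str(record.get("chrom", "")).removeprefix("chr")
        if (chrom, record.get("pos")) in TERT_PROMOTER:
            return DriverCall("TERT", "tert_promoter", dict(record))
        gene = record.get("gene")
        region = record.get("region", "exonic")
        if gene in driver_genes and region in ("exonic", "splice_site"):
            cls = "nonsyn_snv" if rtype == "snv" else "indel"
            return DriverCall(gene, cls, dict(record))
        return None
    if rtype == "cnv":
        gene = record.get("gene")
        cn = float(record.get("copy_number", 2.0))
        if gene == "SNCAIP" and cn > 2.0:
            return DriverCall("SNCAIP", "sncaip_duplication", dict(record))
        if gene in driver_genes:
            if cn >= AMPLIFICATION_MIN_CN:
                return DriverCall(gene, "amplification", dict(record))
            if cn < HOMDEL_MAX_CN:
                return DriverCall(gene, "homozygous_deletion", dict(record))
        return None
    if rtype == "sv":
        if record.get("sv_type") == "duplication" and record.get("gene") == "SNCAIP":
            return DriverCall("SNCAIP", "sncaip_duplication", dict(record))
        score = float(record.get("event_score", 0.0))
        gene = record.get("gene")
        if gene in driver_genes and score >= TRANSLOCATION_MIN_SCORE:
            return DriverCall(gene, "translocation", dict(record))
        return None
    raise ValueError(f"unknown record type {rtype!r}")
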