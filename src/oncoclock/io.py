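"""Tabular input/output and the per-tumour data container.

Coordinate conventions: user-facing tables are 1-based inclusive (VCF
style); internally segments are 0-based half-open so that interval
arithmetic is unambiguous. Variant positions stay 1-based (``pos``), and
are converted on the fly when intersected with segments.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}


class FormatError(ValueError):
    """Malformed input table; message carries the offending line."""


@dataclass
class VariantObservation:
    """A somatic SNV or small indel with its allelic read counts."""

    chrom: str
    pos: int                      # 1-based
    n_var: int
    n_ref: int
    segment_id: int | None = None
    is_indel: bool = False
    timing_class: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.n_var < 0 or self.n_ref < 0 or self.n_var + self.n_ref == 0:
            raise ValueError(
                f"invalid read counts n_var={self.n_var}, n_ref={self.n_ref}"
            )

    @property
    def depth(self) -> int:
        return self.n_var + self.n_ref

    @property
    def vaf(self) -> float:
        return self.n_var / self.depth


@dataclass
class CNSegment:
    """Allele-specific copy-number segment, 0-based half-open."""

    chrom: str
    start: int
    end: int
    cn: int                        # total copy number
    b: int                         # minor-allele copy number
    coverage_ratio: float = float("nan")
    segment_id: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start ({self.start}, {self.end})")
        if self.cn < 0:
            raise ValueError(f"total copy number must be >= 0, got {self.cn}")
        if self.b < 0 or self.b > self.cn - self.b:
            raise ValueError(
                f"minor-allele copies b={self.b} exceed major allele for CN={self.cn}"
            )

    @property
    def length(self) -> int:
        """Segment length g_l in bp."""
        return self.end - self.start

    @property
    def is_autosome(self) -> bool:
        return self.chrom in AUTOSOMES


@dataclass
class SampleMeta:
    """Per-sample metadata: purity, ploidy and clinical annotation."""

    sample_id: str
    purity: float
    ploidy: float = 2.0
    subgroup: str = "NA"
    age_days: float | None = None
    sex: str = "NA"

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")


@dataclass
class TumourSample:
    """One tumour: metadata plus its variants and copy-number segments."""

    meta: SampleMeta
    variants: list[VariantObservation] = field(default_factory=list)
    segments: list[CNSegment] = field(default_factory=list)


@dataclass
class RunConfig:
    """Run configuration; one seed governs every stochastic step."""

    seed: int = 0
    fdr: float = 0.01
    n_bootstrap: int = 1000
    abc_population_size: int = 1000
    abc_max_generations: int = 25
    abc_eps_target: float = 0.05
    output_dir: str = "oncoclock_out"
    first_trimester_weeks: float = 13.0
    birth_weeks: float = 40.0
    infancy_weeks: float = 92.0
    mu_per_division: float = 3.3        # neutral SNVs per haploid genome per division
    mu_eff_per_division: float = 4.0    # effective rate during tumour growth
    mu_lambda_per_day: float | None = None  # cohort SNVs/day per haploid genome

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# readers


_TSV_VARIANT_COLS = {"chrom", "pos", "ref_count", "var_count"}


def read_variants(path: str | Path, dialect: str = "tsv") -> list[VariantObservation]:
    """Read somatic variant calls from a TSV table or a VCF.

    The TSV dialect expects a header with at least chrom/pos/ref_count/
    var_count (an optional ``is_indel`` column is honoured). The VCF
    dialect takes read counts from the allelic-depth (AD) FORMAT field of
    the first (tumour) sample.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_variants_tsv(path)
    if dialect == "vcf":
        return _read_variants_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'vcf'")


def _read_variants_tsv(path: Path) -> list[VariantObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = _TSV_VARIANT_COLS - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    has_indel = "is_indel" in df.columns
    out: list[VariantObservation] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        try:
            out.append(
                VariantObservation(
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    n_var=int(row.var_count),
                    n_ref=int(row.ref_count),
                    is_indel=bool(row.is_indel) if has_indel else False,
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: line {line}: {exc}") from exc
    return out


def _read_variants_vcf(path: Path) -> list[VariantObservation]:
    from cyvcf2 import VCF

    out: list[VariantObservation] = []
    vcf = VCF(str(path))
    for i, rec in enumerate(vcf):
        ad = rec.format("AD")
        if ad is None:
            raise FormatError(
                f"{path}: record {i + 1} ({rec.CHROM}:{rec.POS}): no AD field"
            )
        n_ref, n_var = int(ad[0][0]), int(ad[0][1])
        is_indel = len(rec.REF) != 1 or any(len(a) != 1 for a in rec.ALT[:1])
        try:
            out.append(
                VariantObservation(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    n_var=n_var,
                    n_ref=n_ref,
                    is_indel=is_indel,
                )
            )
        except ValueError as exc:
            raise FormatError(
                f"{path}: record {i + 1} ({rec.CHROM}:{rec.POS}): {exc}"
            ) from exc
    return out


_SEGMENT_COLS = {"chrom", "start", "end", "cn", "b"}


def read_segments(path: str | Path) -> list[CNSegment]:
    """Read allele-specific copy-number segments (1-based inclusive input).

    Coordinates are converted to the internal 0-based half-open
    convention. Overlapping segments on one chromosome are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if df.empty:
        logger.warning("%s: empty segment table", path)
        return []
    missing = _SEGMENT_COLS - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    has_cov = "coverage_ratio" in df.columns
    out: list[CNSegment] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2
        try:
            out.append(
                CNSegment(
                    chrom=str(row.chrom),
                    start=int(row.start) - 1,
                    end=int(row.end),
                    cn=int(row.cn),
                    b=int(row.b),
                    coverage_ratio=float(row.coverage_ratio) if has_cov else float("nan"),
                    segment_id=idx,
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: line {line}: {exc}") from exc
    _check_non_overlapping(out, str(path))
    return out


def _check_non_overlapping(segments: Sequence[CNSegment], origin: str) -> None:
    by_chrom: dict[str, list[CNSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise FormatError(
                    f"{origin}: overlapping segments on {chrom}: "
                    f"[{a.start}, {a.end}) and [{b.start}, {b.end})"
                )


def read_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "purity"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        age = getattr(row, "age_days", None)
        out.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                purity=float(row.purity),
                ploidy=float(getattr(row, "ploidy", 2.0)),
                subgroup=str(getattr(row, "subgroup", "NA")),
                age_days=None if age is None or pd.isna(age) else float(age),
                sex=str(getattr(row, "sex", "NA")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)


def write_variants(variants: Iterable[VariantObservation], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "ref_count": [v.n_ref for v in variants],
            "var_count": [v.n_var for v in variants],
            "is_indel": [v.is_indel for v in variants],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_segments(segments: Iterable[CNSegment], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in segments],
            "start": [s.start + 1 for s in segments],  # back to 1-based inclusive
            "end": [s.end for s in segments],
            "cn": [s.cn for s in segments],
            "b": [s.b for s in segments],
            "coverage_ratio": [s.coverage_ratio for s in segments],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_metadata(metas: Iterable[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metas],
            "purity": [m.purity for m in metas],
            "ploidy": [m.ploidy for m in metas],
            "subgroup": [m.subgroup for m in metas],
            "age_days": [m.age_days for m in metas],
            "sex": [m.sex for m in metas],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------


def assign_variants_to_segments(
    variants: Sequence[VariantObservation], segments: Sequence[CNSegment]
) -> list[VariantObservation]:
    """Link each variant to the unique segment containing it.

    Containment is evaluated on the internal half-open intervals: a
    variant at 1-based position ``pos`` (internal coordinate pos - 1)
    falls in segment [start, end) iff start <= pos - 1 < end. Variants in
    no segment keep ``segment_id = None`` and are excluded downstream.
    """
    _check_non_overlapping(segments, "segments")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {s.chrom for s in segments}:
        segs = sorted((s for s in segments if s.chrom == chrom), key=lambda s: s.start)
        by_chrom[chrom] = (
            np.array([s.start for s in segs]),
            np.array([s.end for s in segs]),
            np.array([s.segment_id for s in segs]),
        )
    n_unassigned = 0
    for v in variants:
        v.segment_id = None
        entry = by_chrom.get(v.chrom)
        if entry is None:
            n_unassigned += 1
            continue
        starts, ends, ids = entry
        coord = v.pos - 1
        i = int(np.searchsorted(starts, coord, side="right")) - 1
        if i >= 0 and coord < ends[i]:
            v.segment_id = int(ids[i])
        else:
            n_unassigned += 1
    if n_unassigned:
        logger.info("%d variants fall outside all segments", n_unassigned)
    return list(variants)


def load_sample(
    meta: SampleMeta,
    variant_path: str | Path,
    segment_path: str | Path,
    dialect: str = "tsv",
) -> TumourSample:
    """Read one tumour's tables and link variants to segments."""
    variants = read_variants(variant_path, dialect=dialect)
    segments = read_segments(segment_path)
    assign_variants_to_segments(variants, segments)
    return TumourSample(meta=meta, variants=variants, segments=segments)
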