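"""Cohort pipeline: per-sample timing through cohort reporting.

Stages: read each tumour's tables, classify mutations, time MRCA/ECA,
convert densities to weeks post conception, test chromosome-level CNV
enrichment, and write per-sample and cohort tables plus a run log. Any
stage failure aborts with the stage name. Subgroup comparisons of
densities (unpaired rank-sum) are reporting plumbing only.
"""
from __future__ import annotations

import itertools
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from . import __version__
from .calibration import cohort_mutation_rate_per_day, division_rate
from .classify import classify_sample
from .drivers import ArmTable, chromosome_enrichment, classify_large_cnv
from .io import RunConfig, TumourSample, load_sample, read_metadata
from .timing import HAPLOID_GENOME_BP, density_to_weeks, time_sample

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: RunConfig,
    metadata_path: str | Path,
    data_dir: str | Path,
    dialect: str = "tsv",
) -> dict[str, pd.DataFrame]:
    """Run the full per-sample and cohort analysis.

    ``data_dir`` must hold ``<sample_id>.variants.tsv`` (or ``.vcf``) and
    ``<sample_id>.segments.tsv`` per sample listed in the metadata table.
    Returns the output tables, which are also written to
    ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    data_dir = Path(data_dir)
    rng = np.random.default_rng(config.seed)

    try:
        metas = read_metadata(metadata_path)
    except Exception as exc:
        raise PipelineError("read_metadata", exc) from exc

    samples: list[TumourSample] = []
    try:
        ext = "vcf" if dialect == "vcf" else "variants.tsv"
        for meta in metas:
            samples.append(
                load_sample(
                    meta,
                    data_dir / f"{meta.sample_id}.{ext}",
                    data_dir / f"{meta.sample_id}.segments.tsv",
                    dialect=dialect,
                )
            )
    except Exception as exc:
        raise PipelineError("load_samples", exc) from exc

    rows, seg_rows = [], []
    timings = {}
    try:
        for sample in samples:
            classify_sample(sample)
            res = time_sample(
                sample, fdr=config.fdr, n_bootstrap=config.n_bootstrap,
                rng=np.random.default_rng(rng.integers(2**31)),
            )
            timings[sample.meta.sample_id] = res
            n_by_assign = pd.Series(res.assignments).value_counts().to_dict()
            rows.append(
                {
                    "sample_id": sample.meta.sample_id,
                    "subgroup": sample.meta.subgroup,
                    "m_mrca": res.m_mrca,
                    "m_mrca_lo": res.ci_mrca[0],
                    "m_mrca_hi": res.ci_mrca[1],
                    "m_eca": res.m_eca,
                    "m_eca_lo": res.ci_eca[0] if res.ci_eca else None,
                    "m_eca_hi": res.ci_eca[1] if res.ci_eca else None,
                    "n_seg_mrca": n_by_assign.get("MRCA", 0),
                    "n_seg_eca": n_by_assign.get("ECA", 0),
                    "n_seg_neither": n_by_assign.get("neither", 0),
                    "n_seg_untimed": n_by_assign.get("untimed", 0),
                }
            )
            for seg_id, label in res.assignments.items():
                seg_rows.append(
                    {
                        "sample_id": sample.meta.sample_id,
                        "segment_id": seg_id,
                        "assignment": label,
                        "p_adj": res.p_adj.get(seg_id),
                    }
                )
    except Exception as exc:
        raise PipelineError("timing", exc) from exc
    timing_df = pd.DataFrame(rows)
    segment_df = pd.DataFrame(seg_rows)

    # real-time conversion
    try:
        mu_lambda = config.mu_lambda_per_day
        if mu_lambda is None:
            ests = []
            for sample in samples:
                if sample.meta.age_days is None:
                    continue
                res = timings[sample.meta.sample_id]
                ests.append(
                    division_rate(
                        m_mrca=res.m_mrca * HAPLOID_GENOME_BP,
                        mu=config.mu_per_division,
                        mu_eff=config.mu_eff_per_division,
                        age_days=sample.meta.age_days,
                    )
                )
            if ests:
                mu_lambda = cohort_mutation_rate_per_day(
                    ests, config.mu_per_division
                ).mu_lambda_per_day
        if mu_lambda is not None:
            for col, week_col, era_col in (
                ("m_mrca", "mrca_weeks_pc", "mrca_era"),
                ("m_eca", "eca_weeks_pc", "eca_era"),
            ):
                weeks, eras = [], []
                for v in timing_df[col]:
                    if v is None or pd.isna(v):
                        weeks.append(None)
                        eras.append(None)
                    else:
                        w, e = density_to_weeks(
                            float(v), mu_lambda,
                            first_trimester_weeks=config.first_trimester_weeks,
                            birth_weeks=config.birth_weeks,
                            infancy_weeks=config.infancy_weeks,
                        )
                        weeks.append(w)
                        eras.append(e)
                timing_df[week_col] = weeks
                timing_df[era_col] = eras
    except Exception as exc:
        raise PipelineError("calibration", exc) from exc

    # chromosome-level CNV enrichment across the cohort
    try:
        arms = ArmTable.load()
        events = []
        for sample in samples:
            for seg in sample.segments:
                if np.isnan(seg.coverage_ratio):
                    continue
                ev = classify_large_cnv(
                    seg.chrom, seg.start, seg.end, seg.coverage_ratio, arms
                )
                if ev is not None:
                    events.append(ev)
        frames = [
            chromosome_enrichment(events, d).assign(direction=d)
            for d in ("gain", "loss")
        ]
        frames = [f for f in frames if not f.empty]
        enrich = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(
                columns=["chrom", "count", "n_total", "p_raw", "p_adj",
                         "significant", "direction"]
            )
        )
    except Exception as exc:
        raise PipelineError("drivers", exc) from exc

    # subgroup rank-sum comparisons (reporting only)
    comp_rows = []
    groups = timing_df.groupby("subgroup")["m_mrca"]
    for (ga, xa), (gb, xb) in itertools.combinations(groups, 2):
        if len(xa) >= 2 and len(xb) >= 2:
            stat, p = mannwhitneyu(xa, xb, alternative="two-sided")
            comp_rows.append(
                {"group_a": ga, "group_b": gb, "statistic": stat, "p_value": p}
            )
    comparisons = pd.DataFrame(comp_rows)

    tables = {
        "timing": timing_df,
        "segments": segment_df,
        "enrichment": enrich,
        "subgroup_comparisons": comparisons,
    }
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    (outdir / "run_log.txt").write_text(
        f"oncoclock {__version__}\nseed: {config.seed}\n"
        f"samples: {len(samples)}\n"
    )
    return tables
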