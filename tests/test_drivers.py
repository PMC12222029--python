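import math

import numpy as np
import pytest

from oncoclock.drivers import (
    ArmTable,
    chromosome_enrichment,
    classify_driver_mutation,
    classify_large_cnv,
    CNVEvent,
)
from oncoclock.validation import binomial_tail_oracle


@pytest.fixture(scope="module")
def arms():
    return ArmTable.load()


class TestClassifyLargeCnv:
    def test_sub_megabase_event_discarded(self, arms):
        assert classify_large_cnv("1", 0, 500_000, 1.5, arms) is None

    def test_neutral_coverage_band_discarded(self, arms):
        assert classify_large_cnv("1", 0, 40_000_000, 0.95, arms) is None
        assert classify_large_cnv("1", 0, 40_000_000, 1.1, arms) is None

    def test_centromere_spanning_event_labelled_both(self, arms):
        # chr17 centromere sits near 22-25 Mb; a 40 Mb event crosses it
        ev = classify_large_cnv("17", 5_000_000, 45_000_000, 1.5, arms)
        assert ev is not None and ev.direction == "gain"
        assert ev.arm == "both"

    def test_arm_specific_labels(self, arms):
        p_ev = classify_large_cnv("17", 0, 20_000_000, 0.7, arms)
        q_ev = classify_large_cnv("17", 30_000_000, 75_000_000, 1.5, arms)
        assert p_ev.arm == "p" and p_ev.direction == "loss"
        assert q_ev.arm == "q" and q_ev.direction == "gain"

    def test_large_but_below_arm_fraction_keeps_no_arm_label(self, arms):
        # 2 Mb on chr1 clears the 1 Mb bar but not 25% of the p arm
        ev = classify_large_cnv("1", 0, 2_000_000, 1.5, arms)
        assert ev is not None and ev.arm is None
        assert not ev.arm_eligible

    def test_unknown_chromosome_rejected(self, arms):
        with pytest.raises(KeyError):
            classify_large_cnv("99", 0, 2_000_000, 1.5, arms)


def _events(chrom_counts, direction="gain"):
    out = []
    for chrom, k in chrom_counts.items():
        out.extend(
            CNVEvent(chrom=chrom, direction=direction, arm="both",
                     size=50_000_000, coverage_ratio=1.5)
            for _ in range(k)
        )
    return out


class TestChromosomeEnrichment:
    def test_raw_p_equals_brute_force_tail(self):
        table = chromosome_enrichment(_events({"17": 6, "4": 5, "7": 9}), "gain")
        n = 20
        for _, row in table.iterrows():
            assert row.p_raw == pytest.approx(
                binomial_tail_oracle(int(row["count"]), n, 1 / 24), abs=1e-12
            )

    def test_six_of_twenty_on_one_chromosome_significant(self):
        events = _events({"17": 6}) + _events({str(i): 1 for i in range(1, 15)})
        table = chromosome_enrichment(events, "gain").set_index("chrom")
        assert table.loc["17", "p_raw"] == pytest.approx(
            binomial_tail_oracle(6, 20, 1 / 24), rel=1e-9
        )
        assert table.loc["17", "p_raw"] < 2e-4
        assert table.loc["17", "significant"]

    def test_all_events_on_one_chromosome(self):
        table = chromosome_enrichment(_events({"8": 50}, "loss"), "loss")
        row = table.set_index("chrom").loc["8"]
        assert row.significant
        assert table.significant.sum() == 1

    def test_holm_adjustment_dominates_raw_and_is_monotone(self):
        table = chromosome_enrichment(
            _events({"1": 4, "2": 3, "3": 2, "4": 1}), "gain"
        )
        assert (table.p_adj >= table.p_raw - 1e-15).all()
        ordered = table.sort_values("p_raw")
        assert ordered.p_adj.is_monotonic_increasing

    def test_direction_separation(self):
        events = _events({"17": 10}) + _events({"8": 10}, "loss")
        gains = chromosome_enrichment(events, "gain").set_index("chrom")
        losses = chromosome_enrichment(events, "loss").set_index("chrom")
        assert gains.loc["17", "count"] == 10 and gains.loc["8", "count"] == 0
        assert losses.loc["8", "count"] == 10 and losses.loc["17", "count"] == 0

    def test_zero_events_empty_result(self):
        assert chromosome_enrichment([], "gain").empty

    def test_excess_on_designated_chromosomes_flagged(self):
        """A cohort built with recurrent chr17 gains and chr8 losses
        flags exactly those chromosomes per direction."""
        rng = np.random.default_rng(0)
        chroms = [str(i) for i in range(1, 23)]
        gains = _events({"17": 12}) + _events(
            {c: int(k) for c, k in zip(chroms, rng.multinomial(12, [1 / 22] * 22))}
        )
        losses = _events({"8": 12}, "loss") + _events(
            {c: int(k) for c, k in zip(chroms, rng.multinomial(12, [1 / 22] * 22))},
            "loss",
        )
        gt = chromosome_enrichment(gains + losses, "gain")
        lt = chromosome_enrichment(gains + losses, "loss")
        assert set(gt[gt.significant].chrom) == {"17"}
        assert set(lt[lt.significant].chrom) == {"8"}


DRIVERS = {"MYC", "PRDM6", "GFI1"}


class TestClassifyDriverMutation:
    def test_tert_promoter_hotspots(self):
        for pos in (1295228, 1295250):
            call = classify_driver_mutation(
                {"type": "snv", "chrom": "5", "pos": pos}, DRIVERS
            )
            assert call.driver_class == "tert_promoter"

    def test_exonic_snv_in_driver_gene(self):
        call = classify_driver_mutation(
            {"type": "snv", "chrom": "8", "pos": 1000, "gene": "MYC",
             "region": "exonic"}, DRIVERS
        )
        assert call.driver_class == "nonsyn_snv"

    def test_amplification_threshold(self):
        rec = {"type": "cnv", "gene": "MYC", "copy_number": 12.0}
        assert classify_driver_mutation(rec, DRIVERS).driver_class == "amplification"
        rec["copy_number"] = 9.0
        assert classify_driver_mutation(rec, DRIVERS) is None

    def test_homozygous_deletion_threshold(self):
        rec = {"type": "cnv", "gene": "GFI1", "copy_number": 0.5}
        assert (
            classify_driver_mutation(rec, DRIVERS).driver_class
            == "homozygous_deletion"
        )

    def test_translocation_score_floor(self):
        rec = {"type": "sv", "gene": "MYC", "event_score": 5.0}
        assert classify_driver_mutation(rec, DRIVERS).driver_class == "translocation"
        rec["event_score"] = 4.0
        assert classify_driver_mutation(rec, DRIVERS) is None

    def test_sncaip_duplication_class(self):
        rec = {"type": "sv", "gene": "SNCAIP", "sv_type": "duplication"}
        assert (
            classify_driver_mutation(rec, DRIVERS).driver_class
            == "sncaip_duplication"
        )

    def test_unknown_record_type_rejected(self):
        with pytest.raises(ValueError):
            classify_driver_mutation({"type": "fusion"}, DRIVERS)

    def test_non_driver_gene_ignored(self):
        rec = {"type": "snv", "chrom": "1", "pos": 5, "gene": "TTN",
               "region": "exonic"}
        assert classify_driver_mutation(rec, DRIVERS) is None
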