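import numpy as np
import pytest
from scipy.stats import binom

from oncoclock.classify import classify_sample
from oncoclock.io import CNSegment, SampleMeta, TumourSample, VariantObservation
from oncoclock.timing import (
    ClonalCounts,
    NoTimeableGenomeError,
    SegmentCounts,
    _em_multiplicity_assignment,
    count_clonal_mutations,
    density_to_weeks,
    detect_eca,
    expected_vaf_peaks,
    mrca_density,
    time_sample,
)


class TestExpectedVafPeaks:
    def test_pure_diploid_heterozygous_collapses_to_half(self):
        pm = expected_vaf_peaks(1.0, 2, 1)
        assert pm.zeta == pytest.approx(2.0)
        assert pm.peaks == {1: pytest.approx(0.5)}

    def test_impure_trisomy(self):
        pm = expected_vaf_peaks(0.8, 3, 1)
        assert pm.zeta == pytest.approx(2.8)
        assert pm.peaks[1] == pytest.approx(0.2857142857, abs=1e-6)
        assert pm.peaks[2] == pytest.approx(0.5714285714, abs=1e-6)

    def test_loh_zero_copy_peak_dropped(self):
        pm = expected_vaf_peaks(0.5, 2, 0)
        assert pm.zeta == pytest.approx(2.0)
        assert sorted(pm.peaks.values()) == [pytest.approx(0.25), pytest.approx(0.5)]
        assert 0 not in pm.peaks

    def test_cn0_at_full_purity_rejected(self):
        with pytest.raises(ValueError):
            expected_vaf_peaks(1.0, 0, 0)

    def test_all_peaks_within_unit_interval(self):
        for rho in (0.2, 0.5, 0.9, 1.0):
            for cn in range(1, 5):
                for b in range(0, cn // 2 + 1):
                    for v in expected_vaf_peaks(rho, cn, b).peaks.values():
                        assert 0.0 < v <= 1.0


class TestMultiplicityAssignment:
    def test_trisomy_high_vaf_variant_assigned_two_copies(self):
        # pure tumour, CN=3/b=1: 66 var / 34 ref reads sits at the 2/3 peak
        peaks = {1: 1 / 3, 2: 2 / 3}
        out = _em_multiplicity_assignment(
            np.array([66]), np.array([100]), peaks
        )
        assert out[0] == 2

    def test_matches_exhaustive_posterior_oracle(self, rng):
        """EM assignment equals the maximum-posterior rule computed by
        brute force on segments with few variants."""
        peaks = {1: 0.25, 2: 0.5}
        for trial in range(20):
            n = int(rng.integers(1, 20))
            depth = rng.integers(30, 150, n)
            true_m = rng.choice([1, 2], n)
            n_var = rng.binomial(depth, [peaks[m] for m in true_m])
            got = _em_multiplicity_assignment(n_var, depth, peaks)
            # oracle: EM weight iteration on the 2-class likelihood matrix
            lik = np.stack(
                [binom.pmf(n_var, depth, peaks[1]), binom.pmf(n_var, depth, peaks[2])],
                axis=1,
            )
            w = np.array([0.5, 0.5])
            for _ in range(500):
                post = lik * w
                post /= post.sum(axis=1, keepdims=True)
                w_new = post.mean(axis=0)
                if np.allclose(w_new, w, atol=1e-12):
                    break
                w = w_new
            oracle = np.where(post[:, 0] >= post[:, 1], 1, 2)
            assert np.array_equal(got, oracle)


def _counts(segments):
    return ClonalCounts(segments=segments)


def _seg(length, cn=2, b=1, chrom="1", seg_id=0):
    return CNSegment(chrom=chrom, start=0, end=length, cn=cn, b=b, segment_id=seg_id)


class TestMrcaDensity:
    def test_single_diploid_segment_direct_value(self, rng):
        # 400 one-copy clonal mutations on 2 Mb of diploid genome:
        # density = 400 / (2e6 * 2) = 1e-4 per bp per copy
        sc = SegmentCounts(segment=_seg(2_000_000), n_by_mult={1: 400.0})
        m, _ = mrca_density(_counts([sc]), n_bootstrap=10, rng=rng)
        assert m == pytest.approx(1e-4)

    def test_zero_mutations_give_zero_density(self, rng):
        sc = SegmentCounts(segment=_seg(2_000_000), n_by_mult={1: 0.0})
        m, _ = mrca_density(_counts([sc]), n_bootstrap=10, rng=rng)
        assert m == 0.0

    def test_duplicating_segments_leaves_point_estimate_unchanged(self, rng):
        scs = [
            SegmentCounts(segment=_seg(2_000_000, seg_id=0), n_by_mult={1: 400.0}),
            SegmentCounts(
                segment=_seg(3_000_000, cn=3, seg_id=1), n_by_mult={1: 100.0, 2: 200.0}
            ),
        ]
        m1, _ = mrca_density(_counts(scs), n_bootstrap=10, rng=rng)
        m2, _ = mrca_density(_counts(scs + scs), n_bootstrap=10, rng=rng)
        assert m1 == pytest.approx(m2)

    def test_ci_brackets_point_estimate(self, rng):
        scs = [
            SegmentCounts(segment=_seg(20_000_000, seg_id=i), n_by_mult={1: 380.0 + i})
            for i in range(8)
        ]
        m, (lo, hi) = mrca_density(_counts(scs), n_bootstrap=200, rng=rng)
        assert lo <= m <= hi


class TestCountClonalMutations:
    def test_filters_record_reasons(self, diploid_sample):
        extra = [
            _seg(5_000_000, chrom="2", seg_id=1),           # too short
            _seg(20_000_000, cn=5, b=2, chrom="3", seg_id=2),  # CN > 4
            CNSegment(chrom="X", start=0, end=2 * 10**7, cn=2, b=1, segment_id=3),
        ]
        diploid_sample.segments.extend(extra)
        classify_sample(diploid_sample)
        counts = count_clonal_mutations(diploid_sample)
        reasons = {seg.segment_id: why for seg, why in counts.excluded}
        assert reasons[1] == "length < 10^7 bp"
        assert reasons[2] == "CN > 4"
        assert reasons[3] == "not an autosome"
        assert [sc.segment.segment_id for sc in counts.segments] == [0]

    def test_no_retained_segments_raises(self):
        meta = SampleMeta(sample_id="t", purity=1.0)
        sample = TumourSample(
            meta=meta, variants=[], segments=[_seg(5_000_000)]
        )
        with pytest.raises(NoTimeableGenomeError):
            count_clonal_mutations(sample)

    def test_diploid_sample_counts_near_truth(self, diploid_sample):
        classify_sample(diploid_sample)
        counts = count_clonal_mutations(diploid_sample)
        total = sum(counts.segments[0].n_by_mult.values())
        assert total == pytest.approx(400, rel=0.05)


class TestDetectEca:
    def _base_segments(self, rng, m=1e-4):
        out = []
        for i in range(6):
            g = 20_000_000
            n = rng.poisson(m * g * 2)
            out.append(
                SegmentCounts(segment=_seg(g, seg_id=i), n_by_mult={1: float(n)})
            )
        return out

    def test_half_density_trisomy_assigned_eca(self, rng):
        m = 1e-4
        scs = self._base_segments(rng, m)
        # trisomy of 10 Mb with amplified density 0.5 m: 500 two-copy
        # mutations where 1000 are expected under the MRCA
        scs.append(
            SegmentCounts(
                segment=_seg(10_000_000, cn=3, seg_id=6),
                n_by_mult={1: 1500.0, 2: 500.0},
            )
        )
        res = detect_eca(_counts(scs), m, n_bootstrap=50, rng=rng)
        assert res.assignments[6] == "ECA"
        assert res.m_eca == pytest.approx(5e-5, rel=0.05)
        assert res.m_eca < res.m_mrca

    def test_mrca_density_gains_not_called_early(self, rng):
        m = 1e-4
        scs = self._base_segments(rng, m)
        for j, g in enumerate((15_000_000, 30_000_000), start=6):
            scs.append(
                SegmentCounts(
                    segment=_seg(g, cn=3, seg_id=j),
                    n_by_mult={1: float(rng.poisson(2 * m * g)),
                               2: float(rng.poisson(m * g))},
                )
            )
        res = detect_eca(_counts(scs), m, n_bootstrap=50, rng=rng)
        assert not res.has_eca
        assert {res.assignments[6], res.assignments[7]} == {"MRCA"}

    def test_discordant_early_segments_split_eca_and_neither(self, rng):
        m = 1e-4
        scs = self._base_segments(rng, m)
        # amplified densities 0.2m and 0.8m with large counts: both are
        # candidate-early, but no joint ECA accommodates both
        scs.append(
            SegmentCounts(
                segment=_seg(100_000_000, cn=3, seg_id=6),
                n_by_mult={1: 16_000.0, 2: 2_000.0},
            )
        )
        scs.append(
            SegmentCounts(
                segment=_seg(100_000_000, cn=3, seg_id=7),
                n_by_mult={1: 10_400.0, 2: 8_000.0},
            )
        )
        res = detect_eca(_counts(scs), m, n_bootstrap=50, rng=rng)
        labels = {res.assignments[6], res.assignments[7]}
        assert "neither" in labels

    def test_loh_never_defines_eca(self, rng):
        m = 1e-4
        scs = self._base_segments(rng, m)
        # copy-neutral LOH with amplified-looking low density: not gained
        scs.append(
            SegmentCounts(
                segment=_seg(50_000_000, cn=2, b=0, seg_id=6),
                n_by_mult={1: 100.0, 2: 100.0},
            )
        )
        res = detect_eca(_counts(scs), m, n_bootstrap=50, rng=rng)
        assert res.assignments[6] == "untimed"
        assert not res.has_eca


class TestDensityToWeeks:
    def test_zero_density_is_gastrulation(self):
        weeks, era = density_to_weeks(0.0, 0.33)
        assert weeks == pytest.approx(2.0)
        assert era == "first trimester"

    def test_direct_inversion(self):
        # mu*lambda = 0.33/day, density 1e-8/bp: t = 14 + 33/0.33 = 114 d
        weeks, era = density_to_weeks(1e-8, 0.33)
        assert weeks == pytest.approx(114.0 / 7.0, rel=1e-6)
        assert era == "late gestation"

    def test_doubling_rate_halves_elapsed_time(self):
        w1, _ = density_to_weeks(1e-8, 0.33)
        w2, _ = density_to_weeks(1e-8, 0.66)
        assert (w2 * 7 - 14) == pytest.approx((w1 * 7 - 14) / 2)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            density_to_weeks(-1e-9, 0.33)

    def test_era_boundaries(self):
        assert density_to_weeks(0.0, 0.33)[1] == "first trimester"
        # pick densities landing in each era at mu*lambda = 0.33/day
        for target, era in ((30, "late gestation"), (60, "infancy"), (200, "childhood")):
            m = (target * 7 - 14) * 0.33 / 3.3e9
            assert density_to_weeks(m, 0.33)[1] == era


def test_time_sample_recovers_diploid_truth(diploid_sample, rng):
    classify_sample(diploid_sample)
    res = time_sample(diploid_sample, n_bootstrap=50, rng=rng)
    assert res.m_mrca == pytest.approx(400 / (2 * 20_000_000), rel=0.06)
    assert not res.has_eca
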