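import numpy as np
import pytest

from oncoclock.growth import GrowthParams
from oncoclock.initiation import InitiationParams
from oncoclock.simulate import (
    SegmentSpec,
    SyntheticTruth,
    default_segments,
    sample_subclonal_tail,
    simulate_cohort,
    simulate_growth_tree,
    simulate_lineage,
    simulate_tumor_reads,
    study_tumour,
)

FAST = InitiationParams(
    mu1=3e-4, mu2=3e-4, r=1.2, s=5.0, lam1=1.0, delta1=0.8,
    lam2=0.8, delta2=1.0, T=30.0,
)


class TestLineage:
    def test_no_first_driver_never_forms_tumour(self):
        p = FAST.with_(mu1=0.0)
        for seed in range(30):
            assert not simulate_lineage(p, seed).formed

    def test_eca_precedes_mrca_when_formed(self):
        formed = 0
        for seed in range(2000):
            out = simulate_lineage(FAST, seed)
            if out.formed:
                formed += 1
                assert 0 < out.t_eca < out.t_mrca
        assert formed > 0

    def test_extinction_is_valid_outcome(self):
        out = simulate_lineage(FAST.with_(mu1=1e-9), 0)
        assert not out.formed and out.t_mrca is None


class TestGrowthTree:
    def test_reaches_target_size_with_mutations(self):
        gp = GrowthParams(lam=1.0, delta=0.2, mu=5.0, t_end=0.0)
        carriers, n_new = simulate_growth_tree(gp, 500, seed=1)
        assert carriers.max() <= 500
        assert carriers.min() >= 1
        assert n_new.sum() > 0

    def test_total_mutation_count_scales_with_mu(self):
        lo = simulate_growth_tree(
            GrowthParams(lam=1.0, delta=0.0, mu=2.0, t_end=0.0), 800, seed=3
        )[1].sum()
        hi = simulate_growth_tree(
            GrowthParams(lam=1.0, delta=0.0, mu=20.0, t_end=0.0), 800, seed=3
        )[1].sum()
        assert hi > 3 * lo


class TestSubclonalTail:
    def test_draws_lie_in_window(self, rng):
        gp = GrowthParams.for_final_size(2000, 0.3, 10.0)
        v = sample_subclonal_tail(gp, 2000, rng)
        assert np.all((v >= 0.05) & (v <= 0.45))

    def test_count_scales_with_mu(self):
        lo = sample_subclonal_tail(
            GrowthParams.for_final_size(2000, 0.3, 5.0), 2000,
            np.random.default_rng(0),
        )
        hi = sample_subclonal_tail(
            GrowthParams.for_final_size(2000, 0.3, 50.0), 2000,
            np.random.default_rng(0),
        )
        assert len(hi) > 5 * len(lo)


class TestTumourReads:
    def test_zero_density_gives_empty_variant_table(self):
        truth = SyntheticTruth(seed=1, m_mrca=0.0, m_eca=None, segment_timing={})
        sample = simulate_tumor_reads(truth, default_segments(0))
        assert sample.variants == []

    def test_same_seed_reproduces_byte_identical_tumour(self):
        a = study_tumour(7)[1]
        b = study_tumour(7)[1]
        assert len(a.variants) == len(b.variants)
        assert all(
            (x.pos, x.n_var, x.n_ref) == (y.pos, y.n_var, y.n_ref)
            for x, y in zip(a.variants, b.variants)
        )

    def test_expected_clonal_count_poisson_property(self):
        # one diploid 50 Mb segment at 2e-6/bp: expect ~200 mutations
        # (100 per allele copy); spread across replicates is Poissonian
        spec = [SegmentSpec(chrom="1", length=50_000_000, cn=2, b=1)]
        counts = []
        for seed in range(40):
            truth = SyntheticTruth(
                seed=seed, m_mrca=2e-6, m_eca=None, segment_timing={}
            )
            counts.append(len(simulate_tumor_reads(truth, spec, rho=1.0).variants))
        mean = np.mean(counts)
        assert abs(mean - 200) < 3 * np.sqrt(200 / 40)

    def test_high_depth_vafs_concentrate_at_expected_peak(self):
        spec = [SegmentSpec(chrom="1", length=50_000_000, cn=2, b=1)]
        truth = SyntheticTruth(seed=3, m_mrca=2e-6, m_eca=None, segment_timing={})
        sample = simulate_tumor_reads(truth, spec, rho=0.8, depth=1e6)
        vafs = np.array([v.vaf for v in sample.variants])
        assert abs(vafs.mean() - 0.8 / 2.0) < 1e-2

    def test_realized_density_recorded(self):
        truth, _ = study_tumour(11)
        assert truth.realized_m_mrca == pytest.approx(truth.m_mrca, rel=0.2)


class TestCohort:
    def test_single_tumour_cohort(self):
        cohort = simulate_cohort(1, seed=2)
        assert len(cohort.samples) == 1 and len(cohort.truths) == 1
        assert cohort.truths[0].params["age_days"] > 0

    def test_fixed_seed_byte_identity(self):
        a = simulate_cohort(3, seed=9)
        b = simulate_cohort(3, seed=9)
        assert [t.to_dict() for t in a.truths] == [t.to_dict() for t in b.truths]
        assert all(
            len(x.variants) == len(y.variants)
            for x, y in zip(a.samples, b.samples)
        )

    def test_eca_truths_precede_mrca(self):
        cohort = simulate_cohort(10, seed=4, eca_fraction=1.0)
        for t in cohort.truths:
            assert t.m_eca is not None
            assert t.m_eca < t.m_mrca
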