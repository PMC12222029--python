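import numpy as np
import pytest

from oncoclock.io import CNSegment, SampleMeta, TumourSample, VariantObservation


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def diploid_sample():
    """A pure-tumour sample with one diploid 20 Mb segment and a handful
    of clonal heterozygous variants."""
    seg = CNSegment(chrom="1", start=0, end=20_000_000, cn=2, b=1, segment_id=0)
    gen = np.random.default_rng(0)
    variants = []
    for pos in range(1000, 1000 + 400):
        d = int(gen.poisson(100))
        nv = int(gen.binomial(max(d, 1), 0.5))
        variants.append(
            VariantObservation(
                chrom="1", pos=pos, n_var=nv, n_ref=max(d, 1) - nv, segment_id=0
            )
        )
    meta = SampleMeta(sample_id="t", purity=1.0)
    return TumourSample(meta=meta, variants=variants, segments=[seg])
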