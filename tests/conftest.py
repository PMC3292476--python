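import numpy as np
import pytest

from exocall.alignment import AlignedRead
from exocall.simulate import ErrorProfile, SimConfig, simulate_reads


@pytest.fixture(scope="session")
def clean_fixture():
    """Planted 100 SNPs + 20 INDELs at uniform depth 30, no sequencing noise."""
    cfg = SimConfig(
        seed=1,
        n_sites=120,
        tp_fraction=1.0,
        indel_fraction=1 / 6,
        depth_mean=30.0,
        depth_cv=0.0,
        weak_site_fraction=0.0,
        error_profile=ErrorProfile(substitution_rate=0.0, indel_rate=0.0),
    )
    reads, reference, truth = simulate_reads(cfg)
    return cfg, reads, reference, truth


@pytest.fixture(scope="session")
def noisy_fixture():
    """Default mixture: true variants plus systematic error sites."""
    cfg = SimConfig(seed=5, n_sites=80, tp_fraction=0.4, indel_fraction=0.25,
                    depth_mean=30.0)
    reads, reference, truth = simulate_reads(cfg)
    return cfg, reads, reference, truth


def make_read(
    pos=0,
    sequence="ACGTACGTAC",
    quals=None,
    cigar=None,
    strand="+",
    chrom="ref1",
    mapq=255,
    read_id="r1",
):
    n = len(sequence)
    return AlignedRead(
        read_id=read_id,
        chrom=chrom,
        pos=pos,
        strand=strand,
        sequence=sequence,
        base_qualities=list(quals) if quals is not None else [30] * n,
        cigar=cigar or [("M", n)],
        mapping_quality=mapq,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
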