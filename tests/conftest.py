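import numpy as np
import pytest

from lohcna import CohortSpec, ProbeMap, Segment, SegmentProfile, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-sample synthetic cohort shared across read-only tests."""
    return generate_cohort(CohortSpec(n_samples=60), seed=20260)


def random_profile(rng: np.random.Generator, chrom: str = "chr1"):
    """A small random segment profile plus a probe map covering it.

    Used as raw material for brute-force oracle checks; segments abut with
    occasional gaps, allele states are arbitrary valid pairs.
    """
    ploidy = float(rng.uniform(1.5, 4.4))
    segments = []
    pos = 1
    for _ in range(int(rng.integers(1, 8))):
        length = int(rng.integers(50, 2000))
        segments.append(_random_segment(rng, chrom, pos, pos + length - 1))
        pos += length + (int(rng.integers(0, 300)) if rng.random() < 0.3 else 0)
    probes = ProbeMap({chrom: np.unique(rng.integers(1, pos + 500, size=200))})
    return SegmentProfile("T", ploidy, 0.8, tuple(segments)), probes


def _random_segment(rng, chrom, start, end):
    n_minor = int(rng.integers(0, 3))
    n_major = n_minor + int(rng.integers(0, 4))
    if n_major == 0 and rng.random() < 0.9:
        n_major = 1  # homozygous deletions kept rare
    return Segment(chrom, start, end, n_major, n_minor)
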