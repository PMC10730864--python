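import numpy as np
import pytest

from bapfish.locus_model import (
    GenomicInterval,
    ProbeColor,
    ProbeFootprint,
    ProbeLabel,
    default_probes,
)


@pytest.fixture(scope="session")
def probes():
    return default_probes()


@pytest.fixture(scope="session")
def cases():
    from bapfish.cohort_cases import load_cases

    return load_cases()


# Miniature locus used by brute-force oracles: small enough coordinates that a
# per-base boolean mask is cheap.
MINI_CHROM = "c"
MINI_LEN = 20_000
MINI_RED = GenomicInterval(MINI_CHROM, 3_000, 5_000)
MINI_GREEN = GenomicInterval(MINI_CHROM, 6_000, 8_000)


@pytest.fixture(scope="session")
def mini_probes():
    return [
        ProbeFootprint(ProbeLabel.FIVE_PRIME_MYC, ProbeColor.RED, MINI_RED),
        ProbeFootprint(ProbeLabel.THREE_PRIME_MYC, ProbeColor.GREEN, MINI_GREEN),
    ]


def random_mini_config(rng: np.random.Generator, max_derivatives: int = 6):
    """Random GenomeConfiguration on the miniature locus (<= 12 segments total)."""
    from bapfish.locus_model import DerivativeChromosome, GenomeConfiguration, SegmentRef

    n_der = int(rng.integers(1, max_derivatives + 1))
    budget = 12
    derivatives = []
    for d in range(n_der):
        remaining = budget - sum(len(x.segments) for x in derivatives)
        if remaining <= 0:
            break
        n_seg = int(rng.integers(1, min(4, remaining) + 1))
        segs = []
        for _ in range(n_seg):
            start = int(rng.integers(0, MINI_LEN - 300))
            length = int(rng.integers(200, MINI_LEN - start))
            orient = "+" if rng.random() < 0.7 else "-"
            segs.append(SegmentRef(GenomicInterval(MINI_CHROM, start, start + length), orient))
        derivatives.append(DerivativeChromosome(f"der{d}", segs))
    return GenomeConfiguration(derivatives)
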