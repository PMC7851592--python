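import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sweepscan.genotype_io import GenotypeMatrix


def random_matrix(
    rng: np.random.Generator,
    n_samples: int,
    n_sites: int,
    chromosome: str = "chr1",
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """A structure-free random genotype matrix for oracle comparisons."""
    calls = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = -1
    positions = np.cumsum(rng.integers(1, 300, size=n_sites))
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n_samples)],
        chromosomes=np.full(n_sites, chromosome, dtype=object),
        positions=positions,
        ref_alleles=np.full(n_sites, "A", dtype=object),
        alt_alleles=np.full(n_sites, "G", dtype=object),
        calls=calls,
    )


def matrix_from_calls(calls, positions=None, chromosome="chr1") -> GenotypeMatrix:
    """Build a single-chromosome matrix from a literal call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        chromosomes=np.full(m, chromosome, dtype=object),
        positions=np.asarray(positions),
        ref_alleles=np.full(m, "A", dtype=object),
        alt_alleles=np.full(m, "G", dtype=object),
        calls=calls,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231107)
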