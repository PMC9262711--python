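import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from hetri.popgen import CallabilityMask, GroupAssignment, VariantMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_matrix(rng, n_samples, n_sites, length=10_000, missing_rate=0.0):
    """Random biallelic haploid matrix for oracle comparisons."""
    pos = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1
    gt = rng.integers(0, 2, size=(n_sites, n_samples)).astype(np.int8)
    if missing_rate:
        gt[rng.random(gt.shape) < missing_rate] = -1
    return VariantMatrix(
        samples=[f"s{i}" for i in range(n_samples)],
        chrom_lengths={"chr1": length},
        positions={"chr1": pos},
        genotypes={"chr1": gt},
    )


@pytest.fixture
def small_two_groups():
    """6 samples in two groups of 3."""
    labels = {f"s{i}": ("rV-group" if i < 3 else "RV1-group") for i in range(6)}
    return GroupAssignment(labels, provenance="truth")


@pytest.fixture
def full_mask():
    def make(chrom_lengths):
        return CallabilityMask.all_usable(chrom_lengths)

    return make
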