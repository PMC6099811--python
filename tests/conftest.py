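import numpy as np
import pytest

from introgress_panel import (
    HaploidDataset,
    LocusRecord,
    SampleRecord,
    SimConfig,
    annotate_loci,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_ds() -> HaploidDataset:
    """30 M + 20 C samples, 2,000 loci, default divergence, with annotations."""
    cfg = SimConfig(n_M=30, n_C=20, n_loci=2_000, seed=11)
    return annotate_loci(generate_dataset(cfg), cfg)


@pytest.fixture(scope="session")
def complete_ds() -> HaploidDataset:
    """Complete-case (no missing calls) dataset for set-identity tests."""
    cfg = SimConfig(n_M=30, n_C=20, n_loci=2_000, missing_rate=0.0, seed=12)
    return annotate_loci(generate_dataset(cfg), cfg)


def make_toy_dataset(calls, populations=None, chrom=1, spacing=10_000):
    """Tiny dataset from an explicit call matrix (rows = samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    populations = populations or ["IHB"] * n
    samples = [
        SampleRecord(sample_id=f"s{i}", population=populations[i])
        for i in range(n)
    ]
    loci = [
        LocusRecord(locus_id=f"l{j}", chrom=chrom, pos=1 + j * spacing)
        for j in range(L)
    ]
    return HaploidDataset(samples=samples, loci=loci, calls=calls)
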