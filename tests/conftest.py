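import numpy as np
import pandas as pd
import pytest

from culturematch.seqio import ASVRecord, AbundanceTable
from culturematch.synthetic import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by read-only tests."""
    cfg = SimConfig(
        seed=7,
        n_taxa=120,
        n_samples_per_stratum=2,
        reads_per_sample=5000,
        isolate_count=60,
    )
    return simulate_study(cfg)


@pytest.fixture
def toy_table():
    """One sample, three ASVs with counts 50/30/20."""
    return AbundanceTable(
        pd.DataFrame([[50, 30, 20]], index=["s1"], columns=["A", "B", "C"])
    )


def random_asvs(rng: np.random.Generator, n: int, lo: int = 40, hi: int = 120) -> list[ASVRecord]:
    """Random, pairwise-distinct unambiguous ASV records."""
    seqs: set[str] = set()
    while len(seqs) < n:
        length = int(rng.integers(lo, hi))
        seqs.add("".join(rng.choice(list("ACGT"), size=length)))
    return [ASVRecord(f"a{i:04d}", s) for i, s in enumerate(sorted(seqs))]
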