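import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from epitrd.trio_data import (
    GenotypeMatrix,
    TrioTable,
    TwoLocusGenotype,
    all_matings,
)


@pytest.fixture(scope="session")
def matings():
    return all_matings()


@pytest.fixture(scope="session")
def hethet_mating(matings):
    """The AaBb x AaBb configuration."""
    idx = 9 * int(TwoLocusGenotype.AaBb) + int(TwoLocusGenotype.AaBb)
    return matings[idx]


def make_genotypes(calls: dict, chrom=("1", "2"), pos=(100, 200)) -> GenotypeMatrix:
    """Build a two-SNP GenotypeMatrix from {animal: (call_a, call_b)}."""
    animals = list(calls)
    arr = np.array([calls[a] for a in animals], dtype=np.int8)
    snp_map = pd.DataFrame(
        {"chrom": list(chrom), "pos": list(pos)}, index=["snpA", "snpB"]
    )
    return GenotypeMatrix(animals, ["snpA", "snpB"], arr, snp_map)


def make_trios(rows) -> TrioTable:
    return TrioTable(
        pd.DataFrame(rows, columns=["offspring", "sire", "dam"])
    )


@pytest.fixture
def trio_builder():
    return make_genotypes, make_trios
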