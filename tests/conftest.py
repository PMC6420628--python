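import numpy as np
import pytest

from remergence import (
    AdmixtureParams,
    GenomeModel,
    GenotypeMatrix,
    VariantLocus,
    build_admixed_population,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_genome():
    """1/50-scale yeast karyotype: fast but still 16 chromosomes."""
    return GenomeModel.yeast(0.02)


@pytest.fixture(scope="session")
def small_population(small_genome):
    """A down-scaled admixed panel (5 founders x 600 muts, 10 mosaics,
    +200 muts per strain) with full truth log."""
    params = AdmixtureParams(muts_per_founder=600, muts_per_strain_post=200)
    return build_admixed_population(
        params, small_genome, rng=np.random.default_rng(99)
    )


@pytest.fixture
def toy_matrix():
    """3 strains x 4 loci with one missing call."""
    loci = [
        VariantLocus("chrI", 5, "C", "T"),
        VariantLocus("chrI", 10, "A", "G"),
        VariantLocus("chrI", 22, "T", "C"),
        VariantLocus("chrII", 3, "G", "A"),
    ]
    calls = np.array(
        [[0, 1, -1, 0], [1, 0, 0, 1], [0, 0, 1, 1]], dtype=np.int8
    )
    return GenotypeMatrix.from_loci(["s1", "s2", "s3"], loci, calls)
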