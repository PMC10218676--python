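import numpy as np
import pandas as pd
import pytest

from gaselect import GenotypeMatrix, Locus, PhenotypeTable


def make_genotypes(codes, chrom="chr1", start_pos=1000, spacing=1000, samples=None):
    """Build a GenotypeMatrix from a raw +-1 array with synthetic locus names."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    loci = [Locus(chrom=chrom, pos=start_pos + j * spacing) for j in range(m)]
    samples = samples or [f"s{i}" for i in range(n)]
    return GenotypeMatrix(samples=samples, loci=loci, codes=codes)


def make_phenotypes(G, y, trait="trait"):
    return PhenotypeTable(samples=G.samples, traits=pd.DataFrame({trait: np.asarray(y, float)}, index=G.samples))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_genotypes(rng):
    """40 samples x 12 independent +-1 SNPs."""
    codes = rng.choice([-1, 1], size=(40, 12))
    return make_genotypes(codes)
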