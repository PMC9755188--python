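import numpy as np
import pytest

from breedscan.vcf_io import GenotypeMatrix, SampleMeta, Variant


def make_gm(
    dosages,
    quals=None,
    chroms=None,
    positions=None,
    breeds=None,
    sexes=None,
    refs=None,
    alts=None,
    n_alleles=None,
    haploid=None,
):
    """Assemble a GenotypeMatrix from plain arrays with sensible defaults."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    quals = [30.0] * p if quals is None else quals
    chroms = ["chr1"] * p if chroms is None else chroms
    positions = list(range(100, 100 + 10 * p, 10)) if positions is None else positions
    refs = ["A"] * p if refs is None else refs
    alts = ["G"] * p if alts is None else alts
    n_alleles = [2] * p if n_alleles is None else n_alleles
    breeds = ["breedX"] * n if breeds is None else breeds
    sexes = ["female"] * n if sexes is None else sexes
    variants = [
        Variant(chrom=chroms[j], pos=positions[j], ref=refs[j], alt=alts[j],
                qual=quals[j], n_alleles=n_alleles[j], vid=f"v{j}")
        for j in range(p)
    ]
    samples = [
        SampleMeta(sample_id=f"s{i}", breed=breeds[i], sex=sexes[i]) for i in range(n)
    ]
    return GenotypeMatrix(dosages, variants, samples, haploid)


@pytest.fixture
def tiny_gm():
    """3 samples x 2 variants, one missing call."""
    return make_gm([[0, 1], [1, 2], [np.nan, 0]])


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
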