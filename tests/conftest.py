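import numpy as np
import pandas as pd
import pytest

from tetragwas.geno import GenotypeMatrix


def make_genotypes(dosage, chromosomes=None, positions=None, samples=None,
                   refs=None, alts=None, quals=None, depths=None,
                   dosage_kind="most_probable"):
    """Build a GenotypeMatrix from a plain dosage array (NaN = missing)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    if chromosomes is None:
        chromosomes = ["chr1"] * m
    if positions is None:
        positions = list(range(1, m + 1))
    markers = pd.DataFrame({
        "marker_id": [f"m{j}" for j in range(m)],
        "chromosome": chromosomes,
        "position": positions,
        "ref": refs if refs is not None else ["A"] * m,
        "alt": alts if alts is not None else [("T",)] * m,
        "qual": quals if quals is not None else [100.0] * m,
    })
    return GenotypeMatrix(samples=list(samples), markers=markers,
                          dosage=dosage, dosage_kind=dosage_kind,
                          depths=None if depths is None
                          else np.asarray(depths, dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genotypes():
    """Five samples x four polymorphic markers on two chromosomes."""
    dosage = np.array([
        [0, 1, 2, 4],
        [1, 2, 0, 3],
        [2, 3, 1, 2],
        [3, 4, 2, 1],
        [4, 0, 3, 0],
    ], dtype=float)
    return make_genotypes(dosage,
                          chromosomes=["chr1", "chr1", "chr2", "chr2"],
                          positions=[100, 200, 100, 200])
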