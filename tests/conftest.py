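import numpy as np
import pandas as pd
import pytest

from bdnfnet.genio import MISSING, GenotypeMatrix, SNPRecord


def make_genotypes(dosage, positions=None, chroms=None, ids=None):
    """Build a GenotypeMatrix from a dosage array with sensible metadata."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    positions = positions if positions is not None else [1000 * (j + 1) for j in range(m)]
    chroms = chroms if chroms is not None else ["1"] * m
    ids = ids if ids is not None else [f"rs{j}" for j in range(m)]
    variants = [SNPRecord(ids[j], str(chroms[j]), int(positions[j]), "A", "G")
                for j in range(m)]
    return GenotypeMatrix([f"s{i}" for i in range(n)], variants, dosage)


@pytest.fixture
def small_genotypes():
    rng = np.random.default_rng(42)
    return make_genotypes(rng.integers(0, 3, size=(30, 12)))


@pytest.fixture
def benign_record_fields():
    """Prenatal record field values that meet no adversity criterion."""
    return dict(money_hassles=2.0, cesd=10.0, stai=1.2, abuse_present=False,
                marital_strain=3.5, health_conditions=frozenset(), smoking=False,
                gestational_age=40.0, birth_percentile=50.0, income=60_000.0)
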