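import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import pleioscan as ps

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Two-family cohort with a handful of unrelated animals."""
    cfg = ps.PopulationConfig(
        n_sires=2,
        daughters_per_sire=20,
        n_unrelated=10,
        n_variants=60,
        chrom_length_bp=2_000_000,
        seed=7,
    )
    return ps.simulate_genotypes(cfg)


@pytest.fixture
def toy_genotypes():
    """3 individuals x 2 variants with hand-checkable dosages."""
    dosages = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
    variants = pd.DataFrame(
        {
            "variant_id": ["a", "b"],
            "chrom": "1",
            "pos": [100_001, 150_001],
            "ref": "A",
            "alt": "C",
        }
    )
    samples = pd.DataFrame({"sample_id": ["i1", "i2", "i3"]})
    return ps.Genotypes(dosages, variants, samples)
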