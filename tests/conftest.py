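import numpy as np
import pandas as pd
import pytest

from strat_spectrum import GenotypeMatrix


def make_gm(dosages, ids=None, positions=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix around a plain dosage array."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "chromosome": "1",
        "position": (np.arange(m) + 1) * 100 if positions is None else positions,
        "allele1": "A",
        "allele2": "G",
    })
    sids = ids if ids is not None else [f"s{i}" for i in range(n)]
    return GenotypeMatrix(dosages=d, sample_ids=np.array(sids, dtype=object),
                         variants=variants)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_pop_cohort():
    from strat_spectrum import SimulationConfig, simulate_cohort

    config = SimulationConfig(
        n_regions=2, samples_per_region=50,
        n_variants_by_stratum={"common": 500},
        ancestral_maf_spectrum={"common": ("uniform", 0.1, 0.5)},
        fst=0.3, private_rare_fraction=0.0,
        missing_rate=0.0, genotype_error_rate=0.0, seed=99)
    return simulate_cohort(config)
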