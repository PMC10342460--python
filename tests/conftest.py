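import numpy as np
import pandas as pd
import pytest

from bariscore.genotypes import GenotypeMatrix
from bariscore.manifest import SNPManifest, SNPVariant
from bariscore.simulate import SimulationConfig, simulate_cohort, simulate_covariates


@pytest.fixture(scope="session")
def default_manifest() -> SNPManifest:
    return SNPManifest.default()


@pytest.fixture
def small_manifest() -> SNPManifest:
    return SNPManifest(
        [
            SNPVariant("GENE1", "rs1", "A", "G", 0.3),
            SNPVariant("GENE1", "rs2", "C", "T", 0.2),
            SNPVariant("GENE2", "rs3", "T", "A", 0.45),
        ]
    )


@pytest.fixture
def small_genotypes(small_manifest) -> GenotypeMatrix:
    dosage = np.array(
        [
            [0, 1, 2],
            [1, 0, 0],
            [2, -1, 1],
            [0, 2, 0],
            [1, 1, -1],
        ],
        dtype=np.int8,
    )
    ids = [f"P{i:04d}" for i in range(1, 6)]
    return GenotypeMatrix(patient_ids=ids, manifest=small_manifest, dosage=dosage)


@pytest.fixture
def covariates_375() -> pd.DataFrame:
    return simulate_covariates(SimulationConfig(n_patients=375, seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """A 375-patient cohort with no planted effects (shared across tests)."""
    cfg = SimulationConfig(n_patients=375, seed=20, missing_genotype_rate=0.02)
    return simulate_cohort(cfg) + (cfg,)
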