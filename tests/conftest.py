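import numpy as np
import pandas as pd
import pytest

from comorbigen.datatypes import GenotypeDataset
from comorbigen.synthetic_data import SimulationSpec, StudyData, simulate_study


def tiny_spec(**kw) -> SimulationSpec:
    base = dict(
        n_trait1=40, n_trait2=40, n_comorbid=25, n_control=60,
        n_variants=240, n_blocks=6, m1=20, m2=20, m12=10,
        effect_sd=0.08, seed=7,
    )
    base.update(kw)
    return SimulationSpec(**base)


@pytest.fixture(scope="session")
def small_study() -> StudyData:
    """A small but complete synthetic study shared across test modules."""
    return simulate_study(tiny_spec())


def binomial_genotypes(
    rng: np.random.Generator,
    n_samples: int,
    mafs: np.ndarray,
    prefix: str = "S",
    chrom: str = "1",
    spacing: int = 400_000,
) -> GenotypeDataset:
    """Independent Hardy-Weinberg genotypes at given allele frequencies.

    Variants are spaced far apart so no pair shares a clumping window.
    """
    m = len(mafs)
    dosages = rng.binomial(2, mafs[None, :], size=(n_samples, m)).astype(np.float32)
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": chrom,
            "pos": (1 + np.arange(m)) * spacing,
            "ea": "A",
            "nea": "G",
            "eaf": mafs,
            "info": np.nan,
        }
    )
    return GenotypeDataset([f"{prefix}{i}" for i in range(n_samples)], variants, dosages)
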