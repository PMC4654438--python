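import numpy as np
import pandas as pd
import pytest

from locuspop.genotype_io import GenotypeMatrix, SampleManifest
from locuspop.synthetic_data import SimulationConfig, study_default_config


SMALL_GROUPS = [
    ("AFR", [("YRI", 20), ("LWK", 20)]),
    ("EUR", [("CEU", 20), ("TSI", 20)]),
    ("EA", [("CHB", 20), ("JPT", 20)]),
    ("AM", [("MXL", 20), ("PUR", 20)]),
]


def small_config(seed=5, n_variants=300, **kw):
    """Study-shaped config scaled to desk size (4 groups x 2 pops x 20)."""
    cfg = study_default_config(seed, n_variants=n_variants, groups=SMALL_GROUPS,
                               index_snps=kw.pop("index_snps", 5), **kw)
    return cfg


@pytest.fixture(scope="session")
def small_sim():
    """One shared small structured simulation (phased, with LD block)."""
    from locuspop.synthetic_data import simulate_balding_nichols

    return simulate_balding_nichols(small_config())


@pytest.fixture()
def two_group_geno():
    """Deterministic 2-group, 10+10 diploid genotype set, p ~ 0.9 vs 0.1.

    Group 1: 8 hom-alt + 2 het (p = 18/20 = 0.9); group 2: 2 het,
    8 hom-ref (p = 2/20 = 0.1). Single locus.
    """
    g1 = [2] * 8 + [1] * 2
    g2 = [1] * 2 + [0] * 8
    dos = np.array([g1 + g2], dtype=np.int8)
    samples = [f"s{i}" for i in range(20)]
    geno = GenotypeMatrix(samples=samples, dosages=dos)
    labels = np.array(["A"] * 10 + ["B"] * 10)
    return geno, labels


def manifest_from_labels(samples, pops, groups):
    return SampleManifest(pd.DataFrame(
        {"sample": samples, "population": pops, "group": groups}))
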