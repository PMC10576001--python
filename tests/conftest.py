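import numpy as np
import pandas as pd
import pytest

from harscore import GenotypeMatrix, SimConfig, gen_study


def scaled_config(seed: int, **overrides) -> SimConfig:
    """Desk-scale study used throughout the suite: 4000 SNPs / 40 LD blocks,
    study-sized cohort (115 HC / 128 SZ) and default planted effects."""
    kw = dict(n_snps=4000, n_hars=240)
    kw.update(overrides)
    return SimConfig(seed=seed, **kw)


@pytest.fixture(scope="session")
def study():
    """One shared synthetic study (seed 11)."""
    return gen_study(scaled_config(11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20230)


def toy_genotypes(dosage, positions=None, chrom="1", ids=None) -> GenotypeMatrix:
    """Small literal GenotypeMatrix for hand-traced examples."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    ids = ids or [f"s{j}" for j in range(m)]
    positions = positions or [1000 * (j + 1) for j in range(m)]
    variants = pd.DataFrame({
        "id": ids,
        "chrom": [chrom] * m if isinstance(chrom, str) else chrom,
        "pos": positions,
        "counted_allele": ["A"] * m,
        "other_allele": ["G"] * m,
    })
    return GenotypeMatrix([f"i{k}" for k in range(n)], variants, dosage)
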