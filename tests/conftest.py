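"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from divland import GenotypeTable, SimulationConfig, simulate


def small_config(seed=0, **kw):
    """A 1-chromosome 1-Mb design with one planted island, fast to simulate."""
    defaults = dict(
        seed=seed,
        n_chromosomes=1,
        chrom_length_bp=1_000_000,
        island_regions=[("chr1", 400_001, 440_000)],
        n_genes=120,
        n_cng=60,
        n_cndg=6,
        n_psg=6,
        n_env_snps=12,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_config(seed=11))


@pytest.fixture(scope="session")
def default_sim():
    """One study-scale simulation (2 x 5 Mb, 26+14 samples, 3 islands)."""
    return simulate(SimulationConfig(seed=5))


def toy_table(dosage, pos=None, species=None, populations=None):
    """Build a GenotypeTable from a (variants x samples) dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    m, n = dosage.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 10
    if species is None:
        half = n // 2
        species = ["X"] * half + ["Y"] * (n - half)
    return GenotypeTable(
        samples=[f"s{i}" for i in range(n)],
        species=np.array(species),
        chrom=np.array(["chr1"] * m, dtype=object),
        pos=np.array(pos),
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["T"] * m, dtype=object),
        dosage=dosage,
        populations=np.array(populations) if populations is not None else None,
    )
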