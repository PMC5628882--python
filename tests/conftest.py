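import numpy as np
import pandas as pd
import pytest

from aicvd.io_formats import GenotypeMatrix


def make_genotype_matrix(dosages, rsids=None, chromosome=1, positions=None,
                         sample_prefix="S", info=None):
    """Small hand-built GenotypeMatrix for unit tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    rsids = rsids or [f"rs{j + 1}" for j in range(m)]
    positions = positions if positions is not None else [1000 * (j + 1) for j in range(m)]
    meta = pd.DataFrame({
        "snp_id": [f"{chromosome}:{p}" for p in positions],
        "rsid": rsids,
        "chromosome": chromosome,
        "position": positions,
        "allele_A": "A",
        "allele_B": "G",
        "info_score": info if info is not None else np.nan,
        "genotyped": True,
    })
    return GenotypeMatrix(
        sample_ids=[f"{sample_prefix}{i + 1}" for i in range(n)],
        snp_meta=meta,
        dosages=dosages,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """One shared small planted-scenario study for integration-style tests."""
    from aicvd.simulate import planted_scenario, simulate_study

    spec = planted_scenario(seed=7, n_snps=520, snps_per_cluster=8,
                            cohort_scale=0.25)
    spec.n_controls = 250
    return simulate_study(spec)
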