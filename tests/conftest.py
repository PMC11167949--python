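import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from divscreen import popfreq, synthetic_data as sd, variant_io

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def pop_specs():
    pa = popfreq.PopulationSpec("A", tuple(f"A{i+1:03d}" for i in range(44)))
    pb = popfreq.PopulationSpec("B", tuple(f"B{i+1:03d}" for i in range(29)))
    return pa, pb


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A modest binomial-sampling cohort with a planted sweep region."""
    cfg = sd.SimulationConfig(
        n_sites=2_000,
        chrom_lengths={"1": 1_000_000, "2": 1_000_000},
        sweep_region=("1", 300_000, 500_000, "A"),
        n_genes=10,
        seed=7,
    )
    out = tmp_path_factory.mktemp("cohort")
    paths = sd.simulate_cohort(cfg, out)
    filtered = out / "filtered.vcf"
    report = variant_io.filter_vcf(paths.vcf, filtered)
    return {"config": cfg, "paths": paths, "filtered": filtered, "report": report}


@pytest.fixture(scope="session")
def small_truth(small_cohort):
    return pd.read_csv(small_cohort["paths"].truth, sep="\t", dtype={"chrom": str})


def random_called_genotypes(rng, n, p):
    """(n, 2) array of 0/1 alleles drawn at ALT frequency p."""
    return (rng.random((n, 2)) < p).astype(np.int8)
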