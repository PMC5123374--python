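import numpy as np
import pandas as pd
import pytest

from oxewas import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """A global-null cohort: no planted CpG, meQTL or disease effects."""
    cfg = SimConfig(
        n_samples=300,
        n_probes=400,
        n_snps=600,
        frac_true_cpg_effects=0.0,
        frac_cis_meqtl=0.0,
        disease_log_or_per_sd=0.0,
        genome_length=10_000_000,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """A small cohort with planted CpG-phenotype, meQTL and triad effects."""
    cfg = SimConfig(
        n_samples=400,
        n_probes=300,
        n_snps=1500,
        frac_true_cpg_effects=0.05,
        cpg_effect_size=0.4,
        frac_cis_meqtl=0.10,
        meqtl_r2=0.3,
        n_triads=1,
        triad_snp_marker_r2=0.08,
        genome_length=20_000_000,
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_regression_fixture(rng, n=30, n_cov=3):
    """A small random design: response, exposure and covariates."""
    X = rng.standard_normal((n, n_cov))
    x = rng.standard_normal(n)
    y = 0.5 * x + X @ rng.standard_normal(n_cov) * 0.3 + rng.standard_normal(n)
    cov = pd.DataFrame(X, columns=[f"c{j}" for j in range(n_cov)])
    return y, x, cov
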