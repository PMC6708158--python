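import numpy as np
import pandas as pd
import pytest

import epiclock as ec


def beta_matrix(n, m, seed=0, prefix="p"):
    """A random valid beta matrix for unit tests."""
    rng = np.random.default_rng(seed)
    b = rng.beta(2.0, 2.0, size=(n, m))
    return ec.MethylationMatrix(
        pd.DataFrame(
            b,
            index=[f"s{i:03d}" for i in range(n)],
            columns=[f"{prefix}{j:04d}" for j in range(m)],
        )
    )


@pytest.fixture(scope="session")
def small_world():
    """Two-cohort world used by several I/O and model tests."""
    cfg = ec.SimulationConfig(
        n_samples=(60, 60),
        age_ranges=((20.0, 70.0), (40.0, 90.0)),
        n_probes=200,
        n_causal=30,
        target_rho2=0.8,
        seed=13,
    )
    matrix, pheno, truth = ec.simulate_world(cfg)
    return cfg, matrix, pheno, truth


@pytest.fixture(scope="session")
def clean_world():
    """Single-cohort, confounder-free world for variance-component tests."""
    cfg = ec.SimulationConfig(
        n_samples=(300,),
        age_ranges=((20.0, 90.0),),
        n_probes=600,
        n_causal=120,
        target_rho2=0.6,
        confounding_strength=0.0,
        batch_sd=0.0,
        seed=21,
    )
    matrix, pheno, truth = ec.simulate_world(cfg)
    ages = pheno.set_index("sample_id").loc[matrix.sample_ids, "age"]
    return cfg, matrix, ages, truth
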