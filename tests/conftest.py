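import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trial(
    n_geno=6,
    n_reps=3,
    trial="T1",
    sigma_e=0.3,
    geno_effects=None,
    mu=5.0,
    seed=0,
    block_size=None,
    covariates=False,
):
    """Balanced single-trial plot records (one block per rep unless block_size)."""
    rng = np.random.default_rng(seed)
    genos = [f"G{k + 1}" for k in range(n_geno)]
    if geno_effects is None:
        geno_effects = rng.normal(0, 0.5, n_geno)
    rows = []
    for r in range(1, n_reps + 1):
        for k, g in enumerate(genos):
            block = 1 if block_size is None else k // block_size + 1
            y = mu + geno_effects[k] + rng.normal(0, sigma_e)
            row = {"trial": trial, "genotype": g, "rep": r, "block": block,
                   "yield_t_ha": y}
            if covariates:
                row["dtf_days"] = 90 + rng.normal(0, 5)
                row["height_cm"] = 100 + rng.normal(0, 8)
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def balanced_trial():
    return make_trial(seed=3)


@pytest.fixture
def full_sib_pedigree():
    """Two unrelated founders A, B and their full sibs X, Y."""
    from eratrend.kinship import Pedigree

    return Pedigree(pd.DataFrame(
        {"genotype": ["A", "B", "X", "Y"],
         "parent1": ["", "", "A", "A"],
         "parent2": ["", "", "B", "B"]}
    ))


@pytest.fixture
def small_gxe_table():
    """Complete 5 genotypes x 3 environments table with uniform SEs."""
    from eratrend.stage2 import GxETable

    rng = np.random.default_rng(7)
    genos = [f"G{k}" for k in range(1, 6)]
    trials = ["E1_2021", "E2_2021", "E3_2021"]
    vals = 4.0 + rng.normal(0, 0.8, (5, 3))
    blues = pd.DataFrame(vals, index=genos, columns=trials)
    ses = pd.DataFrame(0.2, index=genos, columns=trials)
    return GxETable(blues, ses)
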