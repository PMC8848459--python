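"""Shared fixtures: small synthetic datasets with known ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from admixdelim.simgen import (
    PopulationModel,
    SimConfig,
    simulate_allele_frequencies,
    simulate_dataset,
    simulate_genotypes,
)


def match_q_columns(q_hat: np.ndarray, q_true: np.ndarray) -> np.ndarray:
    """Reorder estimated ancestry columns to best match the truth."""
    cost = -(q_true.T @ q_hat)
    rows, cols = linear_sum_assignment(cost)
    return q_hat[:, cols[np.argsort(rows)]]


@pytest.fixture(scope="session")
def bn_three_pop():
    """Balding-Nichols data: K=3, F=0.2, n=60 with a few admixed rows."""
    pops = ["P1", "P2", "P3"]
    model = PopulationModel(pops, drift={p: 0.2 for p in pops})
    freqs = simulate_allele_frequencies(model, 5000, seed=11)
    rng = np.random.default_rng(17)
    rows, names = [], []
    for i in range(60):
        q = np.zeros(3)
        if i % 10 == 9:  # 10% admixed individuals
            q[:] = rng.dirichlet([1.0, 1.0, 1.0])
        else:
            q[i % 3] = 1.0
        rows.append(q)
        names.append(f"s{i:02d}")
    q_true = pd.DataFrame(rows, index=names, columns=pops)
    gm = simulate_genotypes(freqs, q_true, SimConfig(seed=13, n_loci=40))
    return gm, q_true


@pytest.fixture(scope="session")
def coalescent_dataset():
    """Small MSC dataset: 2 clades of 2 populations plus an outgroup."""
    nwk = "((((X1:2,X2:2):3,(Y1:2,Y2:2):3):5,out:10):1)root;"
    model = PopulationModel(["X1", "X2", "Y1", "Y2", "out"], tree=nwk)
    cfg = SimConfig(
        n_loci=20, locus_length=400, mutation_rate=0.01,
        samples_per_population=3, seed=7,
    )
    return simulate_dataset(model, cfg)
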