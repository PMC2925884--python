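import numpy as np
import pandas as pd
import pytest

from adrpath import docking, synthetic
from adrpath.io import Direction, DockingScoreMatrix


@pytest.fixture(scope="session")
def small_bundle():
    """Small planted-effect bundle shared by integration-level tests."""
    params = synthetic.SyntheticParams(
        n_drugs=120, n_proteins=60, n_pathways=10, n_adrs=6, n_planted=2
    )
    return synthetic.generate_synthetic(params, seed=11)


def bundle_to_xy(bundle):
    best = docking.merge_pockets(bundle.docking)
    z = docking.normalize_scores(best, bundle.docking.better_direction)
    called = docking.call_interactions(z)
    X = docking.build_pathway_features(
        called, bundle.pathway_map, drugs=list(bundle.drugs.drug_id)
    )
    Y = bundle.adr_matrix().reindex(X.index)
    return X, Y


@pytest.fixture(scope="session")
def small_xy(small_bundle):
    return bundle_to_xy(small_bundle)


@pytest.fixture
def docking_matrix():
    entries = pd.DataFrame(
        {
            "drug_id": ["d1", "d1", "d1", "d2", "d2"],
            "protein_id": ["p1", "p1", "p2", "p1", "p2"],
            "pocket_id": [1, 2, 1, 1, 2],
            "raw_score": [-8.2, -6.1, -3.0, -5.0, -4.0],
        }
    )
    return DockingScoreMatrix(entries, Direction.LOWER)


def logistic_instance(rng, n, p, sparsity=0.5):
    """Random non-separable logistic instance with standardized features."""
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = rng.normal(scale=0.8, size=p) * (rng.random(p) < sparsity)
    eta = 0.3 * rng.normal() + X @ beta
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    if y.min() == y.max():  # force both classes
        y[0], y[1] = 0.0, 1.0
    return X, y
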