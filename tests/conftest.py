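import logging

import numpy as np
import pytest

from heatconn.data_io import build_edge_weights
from heatconn.model import GraphBatch, make_graph_batch
from heatconn.synthetic import SimConfig, simulate_cohort

logging.getLogger("heatconn").setLevel(logging.ERROR)


def random_adjacency(n: int, rng: np.random.Generator, density: float = 0.4
                     ) -> np.ndarray:
    """Random symmetric nonnegative hollow adjacency, guaranteed connected."""
    a = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    w = rng.random(iu[0].size) * (rng.random(iu[0].size) < density)
    a[iu] = w
    a = a + a.T
    # spanning path ensures a single connected component
    for i in range(n - 1):
        if a[i, i + 1] == 0:
            a[i, i + 1] = a[i + 1, i] = 0.5 + rng.random()
    return a


@pytest.fixture(scope="session")
def tiny_cohort():
    cfg = SimConfig(n_subjects=16, n_rois=20, timepoints=50,
                    n_networks=4, age_networks=(("FRNT", "MEM"),), seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_batch(tiny_cohort) -> GraphBatch:
    cohort, _ = tiny_cohort
    return make_graph_batch(cohort)


def manual_batch(rng: np.random.Generator, s: int = 3, n: int = 8,
                 modalities=("emoid", "nback")) -> GraphBatch:
    """Small synthetic GraphBatch built directly from random features."""
    features, adjacency, eigvals, eigvecs = {}, {}, {}, {}
    for m in modalities:
        x = rng.standard_normal((s, n, n))
        adjs = np.stack([build_edge_weights(np.abs(x[i]) + 0.1, density=0.5)
                         for i in range(s)])
        laps = np.stack([np.diag(a.sum(1)) - a for a in adjs])
        lam, u = np.linalg.eigh(laps)
        features[m], adjacency[m] = x, adjs
        eigvals[m], eigvecs[m] = lam, u
    ages = rng.uniform(8, 22, size=s)
    sexes = (rng.random(s) < 0.5).astype(float)
    return GraphBatch(modalities=tuple(modalities), features=features,
                      adjacency=adjacency, eigvals=eigvals, eigvecs=eigvecs,
                      ages=ages, sexes=sexes,
                      subject_ids=[f"s{i}" for i in range(s)])
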