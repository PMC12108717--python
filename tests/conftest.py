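import numpy as np
import pytest

from simnmf import (
    AssociationMatrix,
    Hyperparameters,
    LatentFactors,
    SimilarityMatrix,
    canonicalize_similarity,
)


def random_instance(rng, n, m, k, mu=0.1, lam=0.2, density=0.3):
    """Random conforming (A, F, Sd, Se, h) tuple for oracle comparisons."""
    A = AssociationMatrix(
        (rng.random((n, m)) < density).astype(float),
        [f"DR{i:03d}" for i in range(n)],
        [f"DS{j:03d}" for j in range(m)],
    )
    F = LatentFactors(rng.random((k, n)), rng.random((k, m)))
    Sd = SimilarityMatrix(canonicalize_similarity(rng.random((n, n)))[0], A.drug_ids)
    Se = SimilarityMatrix(canonicalize_similarity(rng.random((m, m)))[0], A.disease_ids)
    h = Hyperparameters(k=k, mu=mu, lam=lam, seed=0)
    return A, F, Sd, Se, h


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_instance(rng):
    return random_instance(rng, n=6, m=5, k=2)
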