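"""Planted-structure benchmark generator.

Emulates the structure of the drug-repositioning gold-standard bundles
(a sparse binary association matrix plus drug/drug and disease/disease
similarity matrices) with known ground truth: non-negative latent factors
X*, Y* are drawn first, the association matrix is the top-density slice
of X*.T @ Y*, and the similarity matrices are the factor Gram matrices
plus optional symmetric Gaussian noise.  Everything is deterministic
given the seed.

No attempt is made to imitate the value distributions of real chemical-
structure or phenotype-ontology similarities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    AssociationMatrix,
    DatasetBundle,
    LatentFactors,
    SimilarityMatrix,
    canonicalize_similarity,
)
from .errors import ConfigurationError

__all__ = ["SyntheticSpec", "generate"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted benchmark instance.

    Parameters
    ----------
    n, m
        Numbers of drugs and diseases.
    k_true
        Planted latent rank; must be < min(n, m).
    density
        Exact fraction of 1-cells in the association matrix (the count is
        ``round(density * n * m)``, placed on the top-scoring cells).
    sim_noise
        Standard deviation of the symmetric Gaussian perturbation added
        to the Gram similarity matrices before canonicalization; 0 gives
        noise-free similarities.
    seed
        Seed driving factor draws and noise.
    """

    n: int = 100
    m: int = 80
    k_true: int = 8
    density: float = 0.1
    sim_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.m < 2:
            raise ConfigurationError("need at least 2 drugs and 2 diseases")
        if not 0.0 < self.density < 1.0:
            raise ConfigurationError(f"density must lie in (0, 1), got {self.density}")
        if self.k_true >= min(self.n, self.m):
            raise ConfigurationError(
                f"k_true={self.k_true} must be < min(n, m) = {min(self.n, self.m)}"
            )
        if self.sim_noise < 0:
            raise ConfigurationError("sim_noise must be >= 0")
        if round(self.density * self.n * self.m) < 1:
            raise ConfigurationError("density yields no positive cells")


def _noisy_gram(F: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    gram = F.T @ F
    if noise > 0:
        q = gram.shape[0]
        upper = rng.normal(0.0, noise, size=(q, q))
        sym = np.triu(upper, k=1)
        gram = gram + sym + sym.T  # diagonal untouched; canonicalization fixes it
    return canonicalize_similarity(gram)[0]


def generate(
    spec: SyntheticSpec,
) -> tuple[DatasetBundle, LatentFactors, frozenset[tuple[int, int]]]:
    """Generate a planted instance.

    Returns the aligned bundle (A, Sd, Se), the planted factors, and the
    set of planted-positive cells (row, column indices of the A = 1
    entries).  Positive cells are the ``round(density * n * m)``
    top-scoring cells of ``X*.T @ Y*``; score ties are broken by cell
    index so the count is exact and reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.uniform(0.0, 1.0, size=(spec.k_true, spec.n))
    Y = rng.uniform(0.0, 1.0, size=(spec.k_true, spec.m))
    # unit-norm columns: Gram diagonals become exactly 1, matching the
    # canonical self-similarity convention
    X /= np.linalg.norm(X, axis=0, keepdims=True)
    Y /= np.linalg.norm(Y, axis=0, keepdims=True)

    scores = X.T @ Y
    n_pos = int(round(spec.density * spec.n * spec.m))
    flat = scores.ravel()
    top = np.argsort(-flat, kind="stable")[:n_pos]
    A = np.zeros(spec.n * spec.m)
    A[top] = 1.0
    A = A.reshape(spec.n, spec.m)

    drug_ids = tuple(f"DR{i:04d}" for i in range(spec.n))
    disease_ids = tuple(f"DS{j:04d}" for j in range(spec.m))
    bundle = DatasetBundle(
        A=AssociationMatrix(A, drug_ids, disease_ids),
        Sd=SimilarityMatrix(_noisy_gram(X, spec.sim_noise, rng), drug_ids),
        Se=SimilarityMatrix(_noisy_gram(Y, spec.sim_noise, rng), disease_ids),
        provenance=f"synthetic planted instance, seed={spec.seed}",
    )
    truth = frozenset((int(i), int(j)) for i, j in np.argwhere(A == 1.0))
    return bundle, LatentFactors(X, Y), truth
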