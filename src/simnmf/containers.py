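"""Core data containers for similarity-constrained NMF.

The model operates on three matrices: a binary drug-disease association
matrix ``A`` (n drugs x m diseases), a drug-drug similarity matrix ``Sd``
(n x n) and a disease-disease similarity matrix ``Se`` (m x m).  ``A`` is
factorized as ``A ~ X.T @ Y`` with non-negative latent factors
``X`` (k x n) and ``Y`` (k x m); the similarity matrices constrain the
factor Gram matrices ``X.T @ X`` and ``Y.T @ Y``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DimensionError, DomainError

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "Hyperparameters",
    "LatentFactors",
    "ScoreMatrix",
    "FitTrace",
    "DatasetBundle",
    "canonicalize_similarity",
]

#: absolute tolerance within which a similarity matrix must be symmetric
SYMMETRY_ATOL = 1e-8


def _check_ids(ids: Sequence[str], axis: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        raise DomainError(f"{axis} identifiers are not unique")
    return ids


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary n x m matrix of known drug-disease links.

    ``values[i, j] == 1`` records a known association between drug
    ``drug_ids[i]`` and disease ``disease_ids[j]``; 0 means *unknown*,
    not *absent* — unknown cells are the candidate pool for ranking.
    """

    values: np.ndarray
    drug_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise DimensionError("association matrix must be 2-dimensional")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "drug_ids", _check_ids(self.drug_ids, "drug"))
        object.__setattr__(self, "disease_ids", _check_ids(self.disease_ids, "disease"))
        n, m = values.shape
        if n != len(self.drug_ids) or m != len(self.disease_ids):
            raise DimensionError(
                f"association matrix is {n}x{m} but has {len(self.drug_ids)} drug "
                f"and {len(self.disease_ids)} disease identifiers"
            )
        bad = (values != 0.0) & (values != 1.0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise DomainError(
                f"association entry at drug {self.drug_ids[i]!r}, disease "
                f"{self.disease_ids[j]!r} is {values[i, j]!r}; entries must be 0 or 1"
            )

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.values.shape[1]

    @property
    def n_positives(self) -> int:
        return int(self.values.sum())

    def positive_cells(self) -> list[tuple[int, int]]:
        """Row/column indices of every known (A = 1) association."""
        return [tuple(map(int, c)) for c in np.argwhere(self.values == 1.0)]


def canonicalize_similarity(
    values: np.ndarray, *, atol: float = SYMMETRY_ATOL
) -> tuple[np.ndarray, dict]:
    """Bring a raw similarity matrix into canonical form.

    Symmetrizes via ``(S + S.T) / 2``, clips negative entries to 0 (the
    multiplicative update numerators require non-negativity) and sets the
    diagonal to 1, the conventional self-similarity.  Idempotent.

    Returns the canonical matrix and a report of what was changed:
    ``max_asymmetry``, ``n_clipped``, ``n_diagonal_changed``.
    """
    S = np.asarray(values, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise DimensionError(f"similarity matrix must be square, got shape {S.shape}")
    if not np.isfinite(S).all():
        raise DomainError("similarity matrix contains non-finite entries")
    max_asym = float(np.abs(S - S.T).max()) if S.size else 0.0
    out = (S + S.T) / 2.0
    n_clipped = int((out < 0).sum())
    out = np.clip(out, 0.0, None)
    diag = np.diagonal(out)
    n_diag = int((diag != 1.0).sum())
    np.fill_diagonal(out, 1.0)
    report = {
        "max_asymmetry": max_asym,
        "n_clipped": n_clipped,
        "n_diagonal_changed": n_diag,
    }
    return out, report


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric non-negative similarity matrix with identifiers.

    Entries quantify pairwise similarity between drugs (or diseases);
    the diagonal is the unit self-similarity.  Construction validates the
    invariants; use :func:`canonicalize_similarity` (or
    :meth:`from_raw`) to repair a raw matrix first.
    """

    values: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ids", _check_ids(self.ids, "similarity"))
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise DimensionError(f"similarity matrix must be square, got {values.shape}")
        if values.shape[0] != len(self.ids):
            raise DimensionError(
                f"similarity matrix is {values.shape[0]}x{values.shape[1]} "
                f"but has {len(self.ids)} identifiers"
            )
        if values.size:
            if np.abs(values - values.T).max() > SYMMETRY_ATOL:
                raise DomainError("similarity matrix is not symmetric within 1e-8")
            if values.min() < 0:
                raise DomainError("similarity matrix has negative entries")

    @classmethod
    def from_raw(
        cls, values: np.ndarray, ids: Sequence[str], *, warn: bool = True
    ) -> "SimilarityMatrix":
        """Canonicalize a raw matrix and wrap it, warning about repairs."""
        canon, report = canonicalize_similarity(values)
        if warn and (
            report["max_asymmetry"] > SYMMETRY_ATOL
            or report["n_clipped"]
            or report["n_diagonal_changed"]
        ):
            warnings.warn(
                "similarity matrix canonicalized: "
                f"max asymmetry {report['max_asymmetry']:.3g}, "
                f"{report['n_clipped']} negative entries clipped, "
                f"{report['n_diagonal_changed']} diagonal entries set to 1",
                stacklevel=2,
            )
        return cls(canon, tuple(ids))

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class Hyperparameters:
    """Model and optimizer settings.

    Parameters
    ----------
    k
        Latent dimension; must satisfy ``k < min(n, m)`` at fit time.
    mu
        Tikhonov weight on ``||X||_F^2 + ||Y||_F^2``; stabilizes the fit.
    lam
        Similarity weight on ``||X.T X - Sd||_F^2 + ||Y.T Y - Se||_F^2``;
        injects the biological context.
    max_iter
        Maximum number of alternating multiplicative updates.
    tol
        Relative objective-change stopping tolerance; 0 disables early stop.
    eps
        Small additive guard on update denominators.
    seed
        Seed for factor initialization; all randomness flows from it.
    """

    k: int = 50
    mu: float = 0.1
    lam: float = 0.1
    max_iter: int = 1000
    tol: float = 1e-6
    eps: float = 1e-12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError(f"latent dimension k must be positive, got {self.k}")
        if self.mu < 0 or self.lam < 0:
            raise ConfigurationError("regularization weights mu and lam must be >= 0")
        if self.max_iter < 0:
            raise ConfigurationError("max_iter must be >= 0")
        if self.tol < 0:
            raise ConfigurationError("tol must be >= 0")
        if self.eps <= 0:
            raise ConfigurationError("eps must be > 0")


@dataclass(frozen=True)
class LatentFactors:
    """The non-negative factor pair (X: k x n drugs, Y: k x m diseases)."""

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.float64)
        Y = np.asarray(self.Y, dtype=np.float64)
        if X.ndim != 2 or Y.ndim != 2:
            raise DimensionError("latent factors must be 2-dimensional")
        if X.shape[0] != Y.shape[0]:
            raise DimensionError(
                f"factor ranks disagree: X is {X.shape}, Y is {Y.shape}"
            )
        if (X.size and X.min() < 0) or (Y.size and Y.min() < 0):
            raise DomainError("latent factors must be non-negative")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)

    @property
    def k(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class ScoreMatrix:
    """Reconstructed association scores, ``values = X.T @ Y``."""

    values: np.ndarray
    drug_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "drug_ids", _check_ids(self.drug_ids, "drug"))
        object.__setattr__(self, "disease_ids", _check_ids(self.disease_ids, "disease"))
        if values.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise DimensionError("score matrix shape does not match identifier lists")


@dataclass(frozen=True)
class FitTrace:
    """Objective trajectory of a fit.

    ``objective_per_iter[0]`` is the objective at initialization, so the
    sequence has ``iterations_run + 1`` entries.
    """

    objective_per_iter: tuple[float, ...]
    iterations_run: int
    converged: bool

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "objective_per_iter", tuple(float(v) for v in self.objective_per_iter)
        )
        if len(self.objective_per_iter) != self.iterations_run + 1:
            raise ConfigurationError(
                "objective trace length must equal iterations_run + 1"
            )


@dataclass(frozen=True)
class DatasetBundle:
    """An aligned triple (A, Sd, Se) ready for fitting."""

    A: AssociationMatrix
    Sd: SimilarityMatrix
    Se: SimilarityMatrix
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.Sd.ids != self.A.drug_ids:
            raise DimensionError("drug similarity identifiers do not match A's drug order")
        if self.Se.ids != self.A.disease_ids:
            raise DimensionError(
                "disease similarity identifiers do not match A's disease order"
            )
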