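"""Objective, multiplicative updates and fit loop.

The model minimizes, over non-negative factors X (k x n) and Y (k x m),

    L(X, Y) = ||A - X.T Y||_F^2
            + mu * (||X||_F^2 + ||Y||_F^2)
            + lam * (||X.T X - Sd||_F^2 + ||Y.T Y - Se||_F^2)

where A is the binary association matrix and Sd, Se are drug and disease
similarity matrices.  With mu = lam = 0 this is standard NMF; with lam = 0
it is Tikhonov-regularized NMF.  Optimization alternates the multiplicative
updates

    X <- X * (Y A.T + 2 lam X Sd) / (Y Y.T X + mu X + 2 lam X X.T X)
    Y <- Y * (X A  + 2 lam Y Se) / (X X.T Y + mu Y + 2 lam Y Y.T Y)

(elementwise product and division, denominators guarded by eps), which
follow from the KKT conditions of the non-negativity-constrained problem
and preserve non-negativity by construction.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .containers import (
    AssociationMatrix,
    FitTrace,
    Hyperparameters,
    LatentFactors,
    ScoreMatrix,
    SimilarityMatrix,
)
from .errors import ConfigurationError, DimensionError, NumericError

__all__ = [
    "objective_value",
    "update_x",
    "update_y",
    "gradients",
    "init_factors",
    "fit",
    "predict",
    "rank_candidates",
]

logger = logging.getLogger(__name__)

#: objective is logged every LOG_EVERY iterations during fit
LOG_EVERY = 50


def _check_shapes(
    A: AssociationMatrix,
    F: LatentFactors,
    Sd: SimilarityMatrix | None,
    Se: SimilarityMatrix | None,
) -> None:
    n, m = A.values.shape
    if F.X.shape[1] != n:
        raise DimensionError(f"X has {F.X.shape[1]} columns but A has {n} drugs")
    if F.Y.shape[1] != m:
        raise DimensionError(f"Y has {F.Y.shape[1]} columns but A has {m} diseases")
    if Sd is not None and Sd.size != n:
        raise DimensionError(f"Sd is {Sd.size}x{Sd.size} but A has {n} drugs")
    if Se is not None and Se.size != m:
        raise DimensionError(f"Se is {Se.size}x{Se.size} but A has {m} diseases")


def _check_finite(name: str, *arrays: np.ndarray) -> None:
    for arr in arrays:
        if not np.isfinite(arr).all():
            raise NumericError(f"non-finite entries encountered in {name}")


def objective_value(
    A: AssociationMatrix,
    F: LatentFactors,
    Sd: SimilarityMatrix,
    Se: SimilarityMatrix,
    h: Hyperparameters,
) -> float:
    """Evaluate the regularized objective L(X, Y).

    Reduces to the plain NMF reconstruction loss when ``mu = lam = 0``
    and to the Tikhonov model when ``lam = 0``.
    """
    _check_shapes(A, F, Sd, Se)
    X, Y = F.X, F.Y
    recon = A.values - X.T @ Y
    value = float(np.sum(recon * recon))
    if h.mu != 0.0:
        value += h.mu * float(np.sum(X * X) + np.sum(Y * Y))
    if h.lam != 0.0:
        rd = X.T @ X - Sd.values
        re = Y.T @ Y - Se.values
        value += h.lam * float(np.sum(rd * rd) + np.sum(re * re))
    return value


def update_x(
    A: AssociationMatrix,
    F: LatentFactors,
    Sd: SimilarityMatrix,
    h: Hyperparameters,
) -> np.ndarray:
    """One multiplicative update of the drug factor X.

    Entries that are exactly 0 stay 0 (the rule is a ratio scaled by the
    current entry), so zeros are locked for the rest of the fit.
    """
    X, Y = F.X, F.Y
    _check_finite("update_x inputs", A.values, X, Y, Sd.values)
    numer = Y @ A.values.T + 2.0 * h.lam * (X @ Sd.values)
    denom = (Y @ Y.T) @ X + h.mu * X + 2.0 * h.lam * (X @ X.T) @ X
    return X * numer / (denom + h.eps)


def update_y(
    A: AssociationMatrix,
    F: LatentFactors,
    Se: SimilarityMatrix,
    h: Hyperparameters,
) -> np.ndarray:
    """One multiplicative update of the disease factor Y (mirror of X)."""
    X, Y = F.X, F.Y
    _check_finite("update_y inputs", A.values, X, Y, Se.values)
    numer = X @ A.values + 2.0 * h.lam * (Y @ Se.values)
    denom = (X @ X.T) @ Y + h.mu * Y + 2.0 * h.lam * (Y @ Y.T) @ Y
    return Y * numer / (denom + h.eps)


def gradients(
    A: AssociationMatrix,
    F: LatentFactors,
    Sd: SimilarityMatrix,
    Se: SimilarityMatrix,
    h: Hyperparameters,
) -> tuple[np.ndarray, np.ndarray]:
    """Partial derivatives of L with respect to X and Y (multipliers dropped).

    Used for KKT stationarity diagnostics: at a constrained stationary
    point, ``min(X, dL/dX)`` and ``min(Y, dL/dY)`` vanish elementwise.
    """
    _check_shapes(A, F, Sd, Se)
    X, Y = F.X, F.Y
    gX = -Y @ A.values.T + (Y @ Y.T) @ X + h.mu * X + 2.0 * h.lam * (
        (X @ X.T) @ X - X @ Sd.values
    )
    gY = -X @ A.values + (X @ X.T) @ Y + h.mu * Y + 2.0 * h.lam * (
        (Y @ Y.T) @ Y - Y @ Se.values
    )
    return gX, gY


def init_factors(
    A: AssociationMatrix, h: Hyperparameters
) -> LatentFactors:
    """Seeded random initialization.

    Entries are i.i.d. uniform on (0, 1) scaled by ``2 sqrt(mean(A) / k)``
    so the initial reconstruction sits on A's scale: with that factor the
    expected entry of ``X.T Y`` equals ``mean(A)`` exactly.  An
    under-scaled start makes the first multiplicative step overshoot
    (each ratio is far above 1), which can increase the objective before
    descent sets in.  For an all-zero A the scale degenerates to 0 and
    would lock the factors at 0 forever, so a fallback of ``1 / k`` is
    used instead.
    """
    n, m = A.values.shape
    if h.k >= min(n, m):
        raise ConfigurationError(
            f"latent dimension k={h.k} must be < min(n, m) = {min(n, m)}"
        )
    mean_a = float(A.values.mean()) if A.values.size else 0.0
    if mean_a == 0.0:
        warnings.warn(
            "association matrix has no known links; factors initialized on "
            "a nominal 1/k scale",
            stacklevel=2,
        )
        scale = 1.0 / h.k
    else:
        scale = 2.0 * np.sqrt(mean_a / h.k)
    rng = np.random.default_rng(h.seed)
    X = rng.uniform(0.0, 1.0, size=(h.k, n)) * scale
    Y = rng.uniform(0.0, 1.0, size=(h.k, m)) * scale
    return LatentFactors(X, Y)


def fit(
    A: AssociationMatrix,
    Sd: SimilarityMatrix,
    Se: SimilarityMatrix,
    h: Hyperparameters,
) -> tuple[LatentFactors, FitTrace]:
    """Fit the factors by alternating multiplicative updates.

    Stops after ``max_iter`` iterations or as soon as the relative change
    of the objective falls below ``tol``, whichever comes first.  The
    returned trace records the objective at initialization and after each
    completed iteration.  Deterministic given ``h.seed``.
    """
    F = init_factors(A, h)
    _check_shapes(A, F, Sd, Se)
    objectives = [objective_value(A, F, Sd, Se, h)]
    converged = False
    iterations = 0
    for it in range(h.max_iter):
        X_new = update_x(A, F, Sd, h)
        F = LatentFactors(X_new, F.Y)
        Y_new = update_y(A, F, Se, h)
        F = LatentFactors(F.X, Y_new)
        obj = objective_value(A, F, Sd, Se, h)
        objectives.append(obj)
        iterations = it + 1
        if iterations % LOG_EVERY == 0:
            logger.info("iteration %d: objective %.6g", iterations, obj)
        prev = objectives[-2]
        rel_change = abs(prev - obj) / max(abs(prev), h.eps)
        if h.tol > 0 and rel_change < h.tol:
            converged = True
            break
    logger.info(
        "fit finished after %d iterations (converged=%s), objective %.6g",
        iterations,
        converged,
        objectives[-1],
    )
    return F, FitTrace(tuple(objectives), iterations, converged)


def predict(
    F: LatentFactors,
    drug_ids,
    disease_ids,
) -> ScoreMatrix:
    """Reconstruct the score matrix ``X.T @ Y`` with identifier labels."""
    scores = F.X.T @ F.Y
    return ScoreMatrix(scores, tuple(drug_ids), tuple(disease_ids))


def rank_candidates(
    scores: ScoreMatrix,
    A: AssociationMatrix,
    drug_id: str,
    top_k: int,
) -> list[tuple[str, float]]:
    """Top candidate diseases for one drug among its unknown pairs.

    Only cells with ``A = 0`` enter the pool; known associations are
    excluded.  Ties are broken by lexicographic disease identifier so the
    ranking is reproducible across runs and platforms.
    """
    if top_k < 1:
        raise ConfigurationError(f"top_k must be >= 1, got {top_k}")
    if scores.drug_ids != A.drug_ids or scores.disease_ids != A.disease_ids:
        raise DimensionError("score matrix identifiers do not match A's")
    try:
        row = scores.drug_ids.index(drug_id)
    except ValueError:
        raise KeyError(f"unknown drug identifier {drug_id!r}") from None
    pool = [
        (scores.disease_ids[j], float(scores.values[row, j]))
        for j in range(A.n_diseases)
        if A.values[row, j] == 0.0
    ]
    pool.sort(key=lambda item: (-item[1], item[0]))
    return pool[:top_k]
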