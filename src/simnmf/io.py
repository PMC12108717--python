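"""Labeled-matrix and prediction-table I/O.

Matrices travel as delimited text (TSV by default, comma accepted): first
row = column identifiers, first column = row identifiers.  Benchmark
association matrices circulate in either orientation (drugs-as-rows or
diseases-as-rows); the reader accepts both via the ``orientation`` flag.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    AssociationMatrix,
    DatasetBundle,
    Hyperparameters,
    SimilarityMatrix,
)
from .errors import AlignmentError, DimensionError, ParseError

__all__ = [
    "read_labeled_matrix",
    "write_labeled_matrix",
    "align_bundle",
    "write_predictions",
    "read_predictions",
    "write_run_metadata",
]

logger = logging.getLogger(__name__)


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # sep=None sniffs tab vs comma from the file
    frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = frame.index[int(np.argmax(bad.to_numpy()))]
            raise ParseError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
                f"{frame.loc[row, col]!r}"
            )
        if coerced.isna().any():
            row = frame.index[int(np.argmax(coerced.isna().to_numpy()))]
            raise ParseError(f"{path}: missing value at row {row!r}, column {col!r}")
        frame[col] = coerced
    return frame


def read_labeled_matrix(
    path: str | Path,
    kind: str,
    orientation: str = "drugs-rows",
) -> AssociationMatrix | SimilarityMatrix:
    """Read a labeled matrix from delimited text.

    Parameters
    ----------
    kind
        ``"association"`` — entries validated as {0, 1} — or
        ``"similarity"`` — square, canonicalized (symmetrize, clip
        negatives, unit diagonal) with any repair logged.
    orientation
        For associations only: ``"drugs-rows"`` (default) or
        ``"diseases-rows"`` (the table is transposed after reading).
    """
    frame = _read_frame(path)
    if kind == "association":
        if orientation == "diseases-rows":
            frame = frame.T
        elif orientation != "drugs-rows":
            raise ParseError(f"unknown orientation {orientation!r}")
        values = frame.to_numpy(dtype=np.float64)
        bad = (values != 0.0) & (values != 1.0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ParseError(
                f"{path}: association entry at row {frame.index[i]!r}, column "
                f"{frame.columns[j]!r} is {values[i, j]!r}; must be 0 or 1"
            )
        return AssociationMatrix(values, tuple(frame.index), tuple(frame.columns))
    if kind == "similarity":
        if frame.shape[0] != frame.shape[1]:
            raise DimensionError(
                f"{path}: similarity matrix must be square, got {frame.shape}"
            )
        if tuple(frame.index) != tuple(frame.columns):
            raise AlignmentError(
                f"{path}: similarity row and column identifiers differ"
            )
        from .containers import canonicalize_similarity

        canon, report = canonicalize_similarity(frame.to_numpy(dtype=np.float64))
        if report["max_asymmetry"] > 0 or report["n_clipped"] or report["n_diagonal_changed"]:
            logger.warning(
                "%s: canonicalized similarity matrix (max asymmetry %.3g, "
                "%d negatives clipped, %d diagonal entries set to 1)",
                path,
                report["max_asymmetry"],
                report["n_clipped"],
                report["n_diagonal_changed"],
            )
        return SimilarityMatrix(canon, tuple(frame.index))
    raise ParseError(f"unknown matrix kind {kind!r}")


def write_labeled_matrix(
    values: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    path: str | Path,
    sep: str = "\t",
) -> Path:
    """Write a labeled matrix as delimited text (12 significant digits)."""
    path = Path(path)
    frame = pd.DataFrame(np.asarray(values), index=list(row_ids), columns=list(col_ids))
    frame.to_csv(path, sep=sep, float_format="%.12g")
    return path


def align_bundle(
    A: AssociationMatrix,
    Sd: SimilarityMatrix,
    Se: SimilarityMatrix,
    provenance: str = "",
) -> DatasetBundle:
    """Reorder/subset the similarity matrices to A's identifier order.

    Similarity matrices may carry extra identifiers (they are dropped and
    reported); a drug or disease of A missing from its similarity matrix
    is an error listing the missing identifiers.
    """

    def _align(S: SimilarityMatrix, wanted: tuple[str, ...], what: str) -> SimilarityMatrix:
        index = {s: i for i, s in enumerate(S.ids)}
        missing = [w for w in wanted if w not in index]
        if missing:
            raise AlignmentError(
                f"{what} similarity matrix is missing identifiers: {missing}"
            )
        extra = set(S.ids) - set(wanted)
        if extra:
            logger.info(
                "%s similarity matrix: dropping %d unmatched identifiers",
                what,
                len(extra),
            )
        order = [index[w] for w in wanted]
        return SimilarityMatrix(S.values[np.ix_(order, order)], wanted)

    return DatasetBundle(
        A=A,
        Sd=_align(Sd, A.drug_ids, "drug"),
        Se=_align(Se, A.disease_ids, "disease"),
        provenance=provenance,
    )


PREDICTION_COLUMNS = ("drug_id", "disease_id", "score", "rank")


def write_predictions(
    ranked: Mapping[str, Sequence[tuple[str, float]]], path: str | Path
) -> Path:
    """Write per-drug ranked candidate lists as a TSV.

    Columns: drug_id, disease_id, score, rank.  Scores are formatted with
    6 significant digits; an empty ranking yields a header-only file.
    """
    path = Path(path)
    rows = []
    for drug_id, candidates in ranked.items():
        for rank, (disease_id, score) in enumerate(candidates, start=1):
            rows.append((drug_id, disease_id, f"{score:.6g}", rank))
    frame = pd.DataFrame(rows, columns=list(PREDICTION_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_predictions(path: str | Path) -> dict[str, list[tuple[str, float]]]:
    """Read a prediction TSV back into per-drug ranked lists."""
    frame = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "disease_id": str})
    if tuple(frame.columns) != PREDICTION_COLUMNS:
        raise ParseError(
            f"{path}: expected columns {PREDICTION_COLUMNS}, got {tuple(frame.columns)}"
        )
    out: dict[str, list[tuple[str, float]]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(row.drug_id, []).append((row.disease_id, float(row.score)))
    return out


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_run_metadata(
    path: str | Path,
    seed: int,
    h: Hyperparameters | None = None,
    input_paths: Mapping[str, str | Path] | None = None,
    extra: Mapping | None = None,
) -> Path:
    """Record the seed, hyperparameters and input content hashes as JSON."""
    record: dict = {"seed": seed}
    if h is not None:
        record["hyperparameters"] = dataclasses.asdict(h)
    if input_paths:
        record["input_hashes"] = {
            name: _sha256(p) for name, p in input_paths.items()
        }
    if extra:
        record.update(extra)
    path = Path(path)
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return path
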