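"""Dissimilarity and heat-kernel similarity structures.

The retrieval engine is agnostic to how image dissimilarity is measured:
it consumes an ``N x N`` symmetric nonnegative matrix ``A`` produced by any
pairwise dissimilarity function (morphologic shape descriptors, texture
distances, ...).  This module validates and round-trips ``A``, converts it
to heat-kernel affinities ``W(i, j) = exp(-A(i, j) / sigma)``, and handles
per-query dissimilarity columns.

File dialect: comma-delimited text with an id header row and an id first
column, chosen for diff-ability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: asymmetries up to this size are treated as floating-point noise and
#: symmetrized by averaging; anything larger is a hard format error
ASYMMETRY_TOL = 1e-9


class FormatError(ValueError):
    """A dissimilarity file or matrix violates the required structure."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable signal."""


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Pairwise dissimilarities ``A`` over the database images.

    Attributes
    ----------
    ids : tuple of str
        Ordered image identifiers, length ``N``.
    values : ndarray of shape (N, N)
        Symmetric, nonnegative, zero-diagonal dissimilarities.
    """

    ids: tuple
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        _validate_dissimilarity(values, self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, image_id: str) -> int:
        return self.ids.index(str(image_id))

    def subset(self, indices: Sequence[int]) -> "DissimilarityMatrix":
        """Restrict the database to ``indices`` (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return DissimilarityMatrix(
            ids=tuple(self.ids[i] for i in idx),
            values=self.values[np.ix_(idx, idx)],
        )


@dataclass(frozen=True)
class SimilarityMatrix:
    """Heat-kernel affinities ``W`` (or the label-refined ``W^r``).

    Unsupervised entries lie in ``(0, 1]`` with a unit diagonal; the
    supervised refinement may boost same-class entries up to ``2 * W``.
    """

    values: np.ndarray = field(repr=False)
    sigma: float = 1.0
    supervised: bool = False

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise FormatError(f"similarity matrix must be square, got {values.shape}")
        if not np.allclose(values, values.T, rtol=0, atol=1e-12):
            raise FormatError("similarity matrix must be symmetric")
        if not np.all(np.isfinite(values)):
            raise FormatError("similarity matrix contains non-finite entries")
        # exp(-A/sigma) is mathematically positive but may underflow to 0
        # for far-apart pairs; that is how a graph becomes disconnected
        if np.any(values < 0):
            raise FormatError("similarity entries must be nonnegative")
        upper = 2.0 if self.supervised else 1.0 + 1e-12
        if np.any(values > upper):
            raise FormatError(
                f"similarity entries exceed the admissible bound {upper}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class QueryColumn:
    """Dissimilarities and affinities between one query and the database."""

    query_id: str
    dissimilarities: np.ndarray = field(repr=False)
    similarities: np.ndarray = field(repr=False)

    def __post_init__(self):
        d = np.asarray(self.dissimilarities, dtype=float)
        s = np.asarray(self.similarities, dtype=float)
        object.__setattr__(self, "dissimilarities", d)
        object.__setattr__(self, "similarities", s)
        if d.shape != s.shape or d.ndim != 1:
            raise FormatError("query vectors must be 1-D and of equal length")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise FormatError("query dissimilarities must be finite and >= 0")

    @property
    def n(self) -> int:
        return self.dissimilarities.shape[0]


def _validate_dissimilarity(values: np.ndarray, ids: Sequence[str]) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise FormatError(f"dissimilarity matrix must be square, got shape {values.shape}")
    n = values.shape[0]
    if n < 2:
        raise FormatError("dissimilarity matrix needs at least 2 images")
    if len(ids) != n:
        raise FormatError(f"{len(ids)} ids for a {n}x{n} matrix")
    if len(set(ids)) != n:
        raise FormatError("image ids must be unique")
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        i, j = bad[0]
        raise FormatError(f"non-finite entry at ({ids[i]}, {ids[j]})")
    bad = np.argwhere(values < 0)
    if bad.size:
        i, j = bad[0]
        raise FormatError(f"negative dissimilarity at ({ids[i]}, {ids[j]})")
    diag = np.abs(np.diag(values))
    if np.any(diag > ASYMMETRY_TOL):
        i = int(np.argmax(diag))
        raise FormatError(f"nonzero diagonal at ({ids[i]}, {ids[i]}): {values[i, i]}")
    asym = np.abs(values - values.T)
    if np.any(asym > ASYMMETRY_TOL):
        i, j = np.unravel_index(int(np.argmax(asym)), asym.shape)
        raise FormatError(
            f"asymmetric entries at ({ids[i]}, {ids[j]}): "
            f"{values[i, j]} vs {values[j, i]}"
        )


def from_values(values: np.ndarray, ids: Sequence | None = None) -> DissimilarityMatrix:
    """Build a validated :class:`DissimilarityMatrix` from an array.

    Sub-tolerance asymmetries and diagonal residue are cleaned up by
    averaging / zeroing; larger violations raise :class:`FormatError`.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise FormatError(f"dissimilarity matrix must be square, got shape {values.shape}")
    if ids is None:
        ids = [str(i) for i in range(values.shape[0])]
    ids = [str(i) for i in ids]
    _validate_dissimilarity(values, ids)
    clean = 0.5 * (values + values.T)
    np.fill_diagonal(clean, 0.0)
    return DissimilarityMatrix(ids=tuple(ids), values=clean)


def load_dissimilarity(path) -> DissimilarityMatrix:
    """Read a dissimilarity matrix from CSV (id header row, id first column)."""
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    row_ids = [str(i) for i in frame.index]
    col_ids = [str(c) for c in frame.columns]
    if row_ids != col_ids:
        raise FormatError(f"{path}: row ids and column ids disagree")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric entries ({exc})") from exc
    return from_values(values, row_ids)


def save_dissimilarity(matrix: DissimilarityMatrix, path) -> None:
    """Write the matrix in the same CSV dialect ``load_dissimilarity`` reads."""
    frame = pd.DataFrame(matrix.values, index=list(matrix.ids), columns=list(matrix.ids))
    frame.to_csv(path, float_format="%.17g")


def compute_similarity(A: DissimilarityMatrix, sigma: float) -> SimilarityMatrix:
    """Heat-kernel affinity ``W(i, j) = exp(-A(i, j) / sigma)``.

    ``sigma`` is the user-selected bandwidth; :func:`median_sigma` provides
    a scale-free default.  The diagonal is exactly 1.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    W = np.exp(-A.values / sigma)
    np.fill_diagonal(W, 1.0)
    return SimilarityMatrix(values=W, sigma=float(sigma), supervised=False)


def query_similarity(a_q: np.ndarray, sigma: float, query_id: str = "query") -> QueryColumn:
    """Affinity column ``W(i, q) = exp(-A(i, q) / sigma)`` for one query."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    a_q = np.asarray(a_q, dtype=float)
    if a_q.ndim != 1:
        raise FormatError("query dissimilarities must be a 1-D vector")
    if np.any(a_q < 0) or not np.all(np.isfinite(a_q)):
        raise FormatError("query dissimilarities must be finite and >= 0")
    return QueryColumn(
        query_id=str(query_id),
        dissimilarities=a_q,
        similarities=np.exp(-a_q / sigma),
    )


def median_sigma(A: DissimilarityMatrix) -> float:
    """Median off-diagonal dissimilarity, a scale-free bandwidth default.

    Falls back to the smallest positive entry when the median is 0; raises
    :class:`DegenerateInputError` when every off-diagonal entry is 0.
    """
    iu = np.triu_indices(A.n, k=1)
    offdiag = A.values[iu]
    med = float(np.median(offdiag))
    if med > 0:
        return med
    positive = offdiag[offdiag > 0]
    if positive.size:
        return float(positive.min())
    raise DegenerateInputError("all off-diagonal dissimilarities are zero")
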