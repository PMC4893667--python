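"""Out-of-sample placement of new queries in a precomputed embedding.

Re-solving the eigenproblem for every query costs O(N^3).  Instead, a new
point is extrapolated as an affinity-weighted combination of the database
embeddings (a Nystrom extension of the random-walk operator):

    y_q[k] = sum_i W(i, q) * y_i[k] / ((1 - lambda_k) * sum_i W(i, q))

which costs O(N * d) per query.  The normalization follows from the
in-sample identity of the generalized eigenproblem, ``D^-1 W y = (1 -
lambda) y``: extrapolating the affinity column of a database image returns
that image's stored coordinates exactly, which this module treats as its
correctness contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .affinity import (
    DissimilarityMatrix,
    QueryColumn,
    compute_similarity,
)
from .embedding import EmbeddingSpace, LabelAssignment, graph_embed, supervise_similarity

#: (1 - lambda_k) closer to zero than this is a division singularity
EIGENVALUE_GUARD = 1e-10


class EigenvalueSingularityError(ValueError):
    """An eigenvalue too close to 1 makes the extrapolation denominator vanish."""


class IsolationError(ValueError):
    """The query has no affinity to any database image."""


@dataclass(frozen=True)
class ExtrapolatedEmbedding:
    """Embedding coordinates of a query placed by out-of-sample extension."""

    query_id: str
    coordinates: np.ndarray = field(repr=False)
    weights_sum: float = 0.0

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if not np.all(np.isfinite(coords)):
            raise ValueError("extrapolated coordinates are not finite")
        if self.weights_sum <= 0:
            raise IsolationError("query similarity weights sum to zero")


def extrapolate(q: QueryColumn, space: EmbeddingSpace) -> ExtrapolatedEmbedding:
    """Place a query into ``space`` as a weighted sum of database embeddings."""
    if q.n != space.n:
        raise ValueError(f"query length {q.n} != database size {space.n}")
    w = q.similarities
    w_sum = float(w.sum())
    if w_sum <= 0:
        raise IsolationError(f"query {q.query_id!r} has zero affinity to the database")
    denom = 1.0 - space.eigenvalues
    bad = np.flatnonzero(np.abs(denom) < EIGENVALUE_GUARD)
    if bad.size:
        k = int(bad[0])
        raise EigenvalueSingularityError(
            f"eigenvalue lambda_{k + 1} = {space.eigenvalues[k]} is within "
            f"{EIGENVALUE_GUARD} of 1; extrapolation is singular"
        )
    coords = (w @ space.coordinates) / (denom * w_sum)
    return ExtrapolatedEmbedding(query_id=q.query_id, coordinates=coords, weights_sum=w_sum)


def construct_ose_ssl(
    A: DissimilarityMatrix,
    labels: LabelAssignment,
    sigma: float,
    d: int,
) -> EmbeddingSpace:
    """Offline database construction: affinity, label refinement, embedding.

    Returns the (optionally supervised) spectral embedding ``(lambda^r,
    y^r)`` of the database.  With no known labels the refinement is the
    identity and the result equals plain graph embedding.
    """
    W = compute_similarity(A, sigma)
    Wr = supervise_similarity(W, labels)
    space = graph_embed(Wr, d)
    return EmbeddingSpace(
        eigenvalues=space.eigenvalues,
        coordinates=space.coordinates,
        sigma=space.sigma,
        supervised=space.supervised,
        ids=A.ids,
    )
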