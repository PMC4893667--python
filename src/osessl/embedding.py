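"""Spectral embedding of the database and the linear baselines.

The core operation is graph embedding (Laplacian eigenmaps): the database
coordinates ``y`` minimize the affinity-weighted pairwise reconstruction
error, which is equivalent to the generalized eigenproblem

    (D - W) y = lambda * D y,    D(i, i) = sum_j W(i, j)

solved for the ``d`` smallest eigenpairs after excluding zero eigenvalues
(one per connected component of the affinity graph).  Partial class labels
enter through a refinement of ``W`` that boosts same-class affinities and
attenuates different-class ones before the eigendecomposition.

PCA and locality-preserving projections (LPP) over the rows of ``A`` are
provided as the linear retrieval baselines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg as sla
import yaml
from sklearn.decomposition import PCA

from .affinity import DissimilarityMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)

#: sentinel for an image whose class label is not known
UNKNOWN = -1

#: generalized eigenvalues below this fraction of the spectral upper bound
#: (the normalized-Laplacian spectrum lies in [0, 2]) count as "zero valued"
ZERO_EIG_TOL = 1e-10 * 2.0

#: relative residual tolerance each returned eigenpair must satisfy
EIG_RESIDUAL_TOL = 1e-8


@dataclass(frozen=True)
class LabelAssignment:
    """Partial class labels over the database.

    ``labels[i]`` is an integer class in ``{1..Z}`` or :data:`UNKNOWN`.
    """

    labels: np.ndarray = field(repr=False)
    Z: int = 0

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        known = labels[labels != UNKNOWN]
        z = int(self.Z) if self.Z else (int(known.max()) if known.size else 0)
        object.__setattr__(self, "Z", z)
        if known.size and (known.min() < 1 or known.max() > z):
            raise ValueError(f"known labels must lie in [1, {z}]")

    @classmethod
    def all_unknown(cls, n: int) -> "LabelAssignment":
        return cls(labels=np.full(n, UNKNOWN), Z=0)

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def M(self) -> int:
        """Number of known labels."""
        return int(np.sum(self.labels != UNKNOWN))

    def subset(self, indices: Sequence[int]) -> "LabelAssignment":
        return LabelAssignment(labels=self.labels[np.asarray(indices, dtype=int)], Z=self.Z)


@dataclass(frozen=True)
class EmbeddingSpace:
    """A ``d``-dimensional spectral embedding of the database.

    ``coordinates`` columns are D-orthonormal generalized eigenvectors
    (``y^T D y = 1``) of ``(D - W) y = lambda D y`` for the ``d`` smallest
    nonzero eigenvalues, in ascending order.
    """

    eigenvalues: np.ndarray = field(repr=False)
    coordinates: np.ndarray = field(repr=False)
    sigma: float = 1.0
    supervised: bool = False
    ids: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "eigenvalues", np.asarray(self.eigenvalues, dtype=float))
        object.__setattr__(self, "coordinates", np.asarray(self.coordinates, dtype=float))

    @property
    def n(self) -> int:
        return self.coordinates.shape[0]

    @property
    def d(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class LinearProjection:
    """A linear map from dissimilarity rows to ``d`` coordinates.

    ``coordinates[i] = (A[i, :] - center) @ basis`` for every database row.
    """

    basis: np.ndarray = field(repr=False)
    center: np.ndarray = field(repr=False)
    coordinates: np.ndarray = field(repr=False)
    method: str = "pca"

    @property
    def d(self) -> int:
        return self.basis.shape[1]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude entry positive."""
    vectors = vectors.copy()
    for k in range(vectors.shape[1]):
        col = vectors[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            vectors[:, k] = -col
    return vectors


def graph_embed(W: SimilarityMatrix, d: int) -> EmbeddingSpace:
    """Solve ``(D - W) y = lambda D y`` for the ``d`` smallest nonzero pairs.

    Zero eigenvalues (the constant vector, plus one extra per connected
    component of the affinity graph) are excluded; a disconnected graph is
    reported as a warning rather than an error.  Eigenvectors are scaled to
    unit D-norm with a deterministic sign convention.
    """
    n = W.n
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    Wv = W.values
    deg = Wv.sum(axis=1)
    D = np.diag(deg)
    L = D - Wv

    # request a few extra pairs so zero eigenvalues can be dropped without
    # re-solving in the common (connected) case
    want = d + 4
    while True:
        hi = min(want, n) - 1
        vals, vecs = sla.eigh(L, D, subset_by_index=[0, hi])
        nonzero = vals > ZERO_EIG_TOL
        if nonzero.sum() >= d or hi == n - 1:
            break
        want = min(n, want * 2)

    n_zero = int(np.sum(~nonzero))
    if n_zero > 1:
        warnings.warn(
            f"affinity graph appears disconnected: {n_zero} zero eigenvalues excluded",
            RuntimeWarning,
            stacklevel=2,
        )
    keep = np.flatnonzero(nonzero)[:d]
    if keep.size < d:
        raise ValueError(
            f"d={d} requested but only {keep.size} nonzero eigenpairs exist "
            f"(N={n}, {n_zero} zero eigenvalues excluded)"
        )
    vals = vals[keep]
    vecs = vecs[:, keep]

    # scipy returns B-orthonormal vectors for eigh(a, b); renormalize
    # defensively to exact unit D-norm, then fix signs
    norms = np.sqrt(np.einsum("ik,i,ik->k", vecs, deg, vecs))
    vecs = _fix_signs(vecs / norms)
    return EmbeddingSpace(
        eigenvalues=vals,
        coordinates=vecs,
        sigma=W.sigma,
        supervised=W.supervised,
    )


def label_refinement(gamma: np.ndarray, same_class: np.ndarray, any_unknown: np.ndarray) -> np.ndarray:
    """The label-driven affinity refinement, isolated so it can be swapped.

    With ``gamma = W(i, j)``: same-class pairs get ``gamma * (1 + gamma)``,
    different-class pairs ``gamma * (1 - gamma)``, and pairs with any
    unknown label keep ``gamma`` unchanged.  The form is multiplicative so
    refined entries stay in ``[0, 2]`` and vanish with ``gamma``.
    """
    boosted = gamma * (1.0 + gamma)
    damped = gamma * (1.0 - gamma)
    out = np.where(same_class, boosted, damped)
    return np.where(any_unknown, gamma, out)


def supervise_similarity(W: SimilarityMatrix, labels: LabelAssignment) -> SimilarityMatrix:
    """Refine ``W`` into ``W^r`` using the known class labels.

    Same-class affinities are boosted, different-class ones attenuated,
    and pairs involving an unlabeled image are left untouched, so with no
    labels at all ``W^r == W`` exactly.  The diagonal is unchanged.
    """
    if W.supervised:
        raise ValueError("W is already supervised")
    if labels.n != W.n:
        raise ValueError(f"labels length {labels.n} != database size {W.n}")
    if labels.M == 0:
        return W
    known_classes = np.unique(labels.labels[labels.labels != UNKNOWN])
    if known_classes.size < 2:
        raise ValueError(
            "supervision requires at least two distinct known classes; "
            f"got {known_classes.tolist()}"
        )
    lab = labels.labels
    known = lab != UNKNOWN
    same = np.equal.outer(lab, lab) & np.logical_and.outer(known, known)
    any_unknown = ~np.logical_and.outer(known, known)
    refined = label_refinement(W.values, same, any_unknown)
    np.fill_diagonal(refined, np.diag(W.values))
    refined = 0.5 * (refined + refined.T)
    return SimilarityMatrix(values=refined, sigma=W.sigma, supervised=True)


def pca_embed(A: DissimilarityMatrix, d: int) -> LinearProjection:
    """Project the rows of ``A`` onto their top-``d`` principal components."""
    X = A.values
    center = X.mean(axis=0)
    rank = int(np.linalg.matrix_rank(X - center))
    if not 1 <= d <= rank:
        raise ValueError(f"d={d} outside [1, {rank}] (rank of centered A)")
    pca = PCA(n_components=d, svd_solver="full")
    pca.fit(X)
    basis = _fix_signs(pca.components_.T)
    coords = (X - center) @ basis
    return LinearProjection(basis=basis, center=center, coordinates=coords, method="pca")


def lpp_embed(A: DissimilarityMatrix, W: SimilarityMatrix, d: int) -> LinearProjection:
    """Locality-preserving linear projection of the rows of ``A``.

    Loading vectors ``a`` solve the generalized problem
    ``X^T L X a = lambda X^T D X a`` over the centered feature matrix ``X``
    (rows of ``A``) with graph weights ``W``; the ``d`` smallest nontrivial
    solutions define a projection that is linear in a dissimilarity row, so
    queries can be mapped without re-solving.  A singular denominator
    (centering always removes at least one direction) is ridge-regularized
    and logged.
    """
    X = A.values
    center = X.mean(axis=0)
    Xc = X - center
    rank = int(np.linalg.matrix_rank(Xc))
    if not 1 <= d <= rank:
        raise ValueError(f"d={d} outside [1, {rank}] (rank of centered A)")
    deg = W.values.sum(axis=1)
    L = np.diag(deg) - W.values
    num = Xc.T @ L @ Xc
    den = Xc.T @ (deg[:, None] * Xc)
    num = 0.5 * (num + num.T)
    den = 0.5 * (den + den.T)
    scale = np.trace(den) / den.shape[0]
    if scale <= 0:
        raise ValueError("degenerate affinity graph: denominator has zero trace")
    min_eig = float(sla.eigvalsh(den, subset_by_index=[0, 0])[0])
    if min_eig <= 1e-12 * scale:
        logger.info(
            "LPP denominator singular (min eig %.3e); adding ridge %.3e",
            min_eig,
            1e-9 * scale,
        )
        den = den + 1e-9 * scale * np.eye(den.shape[0])
    vals, vecs = sla.eigh(num, den)
    # directions in the nullspace of X project every sample to 0; they show
    # up as (near-)zero eigenvalues and are discarded as trivial
    nontrivial = vals > max(vals.max(), 1.0) * 1e-10
    keep = np.flatnonzero(nontrivial)[:d]
    if keep.size < d:
        raise ValueError(f"only {keep.size} nontrivial LPP directions available, need {d}")
    basis = vecs[:, keep]
    basis = basis / np.linalg.norm(basis, axis=0)
    basis = _fix_signs(basis)
    coords = Xc @ basis
    return LinearProjection(basis=basis, center=center, coordinates=coords, method="lpp")


def project_linear(model: LinearProjection, a_row: np.ndarray) -> np.ndarray:
    """Apply a fitted linear projection to one dissimilarity row."""
    a_row = np.asarray(a_row, dtype=float)
    if a_row.shape != model.center.shape:
        raise ValueError(f"row length {a_row.shape} != expected {model.center.shape}")
    return (a_row - model.center) @ model.basis


def save_embedding(space: EmbeddingSpace, coords_path, meta_path) -> None:
    """Write coordinates as CSV plus a YAML sidecar with the parameters."""
    import pandas as pd

    ids = list(space.ids) if space.ids else [str(i) for i in range(space.n)]
    frame = pd.DataFrame(
        space.coordinates, index=ids, columns=[f"dim{k + 1}" for k in range(space.d)]
    )
    frame.index.name = "id"
    frame.to_csv(coords_path, float_format="%.17g")
    meta = {
        "sigma": float(space.sigma),
        "d": int(space.d),
        "supervised": bool(space.supervised),
        "eigenvalues": [float(v) for v in space.eigenvalues],
    }
    Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def load_embedding(coords_path, meta_path) -> EmbeddingSpace:
    import pandas as pd

    frame = pd.read_csv(coords_path, index_col=0)
    meta = yaml.safe_load(Path(meta_path).read_text())
    return EmbeddingSpace(
        eigenvalues=np.asarray(meta["eigenvalues"], dtype=float),
        coordinates=frame.to_numpy(dtype=float),
        sigma=float(meta["sigma"]),
        supervised=bool(meta["supervised"]),
        ids=tuple(str(i) for i in frame.index),
    )
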