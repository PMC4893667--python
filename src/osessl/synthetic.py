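"""Synthetic datasets with the structure the embedding method assumes.

Two generators are provided: a 3-D Swiss-Roll manifold whose classes are
bands of the intrinsic (geodesic) coordinate — the canonical testbed for
nonlinear embedding — and Gaussian blob clusters with arbitrary per-class
sizes, used to emulate heavily imbalanced class structure such as the
93 / 748 / 47 benign / grade-3 / grade-4 gland counts of a prostate
histopathology database.  Dissimilarity is ambient Euclidean distance.

The database-construction protocol mirrors a leave-one-out retrieval
benchmark: for each query, a stratified sample of fraction ``n`` of the
images (query always excluded) forms the database, and class labels are
revealed for a stratified fraction ``m`` of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .affinity import DissimilarityMatrix, from_values
from .embedding import UNKNOWN, LabelAssignment


@dataclass(frozen=True)
class SyntheticDataset:
    """A fully labeled point set with its pairwise dissimilarity matrix."""

    coordinates: np.ndarray = field(repr=False)
    manifold_param: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    dissimilarity: DissimilarityMatrix = field(repr=False)
    seed: int = 0

    @property
    def n(self) -> int:
        return self.coordinates.shape[0]

    @property
    def Z(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class ProtocolConfig:
    """Benchmark protocol parameters.

    ``n`` is the database size as a fraction of the dataset (``N = n *
    N_all``, query excluded) and ``m`` the known-label fraction of the
    database (``M = m * N``).  Either may be a sequence, in which case the
    experiment harness sweeps the grid.  ``Q = 0`` uses every image once
    as the query (leave-one-out).
    """

    n: object = 1.0
    m: object = 0.0
    seed: int = 0
    Q: int = 0
    metrics: tuple = ("OSE_SSL",)
    sigma: float | None = None
    d: int = 2
    b: int = 5

    def __post_init__(self):
        for frac in self.n_grid:
            if not 0 < frac <= 1:
                raise ValueError(f"database fraction n={frac} outside (0, 1]")
        for frac in self.m_grid:
            if not 0 <= frac <= 1:
                raise ValueError(f"label fraction m={frac} outside [0, 1]")

    @property
    def n_grid(self) -> tuple:
        return tuple(np.atleast_1d(self.n).tolist())

    @property
    def m_grid(self) -> tuple:
        return tuple(np.atleast_1d(self.m).tolist())

    def with_fractions(self, n: float, m: float) -> "ProtocolConfig":
        return replace(self, n=float(n), m=float(m))


def make_swiss_roll(
    n_samples: int,
    n_classes: int = 2,
    noise_sd: float = 0.0,
    seed: int = 0,
    bands_per_class: int = 1,
) -> SyntheticDataset:
    """Swiss-Roll manifold with classes as bands of the roll parameter.

    The intrinsic parameter ``t`` is uniform on ``[1.5*pi, 4.5*pi]`` and
    the ambient point is ``(t*cos t, h, t*sin t)`` plus isotropic Gaussian
    noise.  Classes are contiguous equal-count bands of ``t`` (so class
    structure follows the manifold, not the ambient geometry); with
    ``bands_per_class > 1`` the bands interleave, making the semi-
    supervised separation problem harder.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_samples < 10 * n_classes:
        raise ValueError(f"need at least 10 samples per class, got {n_samples}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    t = rng.uniform(1.5 * np.pi, 4.5 * np.pi, size=n_samples)
    h = rng.uniform(0.0, 21.0, size=n_samples)
    coords = np.column_stack([t * np.cos(t), h, t * np.sin(t)])
    coords = coords + rng.normal(0.0, noise_sd, size=coords.shape)
    n_bands = n_classes * bands_per_class
    ranks = np.argsort(np.argsort(t, kind="stable"), kind="stable")
    band = (ranks * n_bands) // n_samples
    labels = (band % n_classes) + 1
    return SyntheticDataset(
        coordinates=coords,
        manifold_param=t,
        labels=labels.astype(int),
        dissimilarity=from_values(cdist(coords, coords)),
        seed=seed,
    )


def make_blobs(
    class_sizes: Sequence[int],
    separation: float = 1.5,
    seed: int = 0,
) -> SyntheticDataset:
    """Gaussian clusters (unit sd) with explicit, possibly imbalanced sizes.

    Class centers sit on a circle of radius ``separation`` in the
    ``z = 0`` plane of a 3-D ambient space.
    """
    class_sizes = [int(s) for s in class_sizes]
    if len(class_sizes) < 2:
        raise ValueError("need at least 2 classes")
    if any(s < 2 for s in class_sizes):
        raise ValueError("every class needs at least 2 samples")
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    Z = len(class_sizes)
    angles = 2 * np.pi * np.arange(Z) / Z
    centers = separation * np.column_stack([np.cos(angles), np.sin(angles), np.zeros(Z)])
    coords_parts, label_parts = [], []
    for k, size in enumerate(class_sizes):
        coords_parts.append(centers[k] + rng.normal(size=(size, 3)))
        label_parts.append(np.full(size, k + 1))
    coords = np.vstack(coords_parts)
    labels = np.concatenate(label_parts)
    return SyntheticDataset(
        coordinates=coords,
        manifold_param=np.repeat(angles, class_sizes),
        labels=labels.astype(int),
        dissimilarity=from_values(cdist(coords, coords)),
        seed=seed,
    )


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing to ``total``, proportional to ``quotas``.

    Floor each quota, then hand out the remaining units by descending
    fractional remainder (ties broken by class order).
    """
    base = np.floor(quotas).astype(int)
    short = total - int(base.sum())
    if short > 0:
        remainders = quotas - base
        order = np.argsort(-remainders, kind="stable")
        base[order[:short]] += 1
    return base


def reveal_labels(
    true_labels: np.ndarray,
    m_frac: float,
    rng: np.random.Generator,
    Z: int | None = None,
) -> LabelAssignment:
    """Reveal a stratified fraction ``m`` of the true labels.

    ``M = round(m * N)`` labels are drawn per class by largest-remainder
    allocation; the rest are :data:`UNKNOWN`.
    """
    true_labels = np.asarray(true_labels, dtype=int)
    n = true_labels.shape[0]
    M = int(round(float(m_frac) * n))
    revealed = np.full(n, UNKNOWN, dtype=int)
    if M > 0:
        classes, counts = np.unique(true_labels, return_counts=True)
        alloc = _largest_remainder(M * counts / n, M)
        for c, size in zip(classes, alloc):
            members = np.flatnonzero(true_labels == c)
            revealed[rng.choice(members, size=size, replace=False)] = c
    return LabelAssignment(labels=revealed, Z=int(Z or true_labels.max()))


def holdout_split(
    dataset: SyntheticDataset, n_frac: float, rng: np.random.Generator
):
    """Stratified database / held-out-query split of a dataset.

    The database is a stratified sample of ``round(n * N_all)`` images
    (largest-remainder per class); every remaining image is a held-out
    query.  A cheap alternative to the per-query leave-one-out protocol
    when the database need only be embedded once.
    """
    if not 0 < n_frac < 1:
        raise ValueError("holdout split needs 0 < n < 1")
    n_all = dataset.n
    classes, counts = np.unique(dataset.labels, return_counts=True)
    N = int(round(n_frac * n_all))
    alloc = _largest_remainder(N * counts / n_all, N)
    if np.any(alloc == 0):
        raise ValueError(f"class emptied by rounding at n={n_frac}; increase n")
    parts = []
    for c, size in zip(classes, alloc):
        members = np.flatnonzero(dataset.labels == c)
        parts.append(rng.choice(members, size=size, replace=False))
    db_idx = np.sort(np.concatenate(parts))
    query_idx = np.setdiff1d(np.arange(n_all), db_idx)
    return db_idx, query_idx


def build_database(
    dataset: SyntheticDataset,
    config: ProtocolConfig,
    query_index: int,
):
    """One leave-one-out benchmark instance: database, labels, query column.

    The database is a stratified sample of ``N = round(n * N_all)`` images
    (capped at ``N_all - 1``; the query is always excluded) preserving the
    class ratios of the remaining pool via largest-remainder allocation.
    Labels are revealed for a stratified sample of ``M = round(m * N)`` of
    the database.  Returns ``(database_indices, labels, query_column)``.
    """
    n_all = dataset.n
    if not 0 <= query_index < n_all:
        raise ValueError(f"query_index {query_index} outside [0, {n_all})")
    n_frac = float(np.atleast_1d(config.n)[0])
    m_frac = float(np.atleast_1d(config.m)[0])
    rng = np.random.default_rng([int(config.seed), int(query_index)])

    pool = np.setdiff1d(np.arange(n_all), [query_index])
    pool_labels = dataset.labels[pool]
    classes, pool_counts = np.unique(pool_labels, return_counts=True)
    N = min(int(round(n_frac * n_all)), pool.size)
    alloc = _largest_remainder(N * pool_counts / pool.size, N)
    if np.any(alloc == 0):
        empty = int(classes[np.argmin(alloc)])
        raise ValueError(
            f"class {empty} emptied by rounding at n={n_frac}; increase n"
        )
    db_parts = []
    for c, size in zip(classes, alloc):
        members = pool[pool_labels == c]
        db_parts.append(rng.choice(members, size=size, replace=False))
    db_idx = np.sort(np.concatenate(db_parts))

    labels = reveal_labels(dataset.labels[db_idx], m_frac, rng, Z=dataset.Z)
    a_q = dataset.dissimilarity.values[db_idx, query_index]
    return db_idx, labels, a_q
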