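"""Retrieval-quality statistics and the experiment harness.

Two summary statistics are computed per configuration: the area under the
precision-recall curve (AUPRC) of the per-query rankings, with relevance
defined as "same class as the query", and the silhouette index (SI) of the
evaluated coordinate space, a measure of how well images cluster by class.
Paired two-sided t-tests over per-query scores compare metrics.

The experiment harness sweeps (metric, database fraction n, known-label
fraction m) cells with leave-one-out queries over a synthetic dataset and
reports mean +/- sd AUPRC and SI per cell.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .affinity import DegenerateInputError
from .embedding import UNKNOWN, LabelAssignment
from .retrieval import RankedResult, RetrievalEngine

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PRCurve:
    """Precision/recall at every rank cutoff ``alpha`` in ``1..N``.

    ``relevant_at[alpha-1]`` counts relevant items among the closest
    ``alpha``; precision ``p = relevant_at / alpha`` and recall
    ``r = relevant_at / R`` with ``R`` the total number of relevant items.
    """

    relevant_at: np.ndarray = field(repr=False)
    precision: np.ndarray = field(repr=False)
    recall: np.ndarray = field(repr=False)
    auprc: float = 0.0

    @property
    def alpha(self) -> np.ndarray:
        return np.arange(1, self.relevant_at.shape[0] + 1)


@dataclass(frozen=True)
class SilhouetteScore:
    """Per-point and overall silhouette values ``s = (b - a) / max(a, b)``."""

    per_point: np.ndarray = field(repr=False)
    a_terms: np.ndarray = field(repr=False)
    b_terms: np.ndarray = field(repr=False)
    overall: float = 0.0


@dataclass(frozen=True)
class ComparisonReport:
    """Paired comparison of two per-query score vectors."""

    metric_pair: tuple
    scores_a: np.ndarray = field(repr=False)
    scores_b: np.ndarray = field(repr=False)
    t_statistic: float = 0.0
    p_value: float = 1.0

    @property
    def mean_sd_a(self) -> tuple:
        return float(np.mean(self.scores_a)), float(np.std(self.scores_a, ddof=1))

    @property
    def mean_sd_b(self) -> tuple:
        return float(np.mean(self.scores_b)), float(np.std(self.scores_b, ddof=1))


def precision_recall(relevance_in_rank_order: Sequence[int]) -> PRCurve:
    """Precision-recall curve of one ranked candidate list.

    The AUPRC is the trapezoidal area over the achieved (recall,
    precision) points, with the curve extended horizontally from the first
    point back to recall 0 at precision ``p(1)``.
    """
    rel = np.asarray(relevance_in_rank_order)
    if rel.ndim != 1 or not np.isin(rel, (0, 1)).all():
        raise ValueError("relevance must be a 1-D binary vector")
    R = int(rel.sum())
    if R == 0 or R == rel.shape[0]:
        raise DegenerateInputError(
            f"need both relevant and irrelevant items, got {R} of {rel.shape[0]} relevant"
        )
    phi = np.cumsum(rel)
    alpha = np.arange(1, rel.shape[0] + 1)
    precision = phi / alpha
    recall = phi / R
    r_pts = np.concatenate(([0.0], recall))
    p_pts = np.concatenate(([precision[0]], precision))
    auprc = float(np.trapezoid(p_pts, r_pts))
    return PRCurve(relevant_at=phi, precision=precision, recall=recall, auprc=auprc)


def silhouette_index(coords: np.ndarray, labels: LabelAssignment) -> SilhouetteScore:
    """Silhouette index of ``coords`` under a complete class assignment.

    For point ``i``, ``a(i)`` is the mean Euclidean distance to the other
    members of its class and ``b(i)`` the smallest mean distance to any
    other class; ``s(i) = (b - a) / max(a, b)``, averaged over points.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    lab = labels.labels
    if np.any(lab == UNKNOWN):
        raise ValueError("silhouette requires a complete label assignment")
    if lab.shape[0] != coords.shape[0]:
        raise ValueError("labels and coordinates disagree in length")
    classes, counts = np.unique(lab, return_counts=True)
    if classes.size < 2:
        raise ValueError("silhouette requires at least two classes")
    singleton = classes[counts < 2]
    if singleton.size:
        raise ValueError(f"class {int(singleton[0])} has fewer than two members")
    dist = cdist(coords, coords)
    n = coords.shape[0]
    members = {int(c): np.flatnonzero(lab == c) for c in classes}
    a_terms = np.empty(n)
    b_terms = np.empty(n)
    for c in classes:
        idx = members[int(c)]
        # mean distance to same-class others excludes the point itself
        a_terms[idx] = dist[np.ix_(idx, idx)].sum(axis=1) / (idx.size - 1)
        other_means = np.stack(
            [dist[np.ix_(idx, members[int(o)])].mean(axis=1) for o in classes if o != c]
        )
        b_terms[idx] = other_means.min(axis=0)
    denom = np.maximum(a_terms, b_terms)
    per_point = np.where(denom > 0, (b_terms - a_terms) / np.where(denom > 0, denom, 1.0), 0.0)
    return SilhouetteScore(
        per_point=per_point,
        a_terms=a_terms,
        b_terms=b_terms,
        overall=float(per_point.mean()),
    )


def auprc_over_queries(
    ranked_results: Iterable[RankedResult],
    query_labels: Sequence[int],
    database_labels: Sequence[np.ndarray],
) -> tuple:
    """Per-query AUPRC vector with its mean and sample sd.

    ``database_labels[j]`` gives the candidate classes, in database order,
    for the j-th ranked result (databases may differ per query under
    leave-one-out).  Relevance is sharing the query's class; queries whose
    class is absent from their database are skipped with a warning.
    """
    scores = []
    for result, q_label, db_labels in zip(ranked_results, query_labels, database_labels):
        db_labels = np.asarray(db_labels)
        rel = (db_labels[result.order] == q_label).astype(int)
        if rel.sum() == 0:
            warnings.warn(
                f"query {result.query_id!r}: class {q_label} absent from database; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        scores.append(precision_recall(rel).auprc)
    scores = np.asarray(scores, dtype=float)
    mean = float(scores.mean()) if scores.size else float("nan")
    if scores.size < 2:
        logger.info("fewer than two query scores; sd reported as 0 by convention")
        sd = 0.0
    else:
        sd = float(scores.std(ddof=1))
    return scores, mean, sd


def paired_ttest(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    metric_pair: tuple = ("a", "b"),
) -> ComparisonReport:
    """Two-sided paired Student's t-test on per-query score differences."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be paired and equal length")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    if diff.std(ddof=1) == 0.0:
        if diff[0] == 0.0:
            warnings.warn(
                "all paired differences are zero; p = 1", RuntimeWarning, stacklevel=2
            )
            return ComparisonReport(
                metric_pair=tuple(metric_pair), scores_a=a, scores_b=b,
                t_statistic=0.0, p_value=1.0,
            )
        # constant nonzero difference: the t statistic diverges
        return ComparisonReport(
            metric_pair=tuple(metric_pair), scores_a=a, scores_b=b,
            t_statistic=float(np.sign(diff[0]) * np.inf), p_value=0.0,
        )
    t, p = stats.ttest_rel(a, b)
    return ComparisonReport(
        metric_pair=tuple(metric_pair),
        scores_a=a,
        scores_b=b,
        t_statistic=float(t),
        p_value=float(p),
    )


def holdout_experiment(
    dataset,
    n_frac: float,
    m_frac: float,
    metrics: Sequence[str],
    sigma: float,
    d: int,
    seed: int = 0,
) -> dict:
    """One stratified database / held-out-query benchmark instance.

    A stratified fraction ``n`` of the dataset forms the database (embedded
    once); every remaining image is ranked against it as an out-of-sample
    query.  Labels are revealed for a stratified fraction ``m`` of the
    database.  Returns, per metric, the per-query AUPRC vector and the SI
    of the database coordinates in that metric's space.
    """
    from .synthetic import holdout_split, reveal_labels

    rng = np.random.default_rng(seed)
    db_idx, query_idx = holdout_split(dataset, n_frac, rng)
    A_db = dataset.dissimilarity.subset(db_idx)
    db_true = dataset.labels[db_idx]
    labels = reveal_labels(db_true, m_frac, rng, Z=dataset.Z)
    engine = RetrievalEngine(A_db, labels, sigma=sigma, d=d)
    out = {}
    for metric in metrics:
        scores = []
        for qi in query_idx:
            a_q = dataset.dissimilarity.values[db_idx, qi]
            coords, y_q = engine.query_coordinates(metric, a_q, query_id=str(qi))
            order = np.argsort(
                np.linalg.norm(np.atleast_2d(coords) - y_q, axis=1)
                if metric != "HIGH_DIM"
                else a_q,
                kind="stable",
            )
            rel = (db_true[order] == dataset.labels[qi]).astype(int)
            if 0 < rel.sum() < rel.size:
                scores.append(precision_recall(rel).auprc)
        coords, _ = engine.query_coordinates(metric, dataset.dissimilarity.values[db_idx, query_idx[0]])
        si = silhouette_index(coords, LabelAssignment(labels=db_true))
        out[metric] = {
            "auprc_scores": np.asarray(scores),
            "mean_auprc": float(np.mean(scores)),
            "si": si.overall,
        }
    return out


def run_experiment(protocol, dataset) -> pd.DataFrame:
    """Sweep (metric, n, m) cells with leave-one-out queries.

    For each cell the database is a stratified sample of fraction ``n`` of
    the dataset (always excluding the query), labels are revealed for a
    stratified fraction ``m`` of it, every metric ranks all leave-one-out
    queries, and mean +/- sd AUPRC and SI are reported.

    Parameters
    ----------
    protocol : ProtocolConfig
        Defines n/m grids, metrics, sigma, d, b, seed and the number of
        queries (``Q = 0`` means every image once).
    dataset : SyntheticDataset
        Complete dataset with coordinates, labels and dissimilarities.

    Returns
    -------
    pandas.DataFrame
        One row per (metric, n, m) cell.
    """
    from .synthetic import build_database  # deferred to avoid a cycle
    from .affinity import median_sigma

    sigma = protocol.sigma
    if sigma is None:
        sigma = median_sigma(dataset.dissimilarity)
    rng = np.random.default_rng(protocol.seed)
    n_all = dataset.n
    rows = []
    query_ids = np.arange(n_all)
    if protocol.Q and protocol.Q < n_all:
        query_ids = rng.choice(n_all, size=protocol.Q, replace=False)
    for n_frac in protocol.n_grid:
        for m_frac in protocol.m_grid:
            if round(m_frac * round(n_frac * n_all)) > round(n_frac * n_all):
                logger.warning("cell n=%s m=%s infeasible (M > N); skipped", n_frac, m_frac)
                continue
            cell_cfg = protocol.with_fractions(n_frac, m_frac)
            per_metric_scores = {metric: [] for metric in protocol.metrics}
            per_metric_si = {metric: [] for metric in protocol.metrics}
            for q_idx in query_ids:
                db_idx, labels, a_q = build_database(dataset, cell_cfg, int(q_idx))
                A_db = dataset.dissimilarity.subset(db_idx)
                engine = RetrievalEngine(A_db, labels, sigma=sigma, d=protocol.d)
                db_true = dataset.labels[db_idx]
                q_label = int(dataset.labels[q_idx])
                for metric in protocol.metrics:
                    result = engine.retrieve(metric, a_q, b=protocol.b, query_id=str(q_idx))
                    rel = (db_true[result.order] == q_label).astype(int)
                    if 0 < rel.sum() < rel.size:
                        per_metric_scores[metric].append(precision_recall(rel).auprc)
                    coords, _ = engine.query_coordinates(metric, a_q)
                    si = silhouette_index(coords, LabelAssignment(labels=db_true))
                    per_metric_si[metric].append(si.overall)
            for metric in protocol.metrics:
                scores = np.asarray(per_metric_scores[metric])
                sis = np.asarray(per_metric_si[metric])
                rows.append(
                    {
                        "metric": metric,
                        "n": n_frac,
                        "m": m_frac,
                        "sigma": sigma,
                        "d": protocol.d,
                        "mean_auprc": float(scores.mean()),
                        "sd_auprc": float(scores.std(ddof=1)) if scores.size > 1 else 0.0,
                        "mean_si": float(sis.mean()),
                        "sd_si": float(sis.std(ddof=1)) if sis.size > 1 else 0.0,
                        "n_queries": int(scores.size),
                        "seed": protocol.seed,
                    }
                )
    return pd.DataFrame(rows)
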