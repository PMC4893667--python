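"""Reusable benchmark-protocol runners built from the library primitives.

These wrap the leave-one-out and holdout protocols into single calls that
return per-query score vectors, so benchmark scripts and statistical
comparisons do not re-implement the sampling loops.
"""

from __future__ import annotations

import numpy as np

from .evaluation import precision_recall
from .extrapolation import construct_ose_ssl, extrapolate
from .affinity import query_similarity
from .synthetic import ProtocolConfig, SyntheticDataset, build_database


def loo_ose_auprc(
    dataset: SyntheticDataset,
    n_frac: float,
    m_frac: float,
    sigma: float,
    d: int,
    queries: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Per-query AUPRC of out-of-sample retrieval under the leave-one-out protocol.

    For each query index, a stratified database of fraction ``n`` is drawn
    (query excluded), labels are revealed for fraction ``m`` of it, the
    database is embedded, the query extrapolated, and the ranking scored
    with same-class relevance.  With ``n = 1.0`` and ``m = 0.0`` this is
    the full-re-embedding (plain graph embedding) reference.
    """
    cfg = ProtocolConfig(n=n_frac, m=m_frac, seed=seed)
    scores = np.empty(len(queries))
    for j, q_idx in enumerate(queries):
        db_idx, labels, a_q = build_database(dataset, cfg, int(q_idx))
        A_db = dataset.dissimilarity.subset(db_idx)
        space = construct_ose_ssl(A_db, labels, sigma, d)
        y_q = extrapolate(query_similarity(a_q, sigma), space).coordinates
        order = np.argsort(
            np.linalg.norm(space.coordinates - y_q, axis=1), kind="stable"
        )
        relevance = (
            dataset.labels[db_idx][order] == dataset.labels[q_idx]
        ).astype(int)
        scores[j] = precision_recall(relevance).auprc
    return scores
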