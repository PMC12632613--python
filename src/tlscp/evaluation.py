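"""Clustering and estimation metrics, and the Cox + k-means baseline.

The clustering metric is normalized mutual information with arithmetic-mean
normalization, NMI = I(C, D) / [(H(C) + H(D)) / 2]; estimation accuracy is
the relative squared error ||beta_hat - beta*||^2 / ||beta*||^2.  The naive
baseline fits an unpenalized Cox model and clusters the coefficients by 1-D
k-means, choosing the cluster count by average silhouette width.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .cox import SurvivalDataset, fit_cox

logger = logging.getLogger("tlscp")


def _as_labels(part) -> np.ndarray:
    labels = np.asarray(part)
    if labels.ndim != 1:
        raise ValueError("a partition is a flat vector of labels")
    return labels


def nmi(part_a, part_b) -> float:
    """Normalized mutual information between two partitions of {1..p}.

    Natural logarithms (the base cancels).  Degenerate conventions: both
    partitions single-cluster (both entropies zero) -> 1.0; exactly one
    entropy zero -> 0.0.
    """
    la, lb = _as_labels(part_a), _as_labels(part_b)
    if la.shape != lb.shape:
        raise ValueError("partitions cover different index sets")
    p = la.size
    _, ia = np.unique(la, return_inverse=True)
    _, ib = np.unique(lb, return_inverse=True)
    ka, kb = ia.max() + 1, ib.max() + 1
    counts = np.zeros((ka, kb))
    np.add.at(counts, (ia, ib), 1.0)
    pa = counts.sum(axis=1) / p
    pb = counts.sum(axis=0) / p
    ha = -float(np.sum(pa * np.log(pa)))
    hb = -float(np.sum(pb * np.log(pb)))
    if ha <= 0 and hb <= 0:
        return 1.0
    if ha <= 0 or hb <= 0:
        return 0.0
    pij = counts / p
    mask = pij > 0
    mi = float(np.sum(pij[mask] * np.log(pij[mask] / np.outer(pa, pb)[mask])))
    return float(min(max(mi / ((ha + hb) / 2.0), 0.0), 1.0))


def rel_err(beta_hat, beta_true) -> float:
    """Relative squared error ||beta_hat - beta*||^2 / ||beta*||^2."""
    bh = np.asarray(beta_hat, dtype=float)
    bt = np.asarray(beta_true, dtype=float)
    if bh.shape != bt.shape:
        raise ValueError("coefficient vectors differ in length")
    denom = float(bt @ bt)
    if denom == 0.0:
        raise ValueError("beta_true must not be the zero vector")
    diff = bh - bt
    return float(diff @ diff) / denom


def kmeans_partition(values, k_candidates=(2, 3, 4, 5), restarts: int = 10,
                     seed: int = 0):
    """1-D k-means over candidate cluster counts, picked by mean silhouette.

    Returns (labels, k_selected, silhouettes).  Silhouette needs k >= 2; a
    single cluster is reported only when all values coincide to 1e-8.
    """
    v = np.asarray(values, dtype=float).reshape(-1, 1)
    if np.ptp(v) < 1e-8:
        return np.zeros(v.shape[0], dtype=np.int64), 1, {}
    best = None
    sil = {}
    for k in sorted(set(int(k) for k in k_candidates)):
        if k < 2 or k >= v.shape[0]:
            continue
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(v)
        if len(np.unique(km.labels_)) < 2:
            continue
        s = float(silhouette_score(v, km.labels_))
        sil[k] = s
        if best is None or s > best[1] + 1e-12:
            best = (km.labels_.astype(np.int64), s, k)
    if best is None:
        raise ValueError("no admissible k in k_candidates")
    return best[0], best[2], sil


def cox_kmeans(data: SurvivalDataset, k_candidates=(2, 3, 4, 5),
               restarts: int = 10, seed: int = 0, beta_prelim=None):
    """Cox + k-means baseline over the penalized coefficients.

    Fits an unpenalized Cox model (or reuses ``beta_prelim``), then runs
    1-D k-means with silhouette-selected k.  Returns (labels, info) where
    info carries the coefficients, selected k and silhouette widths.
    """
    beta = fit_cox(data) if beta_prelim is None else np.asarray(beta_prelim, float)
    values = beta[data.penalized_cols]
    labels, k_sel, sil = kmeans_partition(values, k_candidates=k_candidates,
                                          restarts=restarts, seed=seed)
    return labels, {"beta": beta, "k_selected": k_sel, "silhouettes": sil}
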