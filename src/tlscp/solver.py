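"""End-to-end SCP: preliminary fit, rank map, outer IRLS loop, BIC tuning.

Survival-based Clustering of Predictors (SCP) estimates a Cox model whose
coefficients are forced into homogeneous clusters.  The outer loop expands
the log partial likelihood into a weighted least squares problem (IRLS) and
hands it to the fusion-penalized solver; with the distance-to-set penalty
the sparsity level k caps the number of fused-difference breaks, hence the
number of coefficient clusters at k + 1.  The cluster count itself is tuned
by BIC over a small grid of k.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .cox import SurvivalDataset, fit_cox, irls_update, log_partial_likelihood
from .fusion import (ENUM_PATTERN_CAP, FusionMatrix, PenaltySpec, RankMap,
                     _breaks_to_mask, _clusters_from_breaks,
                     build_fusion_matrix, build_rank_map, solve_fused_wls)

logger = logging.getLogger("tlscp")

#: gap threshold for declaring two tau-adjacent coefficients distinct;
#: the terminal refit produces exact fusion, tol only guards float noise.
CLUSTER_TOL = 1e-6


@dataclass
class SCPFit:
    """A fitted SCP model.

    ``labels``/``centers`` describe the clustering of the *penalized*
    coefficients; every penalized entry of ``beta`` equals its cluster
    center exactly.  ``bic`` uses the number of events as effective sample
    size and df = (number of clusters) + (number of unpenalized columns).
    """

    beta: np.ndarray
    labels: np.ndarray
    centers: np.ndarray
    k_used: int
    loglik: float
    bic: float
    converged: bool
    tau: RankMap
    spec: PenaltySpec
    n_outer: int = 0
    objective_trace: list = field(default_factory=list, repr=False)

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def to_dict(self, columns=None) -> dict:
        d = {
            "beta": [float(b) for b in self.beta],
            "labels": [int(l) for l in self.labels],
            "centers": [float(c) for c in self.centers],
            "k_used": int(self.k_used),
            "n_clusters": int(self.n_clusters),
            "loglik": float(self.loglik),
            "bic": float(self.bic),
            "converged": bool(self.converged),
            "tau": [int(t) for t in self.tau.order],
            "penalty": self.spec.family,
        }
        if columns is not None:
            d["columns"] = list(columns)
        return d

    def to_json(self, **extra) -> str:
        payload = self.to_dict()
        payload.update(extra)
        return json.dumps(payload, sort_keys=True, indent=2)


def extract_clusters(beta_pen, tau: RankMap, tol: float = CLUSTER_TOL):
    """Cluster labels/centers by walking the tau-ordered coefficients.

    A new cluster starts wherever consecutive ordered coefficients differ
    by more than ``tol``; centers are member means (the exact shared value
    when the solver's terminal refit has run).
    """
    beta_pen = np.asarray(beta_pen, dtype=float)
    if beta_pen.shape != (tau.p,):
        raise ValueError("beta length disagrees with rank map")
    labels = np.empty(tau.p, dtype=np.int64)
    lab = 0
    labels[tau.order[0]] = 0
    for i in range(1, tau.p):
        if abs(beta_pen[tau.order[i]] - beta_pen[tau.order[i - 1]]) > tol:
            lab += 1
        labels[tau.order[i]] = lab
    centers = np.array([beta_pen[labels == c].mean() for c in range(lab + 1)])
    return labels, centers


def _collapsed_cox(data: SurvivalDataset, labels):
    """Constrained Cox MLE with cluster-constant penalized coefficients.

    Columns in a cluster are summed into one covariate (shared coefficient);
    unpenalized columns stay free.  Returns (beta_full, loglik).
    """
    pen = data.penalized_cols
    g = int(labels.max()) + 1
    unpen = sorted(data.unpenalized_cols)
    cols = [data.covariates[:, pen[labels == c]].sum(axis=1) for c in range(g)]
    cols.extend(data.covariates[:, j] for j in unpen)
    collapsed = SurvivalDataset(times=data.times, status=data.status,
                                covariates=np.column_stack(cols))
    gamma = fit_cox(collapsed)
    beta = np.zeros(data.p)
    for c in range(g):
        beta[pen[labels == c]] = gamma[c]
    for i, j in enumerate(unpen):
        beta[j] = gamma[g + i]
    return beta, log_partial_likelihood(collapsed, gamma)


def _final_polish(data, beta, loglik, labels, tau, spec):
    """Replace the fused solution by the constrained Cox MLE of its pattern.

    For the distance family with a small pattern space the best pattern is
    found by exhaustive enumeration of break positions; otherwise only the
    current pattern is refit.  The higher-likelihood solution is kept.
    """
    q = tau.p
    candidates = []
    if spec.family == "distance":
        kb = min(spec.k, q - 1)
        if comb(q - 1, kb) <= ENUM_PATTERN_CAP:
            candidates = [
                _clusters_from_breaks(tau, _breaks_to_mask(br, q))
                for br in combinations(range(1, q), kb)
            ]
    if not candidates:
        candidates = [labels]
    best_beta, best_ll = beta, loglik
    for lab in candidates:
        try:
            beta_c, ll_c = _collapsed_cox(data, lab)
        except (RuntimeError, ValueError):
            continue
        if ll_c > best_ll + 1e-10:
            best_beta, best_ll = beta_c, ll_c
    return best_beta, best_ll


def fit_scp(data: SurvivalDataset, spec: PenaltySpec, tau: RankMap = None,
            beta_init=None, max_outer: int = 50, tol: float = 1e-6,
            keep_trace: bool = False) -> SCPFit:
    """Fit SCP on one cohort for a fixed penalty specification.

    When ``tau`` is omitted it is built from an unpenalized preliminary Cox
    fit (which also initializes the linear predictor); pass the merged rank
    map here to obtain the transfer-learning variant.  The outer loop
    alternates the IRLS expansion with the fused WLS solve, warm-started at
    the current coefficients, until max|Delta beta| < tol or ``max_outer``
    iterations; the best iterate by log partial likelihood is returned.
    """
    X = data.covariates
    pen = data.penalized_cols
    if tau is None or beta_init is None:
        prelim = fit_cox(data)
        if tau is None:
            tau = build_rank_map(prelim[pen])
        if beta_init is None:
            beta_init = prelim
    D = build_fusion_matrix(tau)
    beta = np.asarray(beta_init, dtype=float).copy()

    best_beta, best_ll = None, -np.inf
    trace = []
    converged = False
    n_outer = 0
    beta_prev2 = None
    for n_outer in range(1, max_outer + 1):
        ws = irls_update(data, X @ beta)
        info = {}
        beta_new = solve_fused_wls(
            X, ws.responses, ws.weights, D, spec, beta,
            penalized_cols=pen, unpenalized_cols=sorted(data.unpenalized_cols),
            info=info,
        )
        ll = log_partial_likelihood(data, beta_new)
        if keep_trace:
            trace.append({"outer": n_outer, "loglik": ll,
                          "inner": info.get("trace", [])})
        if ll > best_ll:
            best_ll, best_beta = ll, beta_new
        delta = float(np.max(np.abs(beta_new - beta)))
        # stop on a fixed point or a period-2 cycle between two patterns
        cycling = (beta_prev2 is not None
                   and float(np.max(np.abs(beta_new - beta_prev2))) < tol)
        beta_prev2 = beta
        beta = beta_new
        if delta < tol or cycling:
            converged = True
            break
    if not converged:
        logger.warning("fit_scp hit the outer iteration cap (max|dbeta| > tol)")

    labels, _ = extract_clusters(best_beta[pen], tau)
    beta, loglik = _final_polish(data, best_beta, best_ll, labels, tau, spec)
    labels, centers = extract_clusters(beta[pen], tau)
    df = len(centers) + len(data.unpenalized_cols)
    bic = -2.0 * loglik + df * np.log(data.n_events)
    k_used = spec.k if spec.family == "distance" else -1
    return SCPFit(beta=beta, labels=labels, centers=centers,
                  k_used=int(k_used), loglik=float(loglik), bic=float(bic),
                  converged=converged, tau=tau, spec=spec, n_outer=n_outer,
                  objective_trace=trace)


def select_k_bic(data: SurvivalDataset, spec_grid, tau: RankMap = None,
                 beta_init=None, **fit_kwargs) -> SCPFit:
    """Fit each penalty spec in the grid and return the BIC minimizer.

    BIC = -2 l(beta_hat) + df * log(n_events) with df = cluster count plus
    unpenalized columns; ties prefer the earlier (smaller-k) grid entry.
    Every fit starts from the same preliminary estimate, so the selection
    does not depend on grid order.
    """
    grid = list(spec_grid)
    if not grid:
        raise ValueError("spec_grid must be nonempty")
    if tau is None or beta_init is None:
        prelim = fit_cox(data)
        if tau is None:
            tau = build_rank_map(prelim[data.penalized_cols])
        if beta_init is None:
            beta_init = prelim

    best = None
    failures = []
    for spec in grid:
        try:
            fit = fit_scp(data, spec, tau=tau, beta_init=beta_init, **fit_kwargs)
        except Exception as exc:  # keep scanning the grid
            logger.warning("fit failed for %s: %s", spec, exc)
            failures.append((spec, exc))
            continue
        if best is None or fit.bic < best.bic - 1e-12:
            best = fit
    if best is None:
        raise RuntimeError(f"all {len(grid)} fits in the grid failed: {failures[0][1]}")
    return best


def default_k_grid(p_pen: int, k_max: int = 5, **spec_kwargs):
    """Distance-penalty grid k = 1..min(k_max, p_pen - 1)."""
    return [PenaltySpec(family="distance", k=k, **spec_kwargs)
            for k in range(1, min(k_max, p_pen - 1) + 1)]
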