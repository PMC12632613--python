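"""Rank-based fusion penalty and solvers for the fused WLS subproblem.

The clustering penalty acts on differences of rank-adjacent coefficients:
given a preliminary ordering tau of the penalized coefficients, the fusion
matrix D_tau has rows e_{tau(i)} - e_{tau(i+1)}, so D_tau beta collects the
p_pen - 1 consecutive differences along the sorted order.  Shrinking entries
of D_tau beta to zero fuses coefficients into clusters; the number of
clusters equals ||D_tau beta||_0 + 1.

The workhorse penalty is the distance-to-set penalty
(lambda/2) dist(D_tau beta, C)^2 with C = {z : ||z||_0 <= k}, solved by a
proximal-distance anneal (lambda sent to infinity on a geometric schedule),
so the tuning parameter is the integer sparsity level k rather than a
continuous shrinkage amount.  Lasso/SCAD/MCP alternatives are provided via
an ADMM splitting on u = D beta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import linalg

logger = logging.getLogger("tlscp")

#: pattern spaces at most this large are enumerated exactly; larger ones
#: rely on the proximal-distance anneal to identify the break pattern.
ENUM_PATTERN_CAP = 60


@dataclass(frozen=True)
class RankMap:
    """Permutation tau ordering penalized coefficient indices ascending.

    ``order[i]`` is the (0-based) index of the i-th smallest preliminary
    coefficient; applying ``order`` to the source vector yields a
    nondecreasing sequence.
    """

    order: np.ndarray

    def __post_init__(self):
        order = np.asarray(self.order, dtype=np.int64)
        if order.ndim != 1 or not np.array_equal(np.sort(order), np.arange(order.size)):
            raise ValueError("order must be a permutation of 0..p_pen-1")
        object.__setattr__(self, "order", order)

    @property
    def p(self) -> int:
        return self.order.size

    def ranks(self) -> np.ndarray:
        """1-based rank of each index under this ordering."""
        r = np.empty(self.p, dtype=np.int64)
        r[self.order] = np.arange(1, self.p + 1)
        return r


def build_rank_map(beta_prelim) -> RankMap:
    """Ascending ordering of coefficients, ties broken by first occurrence."""
    beta = np.asarray(beta_prelim, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta_prelim contains non-finite entries")
    return RankMap(order=np.argsort(beta, kind="stable"))


@dataclass(frozen=True)
class FusionMatrix:
    """Signed incidence matrix D_tau of consecutive rank-order differences."""

    rows: np.ndarray
    tau: RankMap

    @property
    def p(self) -> int:
        return self.rows.shape[1]

    def matrix(self, p_full: int = None, penalized_cols=None) -> np.ndarray:
        """Dense D, optionally embedded into a p_full-column design."""
        if p_full is None:
            return self.rows
        D = np.zeros((self.rows.shape[0], p_full))
        D[:, np.asarray(penalized_cols, dtype=np.int64)] = self.rows
        return D

    def to_triplets(self) -> list:
        """Sparse (row, col, value) triplets, for text dumps/debugging."""
        r, c = np.nonzero(self.rows)
        return [(int(i), int(j), float(self.rows[i, j])) for i, j in zip(r, c)]


def build_fusion_matrix(tau: RankMap) -> FusionMatrix:
    """D_tau with i-th row e_{tau(i)} - e_{tau(i+1)}; requires p_pen >= 2."""
    p = tau.p
    if p < 2:
        raise ValueError("fusion matrix needs at least 2 penalized coefficients")
    D = np.zeros((p - 1, p))
    idx = np.arange(p - 1)
    D[idx, tau.order[:-1]] = 1.0
    D[idx, tau.order[1:]] = -1.0
    return FusionMatrix(rows=D, tau=tau)


def project_sparsity(v, k: int) -> np.ndarray:
    """Euclidean projection onto {z : ||z||_0 <= k}.

    Keeps the k largest-magnitude entries (magnitude ties keep the lower
    index) and zeroes the rest; returns v unchanged when k >= len(v).
    """
    v = np.asarray(v, dtype=float)
    if k < 1:
        raise ValueError("k must be a positive integer")
    if k >= v.size:
        return v.copy()
    keep = np.argsort(-np.abs(v), kind="stable")[:k]
    out = np.zeros_like(v)
    out[keep] = v[keep]
    return out


_FAMILIES = ("distance", "lasso", "scad", "mcp")


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family and its tuning parameters.

    distance : sparsity level ``k`` (1 <= k <= p_pen-1) plus the annealing
        schedule (lam0, sched_growth, lam_max).  Schedule values are
        dimensionless: lambda is measured as the ratio of penalty curvature
        to loss curvature (largest generalized eigenvalue of D'D against
        X'WX/n), so lam0 = 1e-3 starts the anneal with the penalty at 0.1%
        of the loss and the pattern free to reorganize; annealing stops
        once the fused differences are feasible to tolerance or the ratio
        reaches lam_max.
    lasso / scad / mcp : shrinkage amount ``lam`` > 0; SCAD concavity a=3.7
        and MCP gamma=3 by convention.
    """

    family: str = "distance"
    k: int = None
    lam: float = None
    lam0: float = 1e-3
    sched_growth: float = 1.2
    lam_max: float = 1e8
    scad_a: float = 3.7
    mcp_gamma: float = 3.0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown penalty family '{self.family}'")
        if self.family == "distance":
            if self.k is None or int(self.k) < 1:
                raise ValueError("distance penalty requires a positive integer k")
            object.__setattr__(self, "k", int(self.k))
        else:
            if self.lam is None or self.lam <= 0:
                raise ValueError(f"{self.family} penalty requires lam > 0")
        if self.lam0 <= 0 or self.sched_growth <= 1:
            raise ValueError("schedule requires lam0 > 0 and sched_growth > 1")
        if self.scad_a <= 2 or self.mcp_gamma <= 1:
            raise ValueError("scad_a must exceed 2 and mcp_gamma must exceed 1")


def _weighted_quadratic(X, z, w):
    """G = X'WX/n, b = X'Wz/n with near-zero weights dropped."""
    from .cox import EPS_WEIGHT

    n = X.shape[0]
    w_eff = np.where(np.asarray(w, float) >= EPS_WEIGHT, w, 0.0) / n
    if not np.any(w_eff > 0):
        raise ValueError("all working weights are zero")
    Xw = X * w_eff[:, None]
    return X.T @ Xw, Xw.T @ np.asarray(z, float)


def _clusters_from_breaks(tau: RankMap, break_mask) -> np.ndarray:
    """Cluster labels over penalized columns from fused-difference breaks.

    break_mask[i] True means the difference beta[tau(i)] - beta[tau(i+1)]
    is allowed to stay nonzero; contiguous runs in tau order otherwise fuse.
    """
    labels = np.empty(tau.p, dtype=np.int64)
    lab = 0
    labels[tau.order[0]] = 0
    for i in range(tau.p - 1):
        if break_mask[i]:
            lab += 1
        labels[tau.order[i + 1]] = lab
    return labels


def _refit_collapsed(X, z, w, labels, penalized_cols, unpenalized_cols, p):
    """Constrained WLS with cluster-constant penalized coefficients.

    Columns within a cluster are summed (shared coefficient); unpenalized
    columns keep their own coefficients.  Returns the full-length beta.
    """
    penalized_cols = np.asarray(penalized_cols, dtype=np.int64)
    g = int(labels.max()) + 1
    cols = []
    for c in range(g):
        members = penalized_cols[labels == c]
        cols.append(X[:, members].sum(axis=1))
    for j in unpenalized_cols:
        cols.append(X[:, j])
    Xc = np.column_stack(cols)
    G, b = _weighted_quadratic(Xc, z, w)
    try:
        gamma = linalg.solve(G, b, assume_a="pos")
    except linalg.LinAlgError:
        gamma = linalg.lstsq(G, b)[0]
    beta = np.zeros(p)
    for c in range(g):
        beta[penalized_cols[labels == c]] = gamma[c]
    for i, j in enumerate(unpenalized_cols):
        beta[j] = gamma[g + i]
    return beta


class _AnnealSolver:
    """Shared factorizations for repeated solves of (G + lam * D'D) beta = rhs.

    With G = L L' and B = L^{-1} (D'D) L^{-T} = U diag(s) U', each lambda
    solve reduces to two triangular solves and two dense products, O(p^2).
    Falls back to direct solves when G is not positive definite.
    """

    def __init__(self, G, D_emb):
        self.D = D_emb
        self.DtD = D_emb.T @ D_emb
        self.G = G
        p = G.shape[1]
        try:
            self.L = linalg.cholesky(G + 1e-12 * np.trace(G) / p * np.eye(p),
                                     lower=True)
            B = linalg.solve_triangular(self.L, self.DtD, lower=True)
            B = linalg.solve_triangular(self.L, B.T, lower=True)
            self.s, self.U = linalg.eigh(B)
            self.s = np.maximum(self.s, 0.0)
            self.fast = True
        except linalg.LinAlgError:
            self.fast = False

    def curvature_range(self):
        """(largest, smallest positive) penalty-vs-loss curvature ratios.

        The anneal starts relative to the largest ratio (penalty initially
        negligible everywhere) and caps relative to the smallest positive
        one (even the weakest difference direction ends fully suppressed).
        """
        if self.fast:
            s_max = float(max(self.s.max(), 1e-12))
            pos = self.s[self.s > 1e-9 * s_max]
            s_min = float(pos.min()) if pos.size else s_max
            return s_max, s_min
        p = self.G.shape[0]
        g_scale = max(float(np.trace(self.G)) / p, 1e-12)
        s_max = float(np.linalg.norm(self.DtD, 2)) / g_scale
        return s_max, s_max

    def solve(self, lam, rhs):
        if self.fast:
            y = linalg.solve_triangular(self.L, rhs, lower=True)
            y = self.U @ ((self.U.T @ y) / (1.0 + lam * self.s))
            return linalg.solve_triangular(self.L, y, lower=True, trans="T")
        A = self.G + lam * self.DtD
        try:
            return linalg.solve(A, rhs, assume_a="pos")
        except linalg.LinAlgError:
            return linalg.lstsq(A, rhs)[0]


class _PatternScorer:
    """Exact scoring of contiguous-break cluster patterns under a quadratic.

    A pattern is a sorted tuple of break positions B in {1..q-1} along the
    tau order; blocks of penalized columns between breaks share one
    coefficient, unpenalized columns keep their own.  The collapsed normal
    matrix of any pattern is assembled in O(g^2) from 2-D prefix sums of
    the tau-permuted G, so thousands of candidate patterns can be scored by
    one batched solve.  The score is the minimized quadratic -0.5 b_c'gamma
    (up to the pattern-independent constant).
    """

    def __init__(self, G, b, tau: RankMap, penalized_cols, unpenalized_cols):
        pen_perm = np.asarray(penalized_cols, dtype=np.int64)[tau.order]
        unpen = np.asarray(sorted(unpenalized_cols), dtype=np.int64)
        q = pen_perm.size
        Gpp = G[np.ix_(pen_perm, pen_perm)]
        self.q = q
        self.u = unpen.size
        self.S2 = np.zeros((q + 1, q + 1))
        self.S2[1:, 1:] = Gpp.cumsum(axis=0).cumsum(axis=1)
        self.Cp = np.zeros((q + 1, self.u))
        if self.u:
            self.Cp[1:] = G[np.ix_(pen_perm, unpen)].cumsum(axis=0)
        self.Guu = G[np.ix_(unpen, unpen)] if self.u else np.zeros((0, 0))
        self.bp = np.zeros(q + 1)
        self.bp[1:] = np.cumsum(b[pen_perm])
        self.bu = b[unpen] if self.u else np.zeros(0)

    def score(self, boundaries):
        """Score a batch of patterns given as an (m, g+1) boundaries array
        (each row [0, b_1, ..., b_k, q], strictly increasing).  Returns
        (values, gammas)."""
        Bnd = np.asarray(boundaries, dtype=np.int64)
        hi = Bnd[:, 1:]
        lo = Bnd[:, :-1]
        Gpen = (self.S2[hi[:, :, None], hi[:, None, :]]
                - self.S2[lo[:, :, None], hi[:, None, :]]
                - self.S2[hi[:, :, None], lo[:, None, :]]
                + self.S2[lo[:, :, None], lo[:, None, :]])
        bc = self.bp[hi] - self.bp[lo]
        m, g = hi.shape
        gg = g + self.u
        A = np.empty((m, gg, gg))
        A[:, :g, :g] = Gpen
        rhs = np.empty((m, gg))
        rhs[:, :g] = bc
        if self.u:
            cross = self.Cp[hi] - self.Cp[lo]
            A[:, :g, g:] = cross
            A[:, g:, :g] = cross.transpose(0, 2, 1)
            A[:, g:, g:] = self.Guu
            rhs[:, g:] = self.bu
        A[:, np.arange(gg), np.arange(gg)] += 1e-10  # guard exact singularity
        try:
            gamma = np.linalg.solve(A, rhs[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            gamma = np.stack([np.linalg.lstsq(Ai, ri, rcond=None)[0]
                              for Ai, ri in zip(A, rhs)])
        values = -0.5 * np.einsum("mg,mg->m", rhs, gamma)
        return values, gamma

    def _boundaries(self, breaks_batch):
        m = len(breaks_batch)
        g = len(breaks_batch[0]) + 1
        Bnd = np.zeros((m, g + 1), dtype=np.int64)
        Bnd[:, -1] = self.q
        for i, br in enumerate(breaks_batch):
            Bnd[i, 1:-1] = br
        return Bnd

    def best_pattern(self, k: int):
        """Exhaustively best break pattern of size k under the quadratic."""
        from itertools import combinations

        kb = min(int(k), self.q - 1)
        combos = list(combinations(range(1, self.q), kb))
        vals, _ = self.score(self._boundaries(combos))
        return list(combos[int(np.argmin(vals))])


def _breaks_to_mask(breaks, q):
    mask = np.zeros(q - 1, dtype=bool)
    for b in breaks:
        mask[b - 1] = True
    return mask


def _solve_distance(X, z, w, D: FusionMatrix, spec, beta_init,
                    penalized_cols, unpenalized_cols, tol, max_steps, info):
    p = X.shape[1]
    G, b = _weighted_quadratic(X, z, w)
    D_emb = D.matrix(p_full=p, penalized_cols=penalized_cols)
    solver = _AnnealSolver(G, D_emb)
    beta = np.asarray(beta_init, dtype=float).copy()
    # schedule in curvature-relative units: lam * s is the ratio of penalty
    # to loss curvature along a difference direction, annealed from
    # spec.lam0 (relative to the stiffest direction) up to spec.lam_max
    # (relative to the softest)
    s_max, s_min = solver.curvature_range()
    lam = spec.lam0 / s_max
    lam_cap = spec.lam_max / s_min
    trace = info.setdefault("trace", [])
    converged = False
    for _ in range(max_steps):
        d = D_emb @ beta
        target = project_sparsity(d, spec.k)
        rhs = b + lam * (D_emb.T @ target)
        beta_new = solver.solve(lam, rhs)
        d_new = D_emb @ beta_new
        dist = float(np.linalg.norm(d_new - project_sparsity(d_new, spec.k)))
        # objective for the monotonicity trace: quadratic loss + lam/2 dist^2
        q = _quad_loss(G, b, z, w, X.shape[0], beta_new)
        trace.append((lam, q + 0.5 * lam * dist**2))
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if dist < tol and delta < tol:
            converged = True
            break
        lam = min(lam * spec.sched_growth, lam_cap)
    info["anneal_converged"] = converged
    if not converged:
        logger.warning("proximal-distance anneal hit the step cap; "
                       "proceeding with the current pattern")
    # terminal stage: hard-project onto the sparsity set and refit the fused
    # pattern so the returned coefficients are exactly cluster-constant; when
    # the pattern space is small enough, take the exhaustively best pattern
    # under the quadratic instead of the annealed one
    q = D.tau.p
    kb = min(spec.k, q - 1)
    if comb(q - 1, kb) <= ENUM_PATTERN_CAP:
        scorer = _PatternScorer(G, b, D.tau, penalized_cols, unpenalized_cols)
        breaks = scorer.best_pattern(kb)
    else:
        d = D_emb @ beta
        kept = project_sparsity(d, spec.k) != 0
        breaks = [int(i) + 1 for i in np.flatnonzero(kept)]
    labels = _clusters_from_breaks(D.tau, _breaks_to_mask(breaks, q))
    info["breaks"] = breaks
    beta = _refit_collapsed(X, z, w, labels, penalized_cols, unpenalized_cols, p)
    return beta


def _quad_loss(G, b, z, w, n, beta):
    w_eff = np.where(np.asarray(w, float) >= 1e-8, w, 0.0) / n
    const = 0.5 * float((w_eff * np.asarray(z, float) ** 2).sum())
    return 0.5 * float(beta @ G @ beta) - float(b @ beta) + const


def _prox_scalar(theta, spec: PenaltySpec, c: float):
    """prox_{c * P_lam}(theta) elementwise for lasso / SCAD / MCP."""
    lam = spec.lam
    a_t = np.abs(theta)
    sgn = np.sign(theta)
    if spec.family == "lasso":
        return sgn * np.maximum(a_t - c * lam, 0.0)
    if spec.family == "scad":
        a = spec.scad_a
        out = np.where(
            a_t <= lam * (1.0 + c),
            sgn * np.maximum(a_t - c * lam, 0.0),
            np.where(
                a_t <= a * lam,
                (theta - sgn * c * a * lam / (a - 1.0)) / max(1.0 - c / (a - 1.0), 1e-12),
                theta,
            ),
        )
        return out
    if spec.family == "mcp":
        g = spec.mcp_gamma
        soft = sgn * np.maximum(a_t - c * lam, 0.0)
        return np.where(a_t <= g * lam, soft / max(1.0 - c / g, 1e-12), theta)
    raise ValueError(spec.family)


def _solve_shrinkage(X, z, w, D: FusionMatrix, spec, beta_init,
                     penalized_cols, unpenalized_cols, tol, max_steps, info):
    """ADMM splitting u = D beta with the family's scalar proximal map."""
    p = X.shape[1]
    G, b = _weighted_quadratic(X, z, w)
    D_emb = D.matrix(p_full=p, penalized_cols=penalized_cols)
    rho = max(spec.lam, 1.0)
    solver = _AnnealSolver(G, D_emb)
    beta = np.asarray(beta_init, dtype=float).copy()
    u = D_emb @ beta
    v = np.zeros_like(u)
    converged = False
    for _ in range(max_steps):
        rhs = b + rho * (D_emb.T @ (u - v))
        beta = solver.solve(rho, rhs)
        Db = D_emb @ beta
        u_new = _prox_scalar(Db + v, spec, 1.0 / rho)
        dual = rho * float(np.linalg.norm(u_new - u))
        u = u_new
        v = v + Db - u
        primal = float(np.linalg.norm(Db - u))
        if primal < tol and dual < tol:
            converged = True
            break
    info["admm_converged"] = converged
    if not converged:
        logger.warning("ADMM splitting hit the iteration cap")
    # fuse on the exact-zero pattern of u and refit, so returned
    # coefficients are exactly cluster-constant (as for distance)
    break_mask = np.abs(u) > 1e-8
    labels = _clusters_from_breaks(D.tau, break_mask)
    return _refit_collapsed(X, z, w, labels, penalized_cols, unpenalized_cols, p)


def solve_fused_wls(X, z, w, D: FusionMatrix, spec: PenaltySpec, beta_init,
                    penalized_cols=None, unpenalized_cols=(),
                    tol: float = 1e-6, max_steps: int = 400,
                    info: dict = None) -> np.ndarray:
    """Minimize (1/2) sum_i (w_i/n)(z_i - x_i' beta)^2 + lam * P(D beta).

    The fusion matrix acts on the ``penalized_cols`` of beta (all columns by
    default).  Distance family: proximal-distance anneal followed by a hard
    projection and constrained WLS refit on the fused pattern, so the result
    is exactly cluster-constant.  Shrinkage families (lasso/scad/mcp): ADMM
    on the split u = D beta, fused on the zero pattern of u and refit.

    Pass ``info`` (a dict) to receive the objective trace and convergence
    flags; non-convergence returns the current iterate with a warning.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if penalized_cols is None:
        penalized_cols = np.arange(p)
    penalized_cols = np.asarray(penalized_cols, dtype=np.int64)
    if D.p != penalized_cols.size:
        raise ValueError("fusion matrix width disagrees with penalized columns")
    if beta_init is None:
        beta_init = np.zeros(p)
    if info is None:
        info = {}
    if spec.family == "distance":
        if spec.k >= D.p - 1:
            # vacuous constraint: dist is identically 0, plain WLS
            labels = _clusters_from_breaks(D.tau, np.ones(D.p - 1, dtype=bool))
            return _refit_collapsed(X, z, w, labels, penalized_cols,
                                    tuple(unpenalized_cols), p)
        return _solve_distance(X, z, w, D, spec, beta_init, penalized_cols,
                               tuple(unpenalized_cols), tol, max_steps, info)
    return _solve_shrinkage(X, z, w, D, spec, beta_init, penalized_cols,
                            tuple(unpenalized_cols), tol, max_steps, info)
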