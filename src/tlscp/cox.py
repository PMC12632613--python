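"""Cox partial-likelihood machinery.

Right-censored survival data are modelled with the Cox proportional hazards
model, h_i(t) = h0(t) exp(x_i' beta).  This module provides the log partial
likelihood under the Breslow tie convention, the IRLS (iteratively reweighted
least squares) quadratic approximation used by the fusion-penalized solver,
and a plain Newton fitter for preliminary coefficient estimates.

All heavy quantities are computed from risk-set cumulative sums after sorting
by observed time, so evaluations are O(n log n) and numerically stable under
large linear predictors (risk sums are formed on exp(eta - max eta)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger("tlscp")

#: weights below this floor are treated as zero in the working least squares
#: problem; the matching working response falls back to eta (no information).
EPS_WEIGHT = 1e-8


@dataclass(frozen=True)
class SurvivalDataset:
    """A right-censored cohort.

    Parameters
    ----------
    times : (n,) array of strictly positive observed times y_i.
    status : (n,) array of event indicators delta_i (1 = event, 0 = censored).
    covariates : (n, p) design matrix, one row per subject.
    unpenalized_cols : indices of covariate columns that are estimated but
        excluded from fusion penalization (e.g. a sex adjustment next to the
        mutation indicators).
    columns : optional covariate names; defaults to x1..xp on file round-trips.
    """

    times: np.ndarray
    status: np.ndarray
    covariates: np.ndarray
    unpenalized_cols: frozenset = frozenset()
    columns: tuple = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        status = np.asarray(self.status, dtype=float)
        X = np.asarray(self.covariates, dtype=float)
        if X.ndim != 2:
            raise ValueError("covariates must be a 2-D matrix")
        n = times.shape[0]
        if status.shape[0] != n or X.shape[0] != n:
            raise ValueError("times, status and covariates disagree on n")
        if not np.all(np.isfinite(times)) or np.any(times <= 0):
            raise ValueError("times must be finite and strictly positive")
        if not np.isin(status, (0.0, 1.0)).all():
            raise ValueError("status must be 0/1")
        if not np.all(np.isfinite(X)):
            raise ValueError("covariates contain missing or non-finite values")
        upc = frozenset(int(j) for j in self.unpenalized_cols)
        if any(j < 0 or j >= X.shape[1] for j in upc):
            raise ValueError("unpenalized_cols out of range")
        cols = self.columns
        if cols is not None:
            cols = tuple(str(c) for c in cols)
            if len(cols) != X.shape[1]:
                raise ValueError("columns length must equal p")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "status", status.astype(np.int64))
        object.__setattr__(self, "covariates", X)
        object.__setattr__(self, "unpenalized_cols", upc)
        object.__setattr__(self, "columns", cols)

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @property
    def penalized_cols(self) -> np.ndarray:
        """Sorted indices of columns subject to the fusion penalty."""
        return np.array(
            [j for j in range(self.p) if j not in self.unpenalized_cols],
            dtype=np.int64,
        )

    @property
    def column_names(self) -> tuple:
        if self.columns is not None:
            return self.columns
        return tuple(f"x{j + 1}" for j in range(self.p))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, unpenalized=()) -> "SurvivalDataset":
        """Build a dataset from a table with `time`, `status` and covariates.

        ``unpenalized`` may name covariate columns (strings) or give indices.
        """
        for col in ("time", "status"):
            if col not in df.columns:
                raise ValueError(f"missing required column '{col}'")
        cov_names = [c for c in df.columns if c not in ("time", "status")]
        idx = set()
        for u in unpenalized:
            if isinstance(u, str):
                if u not in cov_names:
                    raise ValueError(f"unknown unpenalized column '{u}'")
                idx.add(cov_names.index(u))
            else:
                idx.add(int(u))
        return cls(
            times=df["time"].to_numpy(dtype=float),
            status=df["status"].to_numpy(),
            covariates=df[cov_names].to_numpy(dtype=float),
            unpenalized_cols=frozenset(idx),
            columns=tuple(cov_names),
        )

    @classmethod
    def read_csv(cls, path, unpenalized=()) -> "SurvivalDataset":
        return cls.from_dataframe(pd.read_csv(path), unpenalized=unpenalized)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, "status": self.status})
        for j, name in enumerate(self.column_names):
            df[name] = self.covariates[:, j]
        return df

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class CoxWorkingSet:
    """IRLS working quantities at a linear predictor eta.

    ``weights`` are the diagonal curvature terms w_i and ``responses`` the
    working responses z_i of the weighted-least-squares expansion of the
    negative log partial likelihood.  Subjects at risk for no event time
    carry weight exactly 0 and response equal to eta.
    """

    eta: np.ndarray
    weights: np.ndarray
    responses: np.ndarray


def _require_events(data: SurvivalDataset) -> None:
    if data.n_events < 1:
        raise ValueError("no events in dataset")


def _risk_sums(times, status, eta):
    """Per-event risk sums and per-subject cumulative event quantities.

    Returns (loglik_terms, A, B) where, with u_i = exp(eta_i - c) and
    S_k = sum_{j: y_j >= t_k} u_j over event occurrences k (Breslow: tied
    events share the same risk set),

      A_i = sum_{k: t_k <= y_i} 1 / S_k
      B_i = sum_{k: t_k <= y_i} 1 / S_k^2

    and loglik_terms sums eta_{j(k)} - log(S_k) - c over events.
    """
    c = float(np.max(eta))
    u = np.exp(eta - c)
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    # rev[i] = sum of u over subjects with sorted position >= i
    rev = np.cumsum(u[order][::-1])[::-1]

    event_mask = status == 1
    t_events = times[event_mask]
    ev_order = np.argsort(t_events, kind="stable")
    t_ev = t_events[ev_order]
    # risk sum at each event time: subjects with y_j >= t_ev (ties included)
    pos = np.searchsorted(t_sorted, t_ev, side="left")
    S = rev[pos]

    eta_ev = eta[event_mask][ev_order]
    loglik = float(np.sum(eta_ev - np.log(S) - c))

    inv1 = np.cumsum(1.0 / S)
    inv2 = np.cumsum(1.0 / S**2)
    # number of event times <= y_i for every subject
    cnt = np.searchsorted(t_ev, times, side="right")
    A = np.where(cnt > 0, inv1[np.maximum(cnt - 1, 0)], 0.0)
    B = np.where(cnt > 0, inv2[np.maximum(cnt - 1, 0)], 0.0)
    return loglik, u, A, B


def log_partial_likelihood(data: SurvivalDataset, beta) -> float:
    """Breslow log partial likelihood l(beta).

    l(beta) = sum over events [ x_{j(i)}' beta - log sum_{j in R_i} e^{x_j' beta} ]
    with risk sets R_i = {j : y_j >= t_i}; tied event times share a risk set.
    Computed with a log-sum-exp shift for stability.
    """
    _require_events(data)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (data.p,):
        raise ValueError(f"beta must have length {data.p}")
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta contains non-finite entries")
    eta = data.covariates @ beta
    loglik, _, _, _ = _risk_sums(data.times, data.status, eta)
    return loglik


def eta_gradient(data: SurvivalDataset, eta) -> np.ndarray:
    """Gradient of the log partial likelihood with respect to eta."""
    _require_events(data)
    _, u, A, _ = _risk_sums(data.times, data.status, np.asarray(eta, float))
    return data.status - u * A


def irls_update(data: SurvivalDataset, eta) -> CoxWorkingSet:
    """One IRLS expansion of the log partial likelihood at eta.

    w_i = sum_{k in C_i} [ pi_ik - pi_ik^2 ],  pi_ik = e^{eta_i} / sum_{R_k} e^{eta_j}
    z_i = eta_i + (delta_i - sum_{k in C_i} pi_ik) / max(w_i, eps)

    where C_i = {k : t_k <= y_i} runs over event occurrences.  -w is the
    diagonal of the Hessian of l with respect to eta; the z-residual encodes
    its gradient.
    """
    _require_events(data)
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (data.n,) or not np.all(np.isfinite(eta)):
        raise ValueError("eta must be a finite length-n vector")
    _, u, A, B = _risk_sums(data.times, data.status, eta)
    w = np.maximum(u * A - u**2 * B, 0.0)
    grad = data.status - u * A
    z = np.where(w >= EPS_WEIGHT, eta + grad / np.maximum(w, EPS_WEIGHT), eta)
    return CoxWorkingSet(eta=eta, weights=w, responses=z)


def _grad_hess(data: SurvivalDataset, beta):
    """Log partial likelihood with its exact gradient and Hessian in beta.

    With u_i = exp(eta_i - c), risk sums S_k and risk-set means
    mu_k = sum_{R_k} u_j x_j / S_k at each event occurrence k:

      grad l  = X' (delta - u * A)
      -Hess l = X' diag(u * A) X - sum_k mu_k mu_k'

    where A_i = sum_{k in C_i} 1/S_k; the mu_k are formed from reverse
    cumulative sums over time-sorted subjects, so the cost is O(n p + m p^2).
    """
    X = data.covariates
    times, status = data.times, data.status
    eta = X @ beta
    loglik, u, A, _ = _risk_sums(times, status, eta)
    grad = X.T @ (status - u * A)

    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    ux_rev = np.cumsum((u[:, None] * X)[order][::-1], axis=0)[::-1]
    u_rev = np.cumsum(u[order][::-1])[::-1]
    t_ev = np.sort(times[status == 1], kind="stable")
    pos = np.searchsorted(t_sorted, t_ev, side="left")
    S = u_rev[pos]
    V = ux_rev[pos] / S[:, None]  # (m, p) risk-set weighted covariate means
    neg_hess = (X * (u * A)[:, None]).T @ X - V.T @ V
    return loglik, grad, neg_hess


_DIVERGE_CAP = 500.0


def fit_cox(data: SurvivalDataset, ridge: float = 0.0, beta_init=None,
            max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Unpenalized (optionally ridged) Cox fit by Newton/IRLS with step halving.

    Maximizes l(beta)/n - (ridge/2) ||beta||^2.  On divergence (coefficient
    magnitudes growing past a cap) the fit is retried once with ridge=1e-4;
    a second divergence raises.
    """
    _require_events(data)
    try:
        return _fit_cox_inner(data, ridge, beta_init, max_iter, tol)
    except _Divergence:
        if ridge >= 1e-4:
            raise RuntimeError("Cox fit diverged even with ridge regularization")
        logger.warning("Cox fit diverging; retrying with ridge=1e-4")
        try:
            return _fit_cox_inner(data, 1e-4, beta_init, max_iter, tol)
        except _Divergence:
            raise RuntimeError("Cox fit diverged even with ridge regularization")


class _Divergence(Exception):
    pass


def _fit_cox_inner(data, ridge, beta_init, max_iter, tol):
    X = data.covariates
    n = data.n
    beta = (np.zeros(data.p) if beta_init is None
            else np.asarray(beta_init, dtype=float).copy())

    def objective(b):
        return log_partial_likelihood(data, b) / n - 0.5 * ridge * float(b @ b)

    f = objective(beta)
    grow_streak = 0
    prev_norm = float(np.max(np.abs(beta))) if beta.size else 0.0
    eye = np.eye(data.p)
    for _ in range(max_iter):
        _, grad, neg_hess = _grad_hess(data, beta)
        g = grad / n - ridge * beta
        H = neg_hess / n + ridge * eye
        try:
            direction = linalg.solve(H, g, assume_a="pos")
        except linalg.LinAlgError:
            direction = linalg.lstsq(H, g)[0]
        step = 1.0
        f_new, beta_new = f, beta
        for _ in range(21):
            cand = beta + step * direction
            fc = objective(cand)
            if np.isfinite(fc) and fc > f:
                f_new, beta_new = fc, cand
                break
            step *= 0.5
        if f_new <= f:  # no ascent found
            break
        cur_norm = float(np.max(np.abs(beta_new)))
        grow_streak = grow_streak + 1 if cur_norm > prev_norm else 0
        prev_norm = cur_norm
        if cur_norm > _DIVERGE_CAP and grow_streak >= 3:
            raise _Divergence
        delta = (f_new - f) * n  # convergence judged on the loglik scale
        beta, f = beta_new, f_new
        if delta < tol:
            break
    else:
        logger.warning("fit_cox reached the iteration cap without full convergence")
    return beta
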