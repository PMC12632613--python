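"""Transfer learning for SCP by weighted rank averaging (TL-SCP).

When the target cohort is small, the preliminary coefficient ranking that
SCP fuses along is unreliable.  TL-SCP assumes the source and target share
a similar *ranking* of coefficient effects (weaker than the magnitude
similarity used by difference-penalty transfer methods): separate Cox fits
produce rank vectors for each cohort, which are merged by a weighted
average of ranks, and SCP then runs on the target with the merged ordering.
Only ranks cross the cohort boundary — source coefficient magnitudes never
enter the target fit — so summary-level source input (a rank vector)
suffices when individual-level data cannot be shared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .cox import SurvivalDataset, fit_cox
from .fusion import RankMap
from .solver import SCPFit, select_k_bic

logger = logging.getLogger("tlscp")


@dataclass(frozen=True)
class TransferWeights:
    """Per-feature rank-averaging weights (w_S, w_T).

    Scalar mode uses sample-size ratios n_S/(n_S+n_T) and n_T/(n_S+n_T)
    replicated across features.  Per-feature mode uses carrier counts,
    w_Tj = n_Tj/(n_Tj + n_Sj), for predictors (e.g. mutation indicators)
    observed with different frequencies in the two cohorts.
    """

    w_source: np.ndarray
    w_target: np.ndarray

    def __post_init__(self):
        ws = np.asarray(self.w_source, dtype=float)
        wt = np.asarray(self.w_target, dtype=float)
        if ws.shape != wt.shape or ws.ndim != 1:
            raise ValueError("weight vectors must be 1-D with equal length")
        if np.any(ws < 0) or np.any(wt < 0) or np.any(ws + wt <= 0):
            raise ValueError("weights must be nonnegative with w_S + w_T > 0")
        object.__setattr__(self, "w_source", ws)
        object.__setattr__(self, "w_target", wt)

    @classmethod
    def from_sample_sizes(cls, n_source: int, n_target: int, p: int):
        tot = n_source + n_target
        return cls(w_source=np.full(p, n_source / tot),
                   w_target=np.full(p, n_target / tot))

    @classmethod
    def from_carrier_counts(cls, counts_source, counts_target):
        ns = np.asarray(counts_source, dtype=float)
        nt = np.asarray(counts_target, dtype=float)
        tot = ns + nt
        return cls(w_source=ns / tot, w_target=nt / tot)


def ranks_of(beta) -> np.ndarray:
    """1-based ranks of coefficients, ties broken by first occurrence."""
    return rankdata(np.asarray(beta, dtype=float), method="ordinal").astype(np.int64)


def _check_permutation(r, name):
    r = np.asarray(r, dtype=np.int64)
    if r.ndim != 1 or not np.array_equal(np.sort(r), np.arange(1, r.size + 1)):
        raise ValueError(f"{name} is not a permutation of 1..p")
    return r


def weighted_rank_average(rank_source, rank_target,
                          weights: TransferWeights) -> RankMap:
    """Merge two rank vectors into one ordering.

    score_j = w_S[j] * rank_S(j) + w_T[j] * rank_T(j); the merged ordering
    sorts scores ascending with lowest-index tie-break.  Invariant to any
    common positive rescaling of the two weight vectors.
    """
    rs = _check_permutation(rank_source, "rank_source")
    rt = _check_permutation(rank_target, "rank_target")
    if rs.size != rt.size:
        raise ValueError("rank vectors differ in length")
    if weights.w_source.size != rs.size:
        raise ValueError("weights length disagrees with rank vectors")
    scores = weights.w_source * rs + weights.w_target * rt
    return RankMap(order=np.argsort(scores, kind="stable"))


def _restrict_source_ranks(source_ranks: dict, target_names) -> np.ndarray:
    """Re-rank a named source rank vector on the target's covariate set."""
    missing = [c for c in target_names if c not in source_ranks]
    if missing:
        raise ValueError(
            f"source ranks missing target covariates: {missing[:5]}"
        )
    restricted = np.array([float(source_ranks[c]) for c in target_names])
    return ranks_of(restricted)


def fit_tlscp(target: SurvivalDataset, source=None, source_ranks=None,
              weights="auto", spec_grid=None, source_n: int = None,
              **fit_kwargs) -> SCPFit:
    """TL-SCP: merge source/target coefficient rankings, then run SCP.

    ``source`` is a SurvivalDataset; alternatively pass ``source_ranks`` as
    a precomputed rank vector over the target's penalized columns (or a
    {name: rank} mapping keyed by covariate name, which is restricted to
    the target's covariates and re-ranked).  ``weights`` is a
    TransferWeights, or "auto" for scalar sample-size ratios (requires
    ``source_n`` when only ranks are supplied).  ``spec_grid`` defaults to
    the distance penalty with BIC over k in {1..5}.
    """
    pen = target.penalized_cols
    p_pen = pen.size

    prelim_t = fit_cox(target)
    rank_t = ranks_of(prelim_t[pen])

    if source is not None:
        if source_ranks is not None:
            raise ValueError("pass either source data or source ranks, not both")
        src_names = source.column_names
        tgt_pen_names = [target.column_names[j] for j in pen]
        prelim_s = fit_cox(source)
        if tuple(src_names) == tuple(target.column_names):
            rank_s = ranks_of(prelim_s[pen])
        else:
            named = dict(zip(src_names, prelim_s))
            if not set(tgt_pen_names) <= set(src_names):
                raise ValueError(
                    "target penalized covariates must be a subset of the source's"
                )
            rank_s = ranks_of([named[c] for c in tgt_pen_names])
        n_source = source.n
    elif source_ranks is not None:
        if isinstance(source_ranks, dict):
            tgt_pen_names = [target.column_names[j] for j in pen]
            rank_s = _restrict_source_ranks(source_ranks, tgt_pen_names)
        else:
            rank_s = _check_permutation(source_ranks, "source_ranks")
            if rank_s.size != p_pen:
                raise ValueError("source_ranks length disagrees with target")
        n_source = source_n
    else:
        raise ValueError("either source data or source ranks are required")

    if isinstance(weights, str) and weights == "auto":
        if n_source is None:
            raise ValueError("auto weights need the source sample size")
        weights = TransferWeights.from_sample_sizes(n_source, target.n, p_pen)

    tau = weighted_rank_average(rank_s, rank_t, weights)

    if spec_grid is None:
        from .solver import default_k_grid
        spec_grid = default_k_grid(p_pen)
    return select_k_bic(target, spec_grid, tau=tau, beta_init=prelim_t,
                        **fit_kwargs)
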