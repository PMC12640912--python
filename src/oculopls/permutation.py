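"""Permutation nulls for group differences in rank correlations and in
adjusted R^2, plus the paired true-age vs predicted-age comparison.

All tests are two-tailed with "more extreme" read as ``|perm| >= |obs|``
(plain proportion over replicates; optional add-one smoothing). When the
number of distinct relabelings or swap patterns does not exceed the
requested replicate count, the null is enumerated exhaustively instead of
sampled, and the result is flagged ``exact``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pls import ModelingConfig, PLSModelReport, fit_pls, r2_and_adjusted
from .stats import _rank_rho

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult", "permute_rho_difference", "permute_r2_difference",
    "permute_paired_rho_difference",
]


@dataclass(frozen=True)
class PermutationResult:
    statistic_name: str
    observed_difference: float
    n_replicates: int
    p_two_tailed: float
    null_quantiles: tuple[float, float, float]  # 2.5%, 50%, 97.5%
    seed: int
    exact: bool = False
    n_discarded: int = 0
    note: str = ""


def _finish(name, observed, null, seed, exact, n_discarded, add_one,
            note="") -> PermutationResult:
    null = np.asarray(null, dtype=float)
    hits = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    if add_one:
        p = (hits + 1) / (null.size + 1)
    else:
        p = hits / null.size
    q = np.quantile(null, [0.025, 0.5, 0.975])
    return PermutationResult(
        statistic_name=name, observed_difference=float(observed),
        n_replicates=int(null.size), p_two_tailed=float(p),
        null_quantiles=(float(q[0]), float(q[1]), float(q[2])),
        seed=seed, exact=exact, n_discarded=n_discarded, note=note,
    )


def permute_rho_difference(x_a, y_a, x_b, y_b, n_replicates: int = 1000,
                           seed: int = 0, add_one: bool = False,
                           ) -> PermutationResult:
    """Difference in Spearman rho between two groups of (x, y) pairs.

    Null: pool the pairs and reassign group labels preserving group sizes.
    Enumerated exactly when C(n, n_a) <= n_replicates.
    """
    x_a = np.asarray(x_a, dtype=float)
    y_a = np.asarray(y_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    if x_a.size < 3 or x_b.size < 3:
        raise ValueError("each group needs at least 3 pairs")
    rho_a = _rank_rho(x_a, y_a)
    rho_b = _rank_rho(x_b, y_b)
    if math.isnan(rho_a) or math.isnan(rho_b):
        raise ValueError("observed correlation undefined (zero rank variance)")
    observed = rho_a - rho_b
    X = np.concatenate([x_a, x_b])
    Y = np.concatenate([y_a, y_b])
    n = X.size
    n_a = x_a.size

    def diff_for(idx_a: np.ndarray) -> float:
        mask = np.zeros(n, dtype=bool)
        mask[idx_a] = True
        da = _rank_rho(X[mask], Y[mask])
        db = _rank_rho(X[~mask], Y[~mask])
        return da - db

    exact = math.comb(n, n_a) <= n_replicates
    null = []
    discarded = 0
    if exact:
        for combo in itertools.combinations(range(n), n_a):
            d = diff_for(np.asarray(combo))
            if math.isnan(d):
                discarded += 1
                continue
            null.append(d)
    else:
        rng = np.random.default_rng(seed)
        while len(null) < n_replicates:
            d = diff_for(rng.permutation(n)[:n_a])
            if math.isnan(d):
                discarded += 1
                if discarded > 100 * n_replicates:
                    raise ValueError("degenerate data: permuted correlations "
                                     "undefined too often")
                continue
            null.append(d)
    if discarded:
        logger.info("discarded %d degenerate replicates", discarded)
    return _finish("spearman_rho_difference", observed, null, seed, exact,
                   discarded, add_one)


def permute_paired_rho_difference(age_true, age_predicted, score,
                                  n_replicates: int = 1000, seed: int = 0,
                                  add_one: bool = False) -> PermutationResult:
    """rho(true, score) - rho(predicted, score), paired per participant.

    Null: independently swap (true, predicted) within each participant with
    probability 1/2 (sign-flip exchangeability of the proxy). Enumerated
    exactly when 2^n <= n_replicates.
    """
    t = np.asarray(age_true, dtype=float)
    p = np.asarray(age_predicted, dtype=float)
    s = np.asarray(score, dtype=float)
    if not (t.size == p.size == s.size):
        raise ValueError("vectors must be aligned")
    n = t.size
    if n < 4:
        raise ValueError("need at least 4 participants")
    observed = _rank_rho(t, s) - _rank_rho(p, s)
    if math.isnan(observed):
        raise ValueError("observed correlation undefined")

    def diff_for(swap_mask: np.ndarray) -> float:
        a = np.where(swap_mask, p, t)
        b = np.where(swap_mask, t, p)
        return _rank_rho(a, s) - _rank_rho(b, s)

    exact = n <= 30 and 2**n <= n_replicates
    null = []
    discarded = 0
    if exact:
        for bits in range(2**n):
            mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
            d = diff_for(mask)
            if math.isnan(d):
                discarded += 1
                continue
            null.append(d)
    else:
        rng = np.random.default_rng(seed)
        while len(null) < n_replicates:
            d = diff_for(rng.random(n) < 0.5)
            if math.isnan(d):
                discarded += 1
                if discarded > 100 * n_replicates:
                    raise ValueError("degenerate data in paired permutation")
                continue
            null.append(d)
    return _finish("paired_rho_difference", observed, null, seed, exact,
                   discarded, add_one)


def permute_r2_difference(X_a, y_a, X_b, y_b,
                          model_a: PLSModelReport, model_b: PLSModelReport,
                          n_replicates: int = 1000, seed: int = 0,
                          add_one: bool = False) -> PermutationResult:
    """Difference in adjusted R^2 between two fitted per-group models.

    ``X_a``/``X_b`` are complete feature DataFrames (one row per modeled
    participant, columns covering each model's selected features) and
    ``y_a``/``y_b`` the outcome vectors. The null pools participants and
    shuffles group labels preserving sizes; within each pseudo-group the
    PLS coefficients are refit with that group's FIXED selected features
    and component count (feature selection is not redone per replicate),
    and the adjusted-R^2 difference is recomputed.
    """
    feats_a = list(model_a.selected_features)
    feats_b = list(model_b.selected_features)
    k_a, k_b = model_a.n_components, model_b.n_components
    pool_cols = sorted(set(feats_a) | set(feats_b))
    Xp = pd.concat([X_a[pool_cols], X_b[pool_cols]],
                   ignore_index=True).to_numpy(dtype=float)
    yp = np.concatenate([np.asarray(y_a, float), np.asarray(y_b, float)])
    n_a = len(X_a)
    n = len(yp)
    col_idx = {c: i for i, c in enumerate(pool_cols)}
    ia = np.asarray([col_idx[c] for c in feats_a])
    ib = np.asarray([col_idx[c] for c in feats_b])

    observed = model_a.r2_adjusted - model_b.r2_adjusted

    def adj_r2(X, y, cols, k, p_count):
        model = fit_pls(X[:, cols], y, n_components=min(k, cols.size))
        _, adj = r2_and_adjusted(y, model.training_predictions, p_count)
        return adj

    rng = np.random.default_rng(seed)
    null = []
    discarded = 0
    while len(null) < n_replicates:
        perm = rng.permutation(n)
        ra, rb = perm[:n_a], perm[n_a:]
        try:
            d = (adj_r2(Xp[ra], yp[ra], ia, k_a, len(feats_a))
                 - adj_r2(Xp[rb], yp[rb], ib, k_b, len(feats_b)))
        except (ValueError, np.linalg.LinAlgError):
            discarded += 1
            if discarded > 100 * n_replicates:
                raise ValueError("pseudo-groups unfittable too often")
            continue
        null.append(d)
    if discarded:
        logger.info("resampled %d unfittable replicates", discarded)
    return _finish(
        "adjusted_r2_difference", observed, null, seed, False, discarded,
        add_one,
        note="coefficients refit per replicate; feature selection fixed",
    )
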