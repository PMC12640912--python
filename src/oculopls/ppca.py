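"""Probabilistic PCA with missing data, fit by EM, for imputation.

Model: ``x = W z + mu + eps`` with ``z ~ N(0, I_r)`` and isotropic noise
``eps ~ N(0, sigma^2 I)``. Missing entries are marginalized out of the
likelihood exactly (they never enter the E- or M-step), which makes the
observed-data log-likelihood provably nondecreasing across iterations.
Columns are standardized internally on their observed entries and
back-transformed on output.

The E-step groups rows by missing pattern so cohorts with block-structured
missingness (whole task blocks absent) cost one small matrix inverse per
pattern rather than per row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PPCAModel", "ImputationReport", "fit_ppca", "impute", "select_rank"]


@dataclass
class PPCAModel:
    mean_vector: np.ndarray          # per-parameter mean, original units
    loading_matrix: np.ndarray       # parameters x rank, original units
    isotropic_noise_variance: float  # sigma^2 in standardized units
    rank: int
    converged: bool
    n_iterations: int
    final_delta: float               # last relative log-lik change
    log_likelihood_path: np.ndarray = field(repr=False)
    # internal standardized-space parameters used for imputation
    _col_means: np.ndarray = field(repr=False, default=None)
    _col_sds: np.ndarray = field(repr=False, default=None)
    _mu: np.ndarray = field(repr=False, default=None)
    _W: np.ndarray = field(repr=False, default=None)

    @property
    def n_parameters(self) -> int:
        return self.mean_vector.size


@dataclass(frozen=True)
class ImputationReport:
    n_cells_imputed: int
    fraction_missing: float
    rank_used: int
    cv_reconstruction_error: float | None = None


def _check_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all():
        raise ValueError("every row must have at least one observed value")
    if not obs.any(axis=0).all():
        raise ValueError("every column must have at least one observed value")
    return X


def _standardize(X: np.ndarray):
    obs = ~np.isnan(X)
    means = np.nanmean(X, axis=0)
    sds = np.nanstd(X, axis=0, ddof=0)
    if np.any(sds == 0):
        j = int(np.flatnonzero(sds == 0)[0])
        raise ValueError(f"column {j} is constant on its observed entries; "
                         "drop or perturb it before PPCA")
    return (X - means) / sds, means, sds, obs


def _pattern_groups(obs: np.ndarray):
    """Row indices grouped by identical missing pattern."""
    patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
    return [(patterns[k].nonzero()[0], np.flatnonzero(inverse == k))
            for k in range(len(patterns))]


def _e_step(Y, groups, W, mu, sigma2):
    """Posterior latent moments and observed-data log-likelihood."""
    n, d = Y.shape
    r = W.shape[1]
    Ez = np.empty((n, r))
    covs = {}          # group index -> sigma^2 * M^-1 (shared within group)
    loglik = 0.0
    for gi, (O, R) in enumerate(groups):
        WO = W[O]                        # q x r
        M = sigma2 * np.eye(r) + WO.T @ WO
        Minv = np.linalg.inv(M)
        B = Y[np.ix_(R, O)] - mu[O]      # n_g x q
        BW = B @ WO                      # n_g x r
        EzR = BW @ Minv
        Ez[R] = EzR
        covs[gi] = sigma2 * Minv
        q = O.size
        sign, logdet_M = np.linalg.slogdet(M)
        logdet_C = (q - r) * math.log(sigma2) + logdet_M
        quad = (np.einsum("ij,ij->i", B, B)
                - np.einsum("ij,ij->i", BW, EzR)) / sigma2
        loglik += -0.5 * (q * math.log(2 * math.pi) * R.size
                          + logdet_C * R.size + quad.sum())
    return Ez, covs, loglik


def _m_step(Y, groups, Ez, covs, r):
    n, d = Y.shape
    A = np.zeros((d, r + 1, r + 1))
    c = np.zeros((d, r + 1))
    for gi, (O, R) in enumerate(groups):
        E = Ez[R]
        n_g = R.size
        block = np.empty((r + 1, r + 1))
        block[:r, :r] = E.T @ E + n_g * covs[gi]
        block[:r, r] = block[r, :r] = E.sum(axis=0)
        block[r, r] = n_g
        A[O] += block
        Yg = Y[np.ix_(R, O)]
        c[O, :r] += (E.T @ Yg).T
        c[O, r] += Yg.sum(axis=0)
    sol = np.linalg.solve(A, c[..., None])[..., 0]   # d x (r+1)
    W = sol[:, :r]
    mu = sol[:, r]
    # sigma^2 with the new (W, mu) and the current posterior (ECM step)
    sse = 0.0
    n_obs = 0
    for gi, (O, R) in enumerate(groups):
        resid = Y[np.ix_(R, O)] - Ez[R] @ W[O].T - mu[O]
        WcW = np.einsum("ij,jk,ik->i", W[O], covs[gi], W[O])
        sse += (resid**2).sum() + R.size * WcW.sum()
        n_obs += R.size * O.size
    sigma2 = max(sse / n_obs, 1e-12)
    return W, mu, sigma2


def fit_ppca(X, rank: int, tol: float = 1e-6, max_iter: int = 500,
             seed: int = 0) -> PPCAModel:
    """Fit the PPCA model to a matrix with NaN-coded missing entries.

    Initialization is deterministic (truncated SVD of the zero-imputed
    standardized matrix); ``seed`` is accepted for interface stability but
    the fit involves no random draws. Non-convergence within ``max_iter``
    is reported via ``converged=False``, not raised.
    """
    X = _check_matrix(X)
    n, d = X.shape
    if not 1 <= rank < min(n, d):
        raise ValueError(f"rank must be in [1, {min(n, d) - 1}], got {rank}")
    Y, means, sds, obs = _standardize(X)
    Yz = np.where(obs, Y, 0.0)
    groups = _pattern_groups(obs)

    # init: mu from observed column means (0 after standardization),
    # W from truncated SVD, sigma^2 from the residual variance
    U, S, Vt = np.linalg.svd(Yz, full_matrices=False)
    W = (Vt[:rank].T * (S[:rank] / math.sqrt(n)))
    mu = np.zeros(d)
    total_var = (Yz**2).sum() / obs.sum()
    expl = ((S[:rank]**2).sum() / n) / d
    sigma2 = max(total_var - expl, 1e-3)

    path = []
    prev = -np.inf
    delta = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Ez, covs, loglik = _e_step(Y, groups, W, mu, sigma2)
        path.append(loglik)
        if np.isfinite(prev):
            delta = abs(loglik - prev) / (abs(prev) + 1e-300)
            if delta < tol:
                converged = True
                break
        prev = loglik
        W, mu, sigma2 = _m_step(Y, groups, Ez, covs, rank)
        if sigma2 <= 1e-11:
            # noiseless degenerate regime: the likelihood diverges and
            # further iterations only accumulate rounding noise
            converged = True
            break

    return PPCAModel(
        mean_vector=means + sds * mu,
        loading_matrix=W * sds[:, None],
        isotropic_noise_variance=float(sigma2),
        rank=rank,
        converged=converged,
        n_iterations=it,
        final_delta=float(delta),
        log_likelihood_path=np.asarray(path),
        _col_means=means, _col_sds=sds, _mu=mu, _W=W,
    )


def impute(model: PPCAModel, X) -> tuple[np.ndarray, ImputationReport]:
    """Posterior-mean completion; observed cells pass through bit-exactly."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_parameters:
        raise ValueError(
            f"X must have {model.n_parameters} columns, got shape {X.shape}")
    obs = ~np.isnan(X)
    out = X.copy()
    n_missing = int((~obs).sum())
    if n_missing:
        Y = (X - model._col_means) / model._col_sds
        groups = _pattern_groups(obs)
        Ez, _, _ = _e_step(Y, groups, model._W, model._mu,
                           model.isotropic_noise_variance)
        recon_std = model._mu + Ez @ model._W.T
        recon = model._col_means + model._col_sds * recon_std
        out[~obs] = recon[~obs]
    report = ImputationReport(
        n_cells_imputed=n_missing,
        fraction_missing=n_missing / X.size,
        rank_used=model.rank,
    )
    return out, report


def _holdout_cells(obs: np.ndarray, fraction: float, rng) -> np.ndarray:
    """Random observed cells to hide, keeping >=1 observation per row/column."""
    rows, cols = np.nonzero(obs)
    order = rng.permutation(rows.size)
    target = int(round(fraction * rows.size))
    row_left = obs.sum(axis=1).astype(int)
    col_left = obs.sum(axis=0).astype(int)
    chosen = []
    for idx in order:
        if len(chosen) >= target:
            break
        i, j = rows[idx], cols[idx]
        if row_left[i] > 1 and col_left[j] > 1:
            chosen.append((i, j))
            row_left[i] -= 1
            col_left[j] -= 1
    return np.array(chosen, dtype=int).reshape(-1, 2)


def select_rank(X, candidate_ranks, n_folds: int = 5, seed: int = 0,
                holdout_fraction: float = 0.10,
                tol: float = 1e-5, max_iter: int = 200):
    """Choose the PPCA rank by held-out reconstruction error.

    Each fold hides an additional random 10% of the observed cells, fits
    every candidate rank on the remainder, and scores the RMSE on the
    hidden cells. The rank minimizing mean RMSE wins; ties go to the
    smaller rank. Returns ``(rank, curve)`` where ``curve`` maps rank to
    mean RMSE.
    """
    X = _check_matrix(X)
    candidates = sorted(set(int(r) for r in candidate_ranks))
    if not candidates:
        raise ValueError("need at least one candidate rank")
    for r in candidates:
        if not 1 <= r < min(X.shape):
            raise ValueError(f"candidate rank {r} invalid for shape {X.shape}")
    if len(candidates) == 1:
        return candidates[0], {candidates[0]: float("nan")}

    obs = ~np.isnan(X)
    rng = np.random.default_rng(seed)
    errors = {r: [] for r in candidates}
    for _ in range(n_folds):
        cells = _holdout_cells(obs, holdout_fraction, rng)
        if cells.size == 0:
            raise ValueError("not enough observed cells to hold out")
        Xm = X.copy()
        Xm[cells[:, 0], cells[:, 1]] = np.nan
        truth = X[cells[:, 0], cells[:, 1]]
        for r in candidates:
            model = fit_ppca(Xm, rank=r, tol=tol, max_iter=max_iter)
            completed, _ = impute(model, Xm)
            pred = completed[cells[:, 0], cells[:, 1]]
            errors[r].append(float(np.sqrt(np.mean((pred - truth) ** 2))))
    curve = {r: float(np.mean(v)) for r, v in errors.items()}
    best = min(candidates, key=lambda r: (curve[r], r))
    return best, curve
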