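"""Single-response PLS regression and the model-building pipeline.

Contents: the PLS1 (NIPALS) core; latent-component selection minimizing a
BIC computed from 10-fold cross-validated PRESS; correlation screening of
candidate features; exhaustive feature-subset search scored by CV R^2; R^2
bookkeeping; per-score model construction over an imputed cohort; and the
predicted-age (oculomotor "brain age" proxy) analysis.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._plskernel import cv_press
from .cohort import CohortTable
from .ppca import fit_ppca, impute
from .stats import CorrelationResult, _rank_rho, _t_approx_p, spearman_rho

logger = logging.getLogger(__name__)

__all__ = [
    "PLSModel", "PLSModelReport", "SubsetSearchTrace", "ModelingConfig",
    "fit_pls", "predict", "bic_select_components", "screen_features",
    "exhaustive_subset_search", "r2_and_adjusted", "build_score_model",
    "predicted_age_analysis",
]


# --------------------------------------------------------------------------
# PLS1 core
# --------------------------------------------------------------------------

@dataclass
class PLSModel:
    n_components: int
    x_weights: np.ndarray      # p x k
    x_loadings: np.ndarray     # p x k
    y_loadings: np.ndarray     # k
    coefficient_vector: np.ndarray  # per raw feature
    intercept: float
    x_means: np.ndarray
    x_sds: np.ndarray
    y_mean: float
    feature_names: tuple[str, ...]
    training_predictions: np.ndarray = field(repr=False, default=None)


def fit_pls(X, y, n_components: int,
            feature_names: tuple[str, ...] | None = None) -> PLSModel:
    """Fit single-response PLS by NIPALS on z-scored X and centered y.

    The prediction is affine in the raw inputs; the first component's
    weight vector is proportional to the vector of feature-response
    covariances of the standardized data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("PLS requires complete data; impute first")
    if not 1 <= n_components <= p:
        raise ValueError(f"n_components must be in [1, {p}]")
    if n < n_components + 2:
        raise ValueError("too few samples for the requested components")
    x_means = X.mean(axis=0)
    x_sds = X.std(axis=0, ddof=1)
    if np.any(x_sds == 0):
        j = int(np.flatnonzero(x_sds == 0)[0])
        name = feature_names[j] if feature_names else str(j)
        raise ValueError(f"constant feature column {name!r}")
    Xs = (X - x_means) / x_sds
    y_mean = float(y.mean())
    yc = y - y_mean

    Xd = Xs.copy()
    yd = yc.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    k_eff = 0
    for k in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = Xd @ w
        tsq = float(t @ t)
        if tsq < 1e-30:
            break
        pk = Xd.T @ t / tsq
        qk = float(yd @ t) / tsq
        Xd -= np.outer(t, pk)
        yd -= qk * t
        W[:, k] = w
        P[:, k] = pk
        q[k] = qk
        k_eff += 1
    W, P, q = W[:, :k_eff], P[:, :k_eff], q[:k_eff]
    if k_eff == 0:
        raise ValueError("response has no covariance with any feature")
    beta_std = W @ np.linalg.solve(P.T @ W, q)
    coef = beta_std / x_sds
    intercept = y_mean - float(coef @ x_means)
    model = PLSModel(
        n_components=k_eff, x_weights=W, x_loadings=P, y_loadings=q,
        coefficient_vector=coef, intercept=intercept,
        x_means=x_means, x_sds=x_sds, y_mean=y_mean,
        feature_names=tuple(feature_names) if feature_names else
        tuple(str(j) for j in range(p)),
    )
    model.training_predictions = predict(model, X)
    return model


def predict(model: PLSModel, X, feature_names=None) -> np.ndarray:
    """Affine prediction from raw features."""
    if isinstance(X, pd.DataFrame):
        feature_names = tuple(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.coefficient_vector.size:
        raise ValueError("feature count mismatch")
    if feature_names is not None and tuple(feature_names) != model.feature_names:
        raise ValueError("feature names do not match the fitted model")
    if np.isnan(X).any():
        raise ValueError("missing values in prediction input")
    return X @ model.coefficient_vector + model.intercept


def r2_and_adjusted(y_true, y_pred, n_predictors: int):
    """Coefficient of determination and its small-sample adjustment."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    n = y_true.size
    if n <= n_predictors + 1:
        raise ValueError("need n > n_predictors + 1")
    sstot = float(np.sum((y_true - y_true.mean()) ** 2))
    if sstot == 0:
        raise ValueError("zero total sum of squares")
    ssres = float(np.sum((y_true - y_pred) ** 2))
    r2 = 1.0 - ssres / sstot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)
    return r2, adj


# --------------------------------------------------------------------------
# cross-validation machinery
# --------------------------------------------------------------------------

def make_folds(n: int, n_folds: int, seed: int):
    """Seeded fold partition; a pure function of (n, n_folds, seed)."""
    if n < n_folds:
        raise ValueError(f"cannot split {n} samples into {n_folds} folds")
    perm = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(perm, n_folds)
    for test in folds:
        if n - test.size < 2:
            raise ValueError("a fold would leave fewer than 2 training points")
    return folds


def _fold_arrays(X: np.ndarray, y: np.ndarray, folds):
    """Per-fold standardized, padded train/test arrays for the CV kernel."""
    n, p = X.shape
    F = len(folds)
    max_tr = max(n - f.size for f in folds)
    max_te = max(f.size for f in folds)
    Xtr = np.zeros((F, max_tr, p))
    Xte = np.zeros((F, max_te, p))
    ytr = np.zeros((F, max_tr))
    yte = np.zeros((F, max_te))
    ntr = np.zeros(F, dtype=np.int64)
    nte = np.zeros(F, dtype=np.int64)
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        Tr = X[train_mask]
        Te = X[test_idx]
        mu = Tr.mean(axis=0)
        sd = Tr.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        ym = y[train_mask].mean()
        ntr[f] = Tr.shape[0]
        nte[f] = Te.shape[0]
        Xtr[f, :Tr.shape[0]] = (Tr - mu) / sd
        Xte[f, :Te.shape[0]] = (Te - mu) / sd
        ytr[f, :Tr.shape[0]] = y[train_mask] - ym
        yte[f, :Te.shape[0]] = y[test_idx] - ym
    return Xtr, ntr, Xte, nte, ytr, yte


def _bic_from_press(press: np.ndarray, n: int) -> np.ndarray:
    """BIC_k = n ln(PRESS_k / n) + (k+1) ln(n) for k = 1..len(press)."""
    ks = np.arange(1, press.size + 1)
    return n * np.log(np.maximum(press, 1e-300) / n) + (ks + 1) * np.log(n)


def bic_select_components(X, y, max_components: int, n_folds: int = 10,
                          seed: int = 0):
    """Pick the latent-component count minimizing CV-PRESS-based BIC.

    Returns ``(n_components, bic_values)`` with ties resolved toward the
    smaller count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if max_components > p:
        raise ValueError("max_components exceeds the feature count")
    folds = make_folds(n, n_folds, seed)
    kmax = min(max_components, p, min(n - f.size for f in folds) - 1)
    arrays = _fold_arrays(X, y, folds)
    press = cv_press(*arrays, np.arange(p, dtype=np.int64), kmax)
    bic = _bic_from_press(press, n)
    best = int(np.argmin(bic)) + 1  # np.argmin returns the first minimum
    return best, bic


# --------------------------------------------------------------------------
# feature screening and exhaustive subset search
# --------------------------------------------------------------------------

def screen_features(data, outcome=None, n_top: int = 20) -> list[str]:
    """Rank features by |Spearman rho| with the outcome; return the top.

    ``data`` is either a ``CohortTable`` (with ``outcome`` the score name;
    pairwise deletion applies) or a complete DataFrame of features (with
    ``outcome`` a response vector). Ties and rank order are made
    deterministic by breaking on the feature name.
    """
    if isinstance(data, CohortTable):
        y = data.outcome_values(outcome).to_numpy(dtype=float)
        frame = data.frame[list(data.catalog.names)]
    else:
        frame = data
        y = np.asarray(outcome, dtype=float)
    if np.sum(~np.isnan(y)) < 3:
        raise ValueError("outcome observed for fewer than 3 rows")
    scores = []
    for name in frame.columns:
        x = frame[name].to_numpy(dtype=float)
        keep = ~(np.isnan(x) | np.isnan(y))
        rho = _rank_rho(x[keep], y[keep]) if keep.sum() >= 3 else float("nan")
        magnitude = -1.0 if math.isnan(rho) else abs(rho)
        scores.append((-magnitude, name))
    scores.sort()
    return [name for _, name in scores[:n_top]]


@dataclass(frozen=True)
class SubsetSearchTrace:
    n_subsets_evaluated: int
    best_subset: tuple[str, ...]
    best_criterion: float
    criterion_name: str
    best_n_components: int
    cv_folds: int
    seed: int


def exhaustive_subset_search(X, y, candidates, n_folds: int = 10,
                             seed: int = 0, max_candidates_cap: int = 20,
                             max_components: int = 10,
                             parsimony_tol: float = 0.002):
    """Evaluate every nonempty candidate subset; maximize CV R^2.

    For each subset the latent-component count is chosen by CV-PRESS BIC on
    the same seeded folds, and the subset is scored by the CV R^2 at that
    count. The winner is the smallest subset whose CV R^2 comes within
    ``parsimony_tol`` of the maximum (near-ties between nested subsets are
    dominated by CV noise, so a strict argmax systematically drags in
    spurious features); remaining ties prefer the higher criterion, then
    the lexicographically smaller name tuple. Returns
    ``(PLSModel, SubsetSearchTrace)`` where the model is refit on the full
    data with the winning subset and component count.
    """
    if isinstance(X, pd.DataFrame):
        X = X[list(candidates)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    candidates = list(candidates)
    C = len(candidates)
    if not 1 <= C:
        raise ValueError("need at least one candidate")
    if C > max_candidates_cap:
        raise ValueError(
            f"{C} candidates exceed the cap of {max_candidates_cap}; raise "
            "max_candidates_cap explicitly for a full-scale search")
    if X.shape[1] != C:
        raise ValueError("X columns must align with candidates")
    n = X.shape[0]
    folds = make_folds(n, n_folds, seed)
    arrays = _fold_arrays(X, y, folds)
    _, _, _, _, _, yte = arrays
    tss_cv = float((yte**2).sum())
    min_train = min(n - f.size for f in folds)

    evaluated = []  # (cv_r2, size, names, cols, k)
    n_eval = 0
    for size in range(1, C + 1):
        kmax = min(max_components, size, min_train - 1)
        for combo in itertools.combinations(range(C), size):
            cols = np.asarray(combo, dtype=np.int64)
            press = cv_press(*arrays, cols, kmax)
            bic = _bic_from_press(press, n)
            k = int(np.argmin(bic)) + 1
            cv_r2 = 1.0 - press[k - 1] / tss_cv
            n_eval += 1
            names = tuple(candidates[i] for i in combo)
            evaluated.append((cv_r2, size, names, cols, k))

    top = max(e[0] for e in evaluated)
    qualifying = [e for e in evaluated if e[0] >= top - parsimony_tol]
    cv_r2, size, names, cols, k = min(
        qualifying, key=lambda e: (e[1], -e[0], e[2]))
    model = fit_pls(X[:, cols], y, n_components=k, feature_names=names)
    trace = SubsetSearchTrace(
        n_subsets_evaluated=n_eval, best_subset=names,
        best_criterion=float(cv_r2), criterion_name="cv_r2",
        best_n_components=model.n_components, cv_folds=n_folds, seed=seed,
    )
    return model, trace


# --------------------------------------------------------------------------
# per-score model construction and the predicted-age analysis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelingConfig:
    n_top: int = 20            # correlation-screen size
    subset_cap: int = 12       # candidates entering the exhaustive search
    n_folds: int = 10
    max_components: int = 10
    ppca_rank: int = 4
    ppca_tol: float = 1e-6
    ppca_max_iter: int = 500
    seed: int = 0


@dataclass
class PLSModelReport:
    outcome: str
    group: str
    selected_features: tuple[str, ...]
    n_components: int
    r2_insample: float
    r2_adjusted: float
    r2_cv: float
    spearman_pred_vs_true: CorrelationResult
    predictions: pd.DataFrame          # id, true, predicted
    include_age: bool
    seed: int
    n_used: int
    model: PLSModel = field(repr=False, default=None)
    trace: SubsetSearchTrace = field(repr=False, default=None)
    imputation_rank: int | None = None

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome, "group": self.group,
            "selected_features": list(self.selected_features),
            "n_components": self.n_components,
            "r2_insample": self.r2_insample,
            "r2_adjusted": self.r2_adjusted,
            "r2_cv": self.r2_cv,
            "spearman_pred_vs_true": self.spearman_pred_vs_true.rho,
            "spearman_p": self.spearman_pred_vs_true.p_raw,
            "include_age": self.include_age, "seed": self.seed,
            "n_used": self.n_used, "imputation_rank": self.imputation_rank,
            "n_subsets_evaluated": (self.trace.n_subsets_evaluated
                                    if self.trace else None),
        }


def complete_oculo_block(cohort: CohortTable,
                         config: ModelingConfig = ModelingConfig()):
    """PPCA-impute the cohort's oculomotor block once; returns a DataFrame."""
    X = cohort.oculo_matrix()
    if not np.isnan(X).any():
        return pd.DataFrame(X, columns=list(cohort.catalog.names)), None
    model = fit_ppca(X, rank=config.ppca_rank, tol=config.ppca_tol,
                     max_iter=config.ppca_max_iter)
    completed, report = impute(model, X)
    return pd.DataFrame(completed, columns=list(cohort.catalog.names)), report


def build_score_model(cohort: CohortTable, outcome: str,
                      include_age: bool = False,
                      config: ModelingConfig = ModelingConfig(),
                      completed: pd.DataFrame | None = None,
                      ) -> PLSModelReport:
    """Full per-score pipeline: impute, screen, subset-search, refit, report.

    The oculomotor block is imputed once per cohort (pass ``completed`` to
    reuse across outcomes), then rows are restricted to participants with
    the outcome. With ``include_age`` the age column joins the candidate
    set after screening — it is never screened out, but the subset search
    may still drop it.
    """
    if completed is None:
        completed, _ = complete_oculo_block(cohort, config)
    y_all = cohort.outcome_values(outcome).to_numpy(dtype=float)
    rows = ~np.isnan(y_all)
    n = int(rows.sum())
    if n < max(10, config.n_folds):
        raise ValueError(f"only {n} participants have {outcome!r}")
    y = y_all[rows]
    X_frame = completed.loc[rows].reset_index(drop=True)

    screened = screen_features(X_frame, y, n_top=config.n_top)
    candidates = screened[:config.subset_cap]
    if len(screened) > len(candidates):
        logger.info("subset search capped at %d of %d screened candidates",
                    len(candidates), len(screened))
    X_cand = X_frame[candidates].copy()
    if include_age and outcome != "Age":
        X_cand["age"] = cohort.frame.loc[rows, "age"].to_numpy(dtype=float)
        candidates = candidates + ["age"]

    model, trace = exhaustive_subset_search(
        X_cand, y, candidates, n_folds=config.n_folds, seed=config.seed,
        max_candidates_cap=len(candidates), max_components=config.max_components,
    )
    preds = model.training_predictions
    r2, adj = r2_and_adjusted(y, preds, n_predictors=len(model.feature_names))
    rho_res = spearman_rho(y, preds)
    predictions = pd.DataFrame({
        "id": cohort.frame.loc[rows, "id"].to_numpy(),
        "true": y, "predicted": preds,
    })
    return PLSModelReport(
        outcome=outcome, group=str(cohort.frame["group"].iloc[0]) if n else "",
        selected_features=model.feature_names,
        n_components=model.n_components,
        r2_insample=r2, r2_adjusted=adj, r2_cv=float(trace.best_criterion),
        spearman_pred_vs_true=rho_res, predictions=predictions,
        include_age=include_age, seed=config.seed, n_used=n,
        model=model, trace=trace,
    )


def predicted_age_analysis(cohort: CohortTable,
                           age_model_report: PLSModelReport,
                           outcomes) -> pd.DataFrame:
    """Compare score correlations with true age vs PLS-predicted age.

    One row per outcome: Spearman rho of (true age, score) and of
    (predicted age, score) over the participants with both a score and an
    age prediction.
    """
    pred_by_id = dict(zip(age_model_report.predictions["id"],
                          age_model_report.predictions["predicted"]))
    frame = cohort.frame
    rows = []
    for outcome in outcomes:
        score = cohort.outcome_values(outcome).to_numpy(dtype=float)
        has_pred = frame["id"].map(pred_by_id).to_numpy(dtype=float)
        keep = ~(np.isnan(score) | np.isnan(has_pred))
        if keep.sum() < 3:
            raise ValueError(f"outcome {outcome!r} lacks overlap with the "
                             "age model")
        age = frame["age"].to_numpy(dtype=float)[keep]
        pred_age = has_pred[keep]
        sc = score[keep]
        rho_true = _rank_rho(age, sc)
        rho_pred = _rank_rho(pred_age, sc)
        rows.append({
            "outcome": outcome, "n": int(keep.sum()),
            "rho_true_age": rho_true,
            "p_true_age": _t_approx_p(rho_true, int(keep.sum())),
            "rho_predicted_age": rho_pred,
            "p_predicted_age": _t_approx_p(rho_pred, int(keep.sum())),
        })
    return pd.DataFrame(rows)
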