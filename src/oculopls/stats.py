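"""Rank-based association statistics.

Spearman correlations (average ranks for ties, t-approximation p-values),
Benjamini-Hochberg FDR adjustment, per-outcome correlation screens over the
oculomotor parameter catalog, per-task average |rho| summaries, and
Mann-Whitney U group comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .catalog import ParameterCatalog, TASKS
from .cohort import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult", "CorrelationTable", "spearman_rho", "bh_adjust",
    "correlation_screen", "task_average_abs_rho", "mann_whitney_u",
]


@dataclass(frozen=True)
class CorrelationResult:
    """One Spearman correlation with optional multiplicity adjustment.

    ``rho`` is NaN (and ``defined`` False) when either variable has
    zero rank variance after pairwise deletion — an explicitly undefined
    correlation, never silently coerced to 0.
    """

    rho: float
    n_pairs: int
    p_raw: float
    p_adj: float | None = None
    significant: bool | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)


@dataclass
class CorrelationTable:
    """Tidy per-(parameter, outcome) correlation results with BH flags."""

    frame: pd.DataFrame  # parameter, task, outcome, rho, n, p_raw, p_adj, significant
    alpha: float

    def result_for(self, parameter: str) -> CorrelationResult:
        row = self.frame.set_index("parameter").loc[parameter]
        return CorrelationResult(
            rho=float(row["rho"]), n_pairs=int(row["n"]),
            p_raw=float(row["p_raw"]), p_adj=float(row["p_adj"]),
            significant=bool(row["significant"]),
        )


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def _rank_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of average-rank transforms; NaN if degenerate."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    return max(-1.0, min(1.0, rho))


def _t_approx_p(rho: float, n: int) -> float:
    """Two-sided p from t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df."""
    if math.isnan(rho):
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def spearman_rho(x, y) -> CorrelationResult:
    """Spearman correlation with average ranks and a t-approximation p.

    Entries missing in either vector are dropped pairwise; at least three
    complete pairs are required. Zero rank variance yields an undefined
    result (``rho`` NaN) rather than 0.
    """
    xc, yc = _pairwise_complete(x, y)
    n = xc.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    rho = _rank_rho(xc, yc)
    return CorrelationResult(rho=rho, n_pairs=n, p_raw=_t_approx_p(rho, n))


def bh_adjust(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(p_adj, significant)`` arrays aligned with the input order;
    empty input yields empty output. NaN entries (undefined tests) are
    passed through as NaN / not significant and do not count toward the
    family size.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    ok = ~np.isnan(p)
    p_adj = np.full(p.shape, np.nan)
    flags = np.zeros(p.shape, dtype=bool)
    if ok.any():
        rej, adj, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        p_adj[ok] = adj
        # flag from adjusted p directly so flags stay consistent with p_adj
        flags[ok] = adj <= alpha
    return p_adj, flags


def correlation_screen(cohort: CohortTable, outcome: str,
                       disaggregate_by_sex: bool = False,
                       alpha: float = 0.05):
    """Spearman screen of every catalog parameter against one outcome.

    Pairwise deletion per parameter; BH correction within the table (one
    family per outcome). With ``disaggregate_by_sex`` a dict of per-sex
    tables is returned instead.
    """
    if disaggregate_by_sex:
        return {
            sex: correlation_screen(
                cohort.subset(cohort.frame["sex"] == sex), outcome,
                disaggregate_by_sex=False, alpha=alpha)
            for sex in ("male", "female")
        }

    y = cohort.outcome_values(outcome).to_numpy(dtype=float)
    if np.sum(~np.isnan(y)) < 3:
        raise ValueError(f"outcome {outcome!r} observed for fewer than 3 "
                         "participants")
    task_of = cohort.catalog.task_of
    rows = []
    X = cohort.oculo_matrix()
    for j, name in enumerate(cohort.catalog.names):
        xc, yc = _pairwise_complete(X[:, j], y)
        if xc.size < 3:
            rows.append((name, task_of[name], float("nan"), xc.size,
                         float("nan")))
            continue
        rho = _rank_rho(xc, yc)
        rows.append((name, task_of[name], rho, xc.size,
                     _t_approx_p(rho, xc.size)))
    frame = pd.DataFrame(rows, columns=["parameter", "task", "rho", "n",
                                        "p_raw"])
    frame["outcome"] = outcome
    frame["p_adj"], frame["significant"] = bh_adjust(frame["p_raw"], alpha)
    cols = ["parameter", "task", "outcome", "rho", "n", "p_raw", "p_adj",
            "significant"]
    return CorrelationTable(frame[cols], alpha=alpha)


def task_average_abs_rho(table: CorrelationTable,
                         catalog: ParameterCatalog) -> pd.DataFrame:
    """Mean |rho| per oculomotor task; undefined correlations excluded."""
    frame = table.frame
    unknown = set(frame["parameter"]) - set(catalog.names)
    if unknown:
        raise ValueError(f"parameters not in catalog: {sorted(unknown)[:5]}")
    rows = []
    for task in TASKS:
        names = set(catalog.parameters_for(task))
        sub = frame[frame["parameter"].isin(names)]
        if sub.empty:
            logger.warning("task %s has no parameters in the table", task)
            continue
        defined = sub["rho"].dropna()
        rows.append({
            "task": task,
            "outcome": sub["outcome"].iloc[0],
            "mean_abs_rho": float(defined.abs().mean()) if len(defined) else float("nan"),
            "n_parameters": int(len(defined)),
            "n_undefined": int(sub["rho"].isna().sum()),
        })
    return pd.DataFrame(rows)


def mann_whitney_u(a, b, exact_threshold: int = 20000):
    """Two-tailed Mann-Whitney U test.

    Exact enumeration when the number of group assignments C(n_a+n_b, n_a)
    is below ``exact_threshold`` and the pooled data has no ties; otherwise
    the normal approximation with tie and continuity corrections.
    Returns ``(U, p_two_tailed)`` with U counted for sample ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact_ok = (not has_ties
                and math.comb(a.size + b.size, a.size) < exact_threshold)
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact_ok else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)
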