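"""Rank statistics: Spearman, BH adjustment, screens, Mann-Whitney."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from oculopls.stats import (bh_adjust, correlation_screen, mann_whitney_u,
                            spearman_rho, task_average_abs_rho)


def rank_then_pearson(x, y):
    """Independent oracle: explicit average ranks, then Pearson."""
    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks
    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    if dx == 0 or dy == 0:
        return float("nan")
    return num / (dx * dy)


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.arange(1.0, 9.0)
        assert spearman_rho(x, x**2).rho == pytest.approx(1.0)
        assert spearman_rho(x, np.exp(x)).rho == pytest.approx(1.0)

    def test_tied_example_matches_oracle(self):
        res = spearman_rho([1, 2, 3, 4, 5], [5, 6, 7, 8, 7])
        assert res.rho == pytest.approx(0.8208, abs=2e-4)
        assert res.rho == pytest.approx(
            rank_then_pearson([1, 2, 3, 4, 5], [5, 6, 7, 8, 7]))

    def test_antisymmetry(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        y = [2.0, 7.0, 1.0, 8.0, 3.0]
        assert spearman_rho(x, y).rho == pytest.approx(
            -spearman_rho(x, [-v for v in y]).rho)

    def test_pairwise_deletion_and_minimum_n(self):
        x = [1, 2, np.nan, 4, 5]
        y = [2, np.nan, 3, 8, 10]
        res = spearman_rho(x, y)
        assert res.n_pairs == 3
        with pytest.raises(ValueError, match="3 complete pairs"):
            spearman_rho([1, np.nan, 3], [2, 5, np.nan])

    def test_zero_variance_is_undefined_not_zero(self):
        res = spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
        assert not res.defined
        assert math.isnan(res.rho) and math.isnan(res.p_raw)

    def test_agrees_with_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 5, size=12).astype(float)
            y = rng.integers(0, 5, size=12).astype(float)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            ours = spearman_rho(x, y)
            ref = sps.spearmanr(x, y)
            assert ours.rho == pytest.approx(ref.statistic, abs=1e-12)
            assert ours.p_raw == pytest.approx(ref.pvalue, abs=1e-9)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 3), st.integers(1, 3)),
                    min_size=3, max_size=6))
    def test_matches_bruteforce_oracle_on_small_alphabets(self, pairs):
        x = [float(a) for a, _ in pairs]
        y = [float(b) for _, b in pairs]
        expected = rank_then_pearson(x, y)
        res = spearman_rho(x, y)
        if math.isnan(expected):
            assert not res.defined
        else:
            assert res.rho == pytest.approx(expected, abs=1e-12)


def bh_oracle(p, alpha=0.05):
    """Hand step-up: adj_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        running = min(running, p[order[pos]] * m / (pos + 1))
        adj[order[pos]] = running
    return adj, [a <= alpha for a in adj]


class TestBH:
    def test_single_p_unchanged(self):
        adj, sig = bh_adjust([0.03])
        assert adj[0] == pytest.approx(0.03) and sig[0]

    def test_worked_example(self):
        adj, sig = bh_adjust([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(adj, [0.02, 0.04, 0.04, 0.02])
        assert sig.all()

    def test_all_ones(self):
        adj, sig = bh_adjust([1.0] * 5)
        assert (adj == 1.0).all() and not sig.any()

    def test_empty_input(self):
        adj, sig = bh_adjust([])
        assert adj.size == 0 and sig.size == 0

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40)).tolist()
            adj, sig = bh_adjust(p)
            oadj, osig = bh_oracle(p)
            np.testing.assert_allclose(adj, oadj, atol=1e-12)
            assert list(sig) == osig

    def test_monotone_along_sorted_raw_and_idempotent(self):
        rng = np.random.default_rng(2)
        p = rng.random(30)
        adj, sig = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        adj2, sig2 = bh_adjust(adj)
        assert (sig2 == sig).all()

    def test_nan_passthrough(self):
        adj, sig = bh_adjust([0.01, np.nan, 0.5])
        assert math.isnan(adj[1]) and not sig[1]
        # family size excludes the undefined test
        np.testing.assert_allclose([adj[0], adj[2]],
                                   bh_oracle([0.01, 0.5])[0])


class TestCorrelationScreen:
    def test_parameter_equal_to_outcome_has_rho_one(self, tiny_cohort):
        name = tiny_cohort.catalog.names[0]
        tiny_cohort.frame[name] = tiny_cohort.frame["MoCA"]
        table = correlation_screen(tiny_cohort, "MoCA")
        row = table.frame.set_index("parameter").loc[name]
        assert row["rho"] == pytest.approx(1.0)

    def test_one_row_per_parameter_and_bh_consistency(self, hc_cohort_small):
        cohort, _, _ = hc_cohort_small
        table = correlation_screen(cohort, "SDMT")
        assert len(table.frame) == len(cohort.catalog)
        sub = table.frame.dropna(subset=["p_adj"])
        assert ((sub["p_adj"] >= sub["p_raw"] - 1e-15).all())
        assert (sub["significant"] == (sub["p_adj"] <= table.alpha)).all()

    def test_sex_disaggregation_returns_both_tables(self, hc_cohort_small):
        cohort, _, _ = hc_cohort_small
        tables = correlation_screen(cohort, "SDMT", disaggregate_by_sex=True)
        assert set(tables) == {"male", "female"}
        for sex, table in tables.items():
            n_sex = (cohort.frame["sex"] == sex).sum()
            assert table.frame["n"].max() <= n_sex

    def test_planted_parameters_outrank_noise(self, hc_cohort_small):
        cohort, truth, _ = hc_cohort_small
        table = correlation_screen(cohort, "SDMT")
        ranked = table.frame.reindex(
            table.frame["rho"].abs().sort_values(ascending=False).index)
        top10 = set(ranked["parameter"].head(10))
        assert len(top10 & set(truth.informative_param_ids)) >= 8


class TestTaskAverage:
    def test_hand_averages(self, tiny_cohort):
        table = correlation_screen(tiny_cohort, "MoCA")
        frame = table.frame.copy()
        # overwrite with known rhos for one task: {0.3, -0.5} -> 0.4
        fix = tiny_cohort.catalog.parameters_for("fixation")
        frame.loc[frame["parameter"] == fix[0], "rho"] = 0.3
        frame.loc[frame["parameter"] == fix[1], "rho"] = -0.5
        table.frame = frame
        summary = task_average_abs_rho(table, tiny_cohort.catalog)
        row = summary.set_index("task").loc["fixation"]
        assert row["mean_abs_rho"] == pytest.approx(0.4)
        assert set(summary["task"]) <= {"fixation", "pro_saccade",
                                        "anti_saccade", "smooth_pursuit",
                                        "okn"}

    def test_unknown_parameter_rejected(self, tiny_cohort, tiny_catalog):
        table = correlation_screen(tiny_cohort, "MoCA")
        table.frame.loc[0, "parameter"] = "PS_not_in_catalog"
        with pytest.raises(ValueError, match="not in catalog"):
            task_average_abs_rho(table, tiny_catalog)


def mwu_enumeration(a, b):
    """Oracle: exact permutation distribution of U (average ranks)."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    n = len(pooled)

    def u_stat(idx_a):
        ranks = sps.rankdata(pooled)
        ra = ranks[list(idx_a)].sum()
        return ra - n_a * (n_a + 1) / 2

    us = [u_stat(c) for c in itertools.combinations(range(n), n_a)]
    obs = u_stat(range(n_a))
    us = np.asarray(us)
    lo = np.mean(us <= obs)
    hi = np.mean(us >= obs)
    return obs, min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_tiny_example(self):
        U, p = mann_whitney_u([1, 2], [3, 4])
        assert U == 0
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        U, p = mann_whitney_u(a, list(a))
        assert U == pytest.approx(len(a) ** 2 / 2)
        assert p == pytest.approx(1.0)

    def test_u_complement_identity(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=7)
        b = rng.normal(size=9)
        U_a, _ = mann_whitney_u(a, b)
        U_b, _ = mann_whitney_u(b, a)
        assert U_a + U_b == pytest.approx(len(a) * len(b))

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=5)
        b = rng.normal(size=5)
        U, p = mann_whitney_u(a, b)
        U_or, p_or = mwu_enumeration(a, b)
        assert U == pytest.approx(U_or)
        assert p == pytest.approx(p_or, abs=1e-12)

    def test_asymptotic_close_to_enumeration(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        _, p_exact = mwu_enumeration(a, b)
        _, p_norm = mann_whitney_u(a, b, exact_threshold=1)  # force normal
        assert abs(p_norm - p_exact) < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])
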