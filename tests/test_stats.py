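"""Scalar transforms, nonparametric tests, and cohort tables."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from visrkit.stats import (
    COMPRESSION_PAIRS,
    bonferroni_alpha,
    extreme_angle_values,
    group_comparison,
    kruskal_wallis,
    kw_significance_grid,
    normalize_by_baseline,
    normalized_by_compression,
    percent_change,
    percent_change_table,
    strain_from_compression,
    wilcoxon_rank_sum,
)

positive = st.floats(0.1, 1e4)


class TestScalarTransforms:
    def test_strain_values(self):
        assert strain_from_compression(0, 20) == 0.0
        assert strain_from_compression(2, 20) == 10.0
        assert strain_from_compression(5, 20) == 25.0

    def test_strain_domain(self):
        with pytest.raises(ValueError):
            strain_from_compression(-1, 20)
        with pytest.raises(ValueError):
            strain_from_compression(2, 0)

    def test_percent_change_values(self):
        assert percent_change(10, 10) == 0.0
        assert percent_change(10, 12.5) == 25.0
        with pytest.raises(ValueError):
            percent_change(0, 1)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(a=positive, b=positive, c=positive)
    def test_percent_change_chain_identity(self, a, b, c):
        lhs = (1 + percent_change(a, b) / 100) * (1 + percent_change(b, c) / 100)
        rhs = 1 + percent_change(a, c) / 100
        # cancellation in (1 + pc/100) amplifies eps by the value ratio, so
        # "machine precision" here means eps times the dynamic range
        assert lhs == pytest.approx(rhs, rel=1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(scale=positive, v2=positive, v5=positive)
    def test_scale_invariance(self, scale, v2, v5):
        base = {0: 4.0, 2: v2, 5: v5}
        scaled = {k: v * scale for k, v in base.items()}
        n1 = normalize_by_baseline(base)
        n2 = normalize_by_baseline(scaled)
        for k in base:
            assert n1[k] == pytest.approx(n2[k], rel=1e-12)
        assert percent_change(base[0], base[2]) == pytest.approx(
            percent_change(scaled[0], scaled[2]), rel=1e-12
        )

    def test_normalize_examples(self):
        assert normalize_by_baseline({0: 4.0, 2: 5.0, 5: 6.0}) == {0: 1.0, 2: 1.25, 5: 1.5}
        assert normalize_by_baseline({0: 3.0, 2: 3.0, 5: 3.0}) == {0: 1.0, 2: 1.0, 5: 1.0}
        with pytest.raises(ValueError, match="baseline"):
            normalize_by_baseline({2: 5.0})


class TestExtremeAngles:
    def test_worked_example(self):
        assert extreme_angle_values({0: 3.0, 30: 2.0, 60: 4.0, 90: 5.0}) == (30, 2.0, 90, 5.0)

    def test_tie_goes_to_smallest_angle(self):
        assert extreme_angle_values({0: 1.0, 30: 1.0, 60: 1.0, 90: 1.0}) == (0, 1.0, 0, 1.0)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            vals = dict(zip((0, 30, 60, 90), rng.uniform(1, 9, 4)))
            a_min, v_min, a_max, v_max = extreme_angle_values(vals)
            pairs = sorted(vals.items())
            assert (a_min, v_min) == min(pairs, key=lambda kv: (kv[1], kv[0]))
            assert (a_max, v_max) == max(pairs, key=lambda kv: (kv[1], -kv[0]))


def kw_h_oracle(groups):
    """Closed-form H from ranks (no-ties case): 12/(N(N+1)) sum n_i (Rbar_i - (N+1)/2)^2."""
    pooled = np.concatenate(groups)
    order = pooled.argsort()
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, len(pooled) + 1)
    n_total = len(pooled)
    h, start = 0.0, 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (r.mean() - (n_total + 1) / 2) ** 2
        start += len(g)
    return 12.0 / (n_total * (n_total + 1)) * h


def ranksum_exact_p_oracle(x, y):
    """Two-sided exact p by enumerating all assignments of ranks to x."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n = len(x)
    sums = [sum(c) for c in itertools.combinations(range(1, len(pooled) + 1), n)]
    mean_w = n * (len(pooled) + 1) / 2
    dev = abs(w_obs - mean_w)
    extreme = sum(1 for s in sums if abs(s - mean_w) >= dev - 1e-12)
    return extreme / len(sums)


class TestKruskalWallis:
    def test_worked_example_h(self):
        groups = [np.array([1, 2, 3]), np.array([4, 5, 6]), np.array([7, 8, 9])]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(7.2, abs=1e-9)
        assert res.statistic == pytest.approx(kw_h_oracle(groups), abs=1e-9)

    def test_matches_rank_oracle_on_random_data(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            groups = [rng.permutation(rng.uniform(0, 1, n)) for n in (5, 7, 6)]
            res = kruskal_wallis(groups)
            assert res.statistic == pytest.approx(kw_h_oracle(groups), abs=1e-9)

    def test_identical_groups(self):
        g = np.array([3.0, 1.0, 2.0])
        res = kruskal_wallis([g, g[::-1].copy()])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.9

    def test_h_nonnegative_and_monotone_invariant(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(size=8) for _ in range(3)]
        res = kruskal_wallis(groups)
        assert res.statistic >= 0
        transformed = [np.exp(g) for g in groups]  # strictly monotone map
        assert kruskal_wallis(transformed).statistic == pytest.approx(res.statistic, abs=1e-9)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.array([1.0, 2.0])])


class TestWilcoxonRankSum:
    def test_exact_worked_example(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(0.1, abs=1e-12)
        assert res.p == pytest.approx(ranksum_exact_p_oracle([1, 2, 3], [4, 5, 6]), abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = list(rng.uniform(0, 1, 4))
            y = list(rng.uniform(0, 1, 5))
            res = wilcoxon_rank_sum(x, y)
            assert res.p == pytest.approx(ranksum_exact_p_oracle(x, y), abs=1e-9)

    def test_identical_samples_not_significant(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = wilcoxon_rank_sum(x, list(reversed(x)))
        assert res.p > 0.9

    def test_monotone_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(size=9)
        p1 = wilcoxon_rank_sum(x, y).p
        p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y)).p
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBonferroni:
    def test_values(self):
        assert bonferroni_alpha(0.05, 12, 20) == pytest.approx(0.05 / 240)
        assert bonferroni_alpha(0.05, 1, 1) == 0.05
        assert bonferroni_alpha(0.06, 3, 2) == pytest.approx(0.01)

    def test_domain(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0, 20)


def _scalar_frame():
    rows = []
    for subj, dense in (("S01", True), ("S02", False)):
        base = 10.0 if dense else 8.0
        for metric in ("PD", "RE", "RV"):
            for comp, factor in ((0, 1.0), (2, 1.2), (5, 1.5)):
                for k, angle in enumerate((0, 30, 60, 90)):
                    rows.append(
                        {"subject_id": subj, "dense": dense, "metric": metric,
                         "compression_mm": comp, "angle_deg": angle,
                         "value": base * factor * (1 + 0.1 * k)}
                    )
    return pd.DataFrame(rows)


class TestCohortTables:
    def test_normalized_baseline_is_one(self):
        out = normalized_by_compression(_scalar_frame())
        base = out[out["compression_mm"] == 0]["normalized"]
        assert np.allclose(base, 1.0)
        at5 = out[out["compression_mm"] == 5]["normalized"]
        assert np.allclose(at5, 1.5)

    def test_percent_change_modes(self):
        df = _scalar_frame()
        allm = percent_change_table(df, mode="all")
        assert set(allm["pair"]) == {p.label for p in COMPRESSION_PAIRS}
        row = allm.query("subject_id == 'S01' and metric == 'RE' and pair == '0–2'")
        assert row["pct_change"].iloc[0] == pytest.approx(20.0)
        mn = percent_change_table(df, mode="min")
        assert (mn["angle_deg"] == 0).all()  # min always at 0 deg by construction
        mx = percent_change_table(df, mode="max")
        assert (mx["angle_deg"] == 90).all()

    def test_kw_grid_detects_compression_effect(self):
        rng = np.random.default_rng(0)
        rows = []
        for comp, mu in ((0, 10.0), (2, 12.0), (5, 15.0)):
            for v in rng.normal(mu, 0.5, 60):
                rows.append({"subject_id": "S01", "metric": "RE", "angle_deg": 0,
                             "compression_mm": comp, "value": v})
        grid = kw_significance_grid(pd.DataFrame(rows), tests_per_patient=1)
        assert grid["significant"].all()
        assert grid["alpha"].iloc[0] == pytest.approx(0.05)

    def test_group_comparison_degenerate_group(self):
        df = _scalar_frame()
        df = df[~df["dense"]]  # nothing dense left
        out = group_comparison(df, "value", by=["metric"])
        assert out["missing"].all()
        assert not out["significant"].any()

    def test_group_comparison_shapes(self):
        out = group_comparison(_scalar_frame(), "value", by=["metric", "compression_mm"])
        assert len(out) == 9
        assert out["missing"].eq(False).all()
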