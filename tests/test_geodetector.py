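import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treeline_drivers.geodetector import (
    classify_interaction,
    discretize,
    factor_q,
    interaction_q,
    q_sensitivity,
    run_detectors,
)


def q_oracle(y, labels):
    """Brute-force group-variance computation of q = 1 - SSW/SST."""
    y = np.asarray(y, float)
    labels = np.asarray(labels)
    ssw = sum(np.sum((y[labels == h] - y[labels == h].mean()) ** 2)
              for h in np.unique(labels))
    sst = np.sum((y - y.mean()) ** 2)
    return 1.0 - ssw / sst


def optimal_1d_partition(x_sorted, k):
    """Exhaustive optimal 1-D partition into k contiguous groups (DP on SSE)."""
    n = len(x_sorted)
    prefix = np.concatenate([[0.0], np.cumsum(x_sorted)])
    prefix2 = np.concatenate([[0.0], np.cumsum(np.square(x_sorted))])

    def sse(i, j):  # cells i..j-1
        s, s2, m = prefix[j] - prefix[i], prefix2[j] - prefix2[i], j - i
        return s2 - s * s / m

    cost = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for g in range(1, k + 1):
        for j in range(g, n + 1):
            for i in range(g - 1, j):
                cand = cost[g - 1, i] + sse(i, j)
                if cand < cost[g, j]:
                    cost[g, j] = cand
                    split[g, j] = i
    bounds = [n]
    for g in range(k, 0, -1):
        bounds.append(split[g, bounds[-1]])
    bounds = bounds[::-1]
    labels = np.empty(n, dtype=int)
    for g in range(k):
        labels[bounds[g]:bounds[g + 1]] = g + 1
    return labels


class TestDiscretize:
    def test_median_split_of_one_to_ten(self):
        s = discretize(np.arange(1.0, 11.0), method="quantile", k=2)
        np.testing.assert_array_equal(s.labels, [1] * 5 + [2] * 5)

    def test_constant_vector_single_stratum(self, caplog):
        with caplog.at_level("WARNING"):
            s = discretize(np.full(20, 3.0), method="quantile", k=5)
        assert s.L == 1
        assert np.all(s.labels == 1)

    def test_natural_breaks_recover_separated_mixture(self):
        rng = np.random.default_rng(17)
        comps = [rng.normal(mu, 0.5, 70) for mu in (-10.0, 0.0, 10.0)]
        x = np.concatenate(comps)
        s = discretize(x, method="natural-breaks", k=3)
        order = np.argsort(x)
        dp_labels = optimal_1d_partition(x[order], 3)
        # compare partitions on the sorted axis
        np.testing.assert_array_equal(s.labels[order], dp_labels)
        # and the optimal partition is the true component grouping
        true = np.repeat([1, 2, 3], 70)
        np.testing.assert_array_equal(s.labels[order], np.sort(true))

    def test_missing_values_get_missing_label(self):
        x = np.array([1.0, np.nan, 2.0, 3.0, np.nan, 4.0])
        s = discretize(x, k=2)
        assert np.all(s.labels[[1, 4]] == 0)
        assert np.all(s.labels[[0, 2, 3, 5]] > 0)

    def test_categorical_passthrough(self):
        s = discretize(np.array([3.0, 7.0, 3.0, 9.0]), method="categorical")
        np.testing.assert_array_equal(s.labels, [1, 2, 1, 3])

    def test_k_reduced_when_few_distinct_values(self, caplog):
        with caplog.at_level("WARNING"):
            s = discretize(np.array([1.0, 1.0, 2.0, 2.0]), k=5)
        assert s.L == 2


class TestFactorQ:
    def test_two_group_worked_example(self):
        y = np.array([1.0, 2, 3, 10, 11, 12])
        s = discretize(np.array([0, 0, 0, 1, 1, 1.0]), method="categorical")
        res = factor_q(y, s)
        assert res.ssw == pytest.approx(4.0)
        assert res.sst == pytest.approx(125.5)
        assert res.q == pytest.approx(1 - 4 / 125.5, abs=1e-12)

    def test_single_stratum_gives_zero(self):
        y = np.random.default_rng(0).normal(size=30)
        s = discretize(np.zeros(30), method="categorical")
        assert factor_q(y, s).q == pytest.approx(0.0, abs=1e-12)

    def test_pure_strata_give_one(self):
        y = np.arange(10.0)
        s = discretize(y, method="categorical")
        assert factor_q(y, s, min_stratum_n=1).q == pytest.approx(1.0)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = rng.integers(20, 500)
            L = rng.integers(2, 10)
            y = rng.normal(size=n)
            labels = rng.integers(1, L + 1, n)
            s = discretize(labels.astype(float), method="categorical")
            res = factor_q(y, s, min_stratum_n=1)
            assert res.q == pytest.approx(q_oracle(y, labels), abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(31)
        y = rng.normal(size=200)
        s = discretize(rng.normal(size=200), k=4)
        q1 = factor_q(y, s).q
        q2 = factor_q(-3.5 * y + 7.0, s).q
        assert q1 == pytest.approx(q2, abs=1e-12)

    def test_constant_response_rejected(self):
        s = discretize(np.arange(10.0), k=2)
        with pytest.raises(ValueError):
            factor_q(np.ones(10), s)

    def test_small_strata_dropped_and_logged(self):
        y = np.array([1.0, 2, 3, 4, 100.0])
        labels = np.array([1, 1, 2, 2, 3])
        s = discretize(labels.astype(float), method="categorical")
        res = factor_q(y, s, min_stratum_n=2)
        assert res.dropped_strata == [3]
        assert res.n == 4

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.integers(min_value=10, max_value=200),
        st.integers(min_value=2, max_value=8),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_q_always_in_unit_interval(self, n, L, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=n)
        labels = rng.integers(1, L + 1, n)
        s = discretize(labels.astype(float), method="categorical")
        assert 0.0 <= factor_q(y, s, min_stratum_n=1).q <= 1.0


class TestInteraction:
    def test_xor_construction(self):
        # Y = XOR(A, B) on a balanced 2x2 design: singles explain nothing,
        # the overlay explains everything
        a = np.repeat([1, 1, 2, 2], 25)
        b = np.tile([1, 2], 50)
        y = ((a == 2) ^ (b == 2)).astype(float)
        sa = discretize(a.astype(float), method="categorical", factor_name="A")
        sb = discretize(b.astype(float), method="categorical", factor_name="B")
        res = interaction_q(y, sa, sb)
        assert res.q_a == pytest.approx(0.0, abs=1e-12)
        assert res.q_b == pytest.approx(0.0, abs=1e-12)
        assert res.q_ab == pytest.approx(1.0, abs=1e-12)
        assert res.category == "nonlinear-enhance"

    def test_self_overlay_equals_single_q(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=300)
        s = discretize(rng.normal(size=300), k=5)
        res = interaction_q(y, s, s)
        single = factor_q(y, s).q
        assert res.q_ab == pytest.approx(single, abs=1e-12)
        assert res.category == "bi-enhance"  # boundary tie rule

    def test_additive_two_factor_means_match_overlay_oracle(self):
        rng = np.random.default_rng(41)
        a = rng.integers(1, 5, 1000)
        b = rng.integers(1, 4, 1000)
        y = 2.0 * a + 3.0 * b + rng.normal(0, 0.5, 1000)
        sa = discretize(a.astype(float), method="categorical")
        sb = discretize(b.astype(float), method="categorical")
        res = interaction_q(y, sa, sb, min_stratum_n=1)
        overlay = a * 10 + b
        assert res.q_ab == pytest.approx(q_oracle(y, overlay), abs=1e-12)

    def test_refinement_monotonicity(self):
        rng = np.random.default_rng(53)
        for _ in range(10):
            y = rng.normal(size=400)
            sa = discretize(rng.normal(size=400), k=5, factor_name="a")
            sb = discretize(rng.normal(size=400), k=5, factor_name="b")
            res = interaction_q(y, sa, sb)
            assert res.q_ab >= max(res.q_a, res.q_b) - 1e-12


class TestInteractionTaxonomy:
    @pytest.mark.parametrize(
        "qa, qb, qab, expected",
        [
            (0.3, 0.2, 0.9, "nonlinear-enhance"),   # overlay beats the sum
            (0.3, 0.2, 0.4, "bi-enhance"),           # beats the max, not the sum
            (0.3, 0.2, 0.5, "independent"),          # exactly the sum
            (0.3, 0.2, 0.25, "single-weaken"),
            (0.3, 0.2, 0.1, "nonlinear-weaken"),
        ],
    )
    def test_verbal_rules(self, qa, qb, qab, expected):
        assert classify_interaction(qa, qb, qab) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_interaction(1.2, 0.2, 0.5)


class TestRunDetectors:
    @staticmethod
    def planted_table(n=5000, seed=0):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame({f: rng.normal(size=n) for f in ("A", "B", "C")})
        table["response"] = 3.0 * table["A"] + rng.normal(0, 0.5, n)
        return table

    def test_planted_dominant_factor_ranks_first(self):
        reports = run_detectors(self.planted_table(), "response", ["A", "B", "C"])
        assert reports["factor_q"].iloc[0]["factor"] == "A"

    def test_pure_noise_response_has_small_q(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame({f: rng.normal(size=5000) for f in ("A", "B")})
        table["response"] = rng.normal(size=5000)
        reports = run_detectors(table, "response", ["A", "B"])
        assert np.all(reports["factor_q"]["q"] < 0.1)

    def test_duplicated_factor_pair_sits_at_overlay_identity(self):
        table = self.planted_table(n=2000, seed=9)
        table["A_copy"] = table["A"]
        reports = run_detectors(table, "response", ["A", "A_copy", "B"])
        pair = reports["interaction_q"]
        row = pair[(pair["factor_a"] == "A") & (pair["factor_b"] == "A_copy")].iloc[0]
        assert row["q_ab"] == pytest.approx(row["q_a"], abs=1e-12)
        assert row["category"] == "bi-enhance"

    def test_needs_two_factors(self):
        with pytest.raises(ValueError):
            run_detectors(self.planted_table(100), "response", ["A"])


def test_sensitivity_report_covers_requested_strata_counts():
    rng = np.random.default_rng(12)
    x = rng.normal(size=2000)
    y = x + rng.normal(0, 0.5, 2000)
    report = q_sensitivity(y, x, factor_name="x", ks=(3, 5, 8))
    assert list(report["k"]) == [3, 5, 8]
    assert report["q"].between(0, 1).all()
    # finer stratification of the driving factor cannot lose much signal
    assert report["q"].iloc[-1] >= report["q"].iloc[0] - 0.05
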