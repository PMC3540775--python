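import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fcnet import (
    compare_global_metrics,
    compare_node_metrics,
    fdr_bh,
    pearson_correlation_test,
    permutation_test_nodewise,
    two_sample_t,
)

from .oracles import bh_stepup_bruteforce


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        t, p = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=5e-4)
        assert p == pytest.approx(2 * sps.t.sf(3.674, df=4), abs=1e-4)

    def test_scale_invariance(self):
        a, b = np.array([1.0, 2.5, 3.0]), np.array([2.0, 4.0, 5.0])
        t1, _ = two_sample_t(a, b)
        t2, _ = two_sample_t(7 * a, 7 * b)
        assert t1 == pytest.approx(t2)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0], [2.0, 2.0])


class TestPermutationTest:
    def test_constant_node_gets_p_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 3))
        x[:, 1] = 5.0
        labels = np.array([True] * 5 + [False] * 5)
        _, p = permutation_test_nodewise(x, labels, n_perm=199, seed=1)
        assert p[1] == pytest.approx(1.0)

    def test_complete_separation_attains_minimum_p(self):
        labels = np.array([True] * 10 + [False] * 10)
        x = np.where(labels, 100.0, 0.0)[:, None] + np.random.default_rng(2).normal(
            scale=0.01, size=(20, 1)
        )
        _, p = permutation_test_nodewise(x, labels, n_perm=499, seed=3)
        assert p[0] == pytest.approx(1 / 500)

    def test_p_depends_on_values_only_through_t(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(12, 6))
        labels = np.array([True] * 6 + [False] * 6)
        _, p1 = permutation_test_nodewise(x, labels, n_perm=299, seed=7)
        _, p2 = permutation_test_nodewise(3.5 * x - 2.0, labels, n_perm=299, seed=7)
        assert np.array_equal(p1, p2)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(5)
        labels = np.array([True] * 5 + [False] * 5)
        collected = []
        for _ in range(200):
            x = rng.normal(size=(10, 4))
            _, p = permutation_test_nodewise(
                x, labels, n_perm=199, seed=int(rng.integers(2**31))
            )
            collected.extend(p)
        ks = sps.kstest(collected, "uniform").statistic
        assert ks < 0.05

    def test_invalid_inputs_rejected(self):
        x = np.zeros((6, 2))
        labels = np.array([True, True, True, False, False, False])
        with pytest.raises(ValueError):
            permutation_test_nodewise(x, labels, n_perm=0)
        with pytest.raises(ValueError):
            permutation_test_nodewise(x, np.array(["a"] * 6), n_perm=10)


class TestFdrBH:
    def test_examples(self):
        q, sig = fdr_bh(np.ones(5))
        assert not sig.any()
        q, sig = fdr_bh(np.array([0.04]))
        assert sig[0] and q[0] == pytest.approx(0.04)
        q, sig = fdr_bh(np.array([0.001, 0.012, 0.014, 0.8]))
        assert np.allclose(q, [0.004, 0.0186667, 0.0186667, 0.8], atol=1e-6)
        assert list(sig) == [True, True, True, False]

    def test_matches_bruteforce_stepup_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            m = int(rng.integers(1, 21))
            p = rng.uniform(size=m) ** rng.uniform(0.3, 3)
            q, sig = fdr_bh(p)
            q_ref, sig_ref = bh_stepup_bruteforce(p)
            assert np.allclose(q, q_ref)
            assert np.array_equal(sig, sig_ref)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.2]))


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(5.0)
        r, p = pearson_correlation_test(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_vectors(self):
        r, _ = pearson_correlation_test([1, -1, 1, -1], [1, 1, -1, -1])
        assert r == pytest.approx(0.0)

    def test_hand_computed_five_points(self):
        r, p = pearson_correlation_test([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8)
        t = 0.8 * np.sqrt(3) / np.sqrt(1 - 0.64)
        assert p == pytest.approx(2 * sps.t.sf(t, df=3))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation_test([1, 1, 1], [1, 2, 3])


def _metrics_frame(rng, n_per_group=8, shift=0.0):
    rows = []
    for g, n, d in (("control", n_per_group, 0.0), ("case", n_per_group, shift)):
        for _ in range(n):
            c = rng.normal(0.5, 0.05)
            rows.append(
                {
                    "group": g,
                    "grand_mean_raw": rng.normal(d, 0.01),
                    "grand_mean_nonnegative": rng.normal(0.2, 0.01),
                    "grand_mean_thresholded": rng.normal(0.45, 0.02),
                    "L": rng.normal(2.2, 0.1),
                    "C": c,
                    "gamma": rng.normal(2.8, 0.2),
                    "lambda": rng.normal(1.2, 0.05),
                    "sigma": rng.normal(2.3, 0.1),
                    "Q": 0.4 * c + rng.normal(0.2, 0.02),
                }
            )
    return pd.DataFrame(rows)


class TestCompareGlobalMetrics:
    def test_schema_contains_battery_and_cq_rows(self):
        out = compare_global_metrics(_metrics_frame(np.random.default_rng(7)))
        metrics = set(out.loc[out.scope == "global_metric", "identifier"])
        assert {
            "grand_mean_raw",
            "grand_mean_thresholded",
            "L",
            "C",
            "gamma",
            "lambda",
            "sigma",
            "Q",
        } <= metrics
        cq = out.loc[out.scope == "correlation", "identifier"]
        assert set(cq) == {"C_vs_Q[case]", "C_vs_Q[control]"}

    def test_detects_injected_grand_mean_shift(self):
        out = compare_global_metrics(
            _metrics_frame(np.random.default_rng(8), shift=0.1)
        )
        row = out.set_index("identifier").loc["grand_mean_raw"]
        assert row["significant"] and row["direction"] == "case_higher"

    def test_null_type_one_error_is_controlled_per_measure(self):
        rng = np.random.default_rng(9)
        reps = 60
        rejections = {}
        for _ in range(reps):
            out = compare_global_metrics(_metrics_frame(rng))
            for _, row in out[out.scope == "global_metric"].iterrows():
                rejections.setdefault(row["identifier"], []).append(row["significant"])
        for name, flags in rejections.items():
            rate = np.mean(flags)
            # nominal 5% plus 2.5 binomial standard errors
            assert rate <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / reps), name


class TestCompareNodeMetrics:
    def test_label_swap_exchanges_directions(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(12, 5))
        x[:6] += np.array([1.0, -1.0, 0.5, 0.0, 2.0])
        labels = np.array(["case"] * 6 + ["control"] * 6)
        a = compare_node_metrics({"m": x}, labels, n_perm=99, seed=1)
        b = compare_node_metrics({"m": x}, labels[::-1], n_perm=99, seed=1)
        flipped = {
            "case_higher": "control_higher",
            "control_higher": "case_higher",
        }
        assert list(b.direction) == [flipped[d] for d in a.direction]

    def test_uncorrected_threshold_rule_option(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(16, 10))
        x[:8, 0] += 5.0
        labels = np.array(["case"] * 8 + ["control"] * 8)
        out = compare_node_metrics(
            {"m": x}, labels, n_perm=999, seed=3,
            significance_rule="p_threshold", p_threshold=0.01,
        )
        assert np.array_equal(out.significant, out.p_perm < 0.01)
        with pytest.raises(ValueError, match="significance_rule"):
            compare_node_metrics({"m": x}, labels, n_perm=9, significance_rule="bonf")

    def test_strong_effect_survives_fdr(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(20, 30))
        x[:10, :3] += 4.0
        labels = np.array(["case"] * 10 + ["control"] * 10)
        out = compare_node_metrics({"m": x}, labels, n_perm=999, seed=2)
        hit = out[(out.node_id < 3) & out.significant]
        assert len(hit) == 3
        assert (hit.direction == "case_higher").all()
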