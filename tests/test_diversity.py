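"""Tests for Gini statistics, segment usage, and TRA calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thymoquant import (
    call_tras,
    gen_repertoire,
    gini,
    pair_fold_change,
    repertoire_gini,
    segment_usage,
    segment_usage_test,
)
from conftest import gini_pairwise


class TestGini:
    def test_perfect_equality(self):
        assert gini([1, 1, 1, 1]) == 0.0

    def test_maximal_concentration(self):
        assert gini([5] + [0] * 9) == pytest.approx(0.9)

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(100):
            x = rng.uniform(0, 10, size=rng.integers(2, 80))
            assert gini(x) == pytest.approx(gini_pairwise(x), abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gini([0, 0, 0])
        with pytest.raises(ValueError):
            gini([1, -1, 3])
        with pytest.raises(ValueError):
            gini([])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=100), min_size=2, max_size=20),
        st.floats(min_value=0.1, max_value=50),
    )
    def test_scale_invariance(self, x, c):
        assert gini(np.asarray(x) * c) == pytest.approx(gini(x), abs=1e-9)

    def test_schur_convexity_on_random_transfers(self, rng):
        """Moving mass from a smaller to a larger entry never decreases Gini."""
        for _ in range(50):
            x = rng.uniform(1, 10, size=10)
            i, j = np.argsort(x)[[0, -1]]
            amount = rng.uniform(0, x[i])
            y = x.copy()
            y[i] -= amount
            y[j] += amount
            assert gini(y) >= gini(x) - 1e-12


class TestRepertoireGini:
    def test_equal_clone_sizes_give_zero(self):
        rep = gen_repertoire(n_clones=50, seed=0)
        rep["duplicate_count"] = 3
        assert repertoire_gini(rep).iloc[0] == 0.0

    def test_monoclonal_with_singletons_matches_formula(self):
        k, big = 10, 91
        rep = pd.DataFrame(
            {
                "sample_id": "s",
                "junction_aa": [f"CASS{i}F" for i in range(k)],
                "v_call": "TRAV1",
                "j_call": "TRAJ1",
                "duplicate_count": [big] + [1] * (k - 1),
            }
        )
        expected = gini_pairwise([big] + [1] * (k - 1))
        assert repertoire_gini(rep).iloc[0] == pytest.approx(expected)

    def test_record_order_invariance(self, rng):
        rep = gen_repertoire(n_clones=100, seed=1)
        shuffled = rep.sample(frac=1.0, random_state=7)
        pd.testing.assert_series_equal(repertoire_gini(rep), repertoire_gini(shuffled))

    def test_aggregates_duplicate_junctions(self):
        rep = pd.DataFrame(
            {
                "sample_id": "s",
                "junction_aa": ["CAF", "CAF", "CGF"],
                "v_call": ["TRAV1", "TRAV2", "TRAV1"],
                "j_call": "TRAJ1",
                "duplicate_count": [2, 3, 5],
            }
        )
        # junction level pools CAF across V genes: sizes (5, 5) -> Gini 0
        assert repertoire_gini(rep, level="junction_aa").iloc[0] == 0.0
        assert repertoire_gini(rep, level="clonotype").iloc[0] > 0.0

    def test_zipf_skewness_monotonicity(self):
        """Heavier clone-size tails (smaller zipf exponent) raise the Gini."""
        values = []
        for a in (3.0, 2.0, 1.3):
            rep = gen_repertoire(n_clones=500, clone_size_law=("zipf", a), seed=7)
            values.append(repertoire_gini(rep).iloc[0])
        assert values[0] < values[1] < values[2]


class TestSegmentUsage:
    def _cohort(self, shift=0.0, n_per_group=8):
        frames = []
        for g, base_seed in (("MG", 100), ("nonMG", 200)):
            for i in range(n_per_group):
                j_probs = {f"TRAJ{k}": 1 / 8 for k in range(1, 9)}
                if g == "MG" and shift:
                    j_probs = {
                        f"TRAJ{k}": (1 / 8 + shift if k == 1 else (1 - (1 / 8 + shift)) / 7)
                        for k in range(1, 9)
                    }
                frames.append(
                    gen_repertoire(
                        n_clones=400,
                        clone_size_law=("geometric", 0.3),
                        segment_probs={"v": {f"TRAV{k}": 1 / 8 for k in range(1, 9)},
                                       "j": j_probs},
                        sample_id=f"{g}_{i}",
                        group=g,
                        seed=base_seed + i,
                    )
                )
        return pd.concat(frames, ignore_index=True)

    def test_fractions_sum_to_one(self):
        usage = segment_usage(self._cohort(), family="J")
        np.testing.assert_allclose(usage.sum(axis=1), 1.0, atol=1e-9)

    def test_identical_usage_gives_p_one(self):
        rep = pd.concat(
            [
                pd.DataFrame(
                    {
                        "sample_id": f"s{i}",
                        "group": "MG" if i < 2 else "nonMG",
                        "junction_aa": ["CAF", "CGF"],
                        "v_call": "TRAV1",
                        "j_call": ["TRAJ1", "TRAJ2"],
                        "duplicate_count": [3, 7],
                    }
                )
                for i in range(4)
            ],
            ignore_index=True,
        )
        result = segment_usage_test(rep, family="J")
        assert (result["p"] == 1.0).all()

    def test_shifted_segment_has_smallest_q(self):
        result = segment_usage_test(self._cohort(shift=0.2), family="J")
        assert result.iloc[0]["segment"] == "TRAJ1"
        assert result.iloc[0]["q"] == result["q"].min()

    def test_small_group_rejected(self):
        rep = self._cohort(n_per_group=8)
        rep = rep[rep["sample_id"] != "MG_0"]
        rep = rep[~rep["sample_id"].str.startswith("MG_") | (rep["sample_id"] == "MG_1")]
        with pytest.raises(ValueError):
            segment_usage_test(rep, family="J")


class TestPairFoldChange:
    def _table(self, counts_a, counts_b):
        rows = []
        for g, counts in (("MG", counts_a), ("nonMG", counts_b)):
            for (v, j), n in counts.items():
                rows.append({"sample_id": g, "group": g, "v_call": v,
                             "j_call": j, "junction_aa": "CAF",
                             "duplicate_count": n})
        return pd.DataFrame(rows)

    def test_known_ratio(self):
        t = self._table({("V1", "J1"): 15, ("V2", "J2"): 85},
                        {("V1", "J1"): 2, ("V2", "J2"): 98})
        assert pair_fold_change(t, "V1", "J1", "MG", "nonMG") == pytest.approx(7.5)

    def test_identical_groups_give_one(self):
        t = self._table({("V1", "J1"): 10, ("V2", "J2"): 90},
                        {("V1", "J1"): 10, ("V2", "J2"): 90})
        assert pair_fold_change(t, "V1", "J1", "MG", "nonMG") == pytest.approx(1.0)

    def test_absent_in_reference_is_infinite(self):
        t = self._table({("V1", "J1"): 10}, {("V2", "J2"): 90})
        assert pair_fold_change(t, "V1", "J1", "MG", "nonMG") == math.inf

    def test_absent_everywhere_rejected(self):
        t = self._table({("V2", "J2"): 10}, {("V2", "J2"): 90})
        with pytest.raises(ValueError):
            pair_fold_change(t, "V1", "J1", "MG", "nonMG")


class TestCallTras:
    def test_single_tissue_spike_called(self):
        expr = pd.DataFrame([[200.0] + [0.0] * 9], index=["G1"],
                            columns=[f"t{i}" for i in range(10)])
        call = call_tras(expr).iloc[0]
        assert call["gini"] == pytest.approx(0.9)
        assert call["max_tpm"] == 200.0
        assert bool(call["is_tra"])

    def test_uniform_expression_not_called(self):
        expr = pd.DataFrame([[50.0] * 10], index=["G1"],
                            columns=[f"t{i}" for i in range(10)])
        assert not call_tras(expr)["is_tra"].iloc[0]

    def test_low_tpm_spike_fails_second_criterion(self):
        expr = pd.DataFrame([[90.0] + [0.0] * 9], index=["G1"],
                            columns=[f"t{i}" for i in range(10)])
        call = call_tras(expr).iloc[0]
        assert call["gini"] == pytest.approx(0.9)
        assert not bool(call["is_tra"])

    def test_all_zero_gene_missing_gini(self):
        expr = pd.DataFrame([[0.0] * 10], index=["G1"],
                            columns=[f"t{i}" for i in range(10)])
        call = call_tras(expr).iloc[0]
        assert math.isnan(call["gini"])
        assert not bool(call["is_tra"])

    def test_thresholds_are_strict(self):
        # exactly Gini 0.8 (one of 5 tissues) and exactly 100 TPM: not a TRA
        expr = pd.DataFrame([[100.0] + [0.0] * 4], index=["G1"],
                            columns=[f"t{i}" for i in range(5)])
        call = call_tras(expr).iloc[0]
        assert call["gini"] == pytest.approx(0.8)
        assert not bool(call["is_tra"])
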