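"""Ranking, threshold selection, mismatch, and gatekeeper classification."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from gatekeepr import (
    NodeClass,
    ScoreTable,
    SelectionConfig,
    classify,
    compute_mismatch,
    compute_scores,
    fixture,
    rank_nodes,
    select_nodes,
)


def _table(vb, dp, z, degree=None):
    """Assemble a ScoreTable from raw per-node score dicts."""
    nodes = tuple(vb)
    return ScoreTable(
        nodes=nodes,
        vb=vb,
        dp=dp,
        degree=degree or {v: 0 for v in nodes},
        zscore=z,
        rank_vb=rank_nodes(vb),
        rank_dp=rank_nodes(dp),
        rank_z=rank_nodes(z),
    )


def _random_table(seed, n=10):
    rng = random.Random(seed)
    nodes = [f"v{i}" for i in range(n)]
    vb = {v: rng.uniform(0, 20) for v in nodes}
    dp = {v: rng.uniform(0, 3) for v in nodes}
    z = {v: rng.gauss(0, 1) for v in nodes}
    return _table(vb, dp, z)


class TestRankNodes:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ({"a": 3.0, "b": 1.0, "c": 2.0}, {"a": 1, "b": 3, "c": 2}),
            ({"a": 5.0, "b": 5.0, "c": 1.0}, {"a": 1, "b": 1, "c": 3}),
            ({"a": 2.0, "b": 2.0, "c": 2.0}, {"a": 1, "b": 1, "c": 1}),
        ],
    )
    def test_descending_competition_ranking(self, values, expected):
        assert rank_nodes(values) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            rank_nodes({"a": float("nan"), "b": 1.0})

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100), min_size=1, max_size=20
        )
    )
    def test_ranks_are_valid_competition_ranking(self, values):
        named = {f"v{i}": x for i, x in enumerate(values)}
        ranks = rank_nodes(named)
        n = len(named)
        assert all(1 <= r <= n for r in ranks.values())
        for v, x in named.items():
            assert ranks[v] == 1 + sum(1 for y in named.values() if y > x)


class TestSelectNodes:
    def test_threshold_one_selects_everything(self):
        table = _random_table(1)
        assert select_nodes(table, 1.0) == set(table.nodes)

    def test_default_threshold_cutoff_rank(self):
        """n = 10, T = 0.73 -> cutoff rank ceil(7.3) = 8."""
        nodes = [f"v{i}" for i in range(10)]
        vb = {v: float(10 - i) for i, v in enumerate(nodes)}  # ranks 1..10
        table = _table(vb, dict(vb), dict(vb))
        selected = select_nodes(table, 0.73)
        assert selected == {v for v in nodes if table.rank_vb[v] <= 8}
        assert len(selected) == 8

    def test_intersection_semantics(self):
        nodes = ["x", "y", "z", "w"]
        vb = {"x": 4.0, "y": 3.0, "z": 2.0, "w": 1.0}  # x is rank 1 on VB
        dp = {"x": 1.0, "y": 2.0, "z": 3.0, "w": 4.0}  # x is rank 4 on DP
        table = _table(vb, dp, dict(vb))
        assert "x" not in select_nodes(table, 0.5)

    def test_out_of_range_threshold_rejected(self):
        table = _random_table(2)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                select_nodes(table, bad)

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_monotone_in_threshold(self, seed):
        table = _random_table(seed)
        previous = set()
        for t in (0.1, 0.25, 0.5, 0.73, 0.9, 1.0):
            current = select_nodes(table, t)
            assert previous <= current
            previous = current


class TestComputeMismatch:
    def test_equal_ranks_give_zero(self):
        table = _table({"a": 2.0, "b": 1.0}, {"a": 2.0, "b": 1.0},
                       {"a": 2.0, "b": 1.0})
        assert compute_mismatch(table) == {"a": 0.0, "b": 0.0}

    def test_sign_convention(self):
        # a: top on both static measures, bottom on connectivity -> positive
        vb = {"a": 5.0, "b": 4.0, "c": 3.0, "d": 2.0, "e": 1.0}
        z = {"a": 1.0, "b": 5.0, "c": 4.0, "d": 3.0, "e": 2.0}
        table = _table(vb, dict(vb), z)
        mismatch = compute_mismatch(table)
        assert mismatch["a"] == pytest.approx(4.0)  # rank_C 5, static mean 1

    def test_negative_when_connectivity_dominates(self):
        ranks_source = {"a": 1.0, "b": 0.5}
        table = _table(
            vb={"a": 0.5, "b": 1.0},   # a rank 2
            dp={"a": 0.2, "b": 1.0},   # a rank 2
            z=ranks_source,            # a rank 1
        )
        assert compute_mismatch(table)["a"] == pytest.approx(-1.0)


class TestClassify:
    def test_uniform_scores_give_no_gatekeepers(self, toggle):
        result = classify(compute_scores(toggle))
        assert result.recommendations == ()
        assert all(
            c is not NodeClass.GATEKEEPER for c in result.node_class.values()
        )

    def test_recommendations_sorted_by_mismatch_then_name(self):
        table = _random_table(7)
        result = classify(table, SelectionConfig(T=1.0))
        mismatches = [result.mismatch[v] for v in result.recommendations]
        assert mismatches == sorted(mismatches, reverse=True)
        assert set(result.recommendations) == set(
            v for v, c in result.node_class.items() if c is NodeClass.GATEKEEPER
        )

    def test_classes_partition_nodes(self):
        for seed in range(1, 11):
            table = _random_table(seed)
            result = classify(table)
            assert set(result.node_class) == set(table.nodes)
            counts = sum(
                1 for v in table.nodes if result.node_class[v] in NodeClass
            )
            assert counts == len(table.nodes)

    def test_gatekeepers_are_selected_with_positive_mismatch(self):
        table = _random_table(13)
        config = SelectionConfig(T=0.73)
        result = classify(table, config)
        selected = select_nodes(table, config.T)
        for v in table.nodes:
            if result.node_class[v] is NodeClass.GATEKEEPER:
                assert v in selected and result.mismatch[v] > 0
            elif result.node_class[v] is NodeClass.SELECTED_NON_GATEKEEPER:
                assert v in selected and result.mismatch[v] <= 0
            else:
                assert v not in selected

    def test_hub_threshold_does_not_change_gatekeeper_set(self):
        table = _random_table(3)
        low = classify(table, SelectionConfig(hub_threshold=0.0))
        high = classify(table, SelectionConfig(hub_threshold=5.0))
        assert low.recommendations == high.recommendations
        assert sum(low.is_hub.values()) >= sum(high.is_hub.values())

    def test_bottleneck_fixture_recommends_bridge_first(self, bottleneck12):
        """The engineered low-degree bridge must top the recommendation list."""
        result = classify(compute_scores(bottleneck12))
        assert result.recommendations[0] == "b"
        assert result.node_class["b"] is NodeClass.GATEKEEPER
        assert not result.is_hub["b"]

    def test_relabeling_equivariance(self, bottleneck12):
        from gatekeepr import BooleanNetwork, parse_boolnet, write_boolnet

        text = write_boolnet(bottleneck12)
        renamed = parse_boolnet(
            text.replace("b,", "zz_bridge,").replace(" b", " zz_bridge")
        )
        assert isinstance(renamed, BooleanNetwork)
        result = classify(compute_scores(renamed))
        assert result.recommendations[0] == "zz_bridge"

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SelectionConfig(T=0.0)
        with pytest.raises(ValueError):
            SelectionConfig(T=1.2)

    def test_cutoff_float_noise_guard(self):
        # T*n values that are exact integers must not be bumped by fp noise
        table = _random_table(4, n=10)
        assert select_nodes(table, 0.7) == {
            v for v in table.nodes
            if table.rank_vb[v] <= 7 and table.rank_dp[v] <= 7
        }


def test_selection_threshold_percent_parity():
    """T given in percent at the CLI equals T/100 in the library."""
    assert math.ceil(0.73 * 10) == 8
    cfg = SelectionConfig(T=73 / 100)
    assert cfg.T == pytest.approx(0.73)
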