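import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ahpgroup.aggregate import (
    AggregationError,
    BlockWeights,
    aggregate_aip,
    compute_global_weights,
    rank_items,
)
from ahpgroup.core import PriorityVector
from ahpgroup.hierarchy import Hierarchy, build_default_hierarchy


def vec(weights, block="b", items=None):
    w = np.asarray(weights, dtype=float)
    items = items or tuple(f"i{k}" for k in range(len(w)))
    return PriorityVector(block, tuple(items), w)


def log_mean_oracle(mat):
    """Independent aggregation oracle: mean of logs, exponentiate, normalize."""
    g = np.exp(np.mean(np.log(mat), axis=0))
    return g / g.sum()


class TestAggregateAip:
    def test_idempotent_on_identical_vectors(self):
        vs = [vec([0.5, 0.3, 0.2]) for _ in range(5)]
        res = aggregate_aip(vs)
        np.testing.assert_allclose(res.weights, [0.5, 0.3, 0.2], atol=1e-12)
        np.testing.assert_allclose(res.sd, 0.0, atol=1e-15)

    def test_hand_computed_example(self):
        # GM components (0.35355, 0.35355, 0.25), normalizer 0.95711.
        vs = [vec([0.5, 0.25, 0.25]), vec([0.25, 0.5, 0.25])]
        res = aggregate_aip(vs)
        np.testing.assert_allclose(
            res.weights, [0.369398, 0.369398, 0.261204], atol=5e-7
        )

    def test_matches_log_mean_oracle(self, rng):
        mat = rng.dirichlet(np.ones(4), size=10)
        vs = [vec(row, items=("a", "b", "c", "d")) for row in mat]
        res = aggregate_aip(vs)
        np.testing.assert_allclose(res.weights, log_mean_oracle(mat), atol=1e-12)

    def test_single_vector_unchanged(self):
        res = aggregate_aip([vec([0.7, 0.2, 0.1])])
        np.testing.assert_allclose(res.weights, [0.7, 0.2, 0.1], atol=1e-12)
        assert np.all(np.isnan(res.sd))

    def test_sd_is_sample_sd(self, rng):
        mat = rng.dirichlet(np.ones(3), size=8)
        res = aggregate_aip([vec(row) for row in mat])
        np.testing.assert_allclose(res.sd, np.std(mat, axis=0, ddof=1), atol=1e-12)

    def test_zero_weight_rejected(self):
        with pytest.raises(AggregationError, match="geometric mean"):
            aggregate_aip([vec([1.0, 0.0, 0.0])])

    def test_mismatched_blocks_rejected(self):
        with pytest.raises(AggregationError, match="mismatched"):
            aggregate_aip([vec([0.5, 0.5], block="x"), vec([0.5, 0.5], block="y")])

    def test_respondent_weight_exponents(self):
        # All exponent mass on the first respondent reproduces their vector.
        vs = [vec([0.5, 0.25, 0.25]), vec([0.25, 0.5, 0.25])]
        res = aggregate_aip(vs, respondent_weights=[1.0, 0.0])
        np.testing.assert_allclose(res.weights, [0.5, 0.25, 0.25], atol=1e-12)

    def test_negative_exponent_rejected(self):
        vs = [vec([0.5, 0.5]), vec([0.5, 0.5])]
        with pytest.raises(AggregationError):
            aggregate_aip(vs, respondent_weights=[1.5, -0.5])

    def test_empty_rejected(self):
        with pytest.raises(AggregationError):
            aggregate_aip([])


class TestGlobalWeights:
    def test_simple_product(self):
        h = Hierarchy.from_config(
            {"root": "r", "children": {"r": ["p", "q"], "p": ["x", "y"], "q": ["u", "v"]}}
        )
        l2 = aggregate_aip([vec([0.5, 0.5], block="r", items=("p", "q"))])
        l3 = {
            "p": aggregate_aip([vec([0.4, 0.6], block="p", items=("x", "y"))]),
            "q": aggregate_aip([vec([0.5, 0.5], block="q", items=("u", "v"))]),
        }
        gw = compute_global_weights(h, l2, l3)
        assert gw.as_dict()["x"] == pytest.approx(0.2)

    def test_default_hierarchy_excludes_childless_category(self, default_hierarchy):
        h = default_hierarchy
        l2_items = tuple(n.id for n in h.children(h.root))
        l2 = aggregate_aip([vec([0.25] * 4, block=h.root, items=l2_items)])
        l3 = {
            b.block_id: aggregate_aip(
                [vec([1 / 3] * 3, block=b.block_id, items=b.item_ids)]
            )
            for b in h.blocks()
            if b.block_id != h.root
        }
        gw = compute_global_weights(h, l2, l3)
        assert len(gw.items) == 9
        assert "current_events" not in gw.items
        np.testing.assert_allclose(gw.weights, 1 / 12, atol=1e-12)

    def test_leaf_sum_equals_parent_locals_with_children(self, default_hierarchy, rng):
        h = default_hierarchy
        l2_items = tuple(n.id for n in h.children(h.root))
        w2 = rng.dirichlet(np.ones(4))
        l2 = aggregate_aip([vec(w2, block=h.root, items=l2_items)])
        l3 = {
            b.block_id: aggregate_aip(
                [vec(rng.dirichlet(np.ones(3)), block=b.block_id, items=b.item_ids)]
            )
            for b in h.blocks()
            if b.block_id != h.root
        }
        gw = compute_global_weights(h, l2, l3)
        parents_with_children = [n.id for n in h.children(h.root) if n.children]
        expected = sum(l2.as_dict()[p] for p in parents_with_children)
        assert gw.weights.sum() == pytest.approx(expected, abs=1e-12)

    def test_missing_level3_block_rejected(self, default_hierarchy):
        h = default_hierarchy
        l2_items = tuple(n.id for n in h.children(h.root))
        l2 = aggregate_aip([vec([0.25] * 4, block=h.root, items=l2_items)])
        with pytest.raises(AggregationError, match="level-3"):
            compute_global_weights(h, l2, {})


class TestRankItems:
    def test_tied_pair(self):
        r = rank_items(
            ("social", "current", "medical", "research"), (0.30, 0.28, 0.21, 0.21)
        )
        assert r.label_of("social") == "1"
        assert r.label_of("current") == "2"
        assert r.rank_of("medical") == (3, 4)
        assert r.rank_of("research") == (3, 4)

    def test_three_way_tie(self):
        items = ("reg", "psy", "gdp", "cus", "she", "sol", "str", "dig", "the")
        weights = (0.117, 0.075, 0.071, 0.071, 0.071, 0.070, 0.037, 0.031, 0.025)
        r = rank_items(items, weights)
        assert r.label_of("reg") == "1"
        for item in ("gdp", "cus", "she"):
            assert r.rank_of(item) == (3, 4, 5)
        assert r.label_of("sol") == "6"

    def test_strict_weights_give_permutation(self):
        r = rank_items(("a", "b", "c"), (0.2, 0.5, 0.3))
        assert r.rank_sets == ((3,), (1,), (2,))
        assert r.exact_ranks == (3, 1, 2)

    def test_rank_sets_partition_positions(self, rng):
        w = rng.dirichlet(np.ones(6))
        r = rank_items(tuple("abcdef"), w)
        covered = sorted(p for s in set(r.rank_sets) for p in s)
        assert covered == list(range(1, 7))

    def test_ties_only_at_reporting_precision(self):
        r = rank_items(("a", "b"), (0.2514, 0.2496), report_precision=3)
        assert r.rank_of("a") == (1,)
        r2 = rank_items(("a", "b"), (0.2514, 0.2496), report_precision=2)
        assert r2.rank_of("a") == (1, 2)

    def test_empty_rejected(self):
        with pytest.raises(AggregationError):
            rank_items((), ())

    def test_scale_invariance_of_order(self, rng):
        w = rng.dirichlet(np.ones(5))
        r1 = rank_items(tuple("abcde"), w, report_precision=12)
        r2 = rank_items(tuple("abcde"), w * 7.3, report_precision=12)
        assert r1.order() == r2.order()


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=2**31), st.integers(min_value=2, max_value=12))
def test_aggregation_permutation_invariance(seed, n):
    rng = np.random.default_rng(seed)
    mat = rng.dirichlet(np.ones(4), size=n)
    vs = [vec(row, items=("a", "b", "c", "d")) for row in mat]
    perm = rng.permutation(n)
    res1 = aggregate_aip(vs)
    res2 = aggregate_aip([vs[i] for i in perm])
    np.testing.assert_allclose(res1.weights, res2.weights, atol=1e-12)


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=2**31))
def test_gm_of_shared_latent_vector_is_exact(seed):
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(4) * 5)
    vs = [vec(w, items=("a", "b", "c", "d")) for _ in range(7)]
    res = aggregate_aip(vs)
    np.testing.assert_allclose(res.weights, w, atol=1e-12)


class TestBlockWeights:
    def test_column_and_drop(self):
        bw = BlockWeights(
            "b", ("x", "y"), ("r1", "r2", "r3"), np.array([[0.4, 0.6], [0.5, 0.5], [0.6, 0.4]])
        )
        np.testing.assert_allclose(bw.column("y"), [0.6, 0.5, 0.4])
        reduced = bw.drop({"r2"})
        assert reduced.respondent_ids == ("r1", "r3")
        assert reduced.weights.shape == (2, 2)

    def test_shape_validated(self):
        with pytest.raises(ValueError):
            BlockWeights("b", ("x", "y"), ("r1",), np.ones((2, 2)))
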