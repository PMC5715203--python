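import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ahpgroup.core import (
    DEFAULT_RANDOM_INDEX,
    ConvergenceError,
    Judgment,
    MatrixError,
    PairwiseMatrix,
    build_matrix,
    consistency_index,
    consistency_ratio,
    filter_consistent,
    is_on_saaty_scale,
    matrix_consistency,
    principal_eigenvector,
    respondent_consistency,
    snap_to_saaty,
)
from ahpgroup.hierarchy import ComparisonBlock

from conftest import consistent_matrix, random_reciprocal_matrix

BLOCK3 = ComparisonBlock("b", ("A", "B", "C"))


def judgment(a, b, v):
    return Judgment("r1", "b", a, b, v)


# Oracle for the inconsistent 3x3 example a12=2, a13=8, a23=2: the closed
# form lambda_max = 1 + d + 1/d with d = (a13/(a12*a23))**(1/3), cross-checked
# below against a full eigen-decomposition before being trusted.
LAMBDA_3X3 = 1.0 + 2.0 ** (1 / 3) + 2.0 ** (-1 / 3)  # 3.0536215758...


def test_closed_form_oracle_agrees_with_full_eigendecomposition():
    a = np.array([[1, 2, 8], [0.5, 1, 2], [1 / 8, 0.5, 1]])
    eigvals = np.linalg.eigvals(a)
    lam_eig = max(eigvals.real)
    assert lam_eig == pytest.approx(LAMBDA_3X3, abs=1e-12)


class TestBuildMatrix:
    def test_direct_placement(self):
        m = build_matrix(
            [judgment("A", "B", 2), judgment("A", "C", 6), judgment("B", "C", 3)],
            BLOCK3,
        )
        expected = np.array([[1, 2, 6], [0.5, 1, 3], [1 / 6, 1 / 3, 1]])
        np.testing.assert_allclose(m.values, expected)

    def test_reversed_orientation_equivalent(self):
        m1 = build_matrix(
            [judgment("A", "B", 2), judgment("A", "C", 6), judgment("B", "C", 3)],
            BLOCK3,
        )
        m2 = build_matrix(
            [judgment("B", "A", 0.5), judgment("A", "C", 6), judgment("C", "B", 1 / 3)],
            BLOCK3,
        )
        np.testing.assert_allclose(m1.values, m2.values)

    def test_missing_pair_named(self):
        with pytest.raises(MatrixError, match="missing judgment"):
            build_matrix([judgment("A", "B", 2), judgment("A", "C", 6)], BLOCK3)

    def test_duplicate_pair_rejected(self):
        with pytest.raises(MatrixError, match="duplicate"):
            build_matrix(
                [
                    judgment("A", "B", 2),
                    judgment("B", "A", 3),
                    judgment("A", "C", 6),
                    judgment("B", "C", 3),
                ],
                BLOCK3,
            )

    def test_nonpositive_value_rejected(self):
        with pytest.raises(MatrixError, match="positive"):
            judgment("A", "B", 0.0)

    def test_foreign_item_rejected(self):
        with pytest.raises(MatrixError, match="belong"):
            build_matrix([judgment("A", "Z", 2)], BLOCK3)


class TestPrincipalEigenvector:
    def test_uniform_matrix(self):
        m = PairwiseMatrix("b", ("A", "B", "C"), np.ones((3, 3)))
        vec, lam = principal_eigenvector(m)
        np.testing.assert_allclose(vec.weights, [1 / 3, 1 / 3, 1 / 3], atol=1e-12)
        assert lam == pytest.approx(3.0, abs=1e-10)

    def test_consistent_matrix_recovers_generator(self):
        w = np.array([0.6, 0.3, 0.1])
        m = PairwiseMatrix("b", ("A", "B", "C"), consistent_matrix(w))
        vec, lam = principal_eigenvector(m)
        np.testing.assert_allclose(vec.weights, w, atol=1e-10)
        assert lam == pytest.approx(3.0, abs=1e-10)

    def test_inconsistent_3x3_lambda_matches_oracle(self):
        m = PairwiseMatrix(
            "b", ("A", "B", "C"), np.array([[1, 2, 8], [0.5, 1, 2], [1 / 8, 0.5, 1]])
        )
        _, lam = principal_eigenvector(m)
        assert lam == pytest.approx(LAMBDA_3X3, abs=1e-10)
        assert round(lam, 4) == 3.0536

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_full_eigendecomposition(self, n, rng):
        for _ in range(20):
            a = random_reciprocal_matrix(n, rng)
            m = PairwiseMatrix("b", tuple(f"i{k}" for k in range(n)), a)
            vec, lam = principal_eigenvector(m)
            eigvals, eigvecs = np.linalg.eig(a)
            k = np.argmax(eigvals.real)
            ref = np.abs(eigvecs[:, k].real)
            ref = ref / ref.sum()
            assert lam == pytest.approx(eigvals[k].real, abs=1e-8)
            np.testing.assert_allclose(vec.weights, ref, atol=1e-8)
            assert lam >= n - 1e-9

    def test_weights_sum_to_one(self, rng):
        a = random_reciprocal_matrix(5, rng)
        vec, _ = principal_eigenvector(PairwiseMatrix("b", tuple("abcde"), a))
        assert vec.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(vec.weights > 0)

    def test_invalid_matrix_rejected(self):
        a = np.array([[1, 2.0], [0.4, 1]])  # reciprocity broken
        with pytest.raises(MatrixError, match="reciprocity"):
            principal_eigenvector(PairwiseMatrix("b", ("A", "B"), a))


class TestConsistency:
    def test_ci_consistent(self):
        assert consistency_index(3.0, 3) == 0.0

    def test_ci_from_oracle_lambda(self):
        ci = consistency_index(LAMBDA_3X3, 3)
        assert ci == pytest.approx((LAMBDA_3X3 - 3) / 2, abs=1e-15)
        assert round(ci, 4) == 0.0268

    def test_ci_arithmetic(self):
        assert consistency_index(4.2, 4) == pytest.approx(0.2 / 3, abs=1e-12)

    def test_ci_requires_n_ge_2(self):
        with pytest.raises(ValueError):
            consistency_index(1.0, 1)

    def test_ci_clips_negative_within_tolerance(self):
        assert consistency_index(3.0 - 1e-12, 3) == 0.0

    def test_cr_zero_ci(self):
        assert consistency_ratio(0.0, 3) == 0.0

    def test_cr_from_oracle_ci(self):
        ci = consistency_index(LAMBDA_3X3, 3)
        cr = consistency_ratio(ci, 3)
        assert cr == pytest.approx(ci / 0.58, abs=1e-15)
        assert round(cr, 4) == 0.0462

    def test_cr_convention_n2(self):
        assert consistency_ratio(0.5, 2) == 0.0

    def test_cr_unknown_order(self):
        with pytest.raises(ValueError):
            consistency_ratio(0.1, 11)

    def test_ri_table_shape(self):
        assert DEFAULT_RANDOM_INDEX[1] == DEFAULT_RANDOM_INDEX[2] == 0.0
        values = [DEFAULT_RANDOM_INDEX[n] for n in range(1, 11)]
        assert values == sorted(values)

    def test_cr_invariant_under_permutation(self, rng):
        a = random_reciprocal_matrix(4, rng)
        perm = rng.permutation(4)
        m1 = PairwiseMatrix("b", tuple("wxyz"), a)
        m2 = PairwiseMatrix("b", tuple(np.array(list("wxyz"))[perm]), a[np.ix_(perm, perm)])
        r1 = matrix_consistency(m1)
        r2 = matrix_consistency(m2)
        assert r1.cr == pytest.approx(r2.cr, abs=1e-10)


class TestRespondentConsistency:
    def _matrices(self, crs_target):
        # consistent 3x3 (CR 0) plus an inconsistent one as needed
        out = []
        if 0.0 in crs_target:
            out.append(
                PairwiseMatrix("b0", ("A", "B", "C"), consistent_matrix(np.array([0.5, 0.3, 0.2])))
            )
        return out

    def test_all_consistent_gives_zero(self):
        m1 = PairwiseMatrix("b1", ("A", "B", "C"), consistent_matrix(np.array([0.5, 0.3, 0.2])))
        m2 = PairwiseMatrix("b2", ("D", "E"), np.array([[1, 3], [1 / 3, 1]]))
        reports, cr = respondent_consistency([m1, m2])
        assert cr == 0.0
        assert all(r.cr == 0.0 for r in reports.values())

    def test_mean_vs_max_rule(self):
        m1 = PairwiseMatrix("b1", ("A", "B", "C"), consistent_matrix(np.array([0.5, 0.3, 0.2])))
        m2 = PairwiseMatrix(
            "b2", ("D", "E", "F"), np.array([[1, 2, 8], [0.5, 1, 2], [1 / 8, 0.5, 1]])
        )
        reports, cr_mean = respondent_consistency([m1, m2], rule="mean")
        _, cr_max = respondent_consistency([m1, m2], rule="max")
        block_crs = sorted(r.cr for r in reports.values())
        assert cr_mean == pytest.approx(np.mean(block_crs))
        assert cr_max == pytest.approx(max(block_crs))

    def test_single_block_identity(self):
        m = PairwiseMatrix(
            "b", ("A", "B", "C"), np.array([[1, 2, 8], [0.5, 1, 2], [1 / 8, 0.5, 1]])
        )
        reports, cr = respondent_consistency([m])
        assert cr == reports["b"].cr

    def test_unknown_rule(self):
        m = PairwiseMatrix("b", ("A", "B"), np.array([[1, 2], [0.5, 1]]))
        with pytest.raises(ValueError):
            respondent_consistency([m], rule="median")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            respondent_consistency([])


class TestFilterConsistent:
    def test_boundary_inclusive(self):
        res = filter_consistent({"a": 0.1, "b": 0.2, "c": 0.21})
        assert set(res.included) == {"a", "b"}
        assert res.excluded == ["c"]

    def test_subgroup_percentages(self):
        crs = {f"p{i}": (0.1 if i < 67 else 0.3) for i in range(120)}
        res = filter_consistent(crs, subgroups={r: "patient" for r in crs})
        assert res.summary["subgroups"]["patient"]["pct_included"] == 56
        assert res.summary["subgroups"]["patient"]["pct_excluded"] == 44

    def test_empty_cohort_flagged(self):
        res = filter_consistent({})
        assert res.included == [] and res.excluded == []
        assert res.summary["defined"] is False

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            filter_consistent({"a": 0.1}, threshold=0.0)

    def test_summary_stats(self):
        res = filter_consistent({"a": 0.1, "b": 0.3})
        assert res.summary["mean_cr"] == pytest.approx(0.2)
        assert res.summary["median_cr"] == pytest.approx(0.2)


class TestSaatyScale:
    def test_grid_membership(self):
        assert is_on_saaty_scale(1 / 7)
        assert is_on_saaty_scale(9.0)
        assert not is_on_saaty_scale(2.5)

    def test_snap_symmetry(self):
        v = snap_to_saaty(2.2)
        assert snap_to_saaty(1 / 2.2) == pytest.approx(1 / v)

    def test_off_scale_warns(self):
        from ahpgroup.core import warn_off_scale

        with pytest.warns(UserWarning, match="verbal-scale"):
            assert warn_off_scale([2.5, 3.0]) == 1


# -- property-based checks ---------------------------------------------------

weight_vectors = st.lists(
    st.floats(min_value=0.01, max_value=1.0), min_size=3, max_size=6
).map(lambda ws: np.array(ws) / np.sum(ws))


@settings(max_examples=40, deadline=None)
@given(weight_vectors)
def test_consistent_matrix_round_trip(w):
    n = len(w)
    m = PairwiseMatrix("b", tuple(f"i{k}" for k in range(n)), consistent_matrix(w))
    vec, lam = principal_eigenvector(m)
    np.testing.assert_allclose(vec.weights, w, atol=1e-10)
    rep = matrix_consistency(m)
    assert abs(rep.cr) <= 1e-10


@settings(max_examples=40, deadline=None)
@given(st.integers(min_value=3, max_value=6), st.integers(min_value=0, max_value=2**31))
def test_lambda_max_at_least_n(n, seed):
    a = random_reciprocal_matrix(n, np.random.default_rng(seed))
    m = PairwiseMatrix("b", tuple(f"i{k}" for k in range(n)), a)
    _, lam = principal_eigenvector(m)
    assert lam >= n - 1e-9


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31))
def test_cr_invariant_to_judgment_orientation(seed):
    rng = np.random.default_rng(seed)
    vals = {pair: float(np.exp(rng.normal())) for pair in (("A", "B"), ("A", "C"), ("B", "C"))}
    js_fwd = [judgment(a, b, v) for (a, b), v in vals.items()]
    js_rev = [judgment(b, a, 1.0 / v) for (a, b), v in vals.items()]
    cr_fwd = matrix_consistency(build_matrix(js_fwd, BLOCK3)).cr
    cr_rev = matrix_consistency(build_matrix(js_rev, BLOCK3)).cr
    assert cr_fwd == pytest.approx(cr_rev, abs=1e-10)
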