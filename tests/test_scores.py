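"""Per-sample and cross-sample summary scores."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import rankdata

from sigeval import (
    DataError,
    ExpressionMatrix,
    GeneSignature,
    InsufficientGenesError,
    SignatureSet,
    UndefinedScoreError,
    gsva_score,
    ncs_score,
    score_matrix,
    simple_score,
    ssgsea_score,
    zscore_score,
)

finite_vec = st.lists(
    st.floats(-1e4, 1e4, allow_nan=False), min_size=4, max_size=30
)


class TestSimpleScores:
    @pytest.mark.parametrize(
        "values,method,expected",
        [
            ([1, 2, 3, 4], "trimean", 2.5),
            ([1, 2, 3, 4, 100], "mad", 1.0),
            ([1, 2, 3, 4], "midrange", 2.5),
            ([1, 2, 3, 4], "median", 2.5),
            ([2, 4], "mean", 3.0),
            ([0, 0, 10, 10], "aad", 5.0),
        ],
    )
    def test_worked_examples(self, values, method, expected):
        assert simple_score(values, method) == pytest.approx(expected)

    def test_iqm_minimum_four_values_distinct_error(self):
        with pytest.raises(InsufficientGenesError):
            simple_score([1, 2, 3], "iqm")
        # generic undefined-score failures are a different type
        with pytest.raises(UndefinedScoreError):
            simple_score([], "mean")

    def test_iqm_excludes_outliers(self):
        # type-7 quartiles of 1..8 are 2.75 and 6.25 -> inner mean of 3..6
        assert simple_score(range(1, 9), "iqm") == pytest.approx(4.5)

    @given(
        st.lists(st.integers(-10_000, 10_000), min_size=4, max_size=30),
        st.integers(-1000, 1000),
    )
    def test_shift_equivariance_central_tendency(self, v, c):
        # integer-valued inputs keep quartile boundary decisions exact;
        # mode is tested separately (half-sample tie-breaks are exact-arithmetic)
        v = np.asarray(v, dtype=float)
        for m in ("mean", "median", "midrange", "midhinge", "trimean", "iqm"):
            base = simple_score(v, m)
            shifted = simple_score(v + c, m)
            assert shifted == pytest.approx(base + c, rel=1e-12, abs=1e-9)

    def test_mode_shift_equivariance_example(self):
        v = np.array([0.0, 0.25, 0.5, 4.0, 4.2, 4.3, 9.0, 9.5])
        assert simple_score(v + 10.0, "mode") == pytest.approx(
            simple_score(v, "mode") + 10.0
        )

    @given(finite_vec, st.floats(-100, 100, allow_nan=False))
    def test_shift_invariance_dispersion(self, v, c):
        for m in ("iqr", "mad", "aad"):
            assert simple_score(np.asarray(v) + c, m) == pytest.approx(
                simple_score(v, m), rel=1e-9, abs=1e-6
            )

    @given(finite_vec)
    def test_trimean_identity(self, v):
        tm = simple_score(v, "trimean")
        mh = simple_score(v, "midhinge")
        med = simple_score(v, "median")
        assert tm == pytest.approx((mh + med) / 2, rel=1e-12, abs=1e-9)

    def test_half_sample_mode_finds_dense_cluster(self):
        v = [0.0, 0.1, 0.2, 5.0, 5.01, 5.02, 5.03, 9.0]
        assert 4.9 < simple_score(v, "mode") < 5.1

    def test_mode_deterministic(self):
        v = np.random.default_rng(1).normal(size=25)
        assert simple_score(v, "mode") == simple_score(v, "mode")


class TestZscore:
    def test_single_gene_closed_form(self):
        m = ExpressionMatrix(["A"], ["s1", "s2"], np.array([[1.0, 3.0]]))
        s = zscore_score(m, GeneSignature("sig", ("A",)))
        np.testing.assert_allclose(s.to_numpy(), [-0.70710678, 0.70710678])

    def test_zero_mean_across_samples(self, small_matrix):
        s = zscore_score(small_matrix, GeneSignature("sig", ("A", "C", "D")))
        assert s.sum() == pytest.approx(0.0, abs=1e-12)

    def test_constant_gene_only_undefined(self):
        m = ExpressionMatrix(["A"], ["s1", "s2"], np.array([[2.0, 2.0]]))
        with pytest.raises(UndefinedScoreError):
            zscore_score(m, GeneSignature("sig", ("A",)))

    def test_zero_variance_gene_excluded_with_warning(self, small_matrix):
        with pytest.warns(UserWarning, match="zero-variance"):
            s = zscore_score(small_matrix, GeneSignature("sig", ("A", "B")))
        expected = zscore_score(small_matrix, GeneSignature("sig", ("A",)))
        np.testing.assert_allclose(s.to_numpy(), expected.to_numpy())


class TestNCS:
    def test_minmax_endpoints(self):
        m = ExpressionMatrix(["A"], ["s1", "s2"], np.array([[0.0, 10.0]]))
        s = ncs_score(m, GeneSignature("sig", ("A",)))
        np.testing.assert_allclose(s.to_numpy(), [0.0, 1.0])

    def test_opposite_gradients_give_half(self):
        m = ExpressionMatrix(
            ["A", "B"], ["s1", "s2", "s3"],
            np.array([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0]]),
        )
        s = ncs_score(m, GeneSignature("sig", ("A", "B")))
        np.testing.assert_allclose(s.to_numpy(), [0.5, 0.5, 0.5])

    @given(st.integers(0, 2**31 - 1))
    def test_range_zero_one(self, seed):
        rng = np.random.default_rng(seed)
        m = ExpressionMatrix(
            [f"G{i}" for i in range(6)],
            [f"s{j}" for j in range(5)],
            rng.random((6, 5)),
        )
        s = ncs_score(m, GeneSignature("sig", tuple(f"G{i}" for i in range(4))))
        assert ((s >= 0) & (s <= 1)).all()


def ssgsea_bruteforce(values, member, alpha=0.25):
    """Independent running-sum evaluation with explicit loops."""
    n = len(values)
    ranks = rankdata(values, method="average")
    order = sorted(range(n), key=lambda i: -ranks[i])
    k = sum(member)
    denom_in = sum(abs(ranks[i]) ** alpha for i in order if member[i])
    p_in = p_out = 0.0
    total = 0.0
    for i in order:
        if member[i]:
            p_in += abs(ranks[i]) ** alpha / denom_in
        else:
            p_out += 1.0 / (n - k)
        total += p_in - p_out
    return total


class TestSsgsea:
    def test_top_vs_bottom_symmetric_magnitude(self):
        genes = [f"G{i}" for i in range(8)]
        vals = np.arange(8.0, 0.0, -1.0)[:, None]  # G0 highest
        m = ExpressionMatrix(genes, ["s1"], vals)
        top = ssgsea_score(m, GeneSignature("t", ("G0",))).iloc[0]
        bottom = ssgsea_score(m, GeneSignature("b", ("G7",))).iloc[0]
        assert top > 0 > bottom
        assert abs(top) == pytest.approx(abs(bottom))

    def test_empty_intersection_undefined(self, small_matrix):
        with pytest.raises(UndefinedScoreError):
            ssgsea_score(small_matrix, GeneSignature("sig", ("ZZZ",)))

    def test_full_universe_rejected(self, small_matrix):
        with pytest.raises(DataError):
            ssgsea_score(small_matrix, GeneSignature("sig", ("A", "B", "C", "D")))

    def test_identical_rankings_identical_scores(self):
        m = ExpressionMatrix(
            ["A", "B", "C"], ["s1", "s2"],
            np.array([[3.0, 30.0], [2.0, 20.0], [1.0, 10.0]]),
        )
        s = ssgsea_score(m, GeneSignature("sig", ("A",)))
        assert s.iloc[0] == pytest.approx(s.iloc[1])

    @given(st.integers(0, 2**31 - 1), st.integers(5, 12), st.integers(1, 4))
    def test_bruteforce_oracle(self, seed, n, k):
        rng = np.random.default_rng(seed)
        vals = rng.random(n)
        member_idx = rng.choice(n, size=min(k, n - 1), replace=False)
        genes = [f"G{i}" for i in range(n)]
        m = ExpressionMatrix(genes, ["s1"], vals[:, None])
        sig = GeneSignature("sig", tuple(genes[i] for i in member_idx))
        got = ssgsea_score(m, sig).iloc[0]
        member = [i in set(member_idx) for i in range(n)]
        assert got == pytest.approx(ssgsea_bruteforce(vals, member), abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        genes = [f"G{i}" for i in range(10)]
        vals = rng.random((10, 3))
        m1 = ExpressionMatrix(genes, ["a", "b", "c"], vals)
        m2 = ExpressionMatrix(genes, ["a", "b", "c"], np.exp(3 * vals))
        sig = GeneSignature("sig", ("G0", "G3", "G7"))
        np.testing.assert_allclose(
            ssgsea_score(m1, sig).to_numpy(), ssgsea_score(m2, sig).to_numpy()
        )


class TestGsva:
    def _matrix(self, rng, n=10, s=4):
        return ExpressionMatrix(
            [f"G{i}" for i in range(n)],
            [f"s{j}" for j in range(s)],
            rng.random((n, s)),
        )

    def test_sign_separates_top_and_bottom_sample(self):
        # signature genes high in s0, low in s1
        n = 10
        vals = np.random.default_rng(3).random((n, 3))
        vals[:3, 0] = [10, 11, 12]
        vals[:3, 1] = [-10, -11, -12]
        m = ExpressionMatrix([f"G{i}" for i in range(n)], ["s0", "s1", "s2"], vals,
                             scale="log")
        sm = gsva_score(m, GeneSignature("sig", ("G0", "G1", "G2")))
        assert sm.scores.loc["sig", "s0"] > 0 > sm.scores.loc["sig", "s1"]

    def test_sample_order_invariance(self, rng):
        m = self._matrix(rng)
        sig = GeneSignature("sig", ("G0", "G4"))
        sm = gsva_score(m, sig)
        perm = [2, 0, 3, 1]
        m2 = ExpressionMatrix(
            list(m.gene_ids), [m.sample_ids[i] for i in perm], m.values[:, perm]
        )
        sm2 = gsva_score(m2, sig)
        for sid in m.sample_ids:
            assert sm2.scores.loc["sig", sid] == pytest.approx(
                sm.scores.loc["sig", sid]
            )

    def test_needs_three_samples(self, rng):
        m = ExpressionMatrix(["A", "B"], ["s1", "s2"], rng.random((2, 2)))
        with pytest.raises(DataError):
            gsva_score(m, GeneSignature("sig", ("A",)))

    def test_tau_zero_unweights_steps(self, rng):
        m = self._matrix(rng)
        sig = GeneSignature("sig", ("G1", "G5", "G8"))
        sm = gsva_score(m, sig, tau=0.0)
        assert np.isfinite(sm.scores.to_numpy()).all()

    def test_empirical_kcdf_runs(self, rng):
        m = self._matrix(rng)
        sm = gsva_score(m, GeneSignature("sig", ("G2", "G6")), kcdf="empirical")
        assert sm.scores.shape == (1, 4)


class TestScoreMatrixDispatcher:
    def test_iqm_with_three_matched_genes_is_nan(self, small_matrix):
        sig = GeneSignature("sig", ("A", "B", "C"))
        sm = score_matrix(small_matrix, sig, "iqm")
        assert sm.scores.isna().all().all()
        assert sm.n_genes_used["sig"] == 3

    def test_mean_of_single_gene_signature_is_that_gene(self, small_matrix):
        sm = score_matrix(small_matrix, GeneSignature("sig", ("C",)), "mean")
        np.testing.assert_allclose(
            sm.scores.loc["sig"].to_numpy(), small_matrix.values[2]
        )

    def test_gene_order_permutation_invariance(self, small_matrix):
        s1 = score_matrix(small_matrix, GeneSignature("sig", ("A", "C", "D")), "median")
        s2 = score_matrix(small_matrix, GeneSignature("sig", ("D", "A", "C")), "median")
        np.testing.assert_allclose(s1.scores.to_numpy(), s2.scores.to_numpy())

    def test_unknown_method_rejected(self, small_matrix):
        with pytest.raises(DataError):
            score_matrix(small_matrix, GeneSignature("sig", ("A",)), "pc1")

    def test_missing_genes_warn_and_record(self, small_matrix):
        with pytest.warns(UserWarning, match="absent"):
            sm = score_matrix(
                small_matrix, GeneSignature("sig", ("A", "NOPE")), "mean"
            )
        assert sm.n_genes_used["sig"] == 1
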