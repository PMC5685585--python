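"""Distances, sums of squares, pseudo-F, permutation null, FDR."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from patchconn import (
    DegenerateDataError,
    DesignError,
    ParameterError,
    fdr_correct,
    generate_connectivity_cohort,
    node_distance_matrix,
    permutation_test,
    pseudo_f,
    run_mdmr,
    total_sum_squares,
    within_sum_squares,
)
from patchconn.mdmr import NodeDistanceMatrix


def embedding_oracle(rows, labels):
    """ANOVA sums of squares computed in the Euclidean embedding space.

    d = sqrt(2(1-r)) equals the Euclidean distance between centered,
    unit-norm pattern vectors, so SST/SSW/SSA can be computed as ordinary
    deviations from (group) centroids — an independent route to the same
    quantities.
    """
    z = rows - rows.mean(axis=1, keepdims=True)
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    grand = z.mean(axis=0)
    sst = float(((z - grand) ** 2).sum())
    ssw = 0.0
    ssa = 0.0
    labels = np.asarray(labels)
    for g in np.unique(labels):
        zg = z[labels == g]
        cg = zg.mean(axis=0)
        ssw += float(((zg - cg) ** 2).sum())
        ssa += len(zg) * float(((cg - grand) ** 2).sum())
    return sst, ssw, ssa


def uniform_distance_matrix(n, d=1.0):
    D = np.full((n, n), d)
    np.fill_diagonal(D, 0.0)
    return D


class TestNodeDistance:
    def test_identical_and_negated_and_orthogonal_rows(self):
        # subjects with engineered node-0 patterns
        base = np.array([1.0, 2.0, 3.0, 4.0, -2.0])
        negated = -(base - base.mean()) + base.mean()
        orth = np.array([1.0, -1.0, -1.0, 1.0, 0.0])
        assert abs(np.dot(base - base.mean(), orth - orth.mean())) < 1e-12
        stack = np.zeros((4, 5, 5))
        for u, row in enumerate([base, base, negated, orth]):
            stack[u, 0, :] = row
        D = node_distance_matrix(stack, 0, include_diagonal=True).values
        assert D[0, 1] == pytest.approx(0.0, abs=1e-7)
        assert D[0, 2] == pytest.approx(2.0)
        assert D[0, 3] == pytest.approx(np.sqrt(2.0))

    def test_constant_row_rejected_with_subject_and_node(self):
        stack = np.zeros((3, 4, 4))
        stack[1, 2, :] = 5.0
        stack[0, 2, :] = [1, 2, 3, 4]
        stack[2, 2, :] = [4, 1, 2, 2]
        with pytest.raises(DegenerateDataError, match="subject 1, node 2"):
            node_distance_matrix(stack, 2)

    def test_spearman_is_rank_based(self, random_connectomes):
        D1 = node_distance_matrix(random_connectomes, 3, kind="spearman").values
        # any strictly monotone transform of the rows leaves Spearman alone
        transformed = np.power(random_connectomes + 2.0, 3)
        D2 = node_distance_matrix(transformed, 3, kind="spearman").values
        np.testing.assert_allclose(D1, D2, atol=1e-12)


class TestSumsOfSquares:
    def test_hand_evaluated_uniform_distances(self):
        D = uniform_distance_matrix(4)
        labels = ["a", "a", "b", "b"]
        assert total_sum_squares(D) == pytest.approx(1.5)
        assert within_sum_squares(D, labels) == pytest.approx(1.0)
        sst, ssw, ssa, f = pseudo_f(D, labels)
        assert (sst, ssw, ssa) == pytest.approx((1.5, 1.0, 0.5))
        assert f == pytest.approx(3 * 0.5 / 1.0)

    def test_zero_distances_and_scaling(self):
        assert total_sum_squares(np.zeros((5, 5))) == 0.0
        D = np.abs(np.random.default_rng(0).standard_normal((6, 6)))
        D = (D + D.T)
        np.fill_diagonal(D, 0.0)
        assert total_sum_squares(3.0 * D) == pytest.approx(
            9.0 * total_sum_squares(D)
        )

    def test_within_label_symmetry(self):
        rng = np.random.default_rng(1)
        D = np.abs(rng.standard_normal((8, 8)))
        D = D + D.T
        np.fill_diagonal(D, 0.0)
        labels = ["a", "a", "a", "a", "b", "b", "b", "b"]
        assert within_sum_squares(D, labels) == pytest.approx(
            within_sum_squares(D, labels[::-1])
        )

    def test_small_group_rejected(self):
        with pytest.raises(DesignError):
            within_sum_squares(uniform_distance_matrix(4), ["a", "b", "b", "b"])

    def test_perfect_separation_gives_infinite_f(self):
        D = np.zeros((4, 4))
        D[:2, 2:] = 1.0
        D[2:, :2] = 1.0
        sst, ssw, ssa, f = pseudo_f(D, ["a", "a", "b", "b"])
        assert ssw == 0.0 and ssa > 0.0 and np.isinf(f)

    def test_degenerate_all_zero_matrix(self):
        with pytest.raises(DegenerateDataError):
            pseudo_f(np.zeros((4, 4)), ["a", "a", "b", "b"])

    @pytest.mark.parametrize("trial", range(10))
    def test_embedding_oracle_agreement(self, trial):
        """Distance-route Eqs. agree with the embedding-space ANOVA oracle."""
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(6, 21))
        N = int(rng.integers(5, 31))
        rows = rng.standard_normal((n, N))
        n1 = int(rng.integers(2, n - 1))
        labels = ["a"] * n1 + ["b"] * (n - n1)
        z = rows - rows.mean(axis=1, keepdims=True)
        z = z / np.linalg.norm(z, axis=1, keepdims=True)
        D = np.sqrt(np.maximum(2 * (1 - np.clip(z @ z.T, -1, 1)), 0))
        np.fill_diagonal(D, 0.0)
        sst, ssw, ssa, _ = pseudo_f(D, labels)
        o_sst, o_ssw, o_ssa = embedding_oracle(rows, labels)
        assert sst == pytest.approx(o_sst, rel=1e-10)
        assert ssw == pytest.approx(o_ssw, rel=1e-10)
        assert ssa == pytest.approx(o_ssa, rel=1e-10, abs=1e-12)
        assert ssa >= -1e-12
        assert sst == pytest.approx(ssw + ssa, rel=1e-12)


class TestPermutationTest:
    def test_equal_distances_force_p_one(self):
        f, p = permutation_test(
            uniform_distance_matrix(8), ["a"] * 4 + ["b"] * 4,
            n_perm=199, seed=0,
        )
        assert p == 1.0

    def test_seed_reproducibility(self, effect_cohort):
        D = node_distance_matrix(effect_cohort.matrices, 3)
        r1 = permutation_test(D, effect_cohort.labels, n_perm=199, seed=42)
        r2 = permutation_test(D, effect_cohort.labels, n_perm=199, seed=42)
        assert r1 == r2

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ParameterError):
            permutation_test(
                uniform_distance_matrix(4), ["a", "a", "b", "b"], n_perm=50
            )

    def test_monte_carlo_matches_exhaustive_3_plus_3(self, random_connectomes):
        """MC p converges to the exact p over all C(6,3)=20 label splits."""
        stack = random_connectomes[:6]
        labels = ["a"] * 3 + ["b"] * 3
        for node in (0, 5, 9):
            D = node_distance_matrix(stack, node)
            f_obs, p_mc = permutation_test(D, labels, n_perm=9999, seed=7)
            f_splits = []
            for split in combinations(range(6), 3):
                lab = ["b"] * 6
                for i in split:
                    lab[i] = "a"
                f_splits.append(pseudo_f(D, lab)[3])
            p_exact = np.mean(
                np.asarray(f_splits) >= f_obs - 1e-10 * max(abs(f_obs), 1)
            )
            assert p_mc == pytest.approx(p_exact, abs=0.02)

    def test_scaled_f_convention_gives_identical_p(self, effect_cohort):
        """(n-1)*SSA/SSW and the (k-1),(n-k)-normalized F order permutations
        identically, so the permutation p is the same."""
        D = node_distance_matrix(effect_cohort.matrices, 7)
        labels = effect_cohort.labels
        d2 = D.values ** 2
        n = d2.shape[0]
        _, p_default = permutation_test(D, labels, n_perm=999, seed=3)

        # independent re-implementation with the conventional normalization,
        # using the same permutation stream as permutation_test(seed=3)
        codes = np.array([0] * 20 + [1] * 20)
        order = np.argsort(np.random.default_rng(3).random((999, n)), axis=1)
        all_codes = np.vstack([codes[None, :], codes[order]])
        sst = d2.sum() / 2 / n
        ssw = np.zeros(1000)
        for g in (0, 1):
            member = (all_codes == g).astype(float)
            ssw += np.einsum("pi,ij,pj->p", member, d2, member) / (2.0 * 20)
        f_conv = ((sst - ssw) / 1.0) / (ssw / (n - 2))
        p_conv = (1 + np.sum(f_conv[1:] >= f_conv[0] - 1e-12)) / 1000.0
        assert p_default == pytest.approx(p_conv, abs=1e-12)

    def test_null_p_values_approximately_uniform(self):
        """KS check on pooled null p-values from exchangeable cohorts."""
        pvals = []
        master = np.random.SeedSequence(77)
        for rep, child in enumerate(master.spawn(30)):
            cohort = generate_connectivity_cohort(
                30, {"a": 20, "b": 20}, effect_size=0.0, seed=child
            )
            res = run_mdmr(cohort.matrices, cohort.labels, n_perm=999,
                           seed=1000 + rep)
            pvals.extend(res.table["p"])
        assert len(pvals) >= 500
        # p is discrete uniform on {1/1000,...,1}; KS against U(0,1) with the
        # alpha=0.001 critical value plus a one-grid-step allowance
        stat = kstest(pvals, "uniform").statistic
        assert stat < 1.95 / np.sqrt(len(pvals)) + 1.0 / 1000


class TestFdr:
    def test_step_up_matches_brute_force(self):
        p = [0.001, 0.02, 0.03, 0.5]
        q, reject = fdr_correct(p, alpha=0.05)
        # brute-force BH: largest k with p_(k) <= k/m*alpha
        m = len(p)
        ps = np.sort(p)
        k = max((i + 1 for i in range(m) if ps[i] <= (i + 1) / m * 0.05),
                default=0)
        expected = np.asarray(p) <= (k / m * 0.05 if k else -1)
        np.testing.assert_array_equal(reject, expected)
        assert reject.tolist() == [True, True, True, False]

    def test_all_ones_and_single_p(self):
        _, reject = fdr_correct([1.0, 1.0, 1.0], alpha=0.05)
        assert not reject.any()
        _, reject = fdr_correct([0.005], alpha=0.01)
        assert reject.all()

    def test_empty_family_rejected(self):
        from patchconn import ValidationError

        with pytest.raises(ValidationError):
            fdr_correct([], alpha=0.05)


class TestFdrProperties:
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0),
                 min_size=1, max_size=40),
        st.floats(min_value=0.005, max_value=0.2),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_bh_rejections_monotone_in_alpha(self, ps, alpha):
        q1, rej1 = fdr_correct(ps, alpha=alpha)
        _, rej2 = fdr_correct(ps, alpha=min(0.99, 2 * alpha))
        assert set(np.flatnonzero(rej1)) <= set(np.flatnonzero(rej2))
        assert ((q1 >= 0) & (q1 <= 1)).all()
        # q-values never fall below raw p / m-scaling floor: q >= p
        assert (q1 >= np.asarray(ps) - 1e-12).all()


class TestRunMdmr:
    def test_recovers_truth_on_effect_cohort(self, effect_cohort):
        res = run_mdmr(effect_cohort.matrices, effect_cohort.labels,
                       n_perm=999, alpha=0.01, seed=21)
        assert res.significant_nodes == set(effect_cohort.truth)
        table = res.table
        np.testing.assert_allclose(
            table["SST"], table["SSW"] + table["SSA"], rtol=1e-10
        )
        assert (table["SSA"] >= -1e-12).all()
        assert ((table["p"] > 0) & (table["p"] <= 1)).all()

    def test_null_cohort_rarely_significant(self, null_cohort):
        res = run_mdmr(null_cohort.matrices, null_cohort.labels,
                       n_perm=199, alpha=0.01, seed=22)
        assert len(res.significant_nodes) == 0

    def test_parallel_matches_serial(self, effect_cohort):
        kwargs = dict(n_perm=99, alpha=0.01, seed=23)
        r1 = run_mdmr(effect_cohort.matrices, effect_cohort.labels,
                      n_jobs=1, **kwargs)
        r2 = run_mdmr(effect_cohort.matrices, effect_cohort.labels,
                      n_jobs=2, **kwargs)
        np.testing.assert_array_equal(r1.table["p"], r2.table["p"])
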