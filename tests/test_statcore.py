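"""Statistical engine: Holm step-down, permutation t-test, PERMANOVA,
Bray-Curtis, and the classical-test wrappers."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from antwound.statcore import (
    anova_tukey,
    bray_curtis,
    holm_bonferroni,
    mann_whitney_u,
    permanova,
    permutation_t_test,
    welch_t,
)


class TestHolm:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.01, 0.04, 0.03], [0.03, 0.06, 0.06]),
            ([0.5], [0.5]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_worked_examples(self, pvals, expected):
        np.testing.assert_allclose(holm_bonferroni(pvals), expected)

    def test_empty_input(self):
        assert holm_bonferroni([]).size == 0

    @pytest.mark.parametrize("bad", [[-0.1], [1.5], [float("nan")]])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            holm_bonferroni(bad)

    @given(
        arrays(float, st.integers(1, 12), elements=st.floats(0, 1, allow_nan=False))
    )
    @settings(max_examples=50, deadline=None)
    def test_dominance_bounds(self, p):
        """Holm output is between the raw p-values and the Bonferroni bound."""
        adj = holm_bonferroni(p)
        m = len(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= np.minimum(m * p, 1.0) + 1e-12)
        # step-down monotone after sorting by raw p
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


def _brute_force_perm_p(x, y):
    """Enumerate all C(n1+n2, n1) label assignments of the Welch t."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def t_stat(a, b):
        va, vb = a.var(ddof=1), b.var(ddof=1)
        den = math.sqrt(va / len(a) + vb / len(b))
        if den == 0:
            return 0.0 if a.mean() == b.mean() else math.inf
        return (a.mean() - b.mean()) / den

    obs = abs(t_stat(np.asarray(x, float), np.asarray(y, float)))
    hits = total = 0
    for combo in combinations(range(len(pooled)), n1):
        sel = np.zeros(len(pooled), bool)
        sel[list(combo)] = True
        if abs(t_stat(pooled[sel], pooled[~sel])) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestPermutationT:
    def test_exhaustive_separated_groups(self):
        """Fully separated n=3 groups: only the identity and its mirror
        reach the maximal |t| among the 20 assignments."""
        res = permutation_t_test([1, 2, 3], [10, 11, 12], exhaustive=True)
        assert res.n_permutations == 20
        assert res.p_value == pytest.approx(2 / 20)

    def test_degenerate_constant_data(self):
        with pytest.warns(UserWarning, match="constant"):
            res = permutation_t_test([5, 5, 5, 5], [5, 5, 5, 5])
        assert res.p_value == 1.0

    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 5)
        y = rng.normal(0.8, 1.5, 4)
        res = permutation_t_test(x, y, exhaustive=True)
        assert res.p_value == pytest.approx(_brute_force_perm_p(x, y))

    def test_sampled_agrees_with_exhaustive(self):
        """Sampled mode converges on the exhaustive p within Monte-Carlo
        error at n_perm = 10,000."""
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 6)
        y = rng.normal(1.0, 1, 6)
        exact = permutation_t_test(x, y, exhaustive=True).p_value
        sampled = permutation_t_test(x, y, n_perm=10_000, seed=42).p_value
        mc_se = math.sqrt(exact * (1 - exact) / 10_000)
        assert abs(sampled - exact) < 3 * mc_se + 1e-4

    def test_p_never_zero_and_seeded(self):
        x = [0, 0, 0.01, 0]
        y = [10, 10, 10.01, 10]
        r1 = permutation_t_test(x, y, n_perm=500, seed=9)
        r2 = permutation_t_test(x, y, n_perm=500, seed=9)
        assert r1.p_value >= 1 / 501
        assert r1.p_value == r2.p_value

    def test_type_i_error_calibration(self):
        """Null data at alpha = 0.05: rejection rate ~ 0.05 across
        replicates."""
        rng = np.random.default_rng(2024)
        n_rep = 400
        rejections = 0
        for _ in range(n_rep):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0, 1, 8)
            seed = int(rng.integers(2**31 - 1))
            if permutation_t_test(x, y, n_perm=1000, seed=seed).p_value < 0.05:
                rejections += 1
        assert abs(rejections / n_rep - 0.05) < 0.025


def _brute_force_ss(d, groups):
    d2 = d**2
    n = d.shape[0]
    sst = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ssw = 0.0
    for g in set(groups):
        mem = [i for i, gi in enumerate(groups) if gi == g]
        ssw += sum(d2[i, j] for i in mem for j in mem if i < j) / len(mem)
    return sst, ssw


class TestPermanova:
    def test_perfect_separation_r2(self):
        d = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], float
        )
        res = permanova(DistanceMatrix(d, list("abcd")), ["x", "x", "y", "y"], n_perm=99, seed=0)
        assert res.r_squared == pytest.approx(1.0)
        assert math.isinf(res.pseudo_F)

    def test_ss_decomposition_conserved(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(9, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = permanova(DistanceMatrix(d), groups, n_perm=49, seed=1)
        assert res.ss_between + res.ss_within == pytest.approx(res.ss_total, abs=1e-9)
        sst, ssw = _brute_force_ss(d, groups)
        assert res.ss_total == pytest.approx(sst)
        assert res.ss_within == pytest.approx(ssw)

    def test_matches_skbio_pseudo_f(self):
        """Independent cross-check of the pseudo-F against scikit-bio."""
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 3))
        pts[6:] += 1.0
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(12)])
        groups = ["a"] * 6 + ["b"] * 6
        ours = permanova(dm, groups, n_perm=99, seed=0)
        ref = skbio_permanova(dm, grouping=list(groups), permutations=99)
        assert ours.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        groups = np.array(["a"] * 4 + ["b"] * 4)
        res1 = permanova(DistanceMatrix(d), groups, n_perm=9, seed=0)
        perm = rng.permutation(8)
        res2 = permanova(DistanceMatrix(d[np.ix_(perm, perm)]), groups[perm], n_perm=9, seed=0)
        assert res1.pseudo_F == pytest.approx(res2.pseudo_F)

    def test_single_group_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            permanova(DistanceMatrix(d), ["a", "a", "a"])


class TestBrayCurtis:
    def test_hand_example(self):
        dm = bray_curtis([[1, 1, 0], [0, 1, 1]])
        assert dm.data[0, 1] == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        dm = bray_curtis([[2, 3], [2, 3]])
        assert dm.data[0, 1] == pytest.approx(0.0)
        dm = bray_curtis([[1, 0], [0, 5]])
        assert dm.data[0, 1] == pytest.approx(1.0)

    def test_zero_row_names_sample(self):
        with pytest.raises(ValueError, match="s1"):
            bray_curtis([[1, 1], [0, 0]], ids=["s0", "s1"])

    @given(
        arrays(
            float,
            st.tuples(st.integers(2, 6), st.integers(1, 5)),
            elements=st.floats(0, 100, allow_nan=False),
        ).filter(lambda a: (a.sum(axis=1) > 0).all())
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_range(self, mat):
        dm = bray_curtis(mat).data
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0)
        assert (dm >= -1e-12).all() and (dm <= 1 + 1e-12).all()


class TestClassicalWrappers:
    def test_welch_identical_groups(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_welch_textbook_pair(self):
        """Check against numeric integration of the t density."""
        from scipy.integrate import quad
        from scipy.stats import t as tdist

        x = [27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1, 21.9, 22.6, 23.1, 19.6]
        y = [27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8, 22.0, 24.8, 20.2, 21.9, 22.1]
        t_stat, df, p = welch_t(x, y)
        tail, _ = quad(lambda u: tdist.pdf(u, df), abs(t_stat), 60)
        assert p == pytest.approx(2 * tail, rel=1e-6)

    def test_welch_detects_duration_gap(self):
        """Simulated care-duration contrast (85±53 vs 53±36 s) at large n."""
        rng = np.random.default_rng(0)
        x = rng.normal(85, 53, 400)
        y = rng.normal(53, 36, 400)
        _, _, p = welch_t(x, y)
        assert p < 0.05

    def test_mann_whitney_maximal_separation(self):
        """n1=6 all above n2=9 gives U = 54 (the assay's published W)."""
        u, p = mann_whitney_u([10, 11, 12, 13, 14, 15], [1, 2, 3, 4, 5, 6, 7, 8, 9])
        assert u == 54.0
        assert p < 0.001

    def test_mann_whitney_identical(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_mann_whitney_small_vs_enumeration(self):
        """Exact U from rank sums on a small tied-free instance."""
        x = np.array([1.2, 3.4, 5.1])
        y = np.array([2.2, 4.0])
        u, _ = mann_whitney_u(x, y)
        brute = sum((xi > yi) for xi in x for yi in y)
        assert u == brute

    def test_anova_tukey_no_signal(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, 30)
        groups = np.repeat(["a", "b", "c"], 10)
        res = anova_tukey(vals, groups)
        assert (res["p_adj"] > 0.05).all()

    def test_anova_tukey_shifted_group(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate(
            [rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(4, 1, 10)]
        )
        groups = np.repeat(["a", "b", "c"], 10)
        res = anova_tukey(vals, groups)
        c_pairs = res[(res["group1"] == "c") | (res["group2"] == "c")]
        others = res[(res["group1"] != "c") & (res["group2"] != "c")]
        assert (c_pairs["p_adj"] < 0.05).all()
        assert (others["p_adj"] > 0.05).all()

    def test_tukey_matches_studentized_range(self):
        """Balanced 3-group toy against the studentized-range closed form."""
        from scipy.stats import studentized_range

        rng = np.random.default_rng(4)
        groups = np.repeat(["a", "b", "c"], 8)
        vals = rng.normal(0, 1, 24) + np.repeat([0.0, 0.5, 1.0], 8)
        res = anova_tukey(vals, groups)
        # recompute one pair by hand
        g = {k: vals[groups == k] for k in "abc"}
        mse = np.mean([g[k].var(ddof=1) for k in "abc"])
        df_w = 24 - 3
        q = abs(g["a"].mean() - g["c"].mean()) / math.sqrt(mse / 8)
        p_hand = studentized_range.sf(q, 3, df_w)
        row = res[(res["group1"] == "a") & (res["group2"] == "c")]
        assert row["p_adj"].iloc[0] == pytest.approx(p_hand, abs=1e-6)
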