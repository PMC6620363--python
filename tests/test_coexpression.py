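import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from cartx.coexpression import (
    MODULE_COLORS,
    adjacency,
    correlation_matrix,
    detect_modules,
    module_eigengene,
    module_feature_correlation,
    pathway_activity,
    pearson_with_p,
    pick_soft_power,
    top_corr_pairs,
    topological_overlap,
)
from cartx.matrix import CartxError


def tom_triple_loop(A):
    """Independent O(n^3) oracle for the topological overlap formula."""
    n = A.shape[0]
    k = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n))
            T[i, j] = (l + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


class TestPearsonWithP:
    def test_identity_gives_r_one_p_zero(self):
        x = np.arange(5.0)
        res = pearson_with_p(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0

    def test_orthogonal_gives_p_one(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        res = pearson_with_p(x, y)
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_p_matches_quadrature_oracle(self):
        """Two-sided p at fixed r equals numerically integrating the t density."""
        n = 10
        r = 0.9
        # build vectors with exactly this correlation
        x = np.arange(n, dtype=float)
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        noise = np.random.default_rng(0).normal(size=n)
        noise -= noise.mean()
        noise -= xc * (xc @ noise)
        noise /= np.linalg.norm(noise)
        y = r * xc + np.sqrt(1 - r**2) * noise
        res = pearson_with_p(x, y)
        assert res.r == pytest.approx(r, abs=1e-12)
        t_obs = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        tail, _ = integrate.quad(lambda u: stats.t.pdf(u, n - 2), t_obs, np.inf)
        assert res.p == pytest.approx(2 * tail, rel=1e-9)

    def test_preconditions(self):
        with pytest.raises(CartxError, match="constant"):
            pearson_with_p(np.ones(5), np.arange(5.0))
        with pytest.raises(CartxError, match="at least 3"):
            pearson_with_p(np.arange(2.0), np.arange(2.0))


class TestAdjacency:
    @pytest.mark.parametrize(
        "r, beta, expected", [(-0.5, 1, 0.5), (0.5, 2, 0.25), (1.0, 7, 1.0), (-1.0, 4, 1.0)]
    )
    def test_power_of_absolute_correlation(self, toy_matrix, r, beta, expected):
        # two features with exact correlation r across 4 samples
        x = np.array([1.0, 2.0, 3.0, 4.0])
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        e = np.array([1.0, -1.0, -1.0, 1.0])
        e = e - e.mean()
        e -= xc * (xc @ e)
        e /= np.linalg.norm(e)
        y = r * xc + np.sqrt(1 - r**2) * e
        m = toy_matrix(np.vstack([x, y]), unit="log2")
        A = adjacency(m, beta)
        assert A.iloc[0, 1] == pytest.approx(expected, abs=1e-12)
        assert A.iloc[0, 0] == 0.0

    def test_requires_power_and_samples(self, toy_matrix):
        m = toy_matrix(np.random.default_rng(0).normal(size=(3, 4)), unit="log2")
        with pytest.raises(CartxError):
            adjacency(m, 0.5)
        short = toy_matrix(np.random.default_rng(0).normal(size=(3, 2)), unit="log2")
        with pytest.raises(CartxError):
            adjacency(short, 2)


class TestTopologicalOverlap:
    def test_hand_worked_triangle(self):
        A = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        T = topological_overlap(A).values
        assert T[0, 1] == pytest.approx(1.0)
        assert T[1, 2] == pytest.approx(0.5)
        np.testing.assert_allclose(T, tom_triple_loop(A), atol=1e-12)

    def test_zero_adjacency(self):
        T = topological_overlap(np.zeros((4, 4))).values
        assert np.all(T[~np.eye(4, dtype=bool)] == 0.0)
        assert np.all(np.diag(T) == 1.0)

    def test_matches_triple_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = int(rng.integers(2, 11))
            A = rng.uniform(0, 1, size=(n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0.0)
            T = topological_overlap(A).values
            np.testing.assert_allclose(T, tom_triple_loop(A), atol=1e-12)
            assert T.min() >= 0.0 and T.max() <= 1.0 + 1e-12

    def test_rejects_asymmetry(self):
        A = np.array([[0, 0.5], [0.4, 0]])
        with pytest.raises(CartxError, match="symmetric"):
            topological_overlap(A)


class TestDetectModules:
    def _block_tom(self, sizes, within=0.95, between=0.01):
        n = sum(sizes)
        T = np.full((n, n), between)
        start = 0
        for s in sizes:
            T[start : start + s, start : start + s] = within
            start += s
        np.fill_diagonal(T, 1.0)
        ids = [f"g{i:03d}" for i in range(n)]
        return pd.DataFrame(T, index=ids, columns=ids)

    def test_two_clean_blocks(self):
        tom = self._block_tom([30, 30])
        mods = detect_modules(tom, min_module_size=30)
        assert set(mods) == {"turquoise", "blue"}
        assert (mods.iloc[:30] == mods.iloc[0]).all()
        assert (mods.iloc[30:] == mods.iloc[30]).all()

    def test_min_size_larger_than_n_gives_all_grey(self):
        tom = self._block_tom([10, 10])
        mods = detect_modules(tom, min_module_size=25)
        assert (mods == "grey").all()

    def test_single_feature_is_grey(self):
        tom = pd.DataFrame([[1.0]], index=["g"], columns=["g"])
        assert detect_modules(tom).tolist() == ["grey"]

    def test_colors_assigned_by_size_rank(self):
        tom = self._block_tom([40, 60, 50])
        mods = detect_modules(tom, min_module_size=30)
        sizes = mods.value_counts()
        assert sizes["turquoise"] == 60
        assert sizes["blue"] == 50
        assert sizes["brown"] == 40

    def test_feature_order_invariance_as_partition(self):
        rng = np.random.default_rng(4)
        tom = self._block_tom([35, 30], within=0.9, between=0.05)
        perm = rng.permutation(tom.index)
        mods1 = detect_modules(tom)
        mods2 = detect_modules(tom.loc[perm, perm])
        # compare partitions, not labels
        def partition(assign):
            groups = {}
            for f, m in assign.items():
                groups.setdefault(m, set()).add(f)
            return {frozenset(v) for v in groups.values()}

        assert partition(mods1) == partition(mods2)


class TestModuleEigengene:
    def test_identical_profiles_recover_common_z_profile(self, toy_matrix):
        profile = np.array([1.0, 3.0, 2.0, 5.0])
        m = toy_matrix(np.vstack([profile, profile, profile]), unit="log2")
        assign = pd.Series(["blue"] * 3, index=m.feature_ids)
        eg = module_eigengene(m, assign)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(eg.loc["blue"].values, z, atol=1e-10)

    def test_invariant_to_feature_duplication(self, toy_matrix):
        rng = np.random.default_rng(2)
        profile = rng.normal(size=6)
        X = profile + rng.normal(0, 0.1, size=(4, 6))  # a coherent module
        m1 = toy_matrix(X, unit="log2")
        a1 = pd.Series(["m"] * 4, index=m1.feature_ids)
        m2 = toy_matrix(np.vstack([X, X[0]]), unit="log2")
        a2 = pd.Series(["m"] * 5, index=m2.feature_ids)
        e1 = module_eigengene(m1, a1).loc["m"].values
        e2 = module_eigengene(m2, a2).loc["m"].values
        assert abs(np.corrcoef(e1, e2)[0, 1]) > 0.99

    def test_matches_dense_eigensolver_oracle(self, toy_matrix):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(4, 7))
        m = toy_matrix(X, unit="log2")
        assign = pd.Series(["m"] * 4, index=m.feature_ids)
        eg = module_eigengene(m, assign).loc["m"].values
        Z = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        # eigengene spans the leading eigenvector of the sample-sample Gram matrix
        w, V = np.linalg.eigh(Z.T @ Z)
        lead = V[:, np.argmax(w)]
        corr = np.corrcoef(eg, lead)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)
        assert eg.mean() == pytest.approx(0.0, abs=1e-12)
        assert eg.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_module_is_an_error(self, toy_matrix):
        m = toy_matrix(np.ones((2, 5)), unit="log2")
        assign = pd.Series(["m", "m"], index=m.feature_ids)
        with pytest.raises(CartxError, match="m"):
            module_eigengene(m, assign)


class TestModuleFeatureCorrelation:
    def test_self_built_pathway_score_is_significant(self, toy_matrix):
        rng = np.random.default_rng(3)
        profile = rng.normal(size=8)
        X = np.vstack([profile + rng.normal(0, 1e-6, 8) for _ in range(5)])
        m = toy_matrix(X, unit="log2")
        assign = pd.Series(["m"] * 5, index=m.feature_ids)
        eg = module_eigengene(m, assign)
        act = pathway_activity(m, {"own": m.feature_ids})
        out = module_feature_correlation(eg, act)
        assert out.iloc[0]["significant"]

    def test_impossible_r_min_flags_nothing(self, toy_matrix):
        rng = np.random.default_rng(6)
        m = toy_matrix(rng.normal(size=(4, 8)), unit="log2")
        assign = pd.Series(["m"] * 4, index=m.feature_ids)
        eg = module_eigengene(m, assign)
        act = pathway_activity(m, {"s": m.feature_ids[:2]})
        out = module_feature_correlation(eg, act, r_min=1.01)
        assert not out["significant"].any()

    def test_sample_mismatch_rejected(self, toy_matrix):
        m = toy_matrix(np.random.default_rng(0).normal(size=(4, 6)), unit="log2")
        assign = pd.Series(["m"] * 4, index=m.feature_ids)
        eg = module_eigengene(m, assign)
        act = pathway_activity(m, {"s": m.feature_ids}).iloc[:, ::-1]
        with pytest.raises(CartxError, match="sample"):
            module_feature_correlation(eg, act)


class TestTopCorrPairs:
    def test_planted_perfect_pairs_found(self, toy_matrix):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(3, 10))
        noise = rng.normal(size=(3, 10))
        X = np.vstack([base, base * 2 + 1e-9 * noise])  # 3 perfect cross pairs
        m = toy_matrix(X, feature_ids=["a1", "a2", "a3", "b1", "b2", "b3"], unit="log2")
        out = top_corr_pairs(["a1", "a2", "a3"], ["b1", "b2", "b3"], m, n_top=10)
        found = set(zip(out["feature_a"], out["feature_b"]))
        assert {("a1", "b1"), ("a2", "b2"), ("a3", "b3")} <= found

    def test_n_top_one_takes_best_by_tie_rule(self, toy_matrix):
        x = np.arange(8.0)
        X = np.vstack([x, x * 3 + 1, x * 2 + 5])
        m = toy_matrix(X, feature_ids=["a1", "b1", "b2"], unit="log2")
        out = top_corr_pairs(["a1"], ["b1", "b2"], m, n_top=1, r_min=0.5)
        assert len(out) == 1
        # |r| ties at 1; smaller p ties; lexicographic pair id decides
        assert out.iloc[0]["feature_b"] == "b1"
        assert out.attrs["truncated"]

    def test_disjointness_required_and_empty_sets(self, toy_matrix):
        m = toy_matrix(np.random.default_rng(0).normal(size=(2, 5)), unit="log2")
        with pytest.raises(CartxError, match="disjoint"):
            top_corr_pairs(["g1"], ["g1", "g2"], m)
        assert len(top_corr_pairs([], ["g1"], m)) == 0

    def test_false_pair_rate_matches_threshold_on_null(self, toy_matrix):
        """Independent features should essentially never pass r>0.9, p<1e-6 at n=8."""
        rng = np.random.default_rng(7)
        hits = 0
        n_pairs = 0
        for _ in range(60):
            m = toy_matrix(rng.normal(size=(8, 8)), unit="log2")
            ids = m.feature_ids
            out = top_corr_pairs(ids[:4], ids[4:], m, n_top=100)
            hits += len(out)
            n_pairs += 16
        assert hits / n_pairs < 1e-3


class TestPickSoftPower:
    def test_single_candidate_returned_with_flag(self, toy_matrix):
        rng = np.random.default_rng(1)
        m = toy_matrix(rng.normal(size=(12, 6)), unit="log2")
        diag = pick_soft_power(m, candidate_powers=(6,))
        assert diag.power == 6

    def test_chosen_power_matches_independent_re_evaluation(self, toy_matrix):
        """Re-evaluate the scale-free criterion independently per power."""
        rng = np.random.default_rng(10)
        # hub-and-leaves structure: one driver, many partially coupled leaves
        driver = rng.normal(size=12)
        rows = [driver]
        for i in range(30):
            lam = rng.uniform(0.2, 0.95)
            rows.append(lam * driver + np.sqrt(1 - lam**2) * rng.normal(size=12))
        m = toy_matrix(np.array(rows), unit="log2")
        candidates = (1, 2, 3, 4, 6, 8)
        diag = pick_soft_power(m, candidate_powers=candidates, target_r2=0.8)

        from cartx.coexpression import _scale_free_fit

        R = np.abs(correlation_matrix(m).values)
        np.fill_diagonal(R, 0.0)
        fits = {b: _scale_free_fit((R**b).sum(1), 10) for b in candidates}
        passing = [b for b in candidates if fits[b] is not None and fits[b] >= 0.8]
        if passing:
            assert diag.power == passing[0]
            assert diag.fit_reached_target
        else:
            best = max((b for b in candidates if fits[b] is not None), key=lambda b: fits[b])
            assert diag.power == best
            assert not diag.fit_reached_target

    def test_degenerate_identical_correlations_fall_back(self, toy_matrix):
        # two features duplicated: all pairwise |r| = 1, zero variance in k
        x = np.arange(6.0)
        m = toy_matrix(np.vstack([x, x * 2, x + 1]), unit="log2")
        diag = pick_soft_power(m, candidate_powers=(2, 4))
        assert diag.power in (2, 4)
        assert not diag.fit_reached_target


def test_module_color_sequence_starts_with_convention():
    assert MODULE_COLORS[:4] == ("turquoise", "blue", "brown", "yellow")
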