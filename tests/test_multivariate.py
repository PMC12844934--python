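import itertools

import numpy as np
import pytest

from soil2leaf.multivariate import (
    hca_ward,
    lda_stepwise,
    pca_fit,
    varimax_rotate,
)

# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class TestPca:
    def test_rank_one_data(self):
        x = np.arange(10.0)
        res = pca_fit(np.column_stack([x, 3 * x]), standardize=False, n_components=1)
        assert res.explained_pct[0] == pytest.approx(100.0)

    def test_identity_covariance_uniform_spectrum(self, rng):
        data = rng.normal(size=(4000, 4))
        res = pca_fit(data, standardize=False)
        # analytic spectrum of the identity: every share = 25%
        np.testing.assert_allclose(res.explained_pct, 25.0, atol=2.5)

    def test_eigenvalues_match_characteristic_polynomial(self, rng):
        data = rng.normal(size=(12, 3)) @ np.diag([3.0, 1.0, 0.5])
        res = pca_fit(data, standardize=False)
        c = np.cov(data, rowvar=False, ddof=1)
        # char poly coefficients of a 3x3 by trace / principal minors / det
        tr = np.trace(c)
        minors = (
            c[0, 0] * c[1, 1] - c[0, 1] * c[1, 0]
            + c[0, 0] * c[2, 2] - c[0, 2] * c[2, 0]
            + c[1, 1] * c[2, 2] - c[1, 2] * c[2, 1]
        )
        det = np.linalg.det(c)
        roots = np.roots([1.0, -tr, minors, -det])
        np.testing.assert_allclose(res.eigenvalues, np.sort(roots)[::-1], rtol=1e-8)

    def test_trace_invariant_and_descending(self, rng):
        data = rng.normal(size=(30, 5))
        res = pca_fit(data, standardize=True)
        cov = np.cov((data - data.mean(0)) / data.std(0, ddof=1), rowvar=False, ddof=1)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(cov), rel=1e-9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_full_retention_reconstructs_centered_data(self, rng):
        data = rng.normal(size=(15, 4))
        res = pca_fit(data, standardize=False, n_components=4)
        centered = data - data.mean(axis=0)
        np.testing.assert_allclose(res.scores @ res.components.T, centered, atol=1e-10)

    def test_unrotated_scores_uncorrelated(self, rng):
        data = rng.normal(size=(50, 4))
        res = pca_fit(data, n_components=3)
        c = np.cov(res.scores, rowvar=False, ddof=1)
        np.testing.assert_allclose(c - np.diag(np.diag(c)), 0.0, atol=1e-10)

    def test_matches_sklearn_oracle(self, rng):
        sklearn = pytest.importorskip("sklearn.decomposition")
        data = rng.normal(size=(25, 4))
        res = pca_fit(data, standardize=False)
        ref = sklearn.PCA().fit(data)
        np.testing.assert_allclose(res.eigenvalues, ref.explained_variance_, rtol=1e-9)

    def test_n_components_beyond_rank_rejected(self):
        x = np.arange(6.0)
        with pytest.raises(ValueError, match="rank"):
            pca_fit(np.column_stack([x, 2 * x]), standardize=False, n_components=2)


# ---------------------------------------------------------------------------
# varimax
# ---------------------------------------------------------------------------


def _varimax_criterion(lam: np.ndarray) -> float:
    p = lam.shape[0]
    sq = lam**2
    return float(((sq**2).sum(axis=0) / p - (sq.sum(axis=0) / p) ** 2).sum())


class TestVarimax:
    def test_simple_structure_fixed_point(self):
        lam = np.array([[0.9, 0.0], [0.85, 0.0], [0.0, 0.8], [0.0, 0.95]])
        rot = varimax_rotate(lam)
        # already simple: result equals input up to column sign/permutation
        best = None
        for perm in itertools.permutations(range(2)):
            for signs in itertools.product([1, -1], repeat=2):
                cand = rot[:, perm] * np.array(signs)
                err = np.abs(cand - lam).max()
                best = err if best is None else min(best, err)
        assert best < 1e-6

    def test_communalities_conserved(self, rng):
        lam = rng.normal(size=(8, 3))
        rot = varimax_rotate(lam)
        np.testing.assert_allclose(
            (rot**2).sum(axis=1), (lam**2).sum(axis=1), rtol=1e-9
        )

    def test_rotation_is_orthogonal(self, rng):
        lam = rng.normal(size=(10, 3))
        rot = varimax_rotate(lam)
        r = np.linalg.pinv(lam) @ rot
        np.testing.assert_allclose(r.T @ r, np.eye(3), atol=1e-9)

    def test_criterion_beats_one_degree_grid(self, rng):
        # textbook 2-factor case: grid search over the rotation angle is the oracle
        lam = rng.normal(size=(6, 2)) + np.array([[1.0, 0.2]] * 3 + [[0.2, 1.0]] * 3)
        rot = varimax_rotate(lam)
        ours = _varimax_criterion(rot)
        assert ours >= _varimax_criterion(lam) - 1e-12
        for deg in range(90):
            th = np.deg2rad(deg)
            r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            assert ours >= _varimax_criterion(lam @ r) - 1e-9

    def test_single_column_noop(self):
        lam = np.array([[1.0], [2.0]])
        np.testing.assert_array_equal(varimax_rotate(lam), lam)


# ---------------------------------------------------------------------------
# Ward HCA
# ---------------------------------------------------------------------------


def _brute_force_ward(x: np.ndarray):
    """O(n^3) oracle: recompute every Ward merge cost from cluster members."""
    clusters = {i: [i] for i in range(len(x))}
    merges = []
    next_id = len(x)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            ma, mb = x[clusters[a]], x[clusters[b]]
            na, nb = len(ma), len(mb)
            d2 = (
                2.0 * na * nb / (na + nb)
                * ((ma.mean(axis=0) - mb.mean(axis=0)) ** 2).sum()
            )
            if best is None or d2 < best[0] - 1e-15:
                best = (d2, a, b)
        d2, a, b = best
        merges.append((a, b, np.sqrt(d2), len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestHcaWard:
    def test_identical_points_merge_at_zero(self):
        res = hca_ward(np.array([[1.0, 2.0], [1.0, 2.0]]), standardize=False)
        assert len(res.merge_history) == 1
        assert res.merge_history[0][2] == 0.0

    def test_merge_count(self, rng):
        res = hca_ward(rng.normal(size=(9, 3)), standardize=False)
        assert len(res.merge_history) == 8

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle_on_5_point_toys(self, seed):
        x = np.random.default_rng(seed).normal(size=(5, 2))
        res = hca_ward(x, standardize=False)
        oracle = _brute_force_ward(x)
        for got, want in zip(res.merge_history, oracle):
            assert got[0] == want[0] and got[1] == want[1]
            assert got[2] == pytest.approx(want[2], rel=1e-9)
            assert got[3] == want[3]

    def test_matches_scipy_heights(self, rng):
        scipy_h = pytest.importorskip("scipy.cluster.hierarchy")
        x = rng.normal(size=(12, 3))
        res = hca_ward(x, standardize=False)
        link = scipy_h.linkage(x, method="ward")
        np.testing.assert_allclose(
            sorted(m[2] for m in res.merge_history), np.sort(link[:, 2]), rtol=1e-9
        )

    def test_heights_monotone(self, rng):
        res = hca_ward(rng.normal(size=(15, 4)), standardize=False)
        heights = [m[2] for m in res.merge_history]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_reorder_invariance(self, rng):
        x = rng.normal(size=(10, 3))
        perm = rng.permutation(10)
        h1 = sorted(m[2] for m in hca_ward(x, standardize=False).merge_history)
        h2 = sorted(m[2] for m in hca_ward(x[perm], standardize=False).merge_history)
        np.testing.assert_allclose(h1, h2, rtol=1e-9)

    def test_labels_at_k(self):
        x = np.array([[0.0, 0], [0.1, 0], [5.0, 5], [5.1, 5]])
        res = hca_ward(x, standardize=False)
        lab = res.labels_at(2)
        assert lab[0] == lab[1] and lab[2] == lab[3] and lab[0] != lab[2]
        assert len(set(res.labels_at(4))) == 4

    def test_duplicate_ids_rejected(self, rng):
        with pytest.raises(ValueError, match="duplicate"):
            hca_ward(rng.normal(size=(3, 2)), labels=["a", "a", "b"])


# ---------------------------------------------------------------------------
# stepwise LDA
# ---------------------------------------------------------------------------


class TestLdaStepwise:
    def _two_group_data(self, rng, n=30, sep=4.0):
        g = np.repeat([0, 1], n // 2)
        x = rng.normal(size=(n, 4))
        x[:, 2] += sep * g  # only variable 2 separates
        return x, g

    def test_informative_variable_selected_first(self, rng):
        x, g = self._two_group_data(rng)
        res = lda_stepwise(x, g)
        assert res.selected_vars[0] == 2

    def test_wilks_path_strictly_decreasing(self, rng):
        x = rng.normal(size=(40, 4))
        g = np.repeat([0, 1, 2], [14, 13, 13])
        x[:, 0] += 3.0 * g
        x[:, 1] -= 2.0 * g
        res = lda_stepwise(x, g)
        lam = res.wilks_lambda_path
        assert len(lam) >= 1
        assert all(b < a for a, b in zip(lam, lam[1:]))
        assert all(0 < v <= 1 for v in lam)

    def test_two_group_axis_equals_fisher_direction(self, rng):
        x, g = self._two_group_data(rng)
        res = lda_stepwise(x, g, alpha_enter=0.99, standardize=False)
        sel = res.selected_vars
        xs = x[:, sel]
        m0, m1 = xs[g == 0].mean(axis=0), xs[g == 1].mean(axis=0)
        w = np.zeros((len(sel), len(sel)))
        for lvl in (0, 1):
            c = xs[g == lvl] - xs[g == lvl].mean(axis=0)
            w += c.T @ c
        fisher = np.linalg.solve(w, m1 - m0)  # closed-form two-class direction
        axis = res.discriminant_axes[:, 0]
        cos = abs(fisher @ axis) / (np.linalg.norm(fisher) * np.linalg.norm(axis))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_null_groups_mostly_empty_selection(self):
        # simulation oracle: under H0 each candidate enters with prob ~ alpha
        empty = 0
        n_reps = 100
        for seed in range(n_reps):
            r = np.random.default_rng(seed)
            x = r.normal(size=(24, 3))
            g = np.repeat([0, 1], 12)
            res = lda_stepwise(x, g, alpha_enter=0.05)
            empty += not res.selected_vars
        # P(no entry) >= (1-alpha)^3 ~ 0.857 minus stepwise selection bias
        assert empty / n_reps > 0.7

    def test_scores_have_identity_within_covariance(self, rng):
        x = rng.normal(size=(60, 4))
        g = np.repeat([0, 1, 2], 20)
        x[:, 0] += 4.0 * g
        x[:, 1] += 2.0 * (g == 1)
        res = lda_stepwise(x, g, alpha_enter=0.5)
        n, k = len(g), 3
        w = np.zeros((res.scores.shape[1], res.scores.shape[1]))
        for lvl in range(k):
            c = res.scores[g == lvl] - res.scores[g == lvl].mean(axis=0)
            w += c.T @ c
        np.testing.assert_allclose(np.diag(w / (n - k)), 1.0, rtol=1e-8)

    def test_function_count_bounded(self, rng):
        x = rng.normal(size=(40, 5))
        g = np.repeat([0, 1], 20)
        x[:, 0] += 5 * g
        x[:, 1] += 5 * g
        res = lda_stepwise(x, g, alpha_enter=0.9)
        assert res.scores.shape[1] <= min(1, len(res.selected_vars))

    def test_too_few_groups_rejected(self, rng):
        with pytest.raises(ValueError):
            lda_stepwise(rng.normal(size=(10, 2)), np.zeros(10))
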