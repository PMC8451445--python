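"""Diversity, dissimilarity, permutation tests, ordination, spatial
eigenvectors, and GLM likelihood-ratio machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from browsevuln import stats as cs
from browsevuln.datamodel import CoverageTable


def cov_table(rows):
    return CoverageTable(
        pd.DataFrame(rows, columns=["site_id", "plot_id", "species_id", "coverage"])
    )


def euclid_dm(X):
    return cs.DistanceMatrix(squareform(pdist(X)), [str(i) for i in range(len(X))])


class TestDiversity:
    def test_single_species_entropy_zero(self):
        t = cov_table([("S1", 1, "A", 10)])
        assert cs.richness(t, "S1") == 1
        assert cs.shannon(t, "S1") == 0.0

    def test_two_equal_species(self):
        t = cov_table([("S1", 1, "A", 10), ("S1", 2, "B", 10)])
        assert cs.shannon(t, "S1") == pytest.approx(np.log(2), abs=1e-12)

    def test_hand_computed_shares(self):
        # shares (0.5, 0.25, 0.25) -> H' = 1.0397
        t = cov_table([("S1", 1, "A", 10), ("S1", 1, "B", 5), ("S1", 1, "C", 5)])
        assert cs.shannon(t, "S1") == pytest.approx(1.0397, abs=1e-4)

    def test_empty_site(self):
        t = cov_table([("S1", 1, "A", 10)])
        assert cs.richness(t, "S2") == 0
        with pytest.raises(ValueError):
            cs.shannon(t, "S2")

    def test_invariant_to_plot_order(self, rng):
        rows = [("S1", int(p), f"sp{rng.integers(5)}", 5) for p in range(1, 11)]
        rows = list({(r[0], r[1], r[2]): r for r in rows}.values())
        a = cov_table(rows)
        b = cov_table(rows[::-1])
        assert cs.shannon(a, "S1") == cs.shannon(b, "S1")


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        m = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        assert cs.bray_curtis(m).values[0, 1] == 0.0

    def test_disjoint_support_one(self):
        m = pd.DataFrame([[1, 0], [0, 4]], index=["a", "b"])
        assert cs.bray_curtis(m).values[0, 1] == 1.0

    def test_hand_computed(self):
        m = pd.DataFrame([[1, 2], [2, 0]], index=["a", "b"])
        assert cs.bray_curtis(m).values[0, 1] == pytest.approx(0.6, abs=1e-12)

    def test_column_order_irrelevant(self, rng):
        m = pd.DataFrame(rng.random((6, 8)))
        shuffled = m.iloc[:, rng.permutation(8)]
        assert np.allclose(cs.bray_curtis(m).values, cs.bray_curtis(shuffled).values)

    def test_two_zero_rows_rejected(self):
        m = pd.DataFrame([[0, 0], [0, 0], [1, 1]], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            cs.bray_curtis(m)


def oracle_permanova(D, labels):
    """Independent pseudo-F via Gower centring and the hat matrix."""
    n = len(labels)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    X = pd.get_dummies(pd.Series(labels)).to_numpy(dtype=float)
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    a = len(set(labels))
    ss_b = np.trace(H @ G @ H)
    ss_w = np.trace((np.eye(n) - H) @ G @ (np.eye(n) - H))
    return (ss_b / (a - 1)) / (ss_w / (n - a))


class TestPermanova:
    def test_perfect_separation_r2_one(self):
        X = np.array([[0.0, 0], [0, 0], [5, 5], [5, 5]])
        res = cs.permanova(euclid_dm(X), ["a", "a", "b", "b"], n_perm=99, seed=1)
        assert res.R2 == pytest.approx(1.0)

    def test_f_matches_hat_matrix_oracle(self, rng):
        X = rng.random((9, 4))
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        D = euclid_dm(X)
        res = cs.permanova(D, labels, n_perm=9, seed=0)
        assert res.pseudo_F == pytest.approx(oracle_permanova(D.values, labels), rel=1e-10)

    def test_f_matches_scikit_bio(self, rng):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        X = rng.random((12, 5))
        labels = ["a", "b", "c"] * 4
        D = euclid_dm(X)
        ours = cs.permanova(D, labels, n_perm=9, seed=0)
        theirs = skbio_dist.permanova(
            skbio_dist.DistanceMatrix(D.values, D.labels), labels, permutations=9
        )
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-8)

    def test_exhaustive_matches_enumeration_oracle(self, rng):
        X = rng.random((6, 3))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        D = euclid_dm(X)
        res = cs.permanova(D, labels, exhaustive=True)
        fs = [
            oracle_permanova(D.values, labels[list(p)])
            for p in itertools.permutations(range(6))
        ]
        p_oracle = np.mean([f >= res.pseudo_F - 1e-12 for f in fs])
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_single_group_rejected(self):
        D = euclid_dm(np.random.default_rng(0).random((4, 2)))
        with pytest.raises(ValueError):
            cs.permanova(D, ["a"] * 4, n_perm=9)

    def test_deterministic_given_seed(self, rng):
        X = rng.random((12, 3))
        labels = ["a", "b"] * 6
        D = euclid_dm(X)
        r1 = cs.permanova(D, labels, n_perm=199, seed=42)
        r2 = cs.permanova(D, labels, n_perm=199, seed=42)
        assert r1 == r2


class TestStrata:
    def test_no_cross_stratum_exchange(self, rng):
        strata = np.repeat(np.arange(5), 4)
        perms = cs.permutation_indices(20, 500, rng, strata)
        for perm in perms:
            assert (strata[perm] == strata).all()

    def test_factor_constant_within_blocks_is_unresolvable(self, rng):
        # establishment class is constant within a site, so blocking by site
        # must leave the F statistic unchanged and p near 1
        X = rng.random((12, 4)) + np.repeat([0, 1, 2], 4)[:, None]
        labels = np.repeat(["a", "b", "c"], 4)
        strata = np.repeat([f"s{i}" for i in range(6)], 2)
        D = euclid_dm(X)
        res = cs.permanova(D, labels, strata=strata, n_perm=199, seed=3)
        assert res.p_value > 0.95


class TestPermdisp:
    def test_identical_geometry_no_signal(self):
        g1 = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        g2 = g1 + 50.0
        D = euclid_dm(np.vstack([g1, g2]))
        f, p = cs.permdisp(D, ["a"] * 4 + ["b"] * 4, n_perm=199, seed=0)
        assert f == pytest.approx(0.0, abs=1e-10)
        assert p > 0.9

    def test_planted_dispersion_difference_detected(self, rng):
        tight = rng.normal(0, 1, size=(20, 3))
        diffuse = rng.normal(0, 4, size=(20, 3)) + 10
        D = euclid_dm(np.vstack([tight, diffuse]))
        _, p = cs.permdisp(D, ["t"] * 20 + ["d"] * 20, n_perm=499, seed=1)
        assert p < 0.05

    def test_item_order_invariance_of_f(self, rng):
        X = rng.random((16, 3))
        labels = np.array(["a", "b"] * 8)
        order = rng.permutation(16)
        D1 = euclid_dm(X)
        D2 = euclid_dm(X[order])
        f1, _ = cs.permdisp(D1, labels, n_perm=99, seed=5)
        f2, _ = cs.permdisp(D2, labels[order], n_perm=99, seed=5)
        assert f1 == pytest.approx(f2, rel=1e-9)


class TestNmds:
    def test_exact_embedding_low_stress(self, rng):
        X = rng.random((15, 2)) * 10
        res = cs.nmds(euclid_dm(X), k=2, n_starts=8, seed=0)
        assert res.stress < 1e-3

    def test_equilateral_triangle_zero_stress(self):
        D = cs.DistanceMatrix(np.ones((3, 3)) - np.eye(3), ["a", "b", "c"])
        res = cs.nmds(D, k=2, n_starts=4, seed=0)
        assert res.stress < 1e-6

    def test_more_starts_never_worse(self, rng):
        X = rng.random((12, 6))
        D = cs.DistanceMatrix(squareform(pdist(X, "braycurtis")), [str(i) for i in range(12)])
        s5 = cs.nmds(D, n_starts=5, seed=9).stress
        s10 = cs.nmds(D, n_starts=10, seed=9).stress
        assert s10 <= s5 + 1e-12

    def test_stress_invariant_under_rigid_motion(self, rng):
        X = rng.random((10, 3))
        D = euclid_dm(X)
        conf = cs.nmds(D, n_starts=3, seed=2).coords
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        for moved in (conf @ R.T, conf + 5.0, conf * 3.0, -conf):
            assert cs.kruskal_stress1(D, moved) == pytest.approx(
                cs.kruskal_stress1(D, conf), abs=1e-9
            )


class TestDbmem:
    def test_line_of_four_points(self):
        coords = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
        vectors, eigvals = cs.dbmem(coords)
        assert vectors.shape[1] <= 3
        # oracle: direct eigendecomposition of the truncated matrix
        D = squareform(pdist(coords))
        Dt = np.where(D > 1.0, 4.0, D)
        np.fill_diagonal(Dt, 0)
        n = 4
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ (Dt**2) @ J
        w = np.sort(np.linalg.eigvalsh(G))[::-1]
        assert np.allclose(np.sort(eigvals)[::-1], w[: len(eigvals)], atol=1e-9)

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError):
            cs.dbmem(np.array([[0.0, 0], [0, 0], [1, 1]]))

    def test_null_response_rarely_significant(self, rng):
        coords = rng.random((15, 2)) * 100
        vectors, _ = cs.dbmem(coords)
        ps = []
        for rep in range(20):
            y = rng.normal(size=15)
            out = cs.dbmem_test(vectors, y, coords=coords, n_perm=199, seed=rep)
            ps.extend(out["p_value"])
        frac = np.mean(np.array(ps) < 0.05)
        assert frac < 0.15

    def test_spatial_gradient_detected(self, rng):
        coords = np.column_stack([np.arange(16.0), np.zeros(16)])
        vectors, _ = cs.dbmem(coords)
        y = np.sin(np.arange(16) / 2.5) + rng.normal(0, 0.1, 16)
        out = cs.dbmem_test(vectors, y, n_perm=499, seed=0)
        assert (out["p_value"] < 0.05).any()


class TestGlm:
    def test_identical_means_chi2_zero(self):
        y = [4, 4, 4, 4]
        full = cs.glm_fit(y, ["a", "a", "b", "b"], family="poisson")
        null = cs.glm_fit(y, family="poisson")
        chi2, df, p = cs.lrt(full, null)
        assert chi2 == pytest.approx(0.0, abs=1e-8)
        assert df == 1

    def test_poisson_deviance_hand_value(self):
        # groups {2,2} vs {8,8}: 2 * sum y*ln(mu_g / mu_0) = 7.710
        y = [2, 2, 8, 8]
        full = cs.glm_fit(y, ["a", "a", "b", "b"], family="poisson")
        null = cs.glm_fit(y, family="poisson")
        chi2, _, p = cs.lrt(full, null)
        hand = 2 * (4 * np.log(2 / 5) + 16 * np.log(8 / 5))
        assert chi2 == pytest.approx(hand, abs=1e-6)
        assert chi2 == pytest.approx(7.710, abs=1e-3)
        assert 0 < p < 0.01

    def test_saturated_group_design_matches_deviance(self, rng):
        y = rng.poisson(5, size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        full = cs.glm_fit(y, groups, family="poisson")
        null = cs.glm_fit(y, family="poisson")
        chi2, _, _ = cs.lrt(full, null)
        mu0 = y.mean()
        hand = 2 * sum(
            y[groups == g].sum() * np.log(y[groups == g].mean() / mu0)
            for g in "abc"
        )
        assert chi2 == pytest.approx(hand, abs=1e-8)

    def test_gaussian_family(self, rng):
        y = rng.normal(0, 1, 20)
        full = cs.glm_fit(y, ["a", "b"] * 10, family="gaussian")
        null = cs.glm_fit(y, family="gaussian")
        chi2, _, _ = cs.lrt(full, null)
        assert chi2 >= 0

    def test_unsupported_family_rejected(self):
        with pytest.raises(ValueError):
            cs.glm_fit([1, 2], ["a", "b"], family="gamma")


class TestGlmmLaplace:
    def test_zero_variance_shrinks_to_glm(self, rng):
        groups = np.repeat(["a", "b"], 60)
        sites = np.tile(np.repeat([f"s{i}" for i in range(6)], 10), 2)
        mu = np.where(groups == "a", 5.0, 9.0)
        y = rng.poisson(mu)
        fit = cs.glmm_poisson_laplace(y, groups, sites)
        glm = cs.glm_fit(y, groups, family="poisson")
        assert fit["sd_site"] ** 2 < 0.01
        assert np.allclose(fit["beta"], glm.params, atol=0.05)

    def test_planted_site_variance_recovered(self, rng):
        estimates = []
        for rep in range(6):
            sites = np.repeat([f"s{i}" for i in range(12)], 10)
            b = rng.normal(0, 0.5, 12)
            groups = np.tile(["a", "b"], 60)
            eta = 1.5 + np.where(groups == "a", 0, 0.3) + np.repeat(b, 10)
            y = rng.poisson(np.exp(eta))
            fit = cs.glmm_poisson_laplace(y, groups, sites)
            estimates.append(fit["sd_site"])
        mean_sd = np.mean(estimates)
        assert 0.25 < mean_sd < 0.75  # within 50 % of the planted 0.5
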