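"""Profile construction, K-means, and the gap statistic."""

import itertools

import numpy as np
import pandas as pd
import pytest

from browsevuln.clustering import (
    build_profiles,
    cluster_profiles,
    gap_statistic,
    kmeans,
    scale_profiles,
)
from browsevuln.damage import mdg_matrix
from browsevuln.datamodel import CoverageTable, DamageRecord, EstablishmentClass, Site


@pytest.fixture()
def four_sites():
    return {
        f"s{i}": Site(f"s{i}", cls, 2016, 10.0 * i, 0.0)
        for i, cls in enumerate(EstablishmentClass)
    }


class TestBuildProfiles:
    def test_presence_filter_drops_partial_species(self, four_sites):
        rows = [(f"s{i}", 1, "everywhere", 5) for i in range(4)]
        rows += [(f"s{i}", 1, "three_classes", 5) for i in range(3)]
        cov = CoverageTable(
            pd.DataFrame(rows, columns=["site_id", "plot_id", "species_id", "coverage"])
        )
        prof = build_profiles("coverage", cov, four_sites, presence_filter=True)
        assert list(prof.index) == ["everywhere"]
        unfiltered = build_profiles("coverage", cov, four_sites, presence_filter=False)
        assert set(unfiltered.index) == {"everywhere", "three_classes"}

    def test_constant_species_constant_profile(self, four_sites):
        rows = [(f"s{i}", 1, "flat", 20) for i in range(4)]
        cov = CoverageTable(
            pd.DataFrame(rows, columns=["site_id", "plot_id", "species_id", "coverage"])
        )
        prof = build_profiles("coverage", cov, four_sites)
        assert np.allclose(prof.loc["flat"], 20.0)

    def test_mdg_missing_cells_excluded_from_means(self, four_sites):
        recs = [
            DamageRecord("s0", "X", 0, 0, 0, 10),  # MDG 75 in Y1978
            DamageRecord("s1", "X", 10, 0, 0, 0),
            DamageRecord("s2", "X", 10, 0, 0, 0),
            DamageRecord("s3", "X", 10, 0, 0, 0),
        ]
        prof = build_profiles("mdg", mdg_matrix(recs), four_sites)
        assert prof.loc["X", "Y1978"] == 75.0

    def test_class_without_sites_rejected(self, four_sites):
        del four_sites["s3"]
        cov = CoverageTable(
            pd.DataFrame(
                [("s0", 1, "X", 5)],
                columns=["site_id", "plot_id", "species_id", "coverage"],
            )
        )
        with pytest.raises(ValueError, match="without sites"):
            build_profiles("coverage", cov, four_sites)


class TestScaling:
    def test_max_scaling_unit_peak(self):
        prof = pd.DataFrame([[2.0, 4.0, 8.0, 8.0], [0.0, 0.0, 0.0, 0.0]])
        out = scale_profiles(prof, "max")
        assert out.iloc[0].max() == 1.0
        assert np.allclose(out.iloc[1], 0.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            scale_profiles(pd.DataFrame([[1.0]]), "median")


class TestKmeans:
    def test_k_equals_n_zero_dispersion(self, rng):
        X = rng.random((5, 4))
        _, _, w = kmeans(X, 5, seed=0)
        assert w == pytest.approx(0.0, abs=1e-12)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans(rng.random((3, 2)), 4)

    def test_duplicates_co_clustered(self, rng):
        X = np.vstack([np.zeros((3, 2)), np.ones((3, 2)) * 9])
        labels, _, _ = kmeans(X, 2, seed=1)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    def test_two_blobs_match_brute_force_optimum(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (4, 2)), rng.normal(6, 0.3, (4, 2))])
        labels, _, w = kmeans(X, 2, seed=3)
        # brute force over every 2-partition of the 8 points
        best = np.inf
        for mask in itertools.product([0, 1], repeat=8):
            mask = np.array(mask)
            if mask.sum() in (0, 8):
                continue
            w_mask = sum(
                ((X[mask == g] - X[mask == g].mean(axis=0)) ** 2).sum()
                for g in (0, 1)
            )
            best = min(best, w_mask)
        assert w == pytest.approx(best, rel=1e-9)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1


class TestGapStatistic:
    def test_single_tight_blob_chooses_one(self, rng):
        X = rng.normal(0, 0.5, size=(40, 2))
        k, _, _, _ = gap_statistic(X, kmax=4, B=20, seed=0)
        assert k == 1

    def test_three_blobs_chosen(self, rng):
        X = np.vstack(
            [rng.normal(c, 0.3, size=(15, 2)) for c in ((0, 0), (8, 0), (0, 8))]
        )
        k, _, _, _ = gap_statistic(X, kmax=5, B=20, seed=1)
        assert k == 3

    def test_degenerate_identical_points(self):
        X = np.ones((10, 4))
        k, _, _, _ = gap_statistic(X, kmax=3, B=10, seed=0)
        assert k == 1

    def test_w_nonincreasing_in_k(self, rng):
        X = rng.random((30, 4))
        _, W, _, _ = gap_statistic(X, kmax=5, B=10, seed=2)
        assert (np.diff(W) <= 1e-9).all()

    def test_invariant_to_coordinate_permutation(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (12, 4)), rng.normal(5, 0.3, (12, 4))])
        k1, _, _, _ = gap_statistic(X, kmax=4, B=15, seed=5)
        k2, _, _, _ = gap_statistic(X[:, ::-1], kmax=4, B=15, seed=5)
        assert k1 == k2


class TestClusterProfiles:
    def test_deterministic_given_seed(self, rng):
        prof = pd.DataFrame(
            rng.random((20, 4)), columns=["Y1978", "Y2003", "Y2011", "Y2014"]
        )
        a = cluster_profiles(prof, B=10, seed=7)
        b = cluster_profiles(prof, B=10, seed=7)
        assert a.chosen_k == b.chosen_k
        assert (a.labels == b.labels).all()

    def test_fixed_k_override(self, rng):
        prof = pd.DataFrame(
            rng.random((12, 4)), columns=["Y1978", "Y2003", "Y2011", "Y2014"]
        )
        out = cluster_profiles(prof, seed=0, k=3)
        assert out.chosen_k == 3
        assert set(out.labels.unique()) <= {1, 2, 3}

    def test_study_streams_separate(self, study):
        """Declining and flat coverage archetypes land in different clusters."""
        from browsevuln.clustering import build_profiles

        prof = build_profiles("coverage", study.coverage, study.sites)
        out = cluster_profiles(prof, B=20, seed=3)
        arch = {sp: study.truth.archetype[sp] for sp in prof.index}
        a_clusters = {out.labels[sp] for sp in prof.index if arch[sp] == "A"}
        flat_clusters = {out.labels[sp] for sp in prof.index if arch[sp] in "EF"}
        assert a_clusters.isdisjoint(flat_clusters)
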