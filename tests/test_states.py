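"""PCA projection, K-means discretization, elbow selection, landscapes."""

import numpy as np
import pytest

from metastab.errors import DimensionalityError, InfeasibleClusteringError
from metastab.featurize import NeighborhoodFeatures, standardize
from metastab.states import (
    Projection,
    elbow_select_k,
    fit_kmeans,
    free_energy_landscape,
    pca_project,
    representative_frame,
)


def _features(matrix):
    matrix = np.asarray(matrix, dtype=float)
    return NeighborhoodFeatures(
        focal=0,
        neighbor_order=tuple(range(1, matrix.shape[1] + 1)),
        matrix=matrix,
        standardized=True,
    )


def _projection(points):
    points = np.asarray(points, dtype=float)
    k = points.shape[1]
    return Projection(
        coordinates=points,
        components=np.eye(k),
        explained_variance_fraction=np.full(k, 1.0 / k),
    )


class TestPCA:
    def test_rank_one_data_fully_explained(self, rng):
        x = rng.normal(size=200)
        feats = standardize(
            NeighborhoodFeatures(focal=0, neighbor_order=(1, 2), matrix=np.c_[x + 5, 2 * x + 9])
        )
        proj = pca_project(feats, 1)
        assert proj.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-8)

    def test_components_orthonormal_and_fractions_sorted(self, rng):
        feats = standardize(
            NeighborhoodFeatures(
                focal=0, neighbor_order=(1, 2, 3, 4), matrix=rng.uniform(1, 9, size=(100, 4))
            )
        )
        proj = pca_project(feats, 3)
        gram = proj.components @ proj.components.T
        assert np.allclose(gram, np.eye(3), atol=1e-8)
        assert np.all(np.diff(proj.explained_variance_fraction) <= 1e-12)
        # deterministic sign: leading loading positive
        for row in proj.components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_isotropic_gaussian_splits_variance(self):
        r = np.random.default_rng(0)
        feats = _features(r.normal(size=(20000, 2)))
        proj = pca_project(feats, 2)
        assert proj.explained_variance_fraction == pytest.approx([0.5, 0.5], abs=0.02)

    def test_too_many_components(self, rng):
        feats = _features(rng.normal(size=(10, 2)))
        with pytest.raises(DimensionalityError):
            pca_project(feats, 3)

    def test_requires_standardized_input(self, rng):
        feats = NeighborhoodFeatures(
            focal=0, neighbor_order=(1, 2), matrix=rng.uniform(1, 5, size=(10, 2))
        )
        with pytest.raises(ValueError):
            pca_project(feats, 2)


class TestKMeans:
    def test_two_separated_pairs(self):
        proj = _projection([(0, 0), (0, 1), (10, 0), (10, 1)])
        model = fit_kmeans(proj, 2, seed=0)
        assert model.inertia == pytest.approx(1.0)
        assert model.labels[0] == model.labels[1]
        assert model.labels[2] == model.labels[3]
        assert np.allclose(sorted(model.centroids[:, 0]), [0, 10])
        assert model.occupancies.sum() == pytest.approx(1.0, abs=1e-12)

    def test_k_equals_one_gives_mean_and_total_variance(self, rng):
        pts = rng.normal(size=(50, 2))
        model = fit_kmeans(_projection(pts), 1, seed=0)
        assert np.allclose(model.centroids[0], pts.mean(axis=0), atol=1e-8)
        assert model.inertia == pytest.approx(((pts - pts.mean(0)) ** 2).sum(), rel=1e-8)

    def test_k_equals_n_gives_zero_inertia(self, rng):
        pts = rng.normal(size=(7, 2))
        model = fit_kmeans(_projection(pts), 7, seed=0)
        assert model.inertia == pytest.approx(0.0, abs=1e-12)

    def test_infeasible_k(self, rng):
        with pytest.raises(InfeasibleClusteringError):
            fit_kmeans(_projection(rng.normal(size=(5, 2))), 6, seed=0)

    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(size=(200, 2))
        a = fit_kmeans(_projection(pts), 4, seed=9)
        b = fit_kmeans(_projection(pts), 4, seed=9)
        assert np.array_equal(a.labels, b.labels)
        assert a.inertia == b.inertia

    def test_inertia_recomputes_from_labels(self, rng):
        pts = rng.normal(size=(120, 2))
        model = fit_kmeans(_projection(pts), 3, seed=1)
        recomputed = sum(
            ((pts[model.labels == s] - model.centroids[s]) ** 2).sum() for s in range(3)
        )
        assert model.inertia == pytest.approx(recomputed, abs=1e-8)


class TestElbow:
    def test_three_planted_gaussians_selected(self):
        r = np.random.default_rng(5)
        centers = np.array([(0, 0), (12, 0), (0, 12)])
        labels = r.choice(3, size=2000, p=[0.5, 0.3, 0.2])
        pts = centers[labels] + r.normal(scale=1.0, size=(2000, 2))
        scan = elbow_select_k(_projection(pts), 9, seed=0)
        assert scan.chosen_k == 3
        assert np.all(np.diff(scan.inertias) <= 1e-6)  # non-increasing curve

    def test_featureless_gaussian_yields_interior_k(self):
        r = np.random.default_rng(2)
        scan = elbow_select_k(_projection(r.normal(size=(500, 2))), 9, seed=0)
        assert 2 <= scan.chosen_k <= 8
        assert np.all(np.diff(scan.inertias) <= 1e-6)

    def test_small_kmax_rejected(self, rng):
        with pytest.raises(InfeasibleClusteringError):
            elbow_select_k(_projection(rng.normal(size=(100, 2))), 2, seed=0)

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(InfeasibleClusteringError):
            elbow_select_k(_projection(rng.normal(size=(8, 2))), 9, seed=0)


class TestRepresentativeFrame:
    def test_argmin_distance(self):
        pts = [(0.5, 0), (0.1, 0), (0.9, 0)]
        proj = _projection(pts)
        model = fit_kmeans(proj, 1, seed=0)
        # re-center the centroid at the origin to make distances the x values
        object.__setattr__(model, "centroids", np.array([[0.0, 0.0]]))
        assert representative_frame(model, proj, 0) == 1

    def test_single_frame_state(self):
        proj = _projection([(0, 0), (50, 50)])
        model = fit_kmeans(proj, 2, seed=0)
        state_of_1 = model.labels[1]
        assert representative_frame(model, proj, int(state_of_1)) == 1

    def test_matches_exhaustive_oracle(self):
        r = np.random.default_rng(7)
        pts = r.normal(size=(500, 2)) * 3
        proj = _projection(pts)
        model = fit_kmeans(proj, 4, seed=1)
        for s in range(model.k):
            members = np.flatnonzero(model.labels == s)
            d = np.linalg.norm(pts[members] - model.centroids[s], axis=1)
            assert representative_frame(model, proj, s) == members[np.argmin(d)]


class TestLandscape:
    def test_equal_density_bins_are_both_zero(self):
        pts = [(0.25, 0.5), (0.75, 0.5)] * 10
        grid, _, _ = free_energy_landscape(_projection(pts), bins=2)
        occupied = grid[~grid.mask]
        assert np.allclose(occupied, 0.0)

    def test_half_density_costs_ln_two(self):
        pts = [(0.25, 0.5)] * 20 + [(0.75, 0.5)] * 10
        grid, _, _ = free_energy_landscape(_projection(pts), bins=2)
        vals = np.sort(grid[~grid.mask].data)
        assert vals[0] == pytest.approx(0.0, abs=1e-12)
        assert vals[1] == pytest.approx(np.log(2), abs=1e-12)

    def test_empty_bins_masked(self, rng):
        grid, _, _ = free_energy_landscape(_projection(rng.normal(size=(30, 2))), bins=10)
        assert grid.mask.any()

    def test_bad_bins(self, rng):
        with pytest.raises(ValueError):
            free_energy_landscape(_projection(rng.normal(size=(30, 2))), bins=1)


def test_label_permutation_invariant_summary(planted_trajectory):
    """Sorted occupancies and member sets are stable across clustering seeds."""
    from metastab.featurize import min_distance_features, standardize

    spec, traj, truth = planted_trajectory
    feats = standardize(min_distance_features(traj, spec.planted_selection()))
    proj = pca_project(feats, 2)
    models = [fit_kmeans(proj, 3, seed=s) for s in (1, 2)]
    occ = [np.sort(m.occupancies)[::-1] for m in models]
    assert np.allclose(occ[0], occ[1], atol=1e-12)
    sets = [
        {frozenset(np.flatnonzero(m.labels == s).tolist()) for s in range(3)} for m in models
    ]
    assert sets[0] == sets[1]
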