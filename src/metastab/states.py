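"""Metastable-state discovery: PCA, K-means, elbow selection, landscapes.

Frames of the standardized distance features are projected onto their leading
principal components (two by default) and discretized with K-means.  The
number of states K is chosen by the elbow heuristic: K-means is fit for
K = 1..k_max and the selected K maximizes the second difference of the
inertia curve — the point where the decrease in within-cluster sum of squares
turns linear.  Each state's representative conformation is the member frame
closest to its centroid in the projected space, and occupancies are the
fractions of frames assigned to each state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.ma as ma
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from metastab.errors import DimensionalityError, InfeasibleClusteringError
from metastab.featurize import NeighborhoodFeatures


@dataclass(frozen=True)
class Projection:
    """PCA scores plus the orthonormal basis and explained-variance fractions."""

    coordinates: np.ndarray  # (n_frames, n_components)
    components: np.ndarray  # (n_components, n_features)
    explained_variance_fraction: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class StateModel:
    """A fitted K-means discretization of the projected frames."""

    k: int
    centroids: np.ndarray  # (k, n_components)
    labels: np.ndarray  # (n_frames,)
    inertia: float
    occupancies: np.ndarray  # (k,)
    seed: int

    def members(self, state: int) -> np.ndarray:
        """Frame indices assigned to ``state``, ascending."""
        if not 0 <= state < self.k:
            raise IndexError(f"state {state} out of range [0, {self.k})")
        return np.flatnonzero(self.labels == state)

    @property
    def most_populated_state(self) -> int:
        # ties broken toward the lower state id
        return int(np.argmax(self.occupancies))


@dataclass(frozen=True)
class ElbowScan:
    """Inertia curve over K = 1..k_max and the elbow-selected K."""

    k_values: np.ndarray
    inertias: np.ndarray
    chosen_k: int


def pca_project(features: NeighborhoodFeatures, n_components: int = 2) -> Projection:
    """Project standardized features onto the leading principal components.

    Component signs are fixed so that each component's largest-magnitude
    loading is positive, making the projection deterministic.
    """
    if not features.standardized:
        raise ValueError("features must be standardized before PCA")
    if n_components > features.n_neighbors:
        raise DimensionalityError(
            f"n_components={n_components} exceeds the {features.n_neighbors} available features"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(features.matrix)
    components = pca.components_.copy()
    for j in range(components.shape[0]):
        lead = np.argmax(np.abs(components[j]))
        if components[j, lead] < 0:
            components[j] = -components[j]
            scores[:, j] = -scores[:, j]
    return Projection(
        coordinates=scores,
        components=components,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
    )


def fit_kmeans(proj: Projection, k: int, seed: int) -> StateModel:
    """K-means with k-means++ seeding, best of 10 restarts, deterministic per seed."""
    if not 1 <= k <= proj.n_frames:
        raise InfeasibleClusteringError(f"k={k} infeasible for {proj.n_frames} frames")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, tol=1e-6, random_state=seed)
    labels = km.fit_predict(proj.coordinates)
    counts = np.bincount(labels, minlength=k)
    if np.any(counts == 0):  # pragma: no cover - sklearn guarantees non-empty clusters
        raise InfeasibleClusteringError(f"k={k} produced an empty cluster")
    return StateModel(
        k=k,
        centroids=km.cluster_centers_.copy(),
        labels=labels,
        inertia=float(km.inertia_),
        occupancies=counts / labels.size,
        seed=seed,
    )


def elbow_select_k(proj: Projection, k_max: int = 9, seed: int = 0) -> ElbowScan:
    """Scan K = 1..k_max and select the elbow of the inertia curve.

    The chosen K maximizes the discrete second difference
    ``(I(k-1) - I(k)) - (I(k) - I(k+1))`` over interior K, i.e. the point of
    sharpest curvature before the decrease turns linear.  Ties break toward
    the smaller K.
    """
    if k_max < 3:
        raise InfeasibleClusteringError(f"k_max must be >= 3 for an elbow, got {k_max}")
    if proj.n_frames <= k_max:
        raise InfeasibleClusteringError(
            f"need more than k_max={k_max} frames, got {proj.n_frames}"
        )
    k_values = np.arange(1, k_max + 1)
    inertias = np.array([fit_kmeans(proj, int(k), seed).inertia for k in k_values])
    second_diff = inertias[:-2] - 2 * inertias[1:-1] + inertias[2:]
    chosen = int(k_values[1:-1][np.argmax(second_diff)])  # argmax takes first on ties
    return ElbowScan(k_values=k_values, inertias=inertias, chosen_k=chosen)


def representative_frame(model: StateModel, proj: Projection, state: int) -> int:
    """The member frame closest to its state centroid in projection space.

    Ties resolve to the lowest frame index.
    """
    members = model.members(state)
    if members.size == 0:
        raise InfeasibleClusteringError(f"state {state} is empty")
    d = np.linalg.norm(proj.coordinates[members] - model.centroids[state], axis=1)
    return int(members[np.argmin(d)])


def free_energy_landscape(
    proj: Projection, bins: int = 60
) -> tuple[ma.MaskedArray, np.ndarray, np.ndarray]:
    """2-D relative free energy over the first two components, in units of kT.

    ``G(bin) = -ln(count/total)``, shifted so the fullest bin has G = 0.
    Empty bins are masked (their free energy is undefined, not zero).
    Returns ``(grid, x_edges, y_edges)``.
    """
    if proj.n_components < 2:
        raise DimensionalityError("landscape needs at least two components")
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    counts, x_edges, y_edges = np.histogram2d(
        proj.coordinates[:, 0], proj.coordinates[:, 1], bins=bins
    )
    with np.errstate(divide="ignore"):
        g = -np.log(counts / counts.sum())
    g -= g[counts > 0].min()
    grid = ma.masked_array(g, mask=counts == 0)
    return grid, x_edges, y_edges
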