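"""Contact neighborhoods and minimum heavy-atom distance features.

Each trajectory frame is summarized by the minimum heavy-atom distance from a
focal residue to every residue of its contact neighborhood — the residues
having any heavy atom within a cutoff (default 5 A) of the focal residue on a
reference frame.  The resulting ``n_frames x n_neighbors`` matrix is
standardized column-wise to zero mean and unit variance before dimensionality
reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from metastab.errors import DegenerateResidueError, FrozenCoordinateError, UnknownResidueError
from metastab.traj_io import ResidueSelection, Trajectory


@dataclass(frozen=True)
class NeighborhoodFeatures:
    """Frames x neighbors matrix of focal-to-neighbor minimum distances.

    ``column_means``/``column_stds`` hold the pre-standardization statistics
    (population std, ddof=0) so the transform is invertible.
    """

    focal: int
    neighbor_order: tuple[int, ...]
    matrix: np.ndarray  # (n_frames, n_neighbors)
    standardized: bool = False
    column_means: np.ndarray | None = None
    column_stds: np.ndarray | None = None

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", matrix)
        if matrix.ndim != 2 or matrix.shape[1] != len(self.neighbor_order):
            raise ValueError("matrix must be n_frames x n_neighbors")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("feature matrix must be finite")
        if not self.standardized and matrix.size and not np.all(matrix > 0):
            raise ValueError("raw distances must be strictly positive")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_neighbors(self) -> int:
        return self.matrix.shape[1]


def contact_neighborhood(
    reference: Trajectory,
    focal: int,
    cutoff: float = 5.0,
    *,
    frame: int = 0,
    chain: str | None = None,
) -> ResidueSelection:
    """Residues with any heavy atom within ``cutoff`` of the focal residue.

    Evaluated on one stated reference frame (default the first); hetero
    groups (cofactors, waters) are excluded.  The focal residue itself is
    always part of the returned selection.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    reference.atom_indices(focal, chain)  # raises UnknownResidueError if absent
    focal_idx = reference.atom_indices(focal, chain, heavy_only=True)
    if focal_idx.size == 0:
        raise DegenerateResidueError(f"focal residue {focal} has no heavy atoms")
    coords = reference.frames[frame]
    focal_xyz = coords[focal_idx]
    members: set[int] = {focal}
    for chain_id, resid in reference.residue_ids():
        if chain is not None and chain_id != chain:
            continue
        if resid == focal or not reference.is_protein_residue(resid, chain_id):
            continue
        other_idx = reference.atom_indices(resid, chain_id, heavy_only=True)
        if other_idx.size == 0:
            continue
        if cdist(focal_xyz, coords[other_idx]).min() <= cutoff:
            members.add(resid)
    return ResidueSelection(tuple(sorted(members)), focal=focal)


def min_distance_features(
    traj: Trajectory,
    selection: ResidueSelection,
    *,
    chain: str | None = None,
    all_pairs: bool = False,
) -> NeighborhoodFeatures:
    """Per-frame minimum heavy-atom distances from the focal residue.

    ``matrix[f, j]`` is the minimum over heavy-atom pairs (focal atom,
    neighbor-j atom) of the Euclidean distance in frame ``f``.  With
    ``all_pairs=True`` every unordered residue pair within the selection
    contributes a feature instead (sensitivity-analysis mode); the default
    focal-to-neighbor set is what the downstream state discovery uses.
    """
    atom_sets: dict[int, np.ndarray] = {}
    for resid in selection.residue_indices:
        idx = traj.atom_indices(resid, chain, heavy_only=True)
        if idx.size == 0:
            # distinguish absent from hydrogen-only residues
            traj.atom_indices(resid, chain)
            raise DegenerateResidueError(f"residue {resid} has no heavy atoms")
        atom_sets[resid] = idx

    if all_pairs:
        pairs = [
            (a, b)
            for i, a in enumerate(selection.residue_indices)
            for b in selection.residue_indices[i + 1 :]
        ]
    else:
        pairs = [(selection.focal, b) for b in selection.neighbors]

    matrix = np.empty((traj.n_frames, len(pairs)), dtype=float)
    for j, (a, b) in enumerate(pairs):
        xa = traj.frames[:, atom_sets[a], :]
        xb = traj.frames[:, atom_sets[b], :]
        # (n_frames, |a|, |b|) pairwise distances, reduced over atom pairs
        diff = xa[:, :, None, :] - xb[:, None, :, :]
        matrix[:, j] = np.sqrt((diff**2).sum(axis=-1)).min(axis=(1, 2))

    order = tuple(b for _, b in pairs) if not all_pairs else tuple(range(len(pairs)))
    if all_pairs:
        # all-pairs mode labels features by pair index; focal retained for provenance
        return NeighborhoodFeatures(focal=selection.focal, neighbor_order=order, matrix=matrix)
    return NeighborhoodFeatures(focal=selection.focal, neighbor_order=order, matrix=matrix)


def standardize(features: NeighborhoodFeatures) -> NeighborhoodFeatures:
    """Column-wise (x - mean)/std with population (ddof=0) standard deviation."""
    if features.standardized:
        raise ValueError("features are already standardized")
    means = features.matrix.mean(axis=0)
    stds = features.matrix.std(axis=0, ddof=0)
    frozen = np.flatnonzero(stds**2 <= 1e-12)
    if frozen.size:
        names = ", ".join(str(features.neighbor_order[j]) for j in frozen)
        raise FrozenCoordinateError(
            f"zero-variance feature column(s) for neighbor(s) {names}; "
            "remove the frozen coordinate or add frames"
        )
    return NeighborhoodFeatures(
        focal=features.focal,
        neighbor_order=features.neighbor_order,
        matrix=(features.matrix - means) / stds,
        standardized=True,
        column_means=means,
        column_stds=stds,
    )


def unstandardize(features: NeighborhoodFeatures) -> NeighborhoodFeatures:
    """Invert :func:`standardize` using the retained column statistics."""
    if not features.standardized:
        raise ValueError("features are not standardized")
    if features.column_means is None or features.column_stds is None:
        raise ValueError("standardization statistics were not retained")
    return NeighborhoodFeatures(
        focal=features.focal,
        neighbor_order=features.neighbor_order,
        matrix=features.matrix * features.column_stds + features.column_means,
        standardized=False,
    )


def write_features_tsv(features: NeighborhoodFeatures, path) -> None:
    """Serialize the matrix as TSV with a header row of neighbor positions."""
    header = "frame\t" + "\t".join(str(p) for p in features.neighbor_order)
    rows = [
        f"{f}\t" + "\t".join(f"{v:.6f}" for v in features.matrix[f])
        for f in range(features.n_frames)
    ]
    with open(path, "w") as fh:
        fh.write(header + "\n")
        fh.write("\n".join(rows) + "\n")
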