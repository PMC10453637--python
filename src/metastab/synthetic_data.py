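"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes rather
than force-field physics: trajectories are frames drawn from K metastable
conformations (rigid neighbor-residue displacements of a toy extended chain)
with fixed occupancies plus isotropic Gaussian coordinate noise; score tables
plant per-variant neighborhood-sum means; alignments plant per-column residue
profiles; hit tables plant coverage/identity distributions with a known
filter pass fraction.  Every generator is a pure function of its seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from metastab.conservation import CANONICAL_AA
from metastab.errors import ValidationError
from metastab.stability import ResidueScoreTable
from metastab.traj_io import Atom, ResidueSelection, Trajectory

# idealized backbone offsets (A) relative to each residue's CA
_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.90, 0.00]),
    "CA": np.array([0.00, 0.00, 0.00]),
    "C": np.array([1.20, 0.90, 0.00]),
    "O": np.array([1.20, 2.13, 0.00]),
}
_CB_OFFSET = np.array([0.00, -1.30, 0.60])
_CA_SPACING = 3.8
_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


@dataclass(frozen=True)
class TrajectorySpec:
    """Parameters of a planted-state synthetic trajectory.

    Defaults mirror the study conditions the recovery checks assume: 2000
    frames from three states at occupancies 0.6/0.3/0.1, with inter-state
    displacements ten times the coordinate noise.
    """

    n_residues: int = 12
    focal: int = 6
    n_frames: int = 2000
    occupancies: tuple[float, ...] = (0.6, 0.3, 0.1)
    state_displacements: tuple[tuple[float, float, float], ...] | None = None
    noise_sigma: float = 0.3
    seed: int = 0
    displaced_residues: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.occupancies) - 1.0) > 1e-12:
            raise ValidationError(f"occupancies must sum to 1, got {sum(self.occupancies)}")
        if any(o <= 0 for o in self.occupancies):
            raise ValidationError("occupancies must be positive")
        if self.noise_sigma <= 0:
            raise ValidationError("noise_sigma must be positive")
        if self.n_states < 1:
            raise ValidationError("need at least one state")

    @property
    def n_states(self) -> int:
        return len(self.occupancies)

    def resolved_displacements(self) -> np.ndarray:
        """Per-state displacement vectors, pairwise at least 10 sigma apart.

        The default geometry is deliberately non-collinear: the first three
        states sit at (0,0,0), (0, 10s, 0) and (20s/3, -40s/3, 0) with
        s = ``noise_sigma``, so the states form a genuine triangle in the
        focal-to-neighbor distance features rather than a degenerate
        equally-spaced line (on which no inertia-curve elbow can distinguish
        three states from two).
        """
        if self.state_displacements is not None:
            d = np.asarray(self.state_displacements, dtype=float)
            if d.shape != (self.n_states, 3):
                raise ValidationError(f"need {self.n_states} displacement vectors of length 3")
            return d
        step = 10.0 * self.noise_sigma
        base = [
            (0.0, 0.0, 0.0),
            (0.0, step, 0.0),
            (2.0 * step / 3.0, -4.0 * step / 3.0, 0.0),
        ]
        for i in range(3, self.n_states):
            base.append((0.0, i * step, (i - 2) * step))
        return np.array(base[: self.n_states])

    def planted_selection(self) -> ResidueSelection:
        """The focal position plus the residues carrying the planted signal."""
        return ResidueSelection(
            self.resolved_displaced_residues() + (self.focal,), focal=self.focal
        )

    def resolved_displaced_residues(self) -> tuple[int, ...]:
        """Residues carrying the planted signal; default: the two flanking the focal."""
        if self.displaced_residues is not None:
            return self.displaced_residues
        return (self.focal - 1, self.focal + 1)


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth emitted alongside each generated artifact."""

    frame_labels: tuple[int, ...] | None = None
    planted_occupancies: tuple[float, ...] | None = None
    planted_neighborhood_sum_means: dict | None = None
    planted_profiles: dict | None = None
    planted_pass_fraction: float | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {k: v for k, v in self.__dict__.items() if v is not None}
        Path(path).write_text(json.dumps(payload, default=list, indent=1) + "\n")


def make_toy_protein(n_residues: int, sequence: str | None = None) -> Trajectory:
    """Single-frame extended-chain backbone (N, CA, C, O; CB except glycine).

    CA atoms are spaced 3.8 A along x; an all-alanine chain of n residues
    therefore has 5n atoms.
    """
    if n_residues < 3:
        raise ValidationError(f"need at least 3 residues, got {n_residues}")
    if sequence is None:
        sequence = "A" * n_residues
    if len(sequence) != n_residues:
        raise ValidationError("sequence length must equal n_residues")
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    three = {"A": "ALA", "G": "GLY"}
    for i, aa in enumerate(sequence.upper()):
        ca = np.array([i * _CA_SPACING, 0.0, 0.0])
        names = ["N", "CA", "C", "O"] + ([] if aa == "G" else ["CB"])
        for name in names:
            offset = _CB_OFFSET if name == "CB" else _BACKBONE_OFFSETS[name]
            atoms.append(
                Atom(
                    name=name,
                    element=_ELEMENT[name],
                    residue_index=i + 1,
                    residue_name=three.get(aa, "ALA"),
                    chain="A",
                )
            )
            coords.append(ca + offset)
    return Trajectory(atoms=atoms, frames=np.array(coords)[None, :, :])


def simulate_metastable_trajectory(spec: TrajectorySpec) -> tuple[Trajectory, GroundTruth]:
    """Frames drawn from K metastable conformations at planted occupancies.

    Each state rigidly offsets the residues flanking the focal position by
    its displacement vector; i.i.d. Gaussian noise (sigma = ``noise_sigma``)
    is then added to every coordinate.  Deterministic per seed.
    """
    base = make_toy_protein(spec.n_residues)
    displacements = spec.resolved_displacements()
    if spec.n_states > 1:
        pair_sep = min(
            np.linalg.norm(displacements[i] - displacements[j])
            for i in range(spec.n_states)
            for j in range(i + 1, spec.n_states)
        )
        if pair_sep < 3.0 * spec.noise_sigma:
            warnings.warn(
                f"minimum inter-state displacement {pair_sep:.2f} A is below "
                f"3x noise ({3 * spec.noise_sigma:.2f} A): states may be unresolvable",
                stacklevel=2,
            )
    moved = np.array(
        [a.residue_index in spec.resolved_displaced_residues() for a in base.atoms]
    )
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(spec.n_states, size=spec.n_frames, p=np.asarray(spec.occupancies))
    frames = np.repeat(base.frames, spec.n_frames, axis=0)
    frames[:, moved, :] += displacements[labels][:, None, :]
    frames += rng.normal(0.0, spec.noise_sigma, size=frames.shape)
    truth = GroundTruth(
        frame_labels=tuple(int(s) for s in labels),
        planted_occupancies=tuple(spec.occupancies),
    )
    return Trajectory(atoms=base.atoms, frames=frames), truth


def simulate_score_table(
    frames: int,
    neighborhood: ResidueSelection,
    planted_sum_means: dict[str, float],
    noise_sigma: float = 0.1,
    seed: int = 0,
) -> tuple[dict[str, ResidueScoreTable], GroundTruth]:
    """Per-variant score tables whose neighborhood sums are Normal(mean, sigma^2).

    Each frame's planted sum is spread over the neighborhood positions with
    zero-sum per-residue jitter, so per-residue scores vary while the
    neighborhood sum keeps the planted distribution exactly.
    """
    if neighborhood is None or not neighborhood.residue_indices:
        raise ValidationError("neighborhood must not be empty")
    if not all(np.isfinite(list(planted_sum_means.values()))):
        raise ValidationError("planted means must be finite")
    rng = np.random.default_rng(seed)
    positions = neighborhood.residue_indices
    n_pos = len(positions)
    tables: dict[str, ResidueScoreTable] = {}
    for variant, mean in planted_sum_means.items():
        sums = rng.normal(mean, noise_sigma, size=frames) if noise_sigma > 0 else np.full(frames, float(mean))
        jitter = rng.normal(0.0, max(noise_sigma, 1e-6), size=(frames, n_pos))
        jitter -= jitter.mean(axis=1, keepdims=True)  # zero-sum across residues
        scores = sums[:, None] / n_pos + jitter
        tables[variant] = ResidueScoreTable(
            frame_ids=tuple(range(frames)),
            residue_positions=positions,
            scores=scores,
            units="synthetic",
        )
    truth = GroundTruth(planted_neighborhood_sum_means=dict(planted_sum_means))
    return tables, truth


def simulate_msa(
    n_sequences: int,
    length: int,
    profiles: dict[int, dict[str, float]],
    seed: int = 0,
    query_id: str = "query",
) -> tuple[str, GroundTruth]:
    """Aligned FASTA text drawn i.i.d. per column from planted profiles.

    ``profiles`` maps 1-based positions to distributions over residues and
    ``-`` (gap); unspecified columns use a uniform distribution over the 20
    canonical amino acids.  The query sequence is included ungapped, as each
    column's most probable canonical residue.  Returns the FASTA text and
    the planted truth.
    """
    if n_sequences < 1 or length < 1:
        raise ValidationError("need at least one sequence and one column")
    uniform = {aa: 1.0 / len(CANONICAL_AA) for aa in CANONICAL_AA}
    letters: list[list[str]] = []
    probs: list[np.ndarray] = []
    for pos in range(1, length + 1):
        profile = profiles.get(pos, uniform)
        total = sum(profile.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"profile at position {pos} sums to {total}, not 1")
        ls = list(profile)
        letters.append(ls)
        probs.append(np.array([profile[l] for l in ls]))
    rng = np.random.default_rng(seed)
    columns = [
        np.array(letters[c])[rng.choice(len(letters[c]), size=n_sequences, p=probs[c])]
        for c in range(length)
    ]
    query = "".join(
        max(
            ((l, p) for l, p in zip(letters[c], probs[c]) if l in CANONICAL_AA),
            key=lambda t: t[1],
        )[0]
        for c in range(length)
    )
    records = [f">{query_id}\n{query}"]
    for s in range(n_sequences):
        seq = "".join(columns[c][s] for c in range(length))
        records.append(f">homolog_{s + 1}\n{seq}")
    truth = GroundTruth(planted_profiles={str(p): prof for p, prof in profiles.items()})
    return "\n".join(records) + "\n", truth


def simulate_hit_table(
    n_hits: int,
    coverage_distribution=None,
    identity_distribution=None,
    seed: int = 0,
    query_length: int = 500,
) -> tuple[str, GroundTruth]:
    """Tabular (13-column, qcovs-extended) hit list with a known pass fraction.

    Distributions are callables ``f(rng, n) -> array of percentages``;
    defaults draw coverage ~ U(40, 100) and identity ~ U(20, 100).  The
    fraction of rows satisfying the default filters (coverage > 70,
    40 <= identity <= 97) is recorded as ground truth.
    """
    if n_hits < 1:
        raise ValidationError("need at least one hit")
    rng = np.random.default_rng(seed)
    cov_fn = coverage_distribution or (lambda r, n: r.uniform(40.0, 100.0, size=n))
    id_fn = identity_distribution or (lambda r, n: r.uniform(20.0, 100.0, size=n))
    coverage = np.asarray(cov_fn(rng, n_hits), dtype=float)
    identity = np.asarray(id_fn(rng, n_hits), dtype=float)
    for label, v in (("coverage", coverage), ("identity", identity)):
        if v.shape != (n_hits,) or not np.all((v >= 0) & (v <= 100)):
            raise ValidationError(f"{label} distribution must yield {n_hits} values in [0, 100]")
    passes = (coverage > 70.0) & (identity >= 40.0) & (identity <= 97.0)
    rows = []
    for i in range(n_hits):
        aln_len = max(1, int(round(query_length * coverage[i] / 100.0)))
        rows.append(
            "\t".join(
                [
                    "query",
                    f"hit_{i + 1}",
                    f"{identity[i]:.2f}",
                    str(aln_len),
                    str(max(0, int(aln_len * (100 - identity[i]) / 100))),
                    "0",
                    "1",
                    str(aln_len),
                    "1",
                    str(aln_len),
                    "1e-30",
                    "200.0",
                    f"{coverage[i]:.2f}",
                ]
            )
        )
    truth = GroundTruth(planted_pass_fraction=float(passes.mean()))
    return "\n".join(rows) + "\n", truth
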