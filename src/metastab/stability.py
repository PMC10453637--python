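"""Local stability scoring over frames of the most populated state.

Local stability of a focal position is quantified as the sum of per-residue
energy scores over its contact neighborhood, averaged over frames sampled
from a metastable state, with a percentile-bootstrap 95% confidence interval
over the per-frame sums (default 1000 resamples).  Lower is more favorable.

Per-residue scores come from either an imported table (e.g. Rosetta residue
energies in REU) or from the built-in surrogate scorer, which captures the
two qualitative drivers the analysis cares about — heavy-atom packing via a
soft 12-6 potential and backbone hydrogen bonds via a distance criterion.
The two sources share one code path; the table carries a units label and
summaries with different units are never compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from metastab.errors import (
    ComparabilityError,
    CoverageError,
    ScoreTableFormatError,
)
from metastab.states import StateModel
from metastab.traj_io import ResidueSelection, Trajectory

#: van der Waals-like radii (A) used by the surrogate packing term.
SURROGATE_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
PACKING_EPSILON = 0.05
PACKING_CUTOFF = 6.0
PACKING_CAP = 10.0
HBOND_DISTANCE = 3.5
HBOND_MIN_SEPARATION = 2
HBOND_ENERGY = -0.5


@dataclass(frozen=True)
class ResidueScoreTable:
    """Frames x residues matrix of per-residue energies."""

    frame_ids: tuple[int, ...]
    residue_positions: tuple[int, ...]
    scores: np.ndarray  # (n_frames, n_residues)
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (len(self.frame_ids), len(self.residue_positions)):
            raise ScoreTableFormatError(
                f"score matrix shape {scores.shape} does not match "
                f"{len(self.frame_ids)} frames x {len(self.residue_positions)} residues"
            )
        if len(set(self.frame_ids)) != len(self.frame_ids):
            raise ScoreTableFormatError("duplicated frame ids")
        if not np.all(np.isfinite(scores)):
            raise ScoreTableFormatError("scores must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.frame_ids)

    def neighborhood_sums(self, frames, neighborhood: ResidueSelection) -> np.ndarray:
        """Per-frame sum of scores over the neighborhood positions."""
        pos_index = {p: j for j, p in enumerate(self.residue_positions)}
        missing = [p for p in neighborhood.residue_indices if p not in pos_index]
        if missing:
            raise CoverageError(f"neighborhood positions missing from score table: {missing}")
        frame_index = {f: i for i, f in enumerate(self.frame_ids)}
        try:
            rows = [frame_index[f] for f in frames]
        except KeyError as exc:
            raise CoverageError(f"frame {exc.args[0]} missing from score table") from exc
        cols = [pos_index[p] for p in neighborhood.residue_indices]
        return self.scores[np.ix_(rows, cols)].sum(axis=1)


@dataclass(frozen=True)
class LocalEnergySummary:
    """Bootstrap summary of the neighborhood energy sum over sampled frames."""

    focal: int
    neighborhood: ResidueSelection
    n_frames_used: int
    per_frame_sums: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    units: str = "arbitrary"


def read_score_table(path: str | Path, units: str = "arbitrary") -> ResidueScoreTable:
    """Read a TSV score table with header ``frame<TAB>pos1<TAB>pos2...``."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "frame":
            raise ScoreTableFormatError(f"{path}: header must start with 'frame'")
        try:
            positions = tuple(int(p) for p in header[1:])
        except ValueError as exc:
            raise ScoreTableFormatError(f"{path}: non-integer residue position in header") from exc
        frame_ids: list[int] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(positions) + 1:
                raise ScoreTableFormatError(
                    f"{path}: row {lineno} has {len(cells)} fields, expected {len(positions) + 1}"
                )
            try:
                frame_ids.append(int(cells[0]))
                rows.append([float(c) for c in cells[1:]])
            except ValueError as exc:
                raise ScoreTableFormatError(f"{path}: non-numeric cell in row {lineno}") from exc
    return ResidueScoreTable(
        frame_ids=tuple(frame_ids),
        residue_positions=positions,
        scores=np.array(rows, dtype=float).reshape(len(frame_ids), len(positions)),
        units=units,
    )


def write_score_table(table: ResidueScoreTable, path: str | Path) -> None:
    """Writer matching :func:`read_score_table` (lossless round-trip)."""
    df = pd.DataFrame(table.scores, columns=[str(p) for p in table.residue_positions])
    df.insert(0, "frame", table.frame_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _backbone_hbond_scores(traj: Trajectory, coords: np.ndarray, residues: list[tuple[str, int]]) -> dict[tuple[str, int], float]:
    donors = []  # (residue key, xyz) for backbone N
    acceptors = []  # for backbone carbonyl O
    for i, a in enumerate(traj.atoms):
        if a.is_hetero:
            continue
        if a.name == "N":
            donors.append(((a.chain, a.residue_index), coords[i]))
        elif a.name == "O":
            acceptors.append(((a.chain, a.residue_index), coords[i]))
    out: dict[tuple[str, int], float] = {r: 0.0 for r in residues}
    for dk, dxyz in donors:
        for ak, axyz in acceptors:
            if dk[0] == ak[0] and abs(dk[1] - ak[1]) < HBOND_MIN_SEPARATION:
                continue
            if np.linalg.norm(dxyz - axyz) <= HBOND_DISTANCE:
                if dk in out:
                    out[dk] += HBOND_ENERGY
                if ak in out:
                    out[ak] += HBOND_ENERGY
    return out


def surrogate_score_frame(traj: Trajectory, frame: int, *, chain: str | None = None) -> dict[int, float]:
    """Surrogate per-residue energy for one frame; lower = more favorable.

    ``score(r) = packing(r) + hbond(r)`` where packing sums, over heavy-atom
    pairs (a in r, b outside r) within 6 A, the 12-6 term
    ``eps * ((sigma/d)^12 - 2 (sigma/d)^6)`` with ``eps = 0.05`` and
    ``sigma = R(a) + R(b)`` (radii C 1.70, N 1.55, O 1.52, S 1.80 A), each
    pair term capped at +10; hbond adds -0.5 to both partners of every
    backbone N...O=C pair within 3.5 A at sequence separation >= 2.
    """
    if not 0 <= frame < traj.n_frames:
        raise IndexError(f"frame {frame} out of range")
    coords = traj.frames[frame]
    heavy = [
        (i, a) for i, a in enumerate(traj.atoms) if a.is_heavy and (chain is None or a.chain == chain)
    ]
    radii = np.empty(len(heavy))
    for j, (_, a) in enumerate(heavy):
        try:
            radii[j] = SURROGATE_RADII[a.element.upper()]
        except KeyError as exc:
            raise KeyError(
                f"no surrogate radius for element {a.element!r} (atom {a.name})"
            ) from exc
    xyz = np.array([coords[i] for i, _ in heavy])
    res_keys = [(a.chain, a.residue_index) for _, a in heavy]
    residues = sorted(
        {k for (_, a), k in zip(heavy, res_keys) if not a.is_hetero}, key=lambda k: (k[0], k[1])
    )

    packing = {r: 0.0 for r in residues}
    if len(heavy) > 1:
        d = cdist(xyz, xyz)
        sigma = radii[:, None] + radii[None, :]
        # coincident atoms (d=0) are maximal clashes; avoid inf-inf on the diagonal
        ratio = np.divide(sigma, d, out=np.full_like(d, 1e6), where=d > 0)
        with np.errstate(over="ignore"):
            term = np.minimum(PACKING_EPSILON * (ratio**12 - 2 * ratio**6), PACKING_CAP)
        codes = pd.factorize(pd.Series(res_keys))[0]
        same_res = codes[:, None] == codes[None, :]
        term[same_res | (d > PACKING_CUTOFF)] = 0.0
        for j, rk in enumerate(res_keys):
            if rk in packing:
                packing[rk] += term[j].sum()

    hbond = _backbone_hbond_scores(traj, coords, residues)
    totals = {r: packing[r] + hbond[r] for r in residues}
    # collapse to residue_index keys when unambiguous (single chain)
    if len({r[1] for r in residues}) == len(residues):
        return {r[1]: v for r, v in totals.items()}
    return {r: v for r, v in totals.items()}  # pragma: no cover - multi-chain ensembles


def surrogate_score_table(traj: Trajectory, frames=None, *, chain: str | None = None) -> ResidueScoreTable:
    """Score a set of frames (default all) with the surrogate scorer."""
    frames = list(range(traj.n_frames)) if frames is None else list(frames)
    per_frame = [surrogate_score_frame(traj, f, chain=chain) for f in frames]
    positions = tuple(sorted(per_frame[0]))
    scores = np.array([[sf[p] for p in positions] for sf in per_frame])
    return ResidueScoreTable(
        frame_ids=tuple(frames), residue_positions=positions, scores=scores, units="surrogate"
    )


def sample_state_frames(
    model: StateModel, state: int, n: int = 200, seed: int = 0, policy: str = "stride"
) -> np.ndarray:
    """Extract up to ``n`` frames from one state.

    Default policy ``stride`` takes an evenly strided deterministic subsample
    of the state's member frames; ``random`` draws without replacement using
    the seed.  If the state holds fewer than ``n`` frames, all are returned
    with a warning.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    members = model.members(state)
    m = members.size
    if m == 0:
        raise ValueError(f"state {state} is empty")
    if m <= n:
        if m < n:
            warnings.warn(
                f"state {state} holds only {m} frames (< requested {n}); using all of them",
                stacklevel=2,
            )
        return members
    if policy == "stride":
        idx = np.floor(np.arange(n) * m / n).astype(int)
        return members[idx]
    if policy == "random":
        rng = np.random.default_rng(seed)
        return np.sort(rng.choice(members, size=n, replace=False))
    raise ValueError(f"unknown sampling policy {policy!r}")


def _percentile_ci(samples: np.ndarray, level: float) -> tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def local_energy_summary(
    table: ResidueScoreTable,
    frames,
    neighborhood: ResidueSelection,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> LocalEnergySummary:
    """Neighborhood energy sum per frame, with a percentile-bootstrap CI.

    The bootstrap resamples the per-frame sums (the frames, not the residue
    scores), matching error bars taken over the sampled frames.
    """
    frames = list(frames)
    sums = table.neighborhood_sums(frames, neighborhood)
    rng = np.random.default_rng(seed)
    boot_means = rng.choice(sums, size=(n_boot, sums.size), replace=True).mean(axis=1)
    ci_low, ci_high = _percentile_ci(boot_means, level)
    mean = float(sums.mean())
    return LocalEnergySummary(
        focal=neighborhood.focal,
        neighborhood=neighborhood,
        n_frames_used=len(frames),
        per_frame_sums=sums,
        mean=mean,
        ci_low=min(ci_low, mean),
        ci_high=max(ci_high, mean),
        n_boot=n_boot,
        seed=seed,
        units=table.units,
    )


def compare_variants(
    a: LocalEnergySummary, b: LocalEnergySummary, n_boot: int | None = None, seed: int | None = None
) -> dict:
    """Compare two variants' local-energy summaries at the same focal position.

    Reports the mean difference (b - a), a bootstrap CI of the difference
    from independent resampling of each variant's frame sums, and whether
    the individual CIs overlap.
    """
    if a.focal != b.focal or a.neighborhood.residue_indices != b.neighborhood.residue_indices:
        raise ComparabilityError(
            "summaries cover different focal positions or neighborhoods and cannot be compared"
        )
    if a.units != b.units:
        raise ComparabilityError(f"units differ: {a.units!r} vs {b.units!r}")
    n_boot = n_boot if n_boot is not None else max(a.n_boot, b.n_boot)
    seed = seed if seed is not None else a.seed
    rng = np.random.default_rng(seed)
    boot_a = rng.choice(a.per_frame_sums, size=(n_boot, a.per_frame_sums.size), replace=True).mean(axis=1)
    boot_b = rng.choice(b.per_frame_sums, size=(n_boot, b.per_frame_sums.size), replace=True).mean(axis=1)
    diff = boot_b - boot_a
    ci_low, ci_high = _percentile_ci(diff, 0.95)
    return {
        "focal": a.focal,
        "mean_a": a.mean,
        "mean_b": b.mean,
        "mean_difference": b.mean - a.mean,
        "difference_ci": [ci_low, ci_high],
        "individual_cis_overlap": not (a.ci_high < b.ci_low or b.ci_high < a.ci_low),
        "difference_excludes_zero": ci_low > 0 or ci_high < 0,
        "n_boot": n_boot,
        "seed": seed,
        "units": a.units,
    }
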