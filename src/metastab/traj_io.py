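"""Multi-model PDB trajectories: parsing, writing, and residue bookkeeping.

A conformational ensemble is carried as a :class:`Trajectory` — one shared
topology (ordered atoms) plus an ``n_frames x n_atoms x 3`` coordinate array
in Angstrom.  Frames come from MODEL/ENDMDL blocks of a multi-model PDB file;
a file without MODEL records is read as a single-frame ensemble.

Residue positions are 1-based author numbers as printed in the PDB, and a
residue is identified by ``(chain, residue_index)``.  Only alternate location
indicators ``' '`` and ``'A'`` are kept; insertion codes are rejected because
ensembles from simulation carry neither and silent renumbering would corrupt
every downstream residue selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from metastab.errors import EmptyStructureError, PDBParseError, UnknownResidueError

_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass(frozen=True)
class Atom:
    """One atom of the shared topology.

    ``residue_index`` is the 1-based author residue number; ``is_hetero``
    marks HETATM records (cofactors, solvent), which never count as protein
    residues for neighborhood purposes.
    """

    name: str
    element: str
    residue_index: int
    residue_name: str
    chain: str
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.name!r}: element must be non-empty")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN_ELEMENTS


@dataclass
class Trajectory:
    """Ordered atoms plus frames of 3-D coordinates in Angstrom."""

    atoms: list[Atom]
    frames: np.ndarray  # (n_frames, n_atoms, 3)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if self.frames.shape[1] != len(self.atoms):
            raise ValueError(
                f"frame width {self.frames.shape[1]} != number of atoms {len(self.atoms)}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def heavy_mask(self) -> np.ndarray:
        """Boolean mask over atoms, true for non-hydrogen atoms (frame-independent)."""
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    def residue_ids(self) -> list[tuple[str, int]]:
        """Unique (chain, residue_index) pairs in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.residue_index), None)
        return list(seen)

    def atom_indices(self, residue_index: int, chain: str | None = None, *, heavy_only: bool = False) -> np.ndarray:
        """Atom indices of one residue; chain may be omitted for single-chain files."""
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if a.residue_index == residue_index
            and (chain is None or a.chain == chain)
            and (not heavy_only or a.is_heavy)
        ]
        if not idx and not heavy_only:
            raise UnknownResidueError(f"residue {residue_index} not found" + (f" in chain {chain!r}" if chain else ""))
        return np.array(idx, dtype=int)

    def is_protein_residue(self, residue_index: int, chain: str | None = None) -> bool:
        for a in self.atoms:
            if a.residue_index == residue_index and (chain is None or a.chain == chain):
                return not a.is_hetero
        return False


@dataclass(frozen=True)
class ResidueSelection:
    """A focal position plus the residues that form its contact neighborhood."""

    residue_indices: tuple[int, ...]
    focal: int

    def __post_init__(self) -> None:
        indices = tuple(sorted(set(int(i) for i in self.residue_indices)))
        object.__setattr__(self, "residue_indices", indices)
        if self.focal not in indices:
            raise ValueError(f"focal position {self.focal} must be part of the selection")

    @property
    def neighbors(self) -> tuple[int, ...]:
        """Selection without the focal position, ascending."""
        return tuple(i for i in self.residue_indices if i != self.focal)

    @classmethod
    def from_positions(cls, positions: Iterable[int], focal: int) -> "ResidueSelection":
        return cls(tuple(positions), focal)


# The neighbor sets used in the original CHMO study, keyed by focal position.
# They are ordinary explicit selections; any user list works the same way.
CHMO_NEIGHBORHOODS: dict[int, ResidueSelection] = {
    245: ResidueSelection((62, 239, 242, 243, 244, 245, 246, 247, 250, 433, 434, 437, 510), focal=245),
    288: ResidueSelection((280, 281, 286, 287, 288, 289, 290, 294, 482, 483, 484), focal=288),
}


def _element_from_fields(element_field: str, atom_name: str) -> str:
    """Element symbol from columns 77-78, falling back to the atom name.

    The fallback takes the first alphabetic character of the stripped name,
    which maps names such as ``1HB`` or ``HG12`` to hydrogen.
    """
    element = element_field.strip()
    if element:
        return element[0].upper() + element[1:].lower()
    for ch in atom_name.strip():
        if ch.isalpha():
            return ch.upper()
    raise PDBParseError(f"cannot infer element for atom name {atom_name!r}")


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, tuple[float, float, float]] | None:
    altloc = line[16:17]
    if altloc not in (" ", "A"):
        return None
    icode = line[26:27]
    if icode != " ":
        raise PDBParseError(
            f"line {lineno}: insertion code {icode!r} not supported; renumber the structure first"
        )
    name = line[12:16].strip()
    resname = line[17:20].strip()
    chain = line[21:22].strip()
    try:
        resid = int(line[22:26])
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM record: {line.rstrip()!r}") from exc
    element = _element_from_fields(line[76:78] if len(line) >= 78 else "", name)
    atom = Atom(
        name=name,
        element=element,
        residue_index=resid,
        residue_name=resname,
        chain=chain,
        is_hetero=line.startswith("HETATM"),
    )
    return atom, xyz


def read_multi_model_pdb(path: str | Path) -> Trajectory:
    """Read a (possibly multi-model) PDB file into a :class:`Trajectory`.

    Every MODEL block must contain the same atoms in the same order; a
    mismatch raises :class:`PDBParseError` naming the offending model.
    """
    path = Path(path)
    models: list[list[tuple[Atom, tuple[float, float, float]]]] = []
    current: list[tuple[Atom, tuple[float, float, float]]] = []
    model_numbers: list[int] = []
    in_model = False
    saw_model_record = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6]
            if record == "MODEL ":
                saw_model_record = True
                in_model = True
                current = []
                try:
                    model_numbers.append(int(line[6:].split()[0]))
                except (IndexError, ValueError):
                    model_numbers.append(len(models) + 1)
            elif record == "ENDMDL":
                in_model = False
                models.append(current)
                current = []
            elif record in ("ATOM  ", "HETATM"):
                parsed = _parse_atom_line(line, lineno)
                if parsed is not None:
                    current.append(parsed)
    if not saw_model_record:
        if current:
            models = [current]
            model_numbers = [1]
    elif in_model and current:
        # tolerate a final MODEL without ENDMDL
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise EmptyStructureError(f"{path}: no ATOM records found")

    reference = [a for a, _ in models[0]]
    n_atoms = len(reference)
    coords = np.empty((len(models), n_atoms, 3), dtype=float)
    for m, block in enumerate(models):
        number = model_numbers[m] if m < len(model_numbers) else m + 1
        if len(block) != n_atoms:
            raise PDBParseError(
                f"{path}: MODEL {number} has {len(block)} atoms, expected {n_atoms} (as in MODEL {model_numbers[0] if model_numbers else 1})"
            )
        for i, (atom, xyz) in enumerate(block):
            ref = reference[i]
            if (atom.name, atom.residue_index, atom.residue_name, atom.chain) != (
                ref.name,
                ref.residue_index,
                ref.residue_name,
                ref.chain,
            ):
                raise PDBParseError(
                    f"{path}: MODEL {number} atom {i + 1} is {atom.name}/{atom.residue_name}{atom.residue_index}, "
                    f"expected {ref.name}/{ref.residue_name}{ref.residue_index}"
                )
            coords[m, i] = xyz
    return Trajectory(atoms=reference, frames=coords)


def _format_atom_line(serial: int, atom: Atom, xyz: Sequence[float]) -> str:
    record = "HETATM" if atom.is_hetero else "ATOM  "
    name = atom.name
    # PDB convention: 1-3 char names start in column 14 unless 2-char element
    if len(name) < 4 and len(atom.element) < 2:
        name = f" {name}"
    return (
        f"{record}{serial:>5d} {name:<4s} {atom.residue_name:<3s} {atom.chain or 'A':1s}"
        f"{atom.residue_index:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element.upper():>2s}\n"
    )


def write_frame_pdb(traj: Trajectory, frame: int, path: str | Path) -> None:
    """Write one frame of the trajectory as a single-model PDB file.

    Coordinates are serialized at the fixed-format precision of 3 decimals,
    so a read/write round-trip agrees to 0.001 Angstrom.
    """
    if not 0 <= frame < traj.n_frames:
        raise IndexError(f"frame {frame} out of range [0, {traj.n_frames})")
    path = Path(path)
    with path.open("w") as fh:
        for i, atom in enumerate(traj.atoms):
            fh.write(_format_atom_line(i + 1, atom, traj.frames[frame, i]))
        fh.write("END\n")


def write_multi_model_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write the full ensemble as MODEL/ENDMDL blocks."""
    path = Path(path)
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL {f + 1:>8d}\n")
            for i, atom in enumerate(traj.atoms):
                fh.write(_format_atom_line(i + 1, atom, traj.frames[f, i]))
            fh.write("ENDMDL\n")
        fh.write("END\n")
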