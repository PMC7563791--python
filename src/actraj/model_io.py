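"""Structures, trajectories, PDB input/output and the atom-selection language.

The data model is deliberately small: an :class:`Atom` carries identity plus a
van der Waals radius assigned at load time (surface calculations need it), a
:class:`Structure` is an ordered list of atoms, and a :class:`Trajectory` is a
stack of coordinate frames sharing one topology with an explicit frame interval
in nanoseconds (multi-model PDB carries no time information, so ``dt_ns`` is
always supplied by the caller).

Selections reproduce the vocabulary used throughout adenylyl-cyclase trajectory
analysis: "backbone atoms" (N, CA, C, O), "heavy atoms" (element != H),
C-alpha-only, and inclusive author-numbered residue ranges such as 408-420.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "SelectionSpec",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "resolve_selection",
    "DEFAULT_RADII",
    "DEFAULT_RADIUS",
    "BACKBONE_ATOMS",
    "PDBParseError",
    "EmptyStructureError",
    "TopologyMismatchError",
    "EmptySelectionError",
    "FormatOverflowError",
    "InsertionCodeError",
]

# Chothia-style united-atom radii (Å); overridable per call/config.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "H": 1.00,
}
DEFAULT_RADIUS = 1.80

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

# Two-letter element symbols that occur in protein/ligand PDB files and are
# recognised when the atom name starts in column 13 (the PDB convention for
# two-letter elements).
_TWO_LETTER_ELEMENTS = frozenset(
    {"MG", "FE", "ZN", "MN", "CA", "NA", "CL", "BR", "CU", "NI", "CO", "SE", "CD", "HG"}
)


class PDBParseError(ValueError):
    """A PDB record could not be parsed; the message names the offending line."""


class EmptyStructureError(ValueError):
    """A file or operation yielded a structure with zero atoms."""


class TopologyMismatchError(ValueError):
    """Models of a multi-model PDB disagree on atom count/identity."""


class EmptySelectionError(ValueError):
    """A selection resolved to zero atoms."""


class FormatOverflowError(ValueError):
    """A coordinate does not fit the fixed-column PDB coordinate field."""


class InsertionCodeError(ValueError):
    """Residue insertion codes are not supported by this toolkit."""


@dataclasses.dataclass(frozen=True)
class Atom:
    """One atom with author-numbered identity and a van der Waals radius."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: tuple[float, float, float]
    vdw_radius: float

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.serial} {self.name!r}: empty element")
        if not self.vdw_radius > 0:
            raise ValueError(f"atom {self.serial} {self.name!r}: vdw_radius must be > 0")
        if not all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial} {self.name!r}: non-finite position")

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity triple (chain_id, residue_number, name)."""
        return (self.chain_id, self.residue_number, self.name)

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


class Structure:
    """An ordered set of atoms (one snapshot or an average structure)."""

    def __init__(self, atoms: Sequence[Atom], metadata: Mapping[str, object] | None = None):
        atoms = list(atoms)
        if not atoms:
            raise EmptyStructureError("a Structure needs at least one atom")
        seen: set[tuple[str, int, str]] = set()
        for a in atoms:
            if a.key in seen:
                raise ValueError(f"duplicate atom identity {a.key}")
            seen.add(a.key)
        self.atoms: list[Atom] = atoms
        self.metadata: dict[str, object] = dict(metadata or {})
        self._coords: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        chains = sorted({a.chain_id for a in self.atoms})
        return f"<Structure {len(self)} atoms, chains {''.join(chains)}>"

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å (cached; treat as read-only)."""
        if self._coords is None:
            self._coords = np.array([a.position for a in self.atoms], dtype=float)
        return self._coords

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, residue_number) keys in atom order."""
        out: list[tuple[str, int]] = []
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            if a.residue_key not in seen:
                seen.add(a.residue_key)
                out.append(a.residue_key)
        return out

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self), 3):
            raise ValueError(f"expected coords of shape {(len(self), 3)}, got {coords.shape}")
        atoms = [
            dataclasses.replace(a, position=tuple(float(x) for x in xyz))
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms, self.metadata)

    def subset(self, indices: Iterable[int]) -> "Structure":
        return Structure([self.atoms[i] for i in indices], self.metadata)


@dataclasses.dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    ``t0_ns`` implements the equilibration offset: the time stamp of frame *i*
    is ``t0_ns + i * dt_ns``.
    """

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    dt_ns: float
    t0_ns: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (len(self.topology), 3):
            raise TopologyMismatchError(
                f"frames of shape {self.frames.shape} do not match topology with "
                f"{len(self.topology)} atoms"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("a Trajectory needs at least one frame")
        if not self.dt_ns > 0:
            raise ValueError("dt_ns must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times_ns(self) -> np.ndarray:
        return self.t0_ns + self.dt_ns * np.arange(self.n_frames)

    def frame_structure(self, index: int) -> Structure:
        return self.topology.with_coords(self.frames[index])

    def sliced(self, start: int, stop: int | None = None) -> "Trajectory":
        """Frames ``start:stop`` with the time origin shifted accordingly."""
        frames = self.frames[start:stop]
        if frames.shape[0] == 0:
            raise ValueError("slice selects zero frames")
        return Trajectory(self.topology, frames.copy(), self.dt_ns, self.t0_ns + start * self.dt_ns)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_ATOM_CLASSES = ("all", "heavy", "backbone", "calpha", "named")


@dataclasses.dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom subset.

    ``chains=None`` means all chains; ``residue_ranges=None`` means all
    residues; ranges are 1-based inclusive on author numbering, matching the
    usual "408-420" notation.
    """

    chains: frozenset[str] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_class: str = "all"
    atom_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.atom_class not in _ATOM_CLASSES:
            raise ValueError(f"unknown atom_class {self.atom_class!r}; one of {_ATOM_CLASSES}")
        if self.atom_class == "named" and not self.atom_names:
            raise ValueError("atom_class 'named' requires atom_names")
        if self.residue_ranges is not None:
            for lo, hi in self.residue_ranges:
                if lo > hi:
                    raise ValueError(f"residue range {lo}-{hi} has start > end")

    @classmethod
    def parse(cls, text: str) -> "SelectionSpec":
        """Parse selection strings like ``chain=A; resid=408-420,468-475; atoms=backbone``."""
        chains: frozenset[str] | None = None
        ranges: tuple[tuple[int, int], ...] | None = None
        atom_class = "all"
        names: tuple[str, ...] | None = None
        for part in text.split(";"):
            part = part.strip()
            if not part:
                continue
            if "=" not in part:
                raise ValueError(f"cannot parse selection fragment {part!r} in {text!r}")
            key, _, value = part.partition("=")
            key, value = key.strip().lower(), value.strip()
            if key == "chain":
                chains = None if value.lower() == "all" else frozenset(value.replace(",", " ").split())
            elif key == "resid":
                if value.lower() == "all":
                    ranges = None
                else:
                    out = []
                    for token in value.split(","):
                        token = token.strip()
                        m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", token)
                        if not m:
                            raise ValueError(f"cannot parse residue range {token!r} in {text!r}")
                        lo = int(m.group(1))
                        hi = int(m.group(2)) if m.group(2) else lo
                        out.append((lo, hi))
                    ranges = tuple(out)
            elif key == "atoms":
                if value.lower().startswith("named:"):
                    atom_class = "named"
                    names = tuple(n.strip().upper() for n in value[6:].split(",") if n.strip())
                else:
                    atom_class = value.lower()
            else:
                raise ValueError(f"unknown selection key {key!r} in {text!r}")
        return cls(chains=chains, residue_ranges=ranges, atom_class=atom_class, atom_names=names)

    def describe(self) -> str:
        chains = "all" if self.chains is None else ",".join(sorted(self.chains))
        resid = (
            "all"
            if self.residue_ranges is None
            else ",".join(f"{lo}-{hi}" for lo, hi in self.residue_ranges)
        )
        atoms = self.atom_class if self.atom_class != "named" else "named:" + ",".join(self.atom_names or ())
        return f"chain={chains}; resid={resid}; atoms={atoms}"


def resolve_selection(structure: Structure, spec: SelectionSpec) -> np.ndarray:
    """Deterministic ordered atom indices matching *spec* on *structure*."""
    mask = np.ones(len(structure), dtype=bool)
    atoms = structure.atoms
    if spec.chains is not None:
        mask &= np.array([a.chain_id in spec.chains for a in atoms])
    if spec.residue_ranges is not None:
        mask &= np.array(
            [any(lo <= a.residue_number <= hi for lo, hi in spec.residue_ranges) for a in atoms]
        )
    if spec.atom_class == "heavy":
        mask &= np.array([a.is_heavy for a in atoms])
    elif spec.atom_class == "backbone":
        mask &= np.array([a.name in BACKBONE_ATOMS for a in atoms])
    elif spec.atom_class == "calpha":
        mask &= np.array([a.name == "CA" and a.element.upper() == "C" for a in atoms])
    elif spec.atom_class == "named":
        names = set(spec.atom_names or ())
        mask &= np.array([a.name in names for a in atoms])
    indices = np.nonzero(mask)[0]
    if indices.size == 0:
        raise EmptySelectionError(f"selection resolves to zero atoms: {spec.describe()}")
    return indices


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------


def _infer_element(raw_name: str, residue_name: str) -> str:
    """Element from a 4-character PDB atom-name field when cols 77-78 are blank.

    Two-letter elements (MG, FE, ...) start in column 13; ordinary protein
    atoms start in column 14 and their element is the first letter of the name.
    """
    name = raw_name.strip()
    if raw_name[:1] not in (" ", "") and len(name) >= 2 and name[:2].upper() in _TWO_LETTER_ELEMENTS:
        return name[:2].upper().capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {raw_name!r}")


def _assign_radius(element: str, radii_table: Mapping[str, float], default: float) -> float:
    return float(radii_table.get(element.upper(), radii_table.get(element.capitalize(), default)))


def _parse_atom_line(
    line: str, lineno: int, radii_table: Mapping[str, float], default_radius: float
) -> Atom | None:
    """Parse one ATOM/HETATM record; returns None for dropped altlocs."""
    line = line.rstrip("\n")
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: record too short for coordinates: {line!r}")
    altloc = line[16]
    if altloc not in (" ", "A"):
        return None
    icode = line[26]
    if icode != " ":
        raise InsertionCodeError(f"line {lineno}: residue insertion code {icode!r} unsupported")
    try:
        serial = int(line[6:11])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: bad serial field {line[6:11]!r}") from exc
    raw_name = line[12:16]
    name = raw_name.strip()
    residue_name = line[17:20].strip()
    chain_id = line[21]
    try:
        residue_number = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: bad residue number {line[22:26]!r}") from exc
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(
            f"line {lineno}: malformed coordinate field in {line[30:54]!r}"
        ) from exc
    element = line[76:78].strip() if len(line) >= 77 else ""
    if not element:
        try:
            element = _infer_element(raw_name, residue_name)
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: {exc}") from exc
    element = element.capitalize() if len(element) == 2 else element.upper()
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=residue_name,
        residue_number=residue_number,
        chain_id=chain_id,
        position=(x, y, z),
        vdw_radius=_assign_radius(element, radii_table, default_radius),
    )


def read_pdb(
    path: str | Path,
    radii_table: Mapping[str, float] | None = None,
    default_radius: float = DEFAULT_RADIUS,
) -> Structure:
    """Read a single-model PDB file.

    Altloc identifiers other than blank/'A' are dropped; elements come from
    columns 77-78, falling back to atom-name heuristics; van der Waals radii
    are assigned from *radii_table* (Chothia-style united radii by default)
    with *default_radius* for unknown elements.
    """
    radii_table = dict(DEFAULT_RADII if radii_table is None else radii_table)
    path = Path(path)
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                atom = _parse_atom_line(line, lineno, radii_table, default_radius)
                if atom is not None:
                    atoms.append(atom)
            elif line.startswith("ENDMDL"):
                break  # single-model read: stop after the first model
    if not atoms:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms, metadata={"source": str(path)})


def _format_atom_line(atom: Atom, serial: int) -> str:
    for coord in atom.position:
        if abs(coord) >= 10000 or coord <= -1000:
            raise FormatOverflowError(
                f"coordinate {coord:.3f} of atom {atom.key} does not fit the PDB field"
            )
    name = atom.name
    if len(name) < 4 and len(atom.element) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    element_field = f"{atom.element.upper():>2s}"
    x, y, z = atom.position
    return (
        f"ATOM  {serial:>5d} {name_field} {atom.residue_name:>3s} {atom.chain_id}"
        f"{atom.residue_number:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element_field}"
    )


def _model_lines(structure: Structure, start_serial: int = 1) -> list[str]:
    lines: list[str] = []
    serial = start_serial
    prev_chain: str | None = None
    for atom in structure.atoms:
        if prev_chain is not None and atom.chain_id != prev_chain:
            lines.append("TER")
        lines.append(_format_atom_line(atom, serial))
        serial += 1
        prev_chain = atom.chain_id
    return lines


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write fixed-column ATOM records with TER between chains and END."""
    lines = _model_lines(structure)
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB, one MODEL/ENDMDL block per frame."""
    lines: list[str] = []
    for i in range(trajectory.n_frames):
        lines.append(f"MODEL {i + 1:>8d}")
        lines.extend(_model_lines(trajectory.frame_structure(i)))
        lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(
    path: str | Path,
    dt_ns: float,
    t0_ns: float = 0.0,
    radii_table: Mapping[str, float] | None = None,
    default_radius: float = DEFAULT_RADIUS,
) -> Trajectory:
    """Read a multi-model PDB as a Trajectory.

    The topology comes from the first model; every subsequent model must have
    the same atom count. A file without MODEL records is read as one frame.
    """
    radii = dict(DEFAULT_RADII if radii_table is None else radii_table)
    path = Path(path)
    models: list[list[Atom]] = []
    current: list[Atom] | None = None
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("MODEL"):
                saw_model = True
                current = []
            elif line.startswith("ENDMDL"):
                if current:
                    models.append(current)
                current = None
            elif line.startswith(("ATOM  ", "HETATM")):
                atom = _parse_atom_line(line, lineno, radii, default_radius)
                if atom is None:
                    continue
                if current is None:
                    if saw_model:
                        raise PDBParseError(f"line {lineno}: ATOM record outside MODEL block")
                    current = []
                    saw_model = False
                current.append(atom)
    if current:
        models.append(current)
    if not models:
        raise EmptyStructureError(f"{path}: no models with atoms found")
    n0 = len(models[0])
    for i, model in enumerate(models[1:], start=2):
        if len(model) != n0:
            raise TopologyMismatchError(
                f"{path}: model {i} has {len(model)} atoms, expected {n0} (from model 1)"
            )
    topology = Structure(models[0], metadata={"source": str(path)})
    frames = np.array([[a.position for a in model] for model in models], dtype=float)
    return Trajectory(topology, frames, dt_ns=dt_ns, t0_ns=t0_ns)
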