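"""Structure and trajectory I/O in PDB dialects, plus atom selection.

Reads fixed-width PDB v3.3 ATOM/HETATM/MODEL records into lightweight
in-memory containers, writes multi-MODEL PDB trajectories, and supports a
trivial whitespace ``xyz-table`` dialect (``frame atom_index x y z`` with a
header line) for fixture authoring.

Author (PDB) residue numbering is the single numbering used everywhere;
no renumbering is ever applied.  Alternate locations keep the
highest-occupancy conformer (ties resolve to 'A').
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "Selection",
    "ChainMap",
    "PDBParseError",
    "EmptySelectionError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "resolve_selection",
]


class PDBParseError(ValueError):
    """Malformed PDB content; the message names the offending line."""


class EmptySelectionError(ValueError):
    """A selection required to match at least one atom matched none."""


# Two-letter element symbols that occur in protein PDB files; used when the
# element column (77-78) is blank and we must infer from the atom-name field.
_TWO_LETTER_ELEMENTS = {
    "FE", "ZN", "CA", "MG", "NA", "CL", "MN", "CU", "CO", "NI", "BR", "SE", "CD", "HG",
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus position in Angstrom.

    ``atom_name`` follows the PDB column 13-16 convention ("CA", "OE1", ...).
    The key (chain_id, residue_number, atom_name, alt_loc) is unique within
    a model.
    """

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    element: str
    position: np.ndarray
    alt_loc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_name}: non-finite position")
        if not self.element:
            raise ValueError(f"atom {self.atom_name}: empty element")
        object.__setattr__(self, "position", pos)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.atom_name)


class Structure:
    """An ordered collection of atoms (one model).

    Atom order is stable; lookup by (chain, residue_number, atom_name)
    returns at most one atom.
    """

    def __init__(self, atoms, source_id: str = "", model_number: int = 1):
        self.atoms: list[AtomRecord] = list(atoms)
        self.source_id = source_id
        self.model_number = model_number
        self._index: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(self.atoms):
            if a.key in self._index:
                raise ValueError(
                    f"duplicate atom key {a.key} within one model"
                )
            self._index[a.key] = i

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(A, 3) coordinate array in atom order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def index_of(self, chain_id: str, residue_number: int, atom_name: str) -> int:
        """Topology index of one atom; KeyError naming the atom if absent."""
        try:
            return self._index[(chain_id, residue_number, atom_name)]
        except KeyError:
            raise KeyError(
                f"atom {atom_name} of residue {residue_number} chain "
                f"{chain_id!r} not in structure"
            ) from None

    def has_atom(self, chain_id: str, residue_number: int, atom_name: str) -> bool:
        return (chain_id, residue_number, atom_name) in self._index

    def residue_numbers(self, chain_id: str | None = None) -> list[int]:
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            if chain_id is None or a.chain_id == chain_id:
                seen.setdefault((a.chain_id, a.residue_number))
        return [rn for (_, rn) in seen]

    def residue_atoms(self, chain_id: str, residue_number: int) -> list[int]:
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.chain_id == chain_id and a.residue_number == residue_number
        ]

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape does not match atom count")
        atoms = [replace(a, position=coords[i]) for i, a in enumerate(self.atoms)]
        return Structure(atoms, self.source_id, self.model_number)

    def subset(self, indices) -> "Structure":
        return Structure(
            [self.atoms[i] for i in indices], self.source_id, self.model_number
        )


class Trajectory:
    """A topology plus F frames of coordinates (Angstrom).

    Every frame has exactly one position per topology atom, in topology
    order.  ``frame_times`` (ns), if given, is strictly increasing.
    """

    def __init__(self, topology: Structure, frames: np.ndarray, frame_times=None):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[1:] != (len(topology), 3):
            raise ValueError(
                f"frames must be (F, {len(topology)}, 3); got {frames.shape}"
            )
        if frames.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if frame_times is not None:
            frame_times = np.asarray(frame_times, dtype=float)
            if frame_times.shape != (frames.shape[0],):
                raise ValueError("frame_times length must equal frame count")
            if np.any(np.diff(frame_times) <= 0):
                raise ValueError("frame_times must be strictly increasing")
        self.topology = topology
        self.frames = frames
        self.frame_times = frame_times

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def frame_structure(self, frame: int) -> Structure:
        return self.topology.with_coords(self.frames[frame])


@dataclass(frozen=True)
class Selection:
    """Declarative atom selection resolved against a Structure.

    Criteria combine with AND; a None criterion matches everything.
    Resolution is deterministic and order-preserving (topology order).
    """

    chain: str | None = None
    residue_range: tuple[int, int] | None = None
    residue_set: frozenset[int] | None = None
    atom_names: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if lo > hi:
                raise ValueError("residue_range must be (low, high) inclusive")
        if self.residue_set is not None:
            object.__setattr__(self, "residue_set", frozenset(self.residue_set))
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", frozenset(self.atom_names))


@dataclass(frozen=True)
class ChainMap:
    """Role -> chain-letter mapping for the three troponin subunits.

    The source structures do not document which chain letter holds which
    subunit, so this is mandatory user configuration with no default.
    ``calcium_het_names`` lists HETATM residue names treated as Ca ions.
    """

    tnc: str
    tni: str | None = None
    tnt: str | None = None
    calcium_het_names: frozenset[str] = field(default_factory=lambda: frozenset({"CA"}))

    def validate_against(self, struct: Structure) -> None:
        chains = {a.chain_id for a in struct.atoms}
        for role, ch in (("TnC", self.tnc), ("TnI", self.tni), ("TnT", self.tnt)):
            if ch is not None and ch not in chains:
                raise ValueError(
                    f"chain {ch!r} mapped to role {role} not present; "
                    f"structure has chains {sorted(chains)}"
                )


def _infer_element(raw_name: str, residue_name: str, hetero: bool) -> str:
    """Infer the element from the 4-character atom-name field.

    PDB convention: a one-letter element's name starts in column 14, so the
    field begins with a space ('' CA '' is an alpha carbon); a two-letter
    element fills columns 13-14 ('CA  ' on a HETATM is a calcium ion).
    """
    name = raw_name.strip()
    if not name:
        return ""
    two = raw_name[:2].strip().upper()
    if len(raw_name) >= 2 and raw_name[0] not in (" ", "") and two in _TWO_LETTER_ELEMENTS:
        return two.capitalize()
    if hetero and name.upper() in _TWO_LETTER_ELEMENTS and name.upper() == residue_name.strip().upper():
        return name.upper().capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, float]:
    """Parse one ATOM/HETATM line; returns (record, occupancy)."""
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError(f"line {lineno}: ATOM/HETATM record shorter than 54 columns")
    try:
        serial = int(line[6:11])
    except ValueError:
        # serial may overflow to '*****'; fall back to a sentinel
        serial = -1
    raw_name = line[12:16]
    alt_loc = line[16].strip()
    residue_name = line[17:20].strip()
    chain_id = line[21].strip() or " "
    try:
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed fixed-width field ({exc})") from None
    try:
        occupancy = float(line[54:60]) if len(line) >= 60 and line[54:60].strip() else 1.0
    except ValueError:
        occupancy = 1.0
    hetero = line.startswith("HETATM")
    element = line[76:78].strip() if len(line) >= 78 else ""
    if element:
        element = element.capitalize()
    else:
        element = _infer_element(raw_name, residue_name, hetero)
    if not element:
        raise PDBParseError(f"line {lineno}: cannot infer element for atom {raw_name!r}")
    rec = AtomRecord(
        serial=serial,
        atom_name=raw_name.strip(),
        residue_name=residue_name,
        chain_id=chain_id,
        residue_number=residue_number,
        element=element,
        position=np.array([x, y, z]),
        alt_loc=alt_loc,
        is_hetero=hetero,
    )
    return rec, occupancy


def _dedupe_altlocs(records: list[tuple[AtomRecord, float]]) -> list[AtomRecord]:
    """Keep one conformer per atom key: highest occupancy, ties -> 'A'."""
    best: dict[tuple[str, int, str], tuple[AtomRecord, float]] = {}
    order: list[tuple[str, int, str]] = []
    for rec, occ in records:
        k = rec.key
        if k not in best:
            best[k] = (rec, occ)
            order.append(k)
        else:
            cur, cur_occ = best[k]
            if occ > cur_occ or (occ == cur_occ and (rec.alt_loc or "Z") < (cur.alt_loc or "Z")):
                best[k] = (rec, occ)
    return [best[k][0] for k in order]


def _split_models(path: str) -> dict[int, list[tuple[AtomRecord, float]]]:
    models: dict[int, list[tuple[AtomRecord, float]]] = {}
    current: int | None = None
    saw_model_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("MODEL"):
                saw_model_record = True
                try:
                    current = int(line.split()[1])
                except (IndexError, ValueError):
                    raise PDBParseError(f"line {lineno}: malformed MODEL record")
                models.setdefault(current, [])
            elif line.startswith("ENDMDL"):
                current = None
            elif line.startswith(("ATOM", "HETATM")):
                rec = _parse_atom_line(line, lineno)
                if saw_model_record and current is None:
                    # atom outside MODEL framing after models started: attach to model 1
                    models.setdefault(1, []).append(rec)
                else:
                    models.setdefault(current if current is not None else 1, []).append(rec)
    if not models or all(len(v) == 0 for v in models.values()):
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    return models


def read_structure(path: str, model: int = 1) -> Structure:
    """Read one MODEL of a PDB file.

    Elements come from the element column when present, otherwise from the
    atom-name field (so a HETATM named ``CA`` is calcium while a backbone
    ``CA`` is carbon).  Calcium ions are retained.
    """
    models = _split_models(str(path))
    if model not in models:
        raise PDBParseError(
            f"{path}: MODEL {model} not present; available models: "
            f"{sorted(models)}"
        )
    atoms = _dedupe_altlocs(models[model])
    return Structure(atoms, source_id=str(path), model_number=model)


def read_trajectory(
    path: str,
    format: str = "multi-model-pdb",
    topology: Structure | None = None,
) -> Trajectory:
    """Read a trajectory.

    ``multi-model-pdb``: F = number of MODEL blocks (a single-model file is
    a 1-frame trajectory); topology from the first model; every model must
    share atom count and order.

    ``xyz-table``: whitespace-separated ``frame atom_index x y z`` rows
    after one header line.  The dialect carries no chemistry, so pass
    ``topology`` to attach one; otherwise placeholder carbon pseudo-atoms
    are synthesised.
    """
    if format == "multi-model-pdb":
        models = _split_models(str(path))
        keys = sorted(models)
        first = _dedupe_altlocs(models[keys[0]])
        topo = Structure(first, source_id=str(path), model_number=keys[0])
        frames = np.empty((len(keys), len(topo), 3))
        for fi, mk in enumerate(keys):
            atoms = _dedupe_altlocs(models[mk])
            if len(atoms) != len(topo):
                raise PDBParseError(
                    f"{path}: MODEL {mk} has {len(atoms)} atoms, expected "
                    f"{len(topo)} (model index {fi})"
                )
            for ai, (a, ref) in enumerate(zip(atoms, topo.atoms)):
                if a.key != ref.key:
                    raise PDBParseError(
                        f"{path}: MODEL {mk} atom order differs at index {ai}: "
                        f"{a.key} vs {ref.key}"
                    )
                frames[fi, ai] = a.position
        return Trajectory(topo, frames)
    elif format == "xyz-table":
        data = np.loadtxt(str(path), skiprows=1, ndmin=2)
        if data.shape[1] != 5:
            raise PDBParseError(f"{path}: xyz-table needs 5 columns (frame atom x y z)")
        frame_ids = data[:, 0].astype(int)
        atom_ids = data[:, 1].astype(int)
        uniq_frames = np.unique(frame_ids)
        n_atoms = int(atom_ids.max()) + 1
        if topology is not None and len(topology) != n_atoms:
            raise ValueError(
                f"{path}: xyz-table has {n_atoms} atoms but topology has "
                f"{len(topology)}"
            )
        frames = np.full((len(uniq_frames), n_atoms, 3), np.nan)
        for row, f in enumerate(frame_ids):
            fi = int(np.searchsorted(uniq_frames, f))
            frames[fi, atom_ids[row]] = data[row, 2:5]
        if np.any(~np.isfinite(frames)):
            raise PDBParseError(f"{path}: xyz-table is missing atom rows in some frame")
        if topology is None:
            topology = Structure(
                [
                    AtomRecord(i + 1, "CA", "UNK", "A", i + 1, "C", frames[0, i])
                    for i in range(n_atoms)
                ],
                source_id=str(path),
            )
        return Trajectory(topology, frames)
    raise ValueError(f"unknown trajectory format {format!r}")


_PDB_COORD_MIN, _PDB_COORD_MAX = -999.999, 9999.999


def _format_atom_line(a: AtomRecord, serial: int) -> str:
    for c in a.position:
        if not (_PDB_COORD_MIN <= c <= _PDB_COORD_MAX):
            raise ValueError(
                f"coordinate {c:g} of atom {a.key} exceeds the PDB fixed "
                "field width (-999.999..9999.999 A)"
            )
    record = "HETATM" if a.is_hetero else "ATOM  "
    name = a.atom_name
    # column-13 convention: one-letter elements start in column 14
    if len(name) < 4 and len(a.element) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    elem = a.element.upper() if len(a.element) == 1 else a.element.capitalize().upper()
    return (
        f"{record}{serial:>5d} {name_field}{(a.alt_loc or ' ')[:1]}"
        f"{a.residue_name:>3s} {a.chain_id[:1]}{a.residue_number:>4d}    "
        f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.element.upper():>2s}\n"
    )


def write_structure(struct: Structure, path: str) -> None:
    """Write a single-model PDB file."""
    with open(path, "w") as fh:
        for i, a in enumerate(struct.atoms, start=1):
            fh.write(_format_atom_line(a, i))
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path: str, format: str = "multi-model-pdb") -> None:
    """Write a trajectory as multi-MODEL PDB or as an xyz-table.

    Coordinates use the PDB fixed-width 3-decimal convention; a coordinate
    that cannot be represented raises instead of truncating silently.
    """
    if format == "multi-model-pdb":
        with open(path, "w") as fh:
            for fi in range(traj.n_frames):
                fh.write(f"MODEL {fi + 1:>8d}\n")
                for ai, a in enumerate(traj.topology.atoms, start=1):
                    rec = replace(a, position=traj.frames[fi, ai - 1])
                    fh.write(_format_atom_line(rec, ai))
                fh.write("ENDMDL\n")
            fh.write("END\n")
    elif format == "xyz-table":
        with open(path, "w") as fh:
            fh.write("frame atom_index x y z\n")
            for fi in range(traj.n_frames):
                for ai in range(len(traj.topology)):
                    x, y, z = traj.frames[fi, ai]
                    fh.write(f"{fi} {ai} {x:.3f} {y:.3f} {z:.3f}\n")
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def resolve_selection(
    struct: Structure,
    sel: Selection,
    require_nonempty: bool = False,
) -> np.ndarray:
    """Resolve a Selection to topology indices (topology order, deterministic).

    Residues requested by number but absent from the structure are skipped;
    a single warning reports how many were missing (crystal structures
    routinely have unresolved residues).
    """
    if len(struct) == 0:
        raise ValueError("cannot resolve a selection against an empty structure")
    idx = []
    for i, a in enumerate(struct.atoms):
        if sel.chain is not None and a.chain_id != sel.chain:
            continue
        if sel.residue_range is not None and not (
            sel.residue_range[0] <= a.residue_number <= sel.residue_range[1]
        ):
            continue
        if sel.residue_set is not None and a.residue_number not in sel.residue_set:
            continue
        if sel.atom_names is not None and a.atom_name not in sel.atom_names:
            continue
        idx.append(i)

    requested: set[int] | None = None
    if sel.residue_set is not None:
        requested = set(sel.residue_set)
    elif sel.residue_range is not None:
        requested = set(range(sel.residue_range[0], sel.residue_range[1] + 1))
    if requested is not None:
        present = {
            a.residue_number
            for a in struct.atoms
            if sel.chain is None or a.chain_id == sel.chain
        }
        missing = requested - present
        if missing:
            warnings.warn(
                f"selection skipped {len(missing)} residue(s) absent from the "
                f"structure: {sorted(missing)[:10]}{'...' if len(missing) > 10 else ''}",
                stacklevel=2,
            )
    if require_nonempty and not idx:
        raise EmptySelectionError(f"selection {sel} matched no atoms")
    return np.asarray(idx, dtype=int)
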