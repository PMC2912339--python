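"""Structures, trajectories, atom selections and force-field parameter tables.

The in-memory model is deliberately small: a :class:`Topology` (ordered atom
metadata), a :class:`Trajectory` (topology plus a stack of coordinate frames in
Å), and a :class:`Selection` (an ordered, duplicate-free list of atom indices).
Two on-disk dialects are supported:

* multi-model PDB (``MODEL``/``ENDMDL`` blocks, one block per frame), and
* a plain-text *frame dump* — a cheap format for synthetic trajectories::

      # trajscope frame-dump
      natoms 5
      frame 0.0
      x y z          (natoms lines, Å)
      frame 2.0
      ...

Units are fixed globally: Å, ps, kcal/mol, elementary charges, amu, degrees.
Residue numbering is 1-based (as in PDB); atom indexing is 0-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "Trajectory",
    "Selection",
    "ParameterTable",
    "read_structure",
    "write_structure",
    "select",
    "selection_from_indices",
    "assign_parameters",
    "read_parameter_table",
    "write_parameter_table",
]


@dataclass
class AtomRecord:
    """One atom's metadata; coordinates live on the trajectory frames."""

    serial: int
    name: str
    residue_name: str
    residue_id: int
    chain_id: str = "A"
    element: str = ""
    occupancy: float = 1.0
    temp_factor: float = 0.0
    charge: float | None = None          # e
    lj_sigma: float | None = None        # Å
    lj_epsilon: float | None = None      # kcal/mol
    born_radius: float | None = None     # Å
    vdw_radius: float | None = None      # Å
    mass: float = 12.0                   # amu

    def __post_init__(self) -> None:
        if self.residue_id < 1:
            raise ValueError(f"residue_id must be >= 1, got {self.residue_id}")
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive when set")


@dataclass
class Topology:
    """Ordered atom list with per-atom molecule labels.

    ``molecule_labels`` tags each atom as e.g. ``protein``, ``guide-RNA``,
    ``target-RNA``, ``water`` or ``ion``; solvent handling throughout the
    package is label-based only.
    """

    atoms: list[AtomRecord]
    molecule_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.molecule_labels:
            self.molecule_labels = ["protein"] * len(self.atoms)
        if len(self.molecule_labels) != len(self.atoms):
            raise ValueError("molecule_labels length must match atom count")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        q = [a.charge if a.charge is not None else np.nan for a in self.atoms]
        return np.array(q, dtype=float)


@dataclass
class Trajectory:
    """A topology plus an ordered stack of coordinate frames (N × 3, Å)."""

    topology: Topology
    frames: np.ndarray                    # (n_frames, n_atoms, 3)
    time_step: float = 2.0                # ps between stored frames
    frame_times: np.ndarray | None = None  # ps

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology ({self.topology.n_atoms})"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame coordinates must be finite")
        if self.frame_times is None:
            self.frame_times = np.arange(self.n_frames, dtype=float) * self.time_step
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if len(self.frame_times) != self.n_frames:
                raise ValueError("frame_times length must equal frame count")
            if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
                raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class Selection:
    """Ordered, duplicate-free atom indices into a topology."""

    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("selection indices must not repeat")

    def __len__(self) -> int:
        return len(self.indices)

    def asarray(self) -> np.ndarray:
        return np.array(self.indices, dtype=int)


# ---------------------------------------------------------------------------
# PDB dialect

_PDB_COORD_SLICES = (slice(30, 38), slice(38, 46), slice(46, 54))


def _parse_pdb_atom(line: str, lineno: int) -> tuple[AtomRecord, np.ndarray]:
    if len(line) < 54:
        raise ValueError(f"line {lineno}: ATOM record too short")
    if line[26].strip():
        raise ValueError(f"line {lineno}: insertion codes are not supported")
    try:
        xyz = np.array([float(line[s]) for s in _PDB_COORD_SLICES])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: unparsable coordinate field") from exc
    try:
        serial = int(line[6:11])
        resid = int(line[22:26])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: unparsable serial/residue field") from exc
    occ = line[54:60].strip()
    bf = line[60:66].strip()
    rec = AtomRecord(
        serial=serial,
        name=line[12:16].strip(),
        residue_name=line[17:20].strip(),
        residue_id=resid,
        chain_id=line[21].strip() or "A",
        element=line[76:78].strip() if len(line) >= 78 else "",
        occupancy=float(occ) if occ else 1.0,
        temp_factor=float(bf) if bf else 0.0,
    )
    return rec, xyz


def _read_pdb(path: Path) -> Trajectory:
    frames: list[np.ndarray] = []
    atoms: list[AtomRecord] = []
    labels: list[str] = []
    current: list[np.ndarray] = []
    model_count = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6].strip()
            if tag == "MODEL":
                model_count += 1
                current = []
            elif tag == "ENDMDL":
                if frames and len(current) != len(frames[0]):
                    raise ValueError(
                        f"model {model_count} has {len(current)} atoms, "
                        f"expected {len(frames[0])}"
                    )
                frames.append(np.array(current))
            elif tag in ("ATOM", "HETATM"):
                altloc = line[16].strip()
                if altloc and altloc != "A":
                    continue  # first altLoc kept
                rec, xyz = _parse_pdb_atom(line, lineno)
                if model_count <= 1 and not frames:
                    atoms.append(rec)
                    labels.append(_label_for(rec))
                current.append(xyz)
    if current and (model_count == 0):
        # plain single-structure PDB without MODEL records
        frames.append(np.array(current))
    if not frames:
        raise ValueError(f"{path}: no coordinates found")
    if len(atoms) != len(frames[0]):
        atoms = atoms[: len(frames[0])]
    return Trajectory(Topology(atoms, labels[: len(atoms)]), np.stack(frames))


_WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3"}
_ION_RESNAMES = {"MG", "NA", "CL", "K", "ZN", "CA", "MN"}
_NUC_RESNAMES = {"A", "U", "G", "C", "DA", "DT", "DG", "DC", "RA", "RU", "RG", "RC"}


def _label_for(rec: AtomRecord) -> str:
    rn = rec.residue_name.upper()
    if rn in _WATER_RESNAMES:
        return "water"
    if rn in _ION_RESNAMES:
        return "ion"
    if rn in _NUC_RESNAMES:
        return "nucleic"
    return "protein"


def _write_pdb(traj: Trajectory, path: Path) -> None:
    top = traj.topology
    with open(path, "w") as fh:
        for imodel, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {imodel:4d}\n")
            for a, xyz in zip(top.atoms, frame):
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {a.serial:5d} {name:<4.4s} {a.residue_name:<3.3s} "
                    f"{a.chain_id:1.1s}{a.residue_id:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{a.occupancy:6.2f}{a.temp_factor:6.2f}"
                    f"          {a.element:>2.2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# frame-dump dialect

def _read_frame_dump(path: Path) -> Trajectory:
    with open(path) as fh:
        lines = fh.read().splitlines()
    it = iter(enumerate(lines, start=1))
    natoms = None
    frames: list[np.ndarray] = []
    times: list[float] = []
    current: list[list[float]] | None = None
    for lineno, raw in it:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0] == "natoms":
            natoms = int(fields[1])
        elif fields[0] == "frame":
            if current is not None:
                if len(current) != natoms:
                    raise ValueError(
                        f"model {len(frames) + 1} has {len(current)} atoms, "
                        f"expected {natoms}"
                    )
                frames.append(np.array(current))
            times.append(float(fields[1]) if len(fields) > 1 else float(len(times)))
            current = []
        else:
            if current is None or natoms is None:
                raise ValueError(f"line {lineno}: coordinates before header")
            try:
                current.append([float(v) for v in fields[:3]])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: unparsable coordinate field") from exc
    if current is not None:
        if len(current) != natoms:
            raise ValueError(
                f"model {len(frames) + 1} has {len(current)} atoms, expected {natoms}"
            )
        frames.append(np.array(current))
    if not frames:
        raise ValueError(f"{path}: no frames found")
    atoms = [
        AtomRecord(serial=i + 1, name="CA", residue_name="GLY", residue_id=i + 1)
        for i in range(natoms)
    ]
    t = np.array(times)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        t = np.arange(len(frames), dtype=float)
    return Trajectory(Topology(atoms), np.stack(frames), frame_times=t)


def _write_frame_dump(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# trajscope frame-dump\n")
        fh.write(f"natoms {traj.n_atoms}\n")
        for t, frame in zip(traj.frame_times, traj.frames):
            fh.write(f"frame {t:g}\n")
            for xyz in frame:
                fh.write(f"{xyz[0]:.3f} {xyz[1]:.3f} {xyz[2]:.3f}\n")


def read_structure(path: str | Path, dialect: str = "pdb-multimodel") -> Trajectory:
    """Read a trajectory; each MODEL block / frame record becomes one frame.

    Atom metadata is taken from the first model. Raises a hard error naming
    the model index on an inconsistent atom count, and the line number on an
    unparsable coordinate field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if dialect == "pdb-multimodel":
        return _read_pdb(path)
    if dialect == "frame-dump":
        return _read_frame_dump(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_structure(traj: Trajectory, path: str | Path, dialect: str = "pdb-multimodel") -> None:
    """Write a trajectory; round-trips coordinates at 3-decimal (mÅ) precision."""
    if traj.n_frames == 0:
        raise ValueError("cannot write an empty trajectory")
    path = Path(path)
    if dialect == "pdb-multimodel":
        _write_pdb(traj, path)
    elif dialect == "frame-dump":
        _write_frame_dump(traj, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# selection language
#
# Grammar (whitespace-separated):
#   expr     := term ("or" term)*
#   term     := factor ("and" factor)*
#   factor   := "(" expr ")" | predicate
#   predicate:= "name" NAME+ | "resid" RANGE+ | "chain" ID+ | "molecule" LABEL+
#   RANGE    := INT | INT "-" INT

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _Parser:
    def __init__(self, expr: str, top: Topology):
        self.tokens = _TOKEN_RE.findall(expr)
        self.pos = 0
        self.top = top
        if not self.tokens:
            raise ValueError("empty selection expression")

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> set[int]:
        result = self.expr()
        if self.peek() is not None:
            raise ValueError(f"unexpected token {self.peek()!r}")
        return result

    def expr(self) -> set[int]:
        out = self.term()
        while self.peek() == "or":
            self.next()
            out = out | self.term()
        return out

    def term(self) -> set[int]:
        out = self.factor()
        while self.peek() == "and":
            self.next()
            out = out & self.factor()
        return out

    def factor(self) -> set[int]:
        tok = self.peek()
        if tok == "(":
            self.next()
            out = self.expr()
            if self.next() != ")":
                raise ValueError("unbalanced parenthesis in selection")
            return out
        return self.predicate()

    def _values(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek() not in ("and", "or", ")", "(",
                                                              "name", "resid",
                                                              "chain", "molecule"):
            vals.append(self.next())
        if not vals:
            raise ValueError("predicate requires at least one value")
        return vals

    def predicate(self) -> set[int]:
        key = self.next()
        atoms = self.top.atoms
        if key == "name":
            wanted = set(self._values())
            return {i for i, a in enumerate(atoms) if a.name in wanted}
        if key == "chain":
            wanted = set(self._values())
            return {i for i, a in enumerate(atoms) if a.chain_id in wanted}
        if key == "molecule":
            wanted = set(self._values())
            labels = self.top.molecule_labels
            return {i for i in range(len(atoms)) if labels[i] in wanted}
        if key == "resid":
            hits: set[int] = set()
            for v in self._values():
                m = re.fullmatch(r"(\d+)(?:-(\d+))?", v)
                if not m:
                    raise ValueError(f"bad resid range {v!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                hits |= {i for i, a in enumerate(atoms) if lo <= a.residue_id <= hi}
            return hits
        raise ValueError(f"unknown selection keyword {key!r}")


def select(top: Topology, expr: str, label: str | None = None) -> Selection:
    """Evaluate a selection expression; deterministic and order-preserving.

    Supports atom-name match, residue-id ranges, chain ids, molecule labels,
    and ``and``/``or`` combinations with parentheses, e.g.
    ``"name CA and resid 20-100"``. An empty result is legal.
    """
    hits = _Parser(expr, top).parse()
    return Selection(tuple(sorted(hits)), label=label if label is not None else expr)


def selection_from_indices(indices: Iterable[int], n_atoms: int, label: str = "") -> Selection:
    idx = tuple(int(i) for i in indices)
    if any(i < 0 or i >= n_atoms for i in idx):
        raise ValueError("selection index out of range")
    return Selection(idx, label=label)


# ---------------------------------------------------------------------------
# parameter tables

@dataclass
class ParameterTable:
    """Force-field parameters keyed by (residue_name, atom_name); '*' wildcards."""

    rows: dict[tuple[str, str], dict[str, float]]

    def lookup(self, residue_name: str, atom_name: str) -> dict[str, float] | None:
        for key in (
            (residue_name, atom_name),
            (residue_name, "*"),
            ("*", atom_name),
            ("*", "*"),
        ):
            if key in self.rows:
                return self.rows[key]
        return None


_PARAM_FIELDS = ("charge", "lj_sigma", "lj_epsilon", "born_radius", "vdw_radius", "mass")


def read_parameter_table(path: str | Path) -> ParameterTable:
    """Read a tab-separated parameter table with a header line."""
    rows: dict[tuple[str, str], dict[str, float]] = {}
    with open(path) as fh:
        header = fh.readline().split()
        cols = header[2:]
        unknown = set(cols) - set(_PARAM_FIELDS)
        if header[:2] != ["residue_name", "atom_name"] or unknown:
            raise ValueError(f"bad parameter table header: {header}")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            rows[(fields[0], fields[1])] = {
                c: float(v) for c, v in zip(cols, fields[2:])
            }
    return ParameterTable(rows)


def write_parameter_table(top: Topology, path: str | Path) -> None:
    """Write one table row per (residue_name, atom_name) from a topology.

    Inverse of :func:`read_parameter_table` for fully parameterized
    topologies whose (residue_name, atom_name) pairs are unique.
    """
    with open(path, "w") as fh:
        fh.write("residue_name\tatom_name\t" + "\t".join(_PARAM_FIELDS) + "\n")
        seen = set()
        for a in top.atoms:
            key = (a.residue_name, a.name)
            if key in seen:
                continue
            seen.add(key)
            vals = [getattr(a, f) for f in _PARAM_FIELDS]
            if any(v is None for v in vals):
                raise ValueError(f"atom {a.serial} is not fully parameterized")
            fh.write(f"{a.residue_name}\t{a.name}\t"
                     + "\t".join(f"{v:g}" for v in vals) + "\n")


def assign_parameters(top: Topology, table: ParameterTable, strict: bool = False) -> Topology:
    """Return a new topology with charge/LJ/Born/mass fields populated.

    Unmatched atoms keep their previous values; in strict mode an unmatched
    atom is a hard error listing it.
    """
    new_atoms = []
    unmatched = []
    for a in top.atoms:
        row = table.lookup(a.residue_name, a.name)
        if row is None:
            unmatched.append(f"{a.residue_name}{a.residue_id}:{a.name}")
            new_atoms.append(replace(a))
        else:
            new_atoms.append(replace(a, **row))
    if strict and unmatched:
        raise ValueError("unparameterized atoms: " + ", ".join(unmatched))
    out = Topology(new_atoms, list(top.molecule_labels))
    out.unmatched_atoms = unmatched  # type: ignore[attr-defined]
    return out
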