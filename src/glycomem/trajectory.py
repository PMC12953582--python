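"""Trajectory data model, readers and writers.

Coordinates are Ångström throughout, time is nanoseconds, frames are
0-based. The on-disk formats are (a) fixed-column multi-model PDB
(``MODEL``/``ENDMDL`` blocks, one block per frame) and (b) a strict
columnar "frame table" CSV dialect with header
``frame,atom_id,atom_name,residue_name,residue_number,chain_id,x,y,z``.

Both readers validate the structural invariant that every frame carries
the same atoms (same count, same atom_id → name/residue/chain mapping),
so that an atom selection resolved on frame 0 is valid on every frame.
Periodic-boundary images are not handled: inputs are assumed whole.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParseError, SelectionError, StructureError

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "Selection",
    "MetricSeries",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_frame_table",
    "write_frame_table",
    "resolve_selection",
    "write_metric_csv",
]

FRAME_TABLE_HEADER = "frame,atom_id,atom_name,residue_name,residue_number,chain_id,x,y,z"


@dataclass(frozen=True)
class AtomRecord:
    """One atom in one frame.

    ``b_factor`` carries the PDB B-factor column when present; AlphaFold
    model files store the per-residue pLDDT confidence there.
    """

    atom_id: int
    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    b_factor: float | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_id}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def identity(self) -> tuple:
        """Key used to check frame-to-frame consistency of the atom map."""
        return (self.atom_id, self.atom_name, self.residue_name,
                self.residue_number, self.chain_id)


@dataclass
class Frame:
    """An ordered snapshot of atoms; ``time_ns`` is optional."""

    index: int
    atoms: list[AtomRecord]
    time_ns: float | None = None

    def __post_init__(self) -> None:
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise StructureError(f"frame {self.index}: duplicate atom_id")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class Trajectory:
    """An ordered list of structurally identical frames."""

    frames: list[Frame]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructureError("a trajectory needs at least one frame")
        for i, fr in enumerate(self.frames):
            if fr.index != i:
                raise StructureError(
                    f"frame indices must be consecutive from 0; got {fr.index} at position {i}")
        ref = [a.identity for a in self.frames[0].atoms]
        for fr in self.frames[1:]:
            if [a.identity for a in fr.atoms] != ref:
                raise StructureError(
                    f"frame {fr.index} does not carry the same atoms as frame 0 "
                    f"({fr.n_atoms} vs {self.frames[0].n_atoms} atoms or differing identities)")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    def coords(self, atom_indices: Sequence[int] | None = None) -> np.ndarray:
        """Stacked (n_frames, n_atoms, 3) coordinates, optionally subset."""
        arr = np.stack([fr.coords for fr in self.frames])
        if atom_indices is not None:
            arr = arr[:, list(atom_indices), :]
        return arr

    @property
    def times_ns(self) -> np.ndarray | None:
        ts = [fr.time_ns for fr in self.frames]
        if any(t is None for t in ts):
            return None
        return np.asarray(ts, dtype=float)


@dataclass(frozen=True)
class Selection:
    """Predicate over atom metadata: AND across fields, OR within each list.

    A ``None`` field places no constraint. Atom-name matching is exact,
    case-sensitive and whitespace-stripped, because the metric definitions
    name individual atoms (e.g. Arg NH1/NH2, Neu5Ac O11/O12).
    """

    label: str
    atom_name: tuple[str, ...] | None = None
    residue_name: tuple[str, ...] | None = None
    residue_number: tuple[int, ...] | None = None
    chain_id: tuple[str, ...] | None = None

    @classmethod
    def from_dict(cls, spec: dict) -> "Selection":
        def _tup(key, cast):
            v = spec.get(key)
            if v is None:
                return None
            if not isinstance(v, (list, tuple)):
                v = [v]
            return tuple(cast(x) for x in v)

        return cls(
            label=str(spec.get("label", "selection")),
            atom_name=_tup("atom_name", lambda s: str(s).strip()),
            residue_name=_tup("residue_name", lambda s: str(s).strip()),
            residue_number=_tup("residue_number", int),
            chain_id=_tup("chain_id", lambda s: str(s).strip()),
        )

    def matches(self, atom: AtomRecord) -> bool:
        if self.atom_name is not None and atom.atom_name.strip() not in self.atom_name:
            return False
        if self.residue_name is not None and atom.residue_name.strip() not in self.residue_name:
            return False
        if self.residue_number is not None and atom.residue_number not in self.residue_number:
            return False
        if self.chain_id is not None and atom.chain_id.strip() not in self.chain_id:
            return False
        return True


@dataclass
class MetricSeries:
    """A per-frame scalar trace with a declared unit.

    ``mask`` flags valid frames (True = usable); invalid frames are written
    as empty CSV cells and excluded from occupancy-style summaries.
    """

    name: str
    unit: str  # one of {"degree", "angstrom", "fraction"}
    values: np.ndarray
    mask: np.ndarray | None = None
    times_ns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in {"degree", "angstrom", "fraction"}:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask length must equal values length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


# ---------------------------------------------------------------------------
# PDB reading / writing


def _parse_pdb_atom(line: str, lineno: int) -> AtomRecord:
    try:
        atom_id = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain = line[21:22].strip()
        res_num = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    bfac: float | None = None
    bcol = line[60:66].strip()
    if bcol:
        try:
            bfac = float(bcol)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed B-factor field") from exc
    return AtomRecord(atom_id, name, res_name, res_num, chain,
                      np.array([x, y, z]), b_factor=bfac)


def read_multimodel_pdb(path) -> Trajectory:
    """Read a fixed-column PDB with one frame per ``MODEL`` block.

    A file without MODEL records is read as a single-frame trajectory.
    Occupancy is ignored; the B-factor column is retained (AlphaFold files
    store pLDDT there). Raises :class:`ParseError` naming the line on
    malformed columns and :class:`StructureError` if models disagree on
    their atoms.
    """
    frames: list[Frame] = []
    current: list[AtomRecord] | None = None
    in_model = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6]
            if rec == "MODEL ":
                if in_model:
                    raise ParseError(f"line {lineno}: nested MODEL record")
                in_model = True
                current = []
            elif rec == "ENDMDL":
                if not in_model:
                    raise ParseError(f"line {lineno}: ENDMDL without MODEL")
                frames.append(Frame(index=len(frames), atoms=current))
                current, in_model = None, False
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_pdb_atom(raw.rstrip("\n"), lineno)
                if current is None:
                    current = []
                current.append(atom)
    if in_model:
        raise ParseError("file ended inside an unterminated MODEL block")
    if current:  # single coordinate block without MODEL/ENDMDL
        frames.append(Frame(index=len(frames), atoms=current))
    if not frames:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    try:
        return Trajectory(frames, metadata={"source": str(path), "format": "pdb"})
    except StructureError as exc:
        raise StructureError(f"{path}: inconsistent models: {exc}") from exc


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as fixed-column multi-model PDB (3-decimal coords)."""
    with open(path, "w") as fh:
        for fr in traj.frames:
            fh.write(f"MODEL     {fr.index + 1:4d}\n")
            for a in fr.atoms:
                name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
                b = 0.0 if a.b_factor is None else a.b_factor
                fh.write(
                    f"ATOM  {a.atom_id:5d} {name:<4s} {a.residue_name:<3s} "
                    f"{a.chain_id:1s}{a.residue_number:4d}    "
                    f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                    f"{1.0:6.2f}{b:6.2f}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Frame-table CSV dialect


def read_frame_table(path) -> Trajectory:
    """Read the columnar frame-table dialect (comma-separated, Å).

    The header must match :data:`FRAME_TABLE_HEADER` exactly and frame
    indices must be contiguous from 0.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if header != FRAME_TABLE_HEADER:
        raise FormatError(
            f"{path}: header must be exactly {FRAME_TABLE_HEADER!r}; got {header!r}")
    df = pd.read_csv(path, dtype={"atom_name": str, "residue_name": str, "chain_id": str})
    if df.isnull().any().any():
        raise FormatError(f"{path}: missing values in frame table")
    frame_ids = sorted(df["frame"].unique())
    if frame_ids != list(range(len(frame_ids))):
        raise FormatError(
            f"{path}: frame indices must be contiguous from 0; got {frame_ids}")
    frames = []
    for idx, grp in df.groupby("frame", sort=True):
        atoms = [
            AtomRecord(int(r.atom_id), str(r.atom_name), str(r.residue_name),
                       int(r.residue_number), str(r.chain_id),
                       np.array([r.x, r.y, r.z]))
            for r in grp.itertuples(index=False)
        ]
        frames.append(Frame(index=int(idx), atoms=atoms))
    try:
        return Trajectory(frames, metadata={"source": str(path), "format": "frame_table"})
    except StructureError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_frame_table(traj: Trajectory, path) -> None:
    """Write the canonical frame-table form: 3-decimal coordinates, file order.

    Reading the result back and writing it again reproduces the file
    byte-identically.
    """
    with open(path, "w") as fh:
        fh.write(FRAME_TABLE_HEADER + "\n")
        for fr in traj.frames:
            for a in fr.atoms:
                fh.write(
                    f"{fr.index},{a.atom_id},{a.atom_name},{a.residue_name},"
                    f"{a.residue_number},{a.chain_id},"
                    f"{a.position[0]:.3f},{a.position[1]:.3f},{a.position[2]:.3f}\n")


# ---------------------------------------------------------------------------
# Selections and metric output


def resolve_selection(traj: Trajectory, sel: Selection) -> list[int]:
    """Resolve a selection to an ordered atom-index list (file order).

    The trajectory invariant guarantees the same list is valid on every
    frame. Raises :class:`SelectionError` naming the label if empty.
    """
    idx = [i for i, a in enumerate(traj.frames[0].atoms) if sel.matches(a)]
    if not idx:
        raise SelectionError(f"selection {sel.label!r} matches no atoms")
    return idx


def write_metric_csv(series: Iterable[MetricSeries] | MetricSeries, path) -> None:
    """Write one or more aligned metric series as CSV.

    Columns are ``frame,time_ns,<name1>,...``; masked-out values become
    empty fields (never the string ``nan``). All series must share one
    length; time stamps come from the first series that carries them.
    """
    slist = [series] if isinstance(series, MetricSeries) else list(series)
    if not slist:
        raise ValueError("no series given")
    n = len(slist[0])
    if any(len(s) != n for s in slist):
        raise ValueError("all series must have the same length")
    times = next((s.times_ns for s in slist if s.times_ns is not None), None)
    with open(path, "w") as fh:
        fh.write("frame,time_ns," + ",".join(s.name for s in slist) + "\n")
        for i in range(n):
            t = "" if times is None else f"{times[i]:g}"
            cells = [
                f"{s.values[i]:.6g}" if s.mask[i] and np.isfinite(s.values[i]) else ""
                for s in slist
            ]
            fh.write(f"{i},{t}," + ",".join(cells) + "\n")
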