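"""Structure, trajectory and window-series I/O plus named atom selections.

Frames are lists of point charges with residue/atom labels: the only
structural information the electrostatics needs.  Two on-disk formats are
supported — fixed-column PDB (charges assigned from a separate table, since
coordinates files carry none) and a self-contained "XYZQ" dialect of
extended XYZ that stores coordinates and charges together.  Umbrella-window
coordinate series are plain two-column text.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    InsufficientDataError,
    MissingChargeError,
    ParseError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ChargedFrame",
    "Selection",
    "WindowSeries",
    "read_structure",
    "read_charge_table",
    "read_window_series",
    "resolve_selection",
    "read_xyzq",
    "write_xyzq",
    "solvated_atom_count",
]


@dataclass
class AtomRecord:
    """One atom: identity labels, position (angstrom) and partial charge (e).

    ``charge`` may be ``None`` until assigned from a charge table; every
    other consumer in the package requires it to be set.
    """

    serial: int
    atom_name: str
    residue_name: str
    residue_id: int
    position: np.ndarray
    charge: float | None = None
    chain_id: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.atom_name}")
        if self.charge is not None and not np.isfinite(self.charge):
            raise ValueError(f"non-finite charge for atom {self.atom_name}")
        if self.serial <= 0 or self.residue_id <= 0:
            raise ValueError("serial and residue_id must be positive")

    @property
    def key(self) -> tuple[int, str]:
        return (self.residue_id, self.atom_name)


@dataclass
class ChargedFrame:
    """An environment snapshot: ordered atoms, all charged, at one time (ps)."""

    atoms: list[AtomRecord]
    frame_time: float = 0.0

    def __post_init__(self):
        seen = set()
        for a in self.atoms:
            if a.key in seen:
                raise ValueError(f"duplicate atom key {a.key} in frame")
            seen.add(a.key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def charges(self) -> np.ndarray:
        q = [a.charge for a in self.atoms]
        if any(c is None for c in q):
            missing = next(a for a in self.atoms if a.charge is None)
            raise MissingChargeError(
                f"atom {missing.residue_name}{missing.residue_id}:{missing.atom_name} "
                "has no charge assigned"
            )
        return np.array(q, dtype=float)

    def index_of(self, key: tuple[int, str]) -> int:
        for i, a in enumerate(self.atoms):
            if a.key == (int(key[0]), str(key[1])):
                return i
        raise KeyError(f"no atom with key {key} in frame")


#: a member key is either a whole residue id or a (residue_id, atom_name) pair
MemberKey = Union[int, tuple[int, str]]


@dataclass
class Selection:
    """A named include/exclude set of atoms or whole residues.

    ``mode="exclude"`` selects the complement of the members, which is how
    "all protein atoms except the catalytic triad" is expressed.
    """

    member_keys: set = field(default_factory=set)
    mode: str = "include"

    def __post_init__(self):
        if self.mode not in ("include", "exclude"):
            raise ValueError(f"mode must be include or exclude, got {self.mode!r}")
        self.member_keys = set(self.member_keys)


def resolve_selection(frame: ChargedFrame, sel: Selection) -> list[int]:
    """Resolve a Selection to ascending atom indices of ``frame``.

    Member keys that match no atom are logged as warnings, not errors, so a
    single selection can be reused across mutated variants of a structure.
    """
    residue_members = {k for k in sel.member_keys if isinstance(k, int)}
    atom_members = {
        (int(k[0]), str(k[1])) for k in sel.member_keys if not isinstance(k, int)
    }

    matched_res, matched_atoms = set(), set()
    hit = []
    for i, a in enumerate(frame.atoms):
        in_res = a.residue_id in residue_members
        in_atom = a.key in atom_members
        if in_res:
            matched_res.add(a.residue_id)
        if in_atom:
            matched_atoms.add(a.key)
        if in_res or in_atom:
            hit.append(i)

    for k in residue_members - matched_res:
        logger.warning("selection member residue %s matches no atom", k)
    for k in atom_members - matched_atoms:
        logger.warning("selection member atom %s matches no atom", k)

    if sel.mode == "include":
        return hit
    hit_set = set(hit)
    return [i for i in range(len(frame.atoms)) if i not in hit_set]


@dataclass
class WindowSeries:
    """Time-ordered coordinate samples of one umbrella window (ps, angstrom)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise FormatError("times and values must be equal-length 1-D arrays")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise FormatError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_charge_table(path) -> dict[tuple[str, str], float]:
    """Read a CSV with columns residue_name, atom_name, charge into a dict."""
    df = pd.read_csv(path)
    required = {"residue_name", "atom_name", "charge"}
    if not required.issubset(df.columns):
        raise ParseError(f"charge table {path} must have columns {sorted(required)}")
    return {
        (str(r.residue_name).strip(), str(r.atom_name).strip()): float(r.charge)
        for r in df.itertuples()
    }


def read_structure(
    path,
    charge_table: Mapping[tuple[str, str], float] | None = None,
) -> ChargedFrame:
    """Read a structure file into a ChargedFrame.

    ``.pdb`` files are parsed with fixed wwPDB columns (ATOM/HETATM only;
    highest-occupancy altloc kept, ties resolved to the first encountered);
    charges then come from ``charge_table`` keyed by (residue_name,
    atom_name) — every atom must resolve or MissingChargeError is raised.
    ``.xyzq`` files are self-contained and need no table.
    """
    path = Path(path)
    if path.suffix.lower() == ".xyzq":
        return read_xyzq(path)
    return _read_pdb(path, charge_table)


def _read_pdb(path: Path, charge_table) -> ChargedFrame:
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1, altloc="occupancy", extra_fields=["atom_id"])
    except Exception as exc:  # biotite raises various types on bad columns
        raise ParseError(f"failed to parse PDB {path}: {exc}") from exc

    atoms = []
    for i in range(arr.array_length()):
        resn = str(arr.res_name[i])
        name = str(arr.atom_name[i])
        charge = None
        if charge_table is not None:
            try:
                charge = float(charge_table[(resn, name)])
            except KeyError:
                raise MissingChargeError(
                    f"no charge table entry for atom {resn} {name} "
                    f"(residue {int(arr.res_id[i])})"
                ) from None
        atoms.append(
            AtomRecord(
                serial=int(arr.atom_id[i]),
                atom_name=name,
                residue_name=resn,
                residue_id=int(arr.res_id[i]),
                position=np.asarray(arr.coord[i], dtype=float),
                charge=charge,
                chain_id=str(arr.chain_id[i]),
            )
        )
    return ChargedFrame(atoms=atoms)


def read_window_series(path) -> WindowSeries:
    """Read a two-column (time, value) whitespace text file; '#' comments."""
    times, values = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns, got {s!r}")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field in {s!r}") from exc
    if len(times) < 2:
        raise InsufficientDataError(f"{path}: fewer than 2 samples")
    t = np.asarray(times)
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: times are not strictly increasing")
    return WindowSeries(times=t, values=np.asarray(values))


_XYZQ_FMT = "{elem:<4s} {x:.8f} {y:.8f} {z:.8f} {q:.8f} {rid:d} {rname:s} {aname:s}\n"


def write_xyzq(frame: ChargedFrame, path_or_buf) -> None:
    """Write a ChargedFrame in the XYZQ dialect of extended XYZ.

    Per-atom line: ``element x y z charge residue_id residue_name atom_name``
    with 8-decimal fixed output; the comment line carries the frame time.
    """
    own = isinstance(path_or_buf, (str, Path))
    fh = open(path_or_buf, "w") if own else path_or_buf
    try:
        fh.write(f"{len(frame.atoms)}\n")
        fh.write(f"frame_time_ps={frame.frame_time:.8f}\n")
        for a in frame.atoms:
            elem = a.atom_name[:1] if a.atom_name else "X"
            fh.write(
                _XYZQ_FMT.format(
                    elem=elem,
                    x=a.position[0],
                    y=a.position[1],
                    z=a.position[2],
                    q=a.charge if a.charge is not None else float("nan"),
                    rid=a.residue_id,
                    rname=a.residue_name,
                    aname=a.atom_name,
                )
            )
    finally:
        if own:
            fh.close()


def read_xyzq(path_or_buf) -> ChargedFrame:
    """Read the XYZQ dialect written by :func:`write_xyzq`."""
    own = isinstance(path_or_buf, (str, Path))
    fh = open(path_or_buf) if own else path_or_buf
    try:
        lines = fh.readlines()
    finally:
        if own:
            fh.close()
    if len(lines) < 2:
        raise ParseError("XYZQ file too short")
    try:
        n = int(lines[0].strip())
    except ValueError as exc:
        raise ParseError(f"XYZQ line 1: bad atom count {lines[0]!r}") from exc
    frame_time = 0.0
    comment = lines[1].strip()
    if comment.startswith("frame_time_ps="):
        frame_time = float(comment.split("=", 1)[1])
    atoms = []
    for lineno, line in enumerate(lines[2 : 2 + n], 3):
        parts = line.split()
        if len(parts) != 8:
            raise ParseError(f"XYZQ line {lineno}: expected 8 fields, got {len(parts)}")
        try:
            atoms.append(
                AtomRecord(
                    serial=len(atoms) + 1,
                    atom_name=parts[7],
                    residue_name=parts[6],
                    residue_id=int(parts[5]),
                    position=np.array([float(parts[1]), float(parts[2]), float(parts[3])]),
                    charge=float(parts[4]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"XYZQ line {lineno}: {exc}") from exc
    if len(atoms) != n:
        raise ParseError(f"XYZQ: header promised {n} atoms, found {len(atoms)}")
    return ChargedFrame(atoms=atoms, frame_time=frame_time)


def solvated_atom_count(
    n_protein_atoms: int,
    n_substrate_atoms: int,
    n_water_molecules: int,
    n_counterions: int,
) -> int:
    """Total atom count of a solvated protein–substrate system.

    Three-point waters contribute three atoms each; monoatomic counterions
    one each.  Pure composition bookkeeping for solvated-box sanity checks.
    """
    for v in (n_protein_atoms, n_substrate_atoms, n_water_molecules, n_counterions):
        if v < 0 or int(v) != v:
            raise ValueError("composition counts must be non-negative integers")
    return int(n_protein_atoms + n_substrate_atoms + 3 * n_water_molecules + n_counterions)
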