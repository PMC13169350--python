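"""Structure and trajectory I/O plus the atom/residue/selection data model.

All coordinates are stored internally in nanometres; PDB files (which print
angstroms) are converted on read and write. Residue numbering is taken
verbatim from the source file — author numbering such as "residues 112-116"
survives the round trip unchanged. Gold atoms (element Au) are flagged as
nanoparticle atoms on read; the flag drives the protein/nanoparticle split
used by the interface-contact analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import (
    ConfigError,
    EmptyInputError,
    MalformedTrajectoryError,
    ParseError,
    SelectionError,
)

__all__ = [
    "AtomRecord",
    "Trajectory",
    "RegionScheme",
    "Selection",
    "read_pdb_trajectory",
    "write_pdb_trajectory",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_xvg_series",
    "write_xvg_series",
    "write_bfactor_projection",
    "ATOMIC_MASSES",
]

A_PER_NM = 10.0

#: Atomic masses (g/mol) for the elements the bead and protein models use.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "AU": 196.967,
    "NA": 22.990,
    "CL": 35.45,
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology; identity is (chain_id, residue_id, atom_name)."""

    atom_name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    is_nanoparticle: bool = False

    def __post_init__(self):
        if not self.element:
            raise ConfigError("AtomRecord requires a non-empty element symbol")

    @property
    def mass(self) -> float:
        try:
            return ATOMIC_MASSES[self.element.upper()]
        except KeyError:
            raise ConfigError(f"no mass tabulated for element {self.element!r}")


class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    Parameters
    ----------
    topology:
        Sequence of :class:`AtomRecord`, one per atom, in file order.
    coords:
        Array of shape ``(n_frames, n_atoms, 3)`` in nm.
    times:
        Per-frame times in ns, strictly increasing.
    """

    def __init__(self, topology: Sequence[AtomRecord], coords: np.ndarray,
                 times: np.ndarray):
        self.topology = list(topology)
        coords = np.asarray(coords, dtype=float)
        times = np.asarray(times, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise MalformedTrajectoryError(
                f"coords must have shape (n_frames, n_atoms, 3), got {coords.shape}")
        if coords.shape[1] != len(self.topology):
            raise MalformedTrajectoryError(
                f"{coords.shape[1]} coordinates per frame but "
                f"{len(self.topology)} topology atoms")
        if coords.shape[0] != times.shape[0]:
            raise MalformedTrajectoryError("one time per frame required")
        if not np.all(np.isfinite(coords)):
            raise MalformedTrajectoryError("non-finite coordinates")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise MalformedTrajectoryError("frame times must be strictly increasing")
        seen = set()
        for rec in self.topology:
            key = (rec.chain_id, rec.residue_id, rec.atom_name)
            if key in seen:
                raise MalformedTrajectoryError(f"duplicate atom {key} in topology")
            seen.add(key)
        self.coords = coords
        self.times = times

    # -- basic introspection -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain_id, residue_id) pairs in topology order."""
        out, seen = [], set()
        for rec in self.topology:
            key = (rec.chain_id, rec.residue_id)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def residue_atom_indices(self) -> dict[tuple[str, int], np.ndarray]:
        """Atom indices grouped by (chain_id, residue_id), topology order."""
        groups: dict[tuple[str, int], list[int]] = {}
        for i, rec in enumerate(self.topology):
            groups.setdefault((rec.chain_id, rec.residue_id), []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in groups.items()}

    def masses(self) -> np.ndarray:
        return np.array([rec.mass for rec in self.topology])

    def subset_frames(self, index) -> "Trajectory":
        idx = np.atleast_1d(np.asarray(index, dtype=int))
        return Trajectory(self.topology, self.coords[idx], self.times[idx])


@dataclass(frozen=True)
class RegionScheme:
    """Per-chain residue-id ranges splitting a chain into core and dangling
    (C-terminal tail) regions, e.g. core 39-130 and dangling 131-191."""

    core: tuple[int, int]
    dangling: tuple[int, int]

    def __post_init__(self):
        c0, c1 = self.core
        d0, d1 = self.dangling
        if c1 < c0 or d1 < d0:
            raise ConfigError("region ranges must be (low, high) with low <= high")
        if max(c0, d0) <= min(c1, d1):
            raise ConfigError("core and dangling regions must be disjoint")

    def core_selection(self, chains: Iterable[str] | None = None) -> "Selection":
        return Selection.residue_range(*self.core, chains=chains)

    def dangling_selection(self, chains: Iterable[str] | None = None) -> "Selection":
        return Selection.residue_range(*self.dangling, chains=chains)


@dataclass(frozen=True)
class Selection:
    """Declarative atom selection; `None` criteria match everything.

    Resolution against a topology returns atom indices in topology order,
    duplicate-free, and is idempotent.
    """

    chains: frozenset[str] | None = None
    residue_ids: frozenset[int] | None = None
    atom_names: frozenset[str] | None = None
    elements: frozenset[str] | None = None
    nanoparticle: bool | None = None
    predicate: Callable[[AtomRecord], bool] | None = None

    @staticmethod
    def all() -> "Selection":
        return Selection()

    @staticmethod
    def protein() -> "Selection":
        return Selection(nanoparticle=False)

    @staticmethod
    def gold() -> "Selection":
        return Selection(nanoparticle=True)

    @staticmethod
    def residue_range(low: int, high: int,
                      chains: Iterable[str] | None = None) -> "Selection":
        return Selection(
            chains=frozenset(chains) if chains is not None else None,
            residue_ids=frozenset(range(low, high + 1)),
            nanoparticle=False,
        )

    @staticmethod
    def of_atoms(names: Iterable[str], **kw) -> "Selection":
        return Selection(atom_names=frozenset(names), **kw)

    def matches(self, rec: AtomRecord) -> bool:
        if self.chains is not None and rec.chain_id not in self.chains:
            return False
        if self.residue_ids is not None and rec.residue_id not in self.residue_ids:
            return False
        if self.atom_names is not None and rec.atom_name not in self.atom_names:
            return False
        if self.elements is not None and rec.element.upper() not in {
                e.upper() for e in self.elements}:
            return False
        if self.nanoparticle is not None and rec.is_nanoparticle != self.nanoparticle:
            return False
        if self.predicate is not None and not self.predicate(rec):
            return False
        return True

    def resolve(self, topology: Sequence[AtomRecord]) -> np.ndarray:
        idx = [i for i, rec in enumerate(topology) if self.matches(rec)]
        return np.asarray(idx, dtype=int)

    def resolve_nonempty(self, topology: Sequence[AtomRecord]) -> np.ndarray:
        idx = self.resolve(topology)
        if idx.size == 0:
            raise SelectionError("selection resolved to zero atoms")
        return idx


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _element_of(element: str, atom_name: str) -> str:
    el = element.strip()
    if not el:
        # fall back on the first alphabetic character of the atom name
        letters = [c for c in atom_name if c.isalpha()]
        el = letters[0] if letters else ""
    return el.upper() if len(el) > 1 else el


def read_pdb_trajectory(path, default_stride_ns: float = 1.0) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Each MODEL block becomes one frame; frame times are ``index * stride``
    since PDB carries no time column. Au rows are flagged as nanoparticle
    atoms. Coordinates are converted from angstrom to nm.
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise EmptyInputError(f"{path}: no models found")
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on inconsistent models
        raise MalformedTrajectoryError(f"{path}: inconsistent MODEL blocks ({exc})")
    if stack.array_length() == 0:
        raise EmptyInputError(f"{path}: models contain no atoms")
    topology = []
    for i in range(stack.array_length()):
        el = _element_of(stack.element[i], stack.atom_name[i])
        topology.append(AtomRecord(
            atom_name=str(stack.atom_name[i]),
            element=el,
            residue_name=str(stack.res_name[i]),
            residue_id=int(stack.res_id[i]),
            chain_id=str(stack.chain_id[i]),
            is_nanoparticle=(el.upper() == "AU"),
        ))
    coords = np.asarray(stack.coord, dtype=float) / A_PER_NM
    times = np.arange(n_models, dtype=float) * default_stride_ns
    return Trajectory(topology, coords, times)


def _stack_from_trajectory(topology: Sequence[AtomRecord], coords_nm: np.ndarray,
                           b_factors: np.ndarray | None = None) -> struc.AtomArrayStack:
    n_frames, n_atoms = coords_nm.shape[0], len(topology)
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = np.asarray(coords_nm, dtype=np.float32) * A_PER_NM
    stack.chain_id = np.array([r.chain_id for r in topology])
    stack.res_id = np.array([r.residue_id for r in topology])
    stack.res_name = np.array([r.residue_name for r in topology])
    stack.atom_name = np.array([r.atom_name for r in topology])
    el = np.array([r.element.upper() for r in topology])
    stack.element = el
    stack.hetero = np.array([r.is_nanoparticle for r in topology])
    if b_factors is not None:
        stack.add_annotation("b_factor", dtype=float)
        stack.b_factor = np.asarray(b_factors, dtype=float)
    return stack


def write_pdb_trajectory(traj: Trajectory, path) -> None:
    """Write a :class:`Trajectory` as a multi-model PDB file (angstrom)."""
    pdb = PDBFile()
    pdb.set_structure(_stack_from_trajectory(traj.topology, traj.coords))
    pdb.write(str(path))


def write_bfactor_projection(topology: Sequence[AtomRecord], frame_nm: np.ndarray,
                             residue_values: dict[tuple[str, int], float],
                             path) -> None:
    """Write one frame as a PDB with per-residue values in the B-factor column.

    Every atom of a residue carries the residue's value; residues missing
    from ``residue_values`` get 0.0; values are clipped to [0, 999.99] to fit
    the fixed-width column (printed with 2 decimals).
    """
    frame_nm = np.asarray(frame_nm, dtype=float)
    b = np.array([
        float(residue_values.get((r.chain_id, r.residue_id), 0.0))
        for r in topology
    ])
    b = np.clip(b, 0.0, 999.99)
    pdb = PDBFile()
    pdb.set_structure(_stack_from_trajectory(topology, frame_nm[None, :, :], b))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz_trajectory(path, topology: Sequence[AtomRecord],
                        default_stride_ns: float = 1.0) -> Trajectory:
    """Read a multi-frame XYZ file (angstrom) onto a supplied topology.

    The comment line is scanned for ``t= <value>`` (ns); if absent, frame
    times default to ``index * default_stride_ns``.
    """
    lines = Path(path).read_text().splitlines()
    frames, times = [], []
    i, n_expected = 0, len(topology)
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}")
        if n != n_expected:
            raise MalformedTrajectoryError(
                f"{path}:{i + 1}: frame has {n} atoms but topology has {n_expected}")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t = _parse_xyz_time(comment)
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise MalformedTrajectoryError(f"{path}: truncated final frame")
        coords = np.empty((n, 3))
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{i + 3 + j}: malformed XYZ atom line")
            try:
                coords[j] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(f"{path}:{i + 3 + j}: non-numeric coordinate")
        frames.append(coords / A_PER_NM)
        times.append(t)
        i += 2 + n
    if not frames:
        raise EmptyInputError(f"{path}: no frames found")
    if any(t is None for t in times):
        times = [k * default_stride_ns for k in range(len(frames))]
    return Trajectory(topology, np.stack(frames), np.asarray(times, dtype=float))


def _parse_xyz_time(comment: str) -> float | None:
    tokens = comment.replace("=", "= ").split()
    for k, tok in enumerate(tokens):
        if tok in ("t=", "time=") and k + 1 < len(tokens):
            try:
                return float(tokens[k + 1])
            except ValueError:
                return None
    return None


def write_xyz_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory in multi-frame XYZ (angstrom, 6 decimals)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"t= {traj.times[f]:.6f} ns\n")
            for rec, xyz in zip(traj.topology, traj.coords[f] * A_PER_NM):
                fh.write(f"{rec.element:<3s} {xyz[0]:12.6f} {xyz[1]:12.6f} "
                         f"{xyz[2]:12.6f}\n")


# ---------------------------------------------------------------------------
# XVG-style two-column series
# ---------------------------------------------------------------------------

def read_xvg_series(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an XVG-style text series: '#'/'@' lines are comments, data lines
    carry >= 2 numeric columns. Returns (time, value) arrays in file order."""
    t, v = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#") or s.startswith("@"):
                continue
            parts = s.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: fewer than 2 columns")
            try:
                t.append(float(parts[0]))
                v.append(float(parts[1]))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric token")
    if not t:
        raise EmptyInputError(f"{path}: no data lines")
    return np.asarray(t), np.asarray(v)


def write_xvg_series(times: np.ndarray, values: np.ndarray, path,
                     title: str = "") -> None:
    with open(path, "w") as fh:
        if title:
            fh.write(f"@ title \"{title}\"\n")
        fh.write("# written by nptraj\n")
        for t, v in zip(times, values):
            fh.write(f"{t:.6f} {v:.8g}\n")
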