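"""Structure and trajectory I/O for the troponin analysis pipeline.

Reads topologies from PDB files and trajectory frames from multi-model PDB
or DCD files (via MDAnalysis), resolves residue-range selections of the form
``"TnC:3-85:CA"``, and writes frames back out.  Residue numbering is 1-based
author numbering throughout, with inclusive ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "SelectionExpr",
    "StructureError",
    "SelectionError",
    "DEFAULT_CHAIN_MAP",
    "read_topology",
    "read_trajectory",
    "resolve_selection",
    "parse_selection",
    "write_frames",
    "write_pdb_model",
]

#: Default chain-ID -> subunit mapping (1J1D chain convention).
DEFAULT_CHAIN_MAP: dict[str, str] = {"A": "TnC", "B": "TnI", "C": "TnT"}

#: Residue names recognised as phosphoserine.
PHOSPHOSERINE = {"SEP"}


class StructureError(ValueError):
    """Raised on malformed structure or trajectory input."""


class SelectionError(ValueError):
    """Raised when a selection expression cannot be resolved."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology, in file order."""

    atom_name: str
    element: str
    subunit: str
    residue_number: int
    residue_name: str
    atom_index: int


def _infer_element(atom_name: str) -> str:
    """Guess element from a PDB atom name when the element column is absent."""
    name = atom_name.strip()
    if not name:
        return ""
    # Names like "1HB2" / "HG21": leading digits then H means hydrogen.
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] == "H":
        return "H"
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "MN"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


class Topology:
    """Ordered atom table with subunit labels and fast selection arrays."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        if not atoms:
            raise StructureError("topology contains no atoms")
        self.atoms: list[AtomRecord] = list(atoms)
        self.names = np.array([a.atom_name for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])
        self.subunits = np.array([a.subunit for a in self.atoms])
        self.resids = np.array([a.residue_number for a in self.atoms], dtype=int)
        self.resnames = np.array([a.residue_name for a in self.atoms])
        self.subunit_ranges: dict[str, tuple[int, int]] = {}
        for su in dict.fromkeys(self.subunits.tolist()):
            mask = self.subunits == su
            self.subunit_ranges[su] = (int(self.resids[mask].min()), int(self.resids[mask].max()))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    @property
    def has_hydrogens(self) -> bool:
        return bool((self.elements == "H").any())

    def has_phosphoserine(self) -> bool:
        return bool(np.isin(self.resnames, list(PHOSPHOSERINE)).any())

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (subunit, residue_number) keys in topology order."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.subunit, a.residue_number), None)
        return list(seen)


@dataclass
class Frame:
    """Coordinates (Angstrom) of one trajectory frame."""

    coordinates: np.ndarray  # (n_atoms, 3)
    frame_index: int
    run_id: int


class Trajectory:
    """Frames of one or more independent runs over a shared topology.

    Coordinates are stored as a single ``(n_frames, n_atoms, 3)`` float64
    array; ``run_ids`` records which run each frame belongs to.
    """

    def __init__(self, topology: Topology, coordinates: np.ndarray, run_ids: np.ndarray):
        coordinates = np.asarray(coordinates, dtype=float)
        if coordinates.ndim != 3 or coordinates.shape[1] != topology.n_atoms:
            raise StructureError(
                f"coordinate array shape {coordinates.shape} does not match "
                f"topology with {topology.n_atoms} atoms"
            )
        if not np.isfinite(coordinates).all():
            raise StructureError("non-finite coordinates in trajectory")
        self.topology = topology
        self.coordinates = coordinates
        self.run_ids = np.asarray(run_ids, dtype=int)
        if len(self.run_ids) != len(coordinates):
            raise StructureError("run_ids length does not match frame count")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_runs(self) -> int:
        return len(np.unique(self.run_ids))

    def frames_per_run(self) -> dict[int, int]:
        uniq, counts = np.unique(self.run_ids, return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))

    def frame_labels(self) -> list[tuple[int, int]]:
        """(run_id, frame_index) labels; frame_index counts within each run."""
        labels = []
        counters: dict[int, int] = {}
        for rid in self.run_ids.tolist():
            idx = counters.get(rid, 0)
            labels.append((rid, idx))
            counters[rid] = idx + 1
        return labels

    def __iter__(self) -> Iterator[Frame]:
        for i, (rid, fidx) in enumerate(self.frame_labels()):
            yield Frame(self.coordinates[i], fidx, rid)

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class SelectionExpr:
    """Residue-range selection: subunit, inclusive 1-based range, atom filter."""

    subunit: str
    lo: int
    hi: int
    atom_filter: str = "CA"  # one of CA / heavy / all

    def __post_init__(self):
        if self.lo > self.hi:
            raise SelectionError(f"range lo {self.lo} > hi {self.hi}")
        if self.atom_filter not in ("CA", "heavy", "all"):
            raise SelectionError(f"unknown atom filter {self.atom_filter!r}")

    def __str__(self) -> str:
        return f"{self.subunit}:{self.lo}-{self.hi}:{self.atom_filter}"


def parse_selection(text: str) -> SelectionExpr:
    """Parse ``"TnC:3-85:CA"`` (filter optional, default CA)."""
    parts = text.strip().split(":")
    if len(parts) not in (2, 3):
        raise SelectionError(f"cannot parse selection {text!r}")
    subunit, rng = parts[0], parts[1]
    filt = parts[2] if len(parts) == 3 else "CA"
    if "-" in rng:
        lo_s, hi_s = rng.split("-", 1)
    else:
        lo_s = hi_s = rng
    try:
        lo, hi = int(lo_s), int(hi_s)
    except ValueError as exc:
        raise SelectionError(f"bad residue range in {text!r}") from exc
    return SelectionExpr(subunit, lo, hi, filt)


def resolve_selection(topology: Topology, expr: SelectionExpr | str) -> np.ndarray:
    """Resolve a selection to an ordered array of atom indices.

    The CA filter keeps exactly one atom (the alpha carbon) per residue.
    Raises :class:`SelectionError` when nothing matches.
    """
    if isinstance(expr, str):
        expr = parse_selection(expr)
    mask = (
        (topology.subunits == expr.subunit)
        & (topology.resids >= expr.lo)
        & (topology.resids <= expr.hi)
    )
    if expr.atom_filter == "CA":
        mask &= topology.names == "CA"
    elif expr.atom_filter == "heavy":
        mask &= topology.heavy_mask()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(
            f"selection {expr} matched no atoms "
            f"(known subunits: {sorted(topology.subunit_ranges)})"
        )
    return idx


def resolve_selection_union(topology: Topology, exprs: Iterable[SelectionExpr | str]) -> np.ndarray:
    """Ordered union of several selections (one pooled atom set)."""
    parts = [resolve_selection(topology, e) for e in exprs]
    return np.unique(np.concatenate(parts))


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def read_topology(path: str | Path, chain_map: Mapping[str, str] | None = None) -> Topology:
    """Read a PDB topology; chain IDs are mapped to subunit labels.

    Unmapped chain IDs pass through as their own subunit label.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"topology file not found: {path}")
    chain_map = dict(DEFAULT_CHAIN_MAP if chain_map is None else chain_map)
    mda = _import_mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    atoms = []
    seen_serial: dict = {}
    for i, a in enumerate(u.atoms):
        chain = (getattr(a, "chainID", "") or getattr(a, "segid", "") or "").strip()
        element = (getattr(a, "element", "") or "").strip()
        if not element:
            element = _infer_element(a.name)
        serial = getattr(a, "id", i)
        if serial in seen_serial:
            raise StructureError(f"duplicate atom serial {serial} in {path}")
        seen_serial[serial] = True
        atoms.append(
            AtomRecord(
                atom_name=a.name.strip(),
                element=element.capitalize() if len(element) > 1 else element.upper(),
                subunit=chain_map.get(chain, chain or "?"),
                residue_number=int(a.resid),
                residue_name=a.resname.strip(),
                atom_index=i,
            )
        )
    return Topology(atoms)


def read_trajectory(paths: Sequence[str | Path], topology: Topology) -> Trajectory:
    """Concatenate trajectory files; ``run_id`` is the path ordinal.

    Each file may be a multi-model PDB or a DCD with the topology's atom count.
    """
    mda = _import_mda()
    coords_blocks: list[np.ndarray] = []
    run_ids: list[int] = []
    for run, p in enumerate([Path(p) for p in paths]):
        if not p.exists():
            raise StructureError(f"trajectory file not found: {p}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if p.suffix.lower() == ".dcd":
                u = mda.Universe.empty(topology.n_atoms, trajectory=True)
                u.load_new(str(p))
            else:
                u = mda.Universe(str(p))
        if len(u.atoms) != topology.n_atoms:
            raise StructureError(
                f"{p}: atom count {len(u.atoms)} does not match topology "
                f"({topology.n_atoms})"
            )
        block = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
        coords_blocks.append(block)
        run_ids.extend([run] * len(block))
    if not coords_blocks:
        raise StructureError("no trajectory paths given")
    return Trajectory(topology, np.concatenate(coords_blocks, axis=0), np.array(run_ids))


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_SUBUNIT_CHAIN = {"TnC": "A", "TnI": "B", "TnT": "C"}


def _chain_for(subunit: str) -> str:
    if subunit in _SUBUNIT_CHAIN:
        return _SUBUNIT_CHAIN[subunit]
    return subunit[:1] if subunit else "X"


def _pdb_atom_line(serial: int, a: AtomRecord, xyz: np.ndarray) -> str:
    name = a.atom_name
    # PDB columns 13-16: element-aligned names for <4-char names
    name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"ATOM  {serial:>5d} {name_f}{'':1s}{a.residue_name:>3s} "
        f"{_chain_for(a.subunit):1s}{a.residue_number:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {a.element:>2s}"
    )


def write_pdb_model(topology: Topology, coordinates: np.ndarray, path: str | Path) -> None:
    """Write a single-model PDB (e.g. a representative structure)."""
    lines = [
        _pdb_atom_line(i + 1, a, coordinates[i]) for i, a in enumerate(topology.atoms)
    ]
    Path(path).write_text("\n".join(lines) + "\nEND\n")


def write_frames(
    topology: Topology,
    coordinates: np.ndarray,
    path: str | Path,
    fmt: str | None = None,
) -> None:
    """Write frames as a multi-model PDB (default) or a DCD.

    PDB coordinates are written at 3 decimals (the format's native precision);
    round-tripping reproduces coordinates to that precision.
    """
    path = Path(path)
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.ndim == 2:
        coordinates = coordinates[None]
    if fmt is None:
        fmt = "dcd" if path.suffix.lower() == ".dcd" else "pdb"
    if fmt == "pdb":
        out = []
        for m, frame in enumerate(coordinates, start=1):
            out.append(f"MODEL     {m:>4d}")
            out.extend(
                _pdb_atom_line(i + 1, a, frame[i]) for i, a in enumerate(topology.atoms)
            )
            out.append("ENDMDL")
        out.append("END")
        path.write_text("\n".join(out) + "\n")
    elif fmt == "dcd":
        mda = _import_mda()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.coordinates.DCD.DCDWriter(str(path), n_atoms=topology.n_atoms) as w:
                u = mda.Universe.empty(topology.n_atoms, trajectory=True)
                for frame in coordinates:
                    u.atoms.positions = frame
                    w.write(u.atoms)
    else:
        raise StructureError(f"unknown trajectory format {fmt!r}")
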